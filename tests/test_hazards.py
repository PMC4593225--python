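"""Gompertz cause-specific hazards: closed forms against quadrature,
inversion round-trips, cumulative incidence conservation, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from ccbias import (
    CalibrationError,
    CauseSpecificHazard,
    GompertzBaseline,
    calibrate_scale,
    cumulative_hazard,
    cumulative_incidence,
    hazard,
    hwe_probs,
    invert_total_cumulative_hazard,
)

# spec-style construction under the rate reading: shape is the growth rate
# and equals the hazard at the mode
DEATH_RATE = GompertzBaseline(85.0, 0.0004, "rate")
DISEASE_STEEP = GompertzBaseline(25.0, 0.95, "rate")
DISEASE_MILD = GompertzBaseline(50.0, 0.1, "rate")
DEATH_DIST = GompertzBaseline(85.0, 0.0004, "distribution")


def quad_cumhaz(h: CauseSpecificHazard, g: int, t: float) -> float:
    """Independent oracle: numerical quadrature of the hazard."""
    val, _ = integrate.quad(lambda s: hazard(h, g, s), 0.0, t, epsrel=1e-10, limit=200)
    return val


# a mix of rate- and distribution-parameterized hazard pairs for property tests
def _random_hazard_pair(seed: int):
    rng = np.random.default_rng(seed)
    def one(param):
        mode = rng.uniform(20.0, 90.0)
        shape = rng.uniform(0.01, 0.5) if param == "rate" else rng.uniform(1e-4, 0.9)
        return CauseSpecificHazard(
            GompertzBaseline(mode, shape, param),
            scale=10 ** rng.uniform(-3, 0),
            log_irr=rng.uniform(-1.0, 1.0),
        )
    return one(rng.choice(["rate", "distribution"])), one(rng.choice(["rate", "distribution"]))


class TestHazard:
    def test_hazard_at_mode_equals_shape_under_rate_reading(self):
        h = CauseSpecificHazard(DEATH_RATE)
        assert hazard(h, 0, 85.0) == pytest.approx(0.0004, rel=1e-12)

    def test_hazard_at_mode_equals_derived_rate_under_distribution_reading(self):
        h = CauseSpecificHazard(DEATH_DIST)
        b = math.log(1.0 / 0.0004) / 85.0
        assert hazard(h, 0, 85.0) == pytest.approx(b, rel=1e-12)

    def test_zero_scale_annihilates(self):
        h = CauseSpecificHazard(DISEASE_MILD, scale=0.0, log_irr=0.3)
        assert hazard(h, 2, 40.0) == 0.0
        assert cumulative_hazard(h, 2, 40.0) == 0.0

    def test_genotype_multiplier(self):
        h = CauseSpecificHazard(DISEASE_STEEP, scale=1.0, log_irr=math.log(2.0))
        assert hazard(h, 2, 25.0) == pytest.approx(0.95 * 4.0, rel=1e-12)

    def test_density_mode_is_mode_under_both_readings(self):
        # the density f(t) = h(t) exp(-H(t)) peaks at the stated mode
        for base in (DEATH_DIST, GompertzBaseline(50.0, 0.1, "rate")):
            h = CauseSpecificHazard(base)
            t = np.linspace(base.mode - 5, base.mode + 5, 2001)
            f = hazard(h, 0, t) * np.exp(-cumulative_hazard(h, 0, t))
            assert t[np.argmax(f)] == pytest.approx(base.mode, abs=0.01)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            hazard(CauseSpecificHazard(DEATH_RATE), 0, -1.0)

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            hazard(CauseSpecificHazard(DEATH_RATE), 3, 10.0)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            GompertzBaseline(-1.0, 0.1)
        with pytest.raises(ValueError):
            GompertzBaseline(50.0, 1.2, "distribution")


class TestCumulativeHazard:
    def test_zero_at_origin(self):
        assert cumulative_hazard(CauseSpecificHazard(DEATH_RATE), 1, 0.0) == 0.0

    def test_death_rate_reading_value_at_90(self):
        # closed form e^{-0.034} (e^{0.036} - 1), checked against quadrature
        h = CauseSpecificHazard(DEATH_RATE)
        val = cumulative_hazard(h, 0, 90.0)
        assert val == pytest.approx(0.035431, abs=1e-6)
        assert val == pytest.approx(quad_cumhaz(h, 0, 90.0), rel=1e-8)

    def test_linear_in_scale(self):
        h1 = CauseSpecificHazard(DISEASE_MILD, scale=0.005)
        h2 = CauseSpecificHazard(DISEASE_MILD, scale=0.010)
        assert cumulative_hazard(h2, 1, 70.0) == pytest.approx(
            2.0 * cumulative_hazard(h1, 1, 70.0), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_quadrature(self, seed):
        dis, death = _random_hazard_pair(seed)
        for h in (dis, death):
            for t in (10.0, 45.0, 88.0):
                assert cumulative_hazard(h, 1, t) == pytest.approx(
                    quad_cumhaz(h, 1, t), rel=1e-8
                )

    @pytest.mark.parametrize("seed", range(3))
    def test_numerical_derivative_matches_hazard(self, seed):
        dis, _ = _random_hazard_pair(seed)
        ts = np.linspace(5.0, 85.0, 9)
        eps = 1e-5
        for t in ts:
            num = (
                cumulative_hazard(dis, 1, t + eps) - cumulative_hazard(dis, 1, t - eps)
            ) / (2 * eps)
            assert num == pytest.approx(hazard(dis, 1, t), rel=1e-5)


class TestInversion:
    def test_zero_target_maps_to_zero(self):
        dis = CauseSpecificHazard(DISEASE_MILD, scale=0.01)
        death = CauseSpecificHazard(DEATH_DIST)
        assert invert_total_cumulative_hazard(dis, death, 0, 0.0) == 0.0

    def test_death_only_inverse_of_cumhaz_at_90(self):
        dis = CauseSpecificHazard(DISEASE_MILD, scale=0.0)
        death = CauseSpecificHazard(DEATH_RATE)
        target = cumulative_hazard(death, 0, 90.0)
        t = invert_total_cumulative_hazard(dis, death, 0, target)
        assert t == pytest.approx(90.0, abs=1e-6)
        assert invert_total_cumulative_hazard(dis, death, 0, 0.035431) == pytest.approx(
            90.0, abs=0.01
        )

    def test_both_scales_zero_rejected(self):
        dis = CauseSpecificHazard(DISEASE_MILD, scale=0.0)
        death = CauseSpecificHazard(DEATH_DIST, scale=0.0)
        with pytest.raises(ValueError):
            invert_total_cumulative_hazard(dis, death, 0, 1.0)

    @given(st.integers(0, 10_000), st.floats(1.0, 89.0), st.integers(0, 2))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_round_trip(self, seed, t, g):
        dis, death = _random_hazard_pair(seed)
        e = cumulative_hazard(dis, g, t) + cumulative_hazard(death, g, t)
        assert invert_total_cumulative_hazard(dis, death, g, e) == pytest.approx(
            t, abs=1e-6
        )

    def test_vectorized_matches_scalar(self):
        dis, death = _random_hazard_pair(123)
        g = np.array([0, 1, 2, 1])
        e = np.array([0.01, 0.4, 1.3, 0.0])
        vec = invert_total_cumulative_hazard(dis, death, g, e)
        for i in range(4):
            assert vec[i] == pytest.approx(
                invert_total_cumulative_hazard(dis, death, int(g[i]), float(e[i])),
                abs=1e-9,
            )


class TestCumulativeIncidence:
    def test_zero_disease_scale_gives_zero(self):
        dis = CauseSpecificHazard(DISEASE_MILD, scale=0.0)
        death = CauseSpecificHazard(DEATH_DIST)
        assert cumulative_incidence(dis, death, 1, 90.0) == 0.0

    def test_no_competing_event_reduces_to_marginal_cdf(self):
        dis = CauseSpecificHazard(DISEASE_MILD, scale=0.01)
        death = CauseSpecificHazard(DEATH_DIST, scale=0.0)
        for t in (30.0, 60.0, 90.0):
            expected = 1.0 - math.exp(-cumulative_hazard(dis, 1, t))
            assert cumulative_incidence(dis, death, 1, t) == pytest.approx(
                expected, rel=1e-7
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_probability_conservation(self, seed):
        dis, death = _random_hazard_pair(seed)
        for g in (0, 2):
            t = 80.0
            cif_d = cumulative_incidence(dis, death, g, t)
            cif_m = cumulative_incidence(death, dis, g, t)
            surv = math.exp(
                -(cumulative_hazard(dis, g, t) + cumulative_hazard(death, g, t))
            )
            assert cif_d + cif_m + surv == pytest.approx(1.0, abs=1e-6)


class TestCalibration:
    def test_monotone_in_target(self, baselines):
        death = CauseSpecificHazard(baselines["death"])
        c_rare = calibrate_scale(baselines["disease_late"], death, 0.25, 0.025)
        c_common = calibrate_scale(baselines["disease_late"], death, 0.25, 0.22)
        assert 0 < c_rare < c_common <= 1

    @pytest.mark.parametrize("target", [0.025, 0.22])
    def test_round_trip_achieves_target(self, baselines, target):
        death = CauseSpecificHazard(baselines["death"])
        c = calibrate_scale(baselines["disease_early"], death, 0.25, target)
        dis = CauseSpecificHazard(baselines["disease_early"], scale=c)
        w = hwe_probs(0.25)
        achieved = sum(
            w[g] * cumulative_incidence(dis, death, g, 90.0) for g in range(3)
        )
        assert achieved == pytest.approx(target, abs=1e-6)

    def test_deterministic(self, baselines):
        death = CauseSpecificHazard(baselines["death"])
        c1 = calibrate_scale(baselines["disease_late"], death, 0.25, 0.22)
        c2 = calibrate_scale(baselines["disease_late"], death, 0.25, 0.22)
        assert c1 == c2

    def test_unattainable_target_rejected(self, baselines):
        # under the distribution reading the early-onset disease cannot
        # reach a 22% lifetime risk against textbook mortality
        steep_dist = GompertzBaseline(25.0, 0.95, "distribution")
        death = CauseSpecificHazard(baselines["death"])
        with pytest.raises(CalibrationError):
            calibrate_scale(steep_dist, death, 0.25, 0.22)

    def test_bad_inputs_rejected(self, baselines):
        death = CauseSpecificHazard(baselines["death"])
        with pytest.raises(ValueError):
            calibrate_scale(baselines["disease_late"], death, 0.6, 0.1)
        with pytest.raises(ValueError):
            calibrate_scale(baselines["disease_late"], death, 0.25, 0.0)
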