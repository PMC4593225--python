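"""Shared fixtures: scenario factory with memoised calibration, and a
hand-built cohort constructor for design-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from ccbias import (
    DEATH_BASELINE,
    DISEASE_EARLY_BASELINE,
    DISEASE_LATE_BASELINE,
    Cohort,
    GompertzBaseline,
    ScenarioConfig,
    cached_scale,
)


@pytest.fixture(scope="session")
def make_scenario():
    """Factory for study scenarios with the calibrated disease scale
    resolved once per (baseline, rarity) pair."""

    def _make(
        disease_baseline: GompertzBaseline = DISEASE_LATE_BASELINE,
        rarity_target: float = 0.22,
        irr_disease: float = 1.0,
        irr_death: float = 1.0,
        maf: float = 0.25,
        n_individuals: int = 10_000,
        censor_age: float = 90.0,
    ) -> ScenarioConfig:
        return ScenarioConfig(
            maf=maf,
            irr_disease=irr_disease,
            irr_death=irr_death,
            disease_baseline=disease_baseline,
            death_baseline=DEATH_BASELINE,
            rarity_target=rarity_target,
            disease_scale=cached_scale(
                disease_baseline, DEATH_BASELINE, maf, rarity_target, censor_age
            ),
            n_individuals=n_individuals,
            censor_age=censor_age,
        )

    return _make


@pytest.fixture()
def make_cohort():
    """Build a cohort directly from per-individual (time, event[, genotype])."""

    def _make(times, events, genotypes=None, censor_age: float = 90.0) -> Cohort:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=object)
        if genotypes is None:
            genotypes = np.zeros(len(times), dtype=np.int64)
        return Cohort(
            genotype=np.asarray(genotypes, dtype=np.int64),
            time=times,
            event=events,
            censor_age=censor_age,
        )

    return _make


@pytest.fixture(scope="session")
def baselines():
    return {
        "death": DEATH_BASELINE,
        "disease_early": DISEASE_EARLY_BASELINE,
        "disease_late": DISEASE_LATE_BASELINE,
    }
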