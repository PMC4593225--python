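"""Replicate loops, replicate-averaged summaries, sign-based empirical
p-values, the analytic large-sample oracle, and full grid sweeps.

The study design: for every cell of a (MAF x IRR_disease x IRR_death x
disease baseline x rarity) grid, simulate R independent cohorts, draw both
case-control designs from each, fit the matching estimator, and average the
R log-scale estimates. The test of no association uses the replicate sign
distribution: with q the proportion of replicate estimates below zero and
m their mean, the two-sided empirical p-value is 2q when m > 0 and
2(1 - q) otherwise (capped at 1; resolution 2/R).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import ScenarioConfig, simulate_cohort
from .designs import (
    DegenerateDesignError,
    sample_classical,
    sample_incidence_density,
)
from .estimators import AssociationEstimate, fit_conditional_logistic, fit_logistic
from .hazards import (
    DEATH_BASELINE,
    DISEASE_EARLY_BASELINE,
    DISEASE_LATE_BASELINE,
    CauseSpecificHazard,
    GompertzBaseline,
    cached_scale,
    cumulative_incidence,
    hwe_probs,
)

__all__ = [
    "DESIGNS",
    "GridConfig",
    "ReplicateSummary",
    "replicate_rngs",
    "run_replicates",
    "empirical_p",
    "summarize",
    "analytic_or",
    "run_grid",
]

DESIGNS = ("classical", "classical_age_adjusted", "incidence_density")

RESULT_COLUMNS = [
    "maf", "irr_disease", "irr_death", "disease_mode", "disease_shape",
    "disease_parameterization", "death_mode", "death_shape",
    "death_parameterization", "rarity_target", "n_individuals", "design",
    "mean_log_estimate", "mean_estimate", "empirical_p", "empirical_p_uncapped",
    "n_used", "n_degenerate", "analytic_log_or", "true_log_irr",
]


@dataclass(frozen=True)
class GridConfig:
    """The full simulation grid: lists of scenario parameters, replicate
    count, base seed, designs to run and output path. Defaults mirror the
    published grid (960 scenarios, 1000 replicates of 10,000 individuals)."""

    maf: Sequence[float] = (0.1, 0.25, 0.5)
    irr_disease: Sequence[float] = (0.5, 1.0, 1.1, 1.2, 1.5, 1.7, 2.0, 3.0)
    irr_death: Sequence[float] = (0.5, 0.75, 0.9, 1.0, 1.1, 1.2, 1.5, 1.7, 2.0, 3.0)
    disease_baselines: Sequence[GompertzBaseline] = (
        DISEASE_EARLY_BASELINE,
        DISEASE_LATE_BASELINE,
    )
    death_baseline: GompertzBaseline = DEATH_BASELINE
    rarity_targets: Sequence[float] = (0.22, 0.025)
    n_individuals: int = 10_000
    n_replicates: int = 1000
    censor_age: float = 90.0
    controls_per_case: int = 5
    base_seed: int = 0
    designs: Sequence[str] = DESIGNS
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("maf", "irr_disease", "irr_death", "disease_baselines", "rarity_targets"):
            if not len(getattr(self, name)):
                raise ValueError(f"grid list {name} must be non-empty")
        unknown = set(self.designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs {sorted(unknown)}; choose from {DESIGNS}")

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "disease_baselines" in kwargs:
            kwargs["disease_baselines"] = [
                _baseline_from_mapping(b, default_param="rate")
                for b in kwargs["disease_baselines"]
            ]
        if "death_baseline" in kwargs:
            kwargs["death_baseline"] = _baseline_from_mapping(
                kwargs["death_baseline"], default_param="distribution"
            )
        return cls(**kwargs)

    def scenarios(self) -> list[ScenarioConfig]:
        """Cross-product of the grid lists, in a fixed deterministic order."""
        out = []
        for base, target, f, ird, irm in itertools.product(
            self.disease_baselines, self.rarity_targets, self.maf,
            self.irr_disease, self.irr_death,
        ):
            out.append(
                ScenarioConfig(
                    maf=f, irr_disease=ird, irr_death=irm,
                    disease_baseline=base, death_baseline=self.death_baseline,
                    rarity_target=target,
                    disease_scale=cached_scale(base, self.death_baseline, f, target,
                                               self.censor_age),
                    n_individuals=self.n_individuals, censor_age=self.censor_age,
                    controls_per_case=self.controls_per_case,
                )
            )
        return out


def _baseline_from_mapping(b: dict, default_param: str) -> GompertzBaseline:
    return GompertzBaseline(
        float(b["mode"]), float(b["shape"]),
        str(b.get("parameterization", default_param)),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-averaged association for one (scenario, design) cell."""

    scenario: ScenarioConfig
    design: str
    mean_log_estimate: float
    mean_estimate: float
    empirical_p: float
    empirical_p_uncapped: float
    n_used: int
    n_degenerate: int

    @property
    def missing(self) -> bool:
        return self.n_used == 0




def replicate_rngs(base_seed: int, scenario_index: int, r: int):
    """Three independent generators (cohort, classical draw, matched draw)
    deterministically derived from (base seed, scenario index, replicate)."""
    ss = np.random.SeedSequence((base_seed, scenario_index, r))
    return [np.random.default_rng(child) for child in ss.spawn(3)]


def run_replicates(
    scenario: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    designs: Sequence[str] = DESIGNS,
    scenario_index: int = 0,
) -> dict[str, list[AssociationEstimate]]:
    """Simulate ``n_replicates`` cohorts and fit every requested design.

    Deterministic given (scenario, n_replicates, base_seed, scenario_index).
    A degenerate replicate (no cases, separation, non-convergence) never
    aborts the loop; it is recorded as a non-converged estimate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    scenario = _with_resolved_scale(scenario)
    results: dict[str, list[AssociationEstimate]] = {d: [] for d in designs}
    want_classical = any(d.startswith("classical") for d in designs)
    for r in range(n_replicates):
        rng_cohort, rng_classical, rng_matched = replicate_rngs(base_seed, scenario_index, r)
        cohort = simulate_cohort(scenario, rng_cohort)
        if want_classical:
            try:
                cc = sample_classical(
                    cohort, ratio=scenario.controls_per_case,
                    censor_age=scenario.censor_age, rng=rng_classical,
                )
            except DegenerateDesignError:
                cc = None
            for d in designs:
                if not d.startswith("classical"):
                    continue
                if cc is None:
                    results[d].append(_degenerate(d))
                else:
                    results[d].append(fit_logistic(cc, adjust_age=(d == "classical_age_adjusted")))
        if "incidence_density" in designs:
            try:
                md = sample_incidence_density(
                    cohort, m=scenario.controls_per_case, rng=rng_matched
                )
                results["incidence_density"].append(fit_conditional_logistic(md))
            except DegenerateDesignError:
                results["incidence_density"].append(_degenerate("incidence_density"))
    return results


def _degenerate(design: str) -> AssociationEstimate:
    return AssociationEstimate(np.nan, np.nan, design, False, 0, 0)


def _with_resolved_scale(scenario: ScenarioConfig) -> ScenarioConfig:
    if scenario.disease_scale is not None:
        return scenario
    return replace(scenario, disease_scale=scenario.resolve_scale())


def empirical_p(log_estimates: Sequence[float], capped: bool = True) -> float:
    """Two-sided sign-based empirical p-value over replicate estimates.

    With q the proportion of estimates below 0: returns 2q when the mean
    estimate is positive, else 2(1 - q); capped at 1 unless ``capped`` is
    False (the raw formula can exceed 1).
    """
    est = np.asarray(log_estimates, dtype=float)
    if est.size == 0:
        raise ValueError("empirical_p needs at least one estimate")
    q = float(np.mean(est < 0))
    m = float(np.mean(est))
    p = 2.0 * q if m > 0 else 2.0 * (1.0 - q)
    return min(1.0, p) if capped else p


def summarize(
    scenario: ScenarioConfig,
    design: str,
    estimates: Sequence[AssociationEstimate],
    arithmetic_mean: bool = False,
) -> ReplicateSummary:
    """Average the usable replicate estimates and attach the empirical p.

    Averaging is on the log scale (the regression coefficients), then
    exponentiated; ``arithmetic_mean`` instead averages the exponentiated
    estimates, as a sensitivity analysis. Non-converged replicates are
    excluded and counted as degenerate.
    """
    usable = np.array([e.log_estimate for e in estimates if e.converged])
    n_degenerate = len(estimates) - usable.size
    if usable.size == 0:
        return ReplicateSummary(scenario, design, np.nan, np.nan, np.nan, np.nan,
                                0, n_degenerate)
    mean_log = float(np.mean(usable))
    mean_est = float(np.mean(np.exp(usable))) if arithmetic_mean else math.exp(mean_log)
    return ReplicateSummary(
        scenario=scenario, design=design,
        mean_log_estimate=mean_log, mean_estimate=mean_est,
        empirical_p=empirical_p(usable),
        empirical_p_uncapped=empirical_p(usable, capped=False),
        n_used=int(usable.size), n_degenerate=int(n_degenerate),
    )


def analytic_or(scenario: ScenarioConfig, survivors_only: bool = False) -> float:
    """Deterministic large-sample log odds ratio for the classical design.

    Computes P(disease by censor age | g) for g in {0, 1, 2} by quadrature,
    forms the expected case and control genotype distributions implied by
    the design's eligibility rule (controls are the never-diseased, at the
    1:m ratio), and fits the one-covariate logistic model to those expected
    proportions. The fitted slope is the estimate the classical design
    converges to as n and R grow.
    """
    scenario = _with_resolved_scale(scenario)
    dis, death = scenario.hazards()
    w = hwe_probs(scenario.maf)
    cif = np.array([
        cumulative_incidence(dis, death, g, scenario.censor_age) for g in (0, 1, 2)
    ])
    if survivors_only:
        from .hazards import cumulative_hazard
        surv = np.array([
            math.exp(-(cumulative_hazard(dis, g, scenario.censor_age)
                       + cumulative_hazard(death, g, scenario.censor_age)))
            for g in (0, 1, 2)
        ])
        ctrl_mass = w * surv
    else:
        ctrl_mass = w * (1.0 - cif)
    case_mass = w * cif
    if case_mass.sum() == 0:
        raise ValueError("disease never occurs under this scenario")
    # expected counts at the design's case:control ratio
    wcase = case_mass / case_mass.sum()
    wctrl = scenario.controls_per_case * ctrl_mass / ctrl_mass.sum()
    return _weighted_logistic_slope(np.array([0.0, 1.0, 2.0]), wcase, wctrl)


def _weighted_logistic_slope(g: np.ndarray, wcase: np.ndarray, wctrl: np.ndarray) -> float:
    """Newton fit of logit p = b0 + b1*g to expected genotype counts."""
    X = np.column_stack([np.ones_like(g), g])
    y_w = np.concatenate([wcase, np.zeros_like(wctrl)])
    n_w = np.concatenate([wcase, wctrl])
    XX = np.vstack([X, X])
    beta = np.zeros(2)
    for _ in range(100):
        p = expit(XX @ beta)
        grad = XX.T @ (y_w - n_w * p)
        hess = (XX * (n_w * p * (1 - p))[:, None]).T @ XX
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(beta[1])


def run_grid(grid: GridConfig, progress: bool = False) -> pd.DataFrame:
    """Run every (scenario, design) cell of the grid.

    Results are written incrementally to ``grid.output`` (TSV) when set, and
    the sweep is resumable: cells already present in the output file are
    skipped. Deterministic given the base seed.
    """
    out_path = Path(grid.output) if grid.output else None
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_path is not None and out_path.exists():
        existing = pd.read_csv(out_path, sep="\t")
        rows = existing.to_dict("records")
        done = {_row_key(r) for r in rows}
    elif out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)

    scenarios = grid.scenarios()
    for idx, scenario in enumerate(scenarios):
        pending = [d for d in grid.designs
                   if _scenario_key(scenario, d) not in done]
        if not pending:
            continue
        estimates = run_replicates(
            scenario, grid.n_replicates, grid.base_seed,
            designs=pending, scenario_index=idx,
        )
        analytic = analytic_or(scenario)
        for d in pending:
            summ = summarize(scenario, d, estimates[d])
            row = _summary_row(summ, analytic)
            rows.append(row)
            done.add(_row_key(row))
            if out_path is not None:
                pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
                    out_path, sep="\t", index=False, float_format="%.10g"
                )
        if progress:
            print(f"[{idx + 1}/{len(scenarios)}] {_scenario_key(scenario, '')[:-1]}",
                  flush=True)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _summary_row(summ: ReplicateSummary, analytic: float) -> dict:
    s = summ.scenario
    return {
        "maf": s.maf, "irr_disease": s.irr_disease, "irr_death": s.irr_death,
        "disease_mode": s.disease_baseline.mode, "disease_shape": s.disease_baseline.shape,
        "disease_parameterization": s.disease_baseline.parameterization,
        "death_mode": s.death_baseline.mode, "death_shape": s.death_baseline.shape,
        "death_parameterization": s.death_baseline.parameterization,
        "rarity_target": s.rarity_target, "n_individuals": s.n_individuals,
        "design": summ.design,
        "mean_log_estimate": summ.mean_log_estimate,
        "mean_estimate": summ.mean_estimate,
        "empirical_p": summ.empirical_p,
        "empirical_p_uncapped": summ.empirical_p_uncapped,
        "n_used": summ.n_used, "n_degenerate": summ.n_degenerate,
        "analytic_log_or": analytic,
        "true_log_irr": math.log(s.irr_disease),
    }


def _scenario_key(s: ScenarioConfig, design: str) -> tuple:
    return (round(s.maf, 10), round(s.irr_disease, 10), round(s.irr_death, 10),
            round(s.disease_baseline.mode, 10), round(s.disease_baseline.shape, 10),
            s.disease_baseline.parameterization, round(s.rarity_target, 10), design)


def _row_key(row: dict) -> tuple:
    return (round(float(row["maf"]), 10), round(float(row["irr_disease"]), 10),
            round(float(row["irr_death"]), 10), round(float(row["disease_mode"]), 10),
            round(float(row["disease_shape"]), 10), row["disease_parameterization"],
            round(float(row["rarity_target"]), 10), row["design"])
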