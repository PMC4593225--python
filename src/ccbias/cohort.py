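"""Longitudinal cohort simulator: HWE genotypes plus competing-risks event
times by inversion of the total cumulative hazard.

Each simulated individual carries a single biallelic marker (minor-allele
count drawn under Hardy-Weinberg equilibrium) and experiences the first of
two competing events — disease or death — or is censored at ``censor_age``.
Event times follow the standard competing-risks generation scheme: the
waiting time to *any* event is drawn by inverting the total cumulative
hazard at an Exponential(1) deviate, and the event type is then disease
with probability equal to the disease share of the total hazard at that
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .hazards import (
    DEATH_BASELINE,
    CauseSpecificHazard,
    GompertzBaseline,
    cached_scale,
    cumulative_hazard,
    hazard,
    hwe_probs,
    invert_total_cumulative_hazard,
)

__all__ = ["ScenarioConfig", "Cohort", "draw_genotypes", "simulate_cohort"]

EVENT_DISEASE = "disease"
EVENT_DEATH = "death"
EVENT_CENSORED = "censored"


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    ``rarity_target`` is the lifetime risk of disease (cumulative incidence
    at ``censor_age``) the disease hazard is calibrated to; alternatively a
    pre-computed ``disease_scale`` may be supplied to skip calibration.
    """

    maf: float
    irr_disease: float
    irr_death: float
    disease_baseline: GompertzBaseline
    death_baseline: GompertzBaseline = DEATH_BASELINE
    rarity_target: Optional[float] = 0.22
    disease_scale: Optional[float] = None
    n_individuals: int = 10_000
    censor_age: float = 90.0
    controls_per_case: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.irr_disease <= 0 or self.irr_death <= 0:
            raise ValueError("incidence rate ratios must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.censor_age <= 0:
            raise ValueError("censor_age must be positive")
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.rarity_target is None and self.disease_scale is None:
            raise ValueError("one of rarity_target or disease_scale is required")

    def resolve_scale(self) -> float:
        """Disease scaling constant: supplied directly, or calibrated so the
        null-effect lifetime risk equals ``rarity_target``."""
        if self.disease_scale is not None:
            return self.disease_scale
        return cached_scale(
            self.disease_baseline,
            self.death_baseline,
            self.maf,
            self.rarity_target,
            self.censor_age,
        )

    def hazards(self) -> tuple[CauseSpecificHazard, CauseSpecificHazard]:
        """The (disease, death) cause-specific hazards for this scenario."""
        dis = CauseSpecificHazard(
            self.disease_baseline,
            scale=self.resolve_scale(),
            log_irr=float(np.log(self.irr_disease)),
        )
        death = CauseSpecificHazard(
            self.death_baseline, scale=1.0, log_irr=float(np.log(self.irr_death))
        )
        return dis, death


@dataclass(frozen=True)
class Cohort:
    """Per-individual genotype, first-event time and event type.

    ``event`` is one of ``disease``, ``death``, ``censored``; ``time`` is the
    age in years of the first event, equal to the censoring age iff the
    individual is censored.
    """

    genotype: np.ndarray
    time: np.ndarray
    event: np.ndarray
    censor_age: float = 90.0

    def __len__(self) -> int:
        return len(self.genotype)

    @property
    def n_cases(self) -> int:
        return int((self.event == EVENT_DISEASE).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "genotype": self.genotype,
                "time": self.time,
                "event": self.event,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, censor_age: Optional[float] = None) -> "Cohort":
        df = pd.read_csv(path, sep="\t")
        missing = {"id", "genotype", "time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort table {path} lacks columns {sorted(missing)}")
        df = df.sort_values("id")
        if censor_age is None:
            cens = df.loc[df["event"] == EVENT_CENSORED, "time"]
            censor_age = float(cens.iloc[0]) if len(cens) else float(df["time"].max())
        return cls(
            genotype=df["genotype"].to_numpy(np.int64),
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(object),
            censor_age=censor_age,
        )


def draw_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. minor-allele counts under Hardy-Weinberg equilibrium."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = hwe_probs(maf)  # validates maf
    u = rng.random(n)
    return (u >= probs[0]).astype(np.int64) + (u >= probs[0] + probs[1])


def simulate_cohort(config: ScenarioConfig, rng: np.random.Generator) -> Cohort:
    """Simulate one cohort under ``config``.

    RNG stream order (fixed for reproducibility): genotype uniforms, then
    waiting-time uniforms, then cause-assignment uniforms.
    """
    dis, death = config.hazards()
    n = config.n_individuals

    g = draw_genotypes(config.maf, n, rng)
    e = -np.log(rng.random(n))  # Exponential(1) total-cumulative-hazard targets
    u_cause = rng.random(n)

    time = np.full(n, config.censor_age)
    event = np.full(n, EVENT_CENSORED, dtype=object)

    # an individual is censored iff their exponential target exceeds the
    # total cumulative hazard at the censoring age
    h_at_censor = cumulative_hazard(dis, g, config.censor_age) + cumulative_hazard(
        death, g, config.censor_age
    )
    active = e < h_at_censor
    if active.any():
        t_event = invert_total_cumulative_hazard(dis, death, g[active], e[active])
        hd = hazard(dis, g[active], t_event)
        hm = hazard(death, g[active], t_event)
        p_disease = np.divide(hd, hd + hm, out=np.zeros_like(hd), where=(hd + hm) > 0)
        is_disease = u_cause[active] < p_disease
        time[active] = t_event
        event[active] = np.where(is_disease, EVENT_DISEASE, EVENT_DEATH)

    return Cohort(genotype=g, time=time, event=event, censor_age=config.censor_age)
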