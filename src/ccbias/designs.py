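"""The two epidemiological sampling designs drawn from a simulated cohort.

Classical (unrelated) case-control sampling: cases are everyone diseased
before the censoring age; controls are sampled uniformly from the
never-diseased (by default including those who died disease-free) at a 1:m
ratio. Each control is assigned a uniformly distributed age covariate; a
case's age is their onset age.

Incidence-density (time-matched) sampling: at each case's onset age, up to
m controls are drawn uniformly without replacement from the risk set — the
individuals whose own event or censoring time lies strictly beyond the
onset age. Individuals may serve as controls for several cases and may
later become cases themselves; excluding future cases would bias the
estimate toward the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EVENT_CENSORED, EVENT_DISEASE, Cohort

__all__ = [
    "CaseControlDataset",
    "MatchedDataset",
    "DegenerateDesignError",
    "sample_classical",
    "sample_incidence_density",
]


class DegenerateDesignError(ValueError):
    """Raised when a cohort yields no usable design (e.g. zero cases)."""


@dataclass(frozen=True)
class CaseControlDataset:
    """Unrelated case-control sample: genotype, case indicator and an age
    covariate (onset age for cases, uniform age for controls)."""

    genotype: np.ndarray
    is_case: np.ndarray
    age: np.ndarray

    def __len__(self) -> int:
        return len(self.genotype)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case.astype(bool)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": self.genotype,
                "is_case": self.is_case.astype(int),
                "age": self.age,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "CaseControlDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(
            genotype=df["genotype"].to_numpy(np.int64),
            is_case=df["is_case"].to_numpy(bool),
            age=df["age"].to_numpy(float),
        )


@dataclass(frozen=True)
class MatchedDataset:
    """Time-matched (1:m) nested case-control sample.

    One matched set per retained case: the case's onset age and genotype,
    plus the genotypes of its sampled risk-set controls (fewer than m when
    the risk set is small). ``n_dropped_sets`` counts cases whose risk set
    was empty.
    """

    match_age: np.ndarray
    case_genotype: np.ndarray
    control_genotypes: list[np.ndarray]
    n_dropped_sets: int = 0
    # provenance within the source cohort (None when loaded from TSV);
    # control_indices records multiplicity when one individual serves
    # several sets
    case_index: np.ndarray | None = None
    control_indices: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.case_genotype)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self)):
            rows.append((i, 1, int(self.case_genotype[i]), float(self.match_age[i])))
            for gc in self.control_genotypes[i]:
                rows.append((i, 0, int(gc), float(self.match_age[i])))
        return pd.DataFrame(rows, columns=["set_id", "is_case", "genotype", "match_age"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "MatchedDataset":
        df = pd.read_csv(path, sep="\t")
        ages, cases, controls = [], [], []
        for _, grp in df.groupby("set_id", sort=True):
            case_rows = grp[grp["is_case"] == 1]
            if len(case_rows) != 1:
                raise ValueError("each matched set must contain exactly one case")
            ages.append(float(case_rows["match_age"].iloc[0]))
            cases.append(int(case_rows["genotype"].iloc[0]))
            controls.append(grp.loc[grp["is_case"] == 0, "genotype"].to_numpy(np.int64))
        return cls(
            match_age=np.asarray(ages),
            case_genotype=np.asarray(cases, dtype=np.int64),
            control_genotypes=controls,
        )


def sample_classical(
    cohort: Cohort,
    ratio: int = 5,
    censor_age: float | None = None,
    rng: np.random.Generator | None = None,
    survivors_only: bool = False,
) -> CaseControlDataset:
    """Draw the unrelated case-control sample.

    Cases are all disease records; eligible controls are everyone never
    diseased — including those who died disease-free, unless
    ``survivors_only`` restricts eligibility to individuals censored alive.
    If more than ``ratio`` controls per case are eligible, controls are
    subsampled uniformly without replacement; otherwise all are kept.
    """
    if rng is None:
        rng = np.random.default_rng()
    if censor_age is None:
        censor_age = cohort.censor_age
    is_case = cohort.event == EVENT_DISEASE
    case_idx = np.flatnonzero(is_case)
    if len(case_idx) == 0:
        raise DegenerateDesignError("cohort contains no disease cases")
    if survivors_only:
        eligible = np.flatnonzero(cohort.event == EVENT_CENSORED)
    else:
        eligible = np.flatnonzero(~is_case)
    n_wanted = ratio * len(case_idx)
    if len(eligible) > n_wanted:
        control_idx = rng.choice(eligible, size=n_wanted, replace=False)
    else:
        control_idx = eligible
    control_ages = rng.uniform(0.0, censor_age, size=len(control_idx))
    return CaseControlDataset(
        genotype=np.concatenate([cohort.genotype[case_idx], cohort.genotype[control_idx]]),
        is_case=np.concatenate(
            [np.ones(len(case_idx), dtype=bool), np.zeros(len(control_idx), dtype=bool)]
        ),
        age=np.concatenate([cohort.time[case_idx], control_ages]),
    )


def sample_incidence_density(
    cohort: Cohort, m: int = 5, rng: np.random.Generator | None = None
) -> MatchedDataset:
    """Draw the 1:m incidence-density (risk-set) sample.

    For each disease case with onset age t, the risk set is every other
    individual whose time is strictly greater than t; min(m, |risk set|)
    controls are drawn uniformly without replacement. Cases with empty risk
    sets are dropped and counted.
    """
    if rng is None:
        rng = np.random.default_rng()
    case_idx = np.flatnonzero(cohort.event == EVENT_DISEASE)
    if len(case_idx) == 0:
        raise DegenerateDesignError("cohort contains no disease cases")

    # individuals ordered by descending time: the risk set at age t is a
    # prefix of this ordering (strict inequality excludes exact ties, and
    # with it the index case itself)
    order = np.argsort(-cohort.time, kind="stable")
    sorted_desc = cohort.time[order]

    ages, case_g, control_g = [], [], []
    kept_case_idx, control_idx = [], []
    n_dropped = 0
    for i in case_idx:
        t = cohort.time[i]
        k = int(np.searchsorted(-sorted_desc, -t, side="left"))  # times > t
        if k == 0:
            n_dropped += 1
            continue
        take = min(m, k)
        picked = order[rng.choice(k, size=take, replace=False)]
        ages.append(t)
        case_g.append(cohort.genotype[i])
        control_g.append(cohort.genotype[picked])
        kept_case_idx.append(i)
        control_idx.append(picked)
    if not ages:
        raise DegenerateDesignError("every matched set had an empty risk set")
    return MatchedDataset(
        match_age=np.asarray(ages, dtype=float),
        case_genotype=np.asarray(case_g, dtype=np.int64),
        control_genotypes=control_g,
        n_dropped_sets=n_dropped,
        case_index=np.asarray(kept_case_idx, dtype=np.int64),
        control_indices=control_idx,
    )
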