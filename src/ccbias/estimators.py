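"""Association estimators for the two designs.

The classical design is analysed with unconditional logistic regression of
case status on minor-allele count (optionally adjusted for a linear age
trend); the fitted slope is the log odds ratio per allele. The time-matched
design is analysed with conditional logistic regression, whose per-set
conditional likelihood

    L_i(beta) = exp(beta * g_case) / sum_{j in set} exp(beta * g_j)

(the sum running over the case and its matched controls) is free of the
age-specific baseline, so the fitted slope estimates the log incidence
rate ratio per allele. With exactly one case per set no tie-handling
method is needed and the likelihood is an exact softmax; it is maximised
here by Newton-Raphson with step-halving (relative log-likelihood
convergence 1e-8, at most 100 iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .designs import CaseControlDataset, MatchedDataset

__all__ = ["AssociationEstimate", "fit_logistic", "fit_conditional_logistic"]

_MAX_ABS_BETA = 30.0  # |log ratio| beyond this is numerically a separation


@dataclass(frozen=True)
class AssociationEstimate:
    """A fitted per-allele association: log OR (classical designs) or log
    IRR (incidence-density design), with its asymptotic standard error."""

    log_estimate: float
    std_err: float
    design: str
    converged: bool
    n_cases: int
    n_controls: int

    @property
    def estimate(self) -> float:
        """The estimate on the ratio scale (OR or IRR)."""
        return float(np.exp(self.log_estimate))


def fit_logistic(data: CaseControlDataset, adjust_age: bool = False) -> AssociationEstimate:
    """Maximum-likelihood logistic regression of case status on genotype.

    Model: logit P(case) = b0 + b1*genotype (+ b2*age when ``adjust_age``).
    Returns b1 and its observed-information standard error. Complete or
    quasi-complete separation and non-convergence are reported through
    ``converged=False`` rather than raised.
    """
    design = "classical_age_adjusted" if adjust_age else "classical"
    n_cases, n_controls = data.n_cases, data.n_controls
    if n_cases == 0 or n_controls == 0:
        raise ValueError("logistic fit needs at least one case and one control")
    if np.ptp(data.genotype) == 0:
        raise ValueError("genotype is constant; the association is unidentifiable")

    cols = [data.genotype.astype(float)]
    if adjust_age:
        cols.append(data.age.astype(float))
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    y = data.is_case.astype(float)

    def failed() -> AssociationEstimate:
        return AssociationEstimate(np.nan, np.nan, design, False, n_cases, n_controls)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
    except (
        PerfectSeparationError,
        ConvergenceWarning,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ):
        return failed()
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not (res.mle_retvals.get("converged", False) and abs(beta) < _MAX_ABS_BETA):
        return failed()
    return AssociationEstimate(beta, se, design, True, n_cases, n_controls)


def _set_loglik_terms(beta: float, case_g, sets_g, sets_len):
    """Flattened per-set softmax terms; returns (loglik, score, information)."""
    # sets_g: flat array of genotypes (case first within each set),
    # sets_len: per-set lengths; computed with segment reductions
    w = np.exp(beta * sets_g)
    seg = np.repeat(np.arange(len(sets_len)), sets_len)
    denom = np.bincount(seg, weights=w)
    mean_g = np.bincount(seg, weights=w * sets_g) / denom
    mean_g2 = np.bincount(seg, weights=w * sets_g**2) / denom
    loglik = float(np.sum(beta * case_g - np.log(denom)))
    score = float(np.sum(case_g - mean_g))
    info = float(np.sum(mean_g2 - mean_g**2))
    return loglik, score, info


def fit_conditional_logistic(data: MatchedDataset) -> AssociationEstimate:
    """Conditional logistic regression on 1:m matched sets.

    Sets in which every member shares one genotype contribute a constant
    to the likelihood and are set aside; if no informative set remains, or
    the likelihood is monotone in beta (separation), the estimate is
    flagged as not converged.
    """
    n_sets = len(data)
    if n_sets == 0:
        raise ValueError("matched dataset is empty")
    n_controls_total = int(sum(len(c) for c in data.control_genotypes))

    def failed() -> AssociationEstimate:
        return AssociationEstimate(
            np.nan, np.nan, "incidence_density", False, n_sets, n_controls_total
        )

    case_g, flat_g, lens = [], [], []
    for gc, gctrl in zip(data.case_genotype, data.control_genotypes):
        members = np.concatenate([[gc], gctrl]).astype(float)
        if np.ptp(members) == 0:  # uninformative: constant genotype
            continue
        case_g.append(float(gc))
        flat_g.append(members)
        lens.append(len(members))
    if not lens:
        return failed()
    case_g = np.asarray(case_g)
    flat_g = np.concatenate(flat_g)
    lens = np.asarray(lens)

    beta, ll_old = 0.0, None
    for _ in range(100):
        ll, score, info = _set_loglik_terms(beta, case_g, flat_g, lens)
        if info <= 0:
            return failed()
        step = score / info
        # step-halving: insist on a likelihood increase
        new_beta = beta + step
        for _ in range(30):
            ll_new, _, _ = _set_loglik_terms(new_beta, case_g, flat_g, lens)
            if ll_new >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta = new_beta
        if abs(beta) > _MAX_ABS_BETA:
            return failed()
        if ll_old is not None and abs(ll_new - ll_old) <= 1e-8 * (abs(ll_old) + 1e-12):
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        return failed()

    # a log-likelihood at (numerically) zero means every case is predicted
    # perfectly — a monotone likelihood, the conditional analogue of
    # complete separation
    if ll_old > -1e-8 * len(lens):
        return failed()

    _, _, info = _set_loglik_terms(beta, case_g, flat_g, lens)
    return AssociationEstimate(
        float(beta), float(1.0 / np.sqrt(info)), "incidence_density", True, n_sets,
        n_controls_total,
    )
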