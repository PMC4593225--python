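# Methods

## The simulated population

The generator produces a closed cohort observed from birth. Each
individual carries one biallelic marker; minor-allele counts are i.i.d.
Hardy–Weinberg draws at a configurable MAF (study grid: 0.1, 0.25, 0.5).
Two competing events, disease and death, act through cause-specific
hazards of Cox multiplicative form

    λ_k(t | g) = c_k · a_k e^{b_k t} · θ_k^g,

with per-allele incidence rate ratios θ_disease (grid: 0.5–3.0) and
θ_death (grid: 0.5–3.0), a disease scaling constant c_disease ≤ 1 and
c_death = 1. Follow-up ends at the first of disease, death, or censoring
at age 90. Post-onset mortality is deliberately out of scope: the model
describes time to *first* event only, so nothing is asserted about
survival after diagnosis.

Waiting times are generated exactly (no discretisation): T solves
Λ_dis(T|g) + Λ_death(T|g) = E with E ~ Exponential(1), where Λ_k is the
closed-form Gompertz cumulative hazard; the root is found by bracketed
elementwise root-finding (bracket width tolerance 1e-10 years) on the
strictly increasing total cumulative hazard. The event is disease with
probability λ_dis(T)/(λ_dis(T)+λ_death(T)). Ties between event times have
probability zero and receive no special handling; the risk-set sampler
uses strict inequalities, so an exact tie would conservatively exclude
the tied individual.

## Gompertz baselines: the mode/shape readings

Baselines are specified by the age M at which the event-time density
peaks and a shape parameter s. Two readings of s are implemented, both
yielding a hazard of the form a·e^{bt}:

* **distribution** — s is the shape parameter η of the standard Gompertz
  distribution (survival exp(−η(e^{bt}−1))); the growth rate follows from
  the mode as b = ln(1/η)/M. Requires η < 1.
* **rate** — s is the growth rate b itself, and the hazard is anchored so
  the density peaks at M: λ(t) = b·e^{b(t−M)}; the hazard at the mode
  then equals s.

The study defaults mix the readings deliberately. The death baseline
(M = 85, s = 4·10⁻⁴) uses the distribution reading: the derived growth
rate, ≈0.092/yr, is the textbook human mortality-doubling rate (doubling
every ≈7.5 years), ≈79% of a cohort dies by 90, and the death-age density
visibly peaks at 85. Under the rate reading the same numbers would give a
nearly flat hazard with only ≈3.5% mortality by 90, i.e. virtually no
competing event and no design effect to study. The two disease baselines
(M = 25, s = 0.95 and M = 50, s = 0.1) use the rate reading: under the
distribution reading the early-onset baseline could never reach a 22%
lifetime risk against that mortality (its ceiling is ≈15%), so a common
early-onset disease would be unrepresentable. This mixed default is the
only combination of readings that is simultaneously consistent with the
stated parameter values, the targeted lifetime risks, and a death hazard
strong enough to act as a genuine competing risk. Both readings remain
selectable per baseline.

One consequence worth knowing: multiplying a steep baseline by a small
constant shifts the bulk of simulated onsets to much later ages than the
baseline's nominal mode (the scaled density for the M = 25, s = 0.95
disease peaks in the 80s). The scaling constant trades lifetime risk
against onset timing; the mode parameter describes the unscaled baseline,
not the calibrated disease.

## Calibration of the disease scale

c_disease solves

    Σ_g HWE(g) · CIF_disease(c, g, 90) = target

with genotype effects at null during calibration, so one constant serves
a whole (baseline, rarity) pair; targets default to 0.22 ("common") and
0.025 ("rare"). The cumulative incidence function is evaluated by
adaptive quadrature (relative tolerance 1e-8) of λ_dis·S_total, with
breakpoints planted where the total cumulative hazard passes through
O(1) so that sharply concentrated integrands are not missed. Because the
constant can be dozens of orders of magnitude below 1 for steep
baselines, the root is bracketed and solved on the log scale; achieved
lifetime risk matches the target to 1e-6 absolute. Calibration is
deterministic and memoised. All numerical tolerances (quadrature 1e-8
relative, inversion 1e-10, calibration 1e-6) sit far below Monte-Carlo
noise at the study's sample sizes, so they never shape results.

## Sampling designs

**Classical case-control.** Cases are all disease records. Eligible
controls are every never-diseased record — including those who died
disease-free, the literal reading of sampling "among all persons not
diseased before age 90"; a `survivors_only` switch restricts eligibility
to individuals censored alive, for sensitivity. When eligible controls
exceed 5 per case they are subsampled uniformly without replacement,
otherwise all are kept. Controls receive a Uniform(0, 90) age covariate;
cases carry their onset age. The optional age adjustment adds this age
linearly to the logistic model.

**Incidence-density.** For each case, the risk set is every other
individual whose event/censoring time strictly exceeds the onset age;
min(5, risk-set size) controls are drawn uniformly without replacement.
Sets with empty risk sets are dropped and counted; undersized sets are
kept (the conditional likelihood handles variable set sizes, and dropping
them would discard information). Individuals may serve several sets and
may later become cases themselves — excluding future cases is a known
source of bias in risk-set sampling, so multiplicity is recorded rather
than prevented.

## Estimators

Unconditional logistic regression is fitted by maximum likelihood
(Newton, relative log-likelihood convergence 1e-8, via statsmodels);
conditional logistic regression maximises the exact per-set softmax
likelihood — one case per set, so no tie-approximation is involved — by
Newton–Raphson with step-halving (same tolerance, at most 100
iterations), with the observed-information standard error. Genotype
enters as a single log-additive covariate in both models. Degenerate
fits — no cases, constant genotype within every set, complete or
monotone separation (detected as a diverging coefficient or a
log-likelihood at numerical zero), or non-convergence — are flagged,
excluded from replicate averages, and counted; they never abort a
replicate loop.

## Replicate machinery and the empirical p-value

Replicate r of scenario i derives its generators from a seed sequence
keyed on (base seed, i, r), with separate child streams for cohort
generation, classical control sampling and matched sampling, so any
single replicate is reproducible in isolation and designs never perturb
each other's randomness. Replicate estimates are averaged on the log
scale and exponentiated (the estimators produce log ratios); an
arithmetic-mean option exists for sensitivity. The two-sided empirical
p-value is 2q when the mean is positive and 2(1−q) otherwise (q = share
of estimates below zero), capped at 1 with the uncapped value kept as a
diagnostic; its resolution is 2/R, so with R = 1000 no p below 0.002 is
observable and genome-wide thresholds are a reporting annotation only.

## The analytic large-sample oracle

For the classical design, the expected genotype distribution among cases
is ∝ HWE(g)·CIF(g) and among controls ∝ HWE(g)·(1−CIF(g)), scaled to the
1:5 ratio; fitting the one-covariate logistic model to these expected
counts (weighted Newton) yields the log OR the design converges to as
both cohort size and replicate count grow. This oracle is deterministic,
independent of the simulator's randomness, and is what the replicate
averages are tested against. At null (both IRRs 1) it is exactly zero;
for a rare disease with no death association it reproduces the classic
rare-disease approximation OR ≈ IRR to within 0.02 on the log scale for
IRRs up to 2.

## What the generator does and does not emulate

It emulates: HWE genotypes at one biallelic marker, proportional-hazards
genotype effects on two competing Gompertz risks, administrative
censoring at a fixed age, and the two control-sampling designs. It does
not emulate: linkage disequilibrium or multiple markers, covariates
beyond genotype and age, time-varying effects or frailty, mortality after
disease onset, emigration or other competing events, or genotyping error.
Passing tests therefore demonstrate properties of the design comparison
under a clean proportional-hazards world, not robustness of either design
to real-data complications such as confounding or broken matching.

## Problem sizes in the tests and acceptance script

The shipped checks run the pipeline at the study's cohort size (10,000;
100,000 for simulator-vs-quadrature agreement) but with 100–200
replicates per scenario rather than 1000, which leaves Monte-Carlo
standard errors of ≈0.003–0.006 on mean log estimates — tight enough for
every comparison made. The full 960-scenario, 1000-replicate grid is
expressed in `configs/paper_defaults.yaml` and runs through the same code
path (resumable, incrementally written TSV).

## Known limitations

* The scaling constants and therefore exact onset-age distributions of
  the original study are not recoverable from its text; calibrated
  lifetime risks (0.22/0.025) reproduce its reported ≈22%/≈2.5% but
  per-scenario cumulative incidences may differ in the second decimal.
* The empirical p-value's 2/R resolution makes very small published
  p-values unreachable by construction; the formula is implemented as
  stated and not extrapolated.
* `analytic_or` describes the unadjusted classical estimate; no analytic
  oracle is provided for the age-adjusted fit (its control ages are
  design noise, not biology).
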