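# Methods

## The problem

Free-range laying hens eat an unknown amount of plant material on top of
their commercial ration. n-Alkanes — saturated straight-chain hydrocarbons
of the plant epicuticular wax, dominated by odd chain lengths C25–C33 —
act as natural internal markers: each dietary component has a
characteristic alkane fingerprint, and the fingerprint excreted in feces is
a mixture of the fingerprints eaten, attenuated marker-by-marker by
incomplete fecal recovery. `alkanediet` turns that observation into a
quantitative estimate of the plant share of dietary dry matter (DM) and a
qualitative diet classification.

## Recovery rates

Recovery of marker *i* in one animal is the standard marker balance

    R_i = (fecal concentration_i × fecal DM output) /
          (dietary concentration_i × DM intake),

daily excretion over daily ingestion (mg/d over mg/d). Recovery is well
below 1 (roughly 0.30–0.48 for these markers in hens) and depends on both
chain length and diet, so diet-specific per-marker means are estimated from
a digestibility-trial-style data set and used to correct fecal profiles.

Values above 1 are biologically impossible in expectation but can occur
under measurement noise; they are kept, with a warning. Whole-panel
("total") recovery — summed output over summed intake, i.e. the
intake-weighted mean of the per-marker recoveries — feeds an explicit
outlier screen: an animal is excluded from the mean aggregation when its
total recovery exceeds an absolute threshold (default 0.60) or lies more
than k = 3.5 scaled median absolute deviations from its diet group's
median. The classic failure mode this catches is an implausibly high
recovery driven by anomalously low feed intake. Both knobs are
configurable; flagged animals stay in the raw observation table so the
exclusion is auditable. Cell means are plain arithmetic means with their
standard errors; for a single animal the SEM is reported as missing, never
as zero.

## The estimator

For each animal and a marker subset S, the corrected fecal concentrations
E*_i = E_i / R(diet, i) are regressed on the component profiles with
non-negative coefficients:

    minimise Σ_{i∈S} (x_f F_i + x_a A_i − E*_i)²   s.t.  x_f, x_a ≥ 0,

solved by the Lawson–Hanson active-set algorithm implemented in this
package (dual tolerance 1e-10 relative to the gradient scale at x = 0,
iteration cap 3 × number of components, entering-variable ties broken by
lowest column index, markers always in ascending carbon order — all of
which makes the solver deterministic). At return the KKT conditions hold:
the dual is ~0 on positive coefficients and non-positive (to tolerance) on
zero ones. The plant proportion is

    p = x_a / (x_a + x_f)   (multi-plant: Σ plant x over total),

reported as explicitly *undefined* when all coefficients are zero.

Two properties shape the numerical choices. First, correction direction:
dividing by recovery maps fecal concentrations back onto an
intake-equivalent scale; it is the direction under which the coefficient
ratio is a DM-*intake* proportion. Second, any rescaling common to all
markers — fecal-DM-to-intake ratio, whole-diet digestibility, a uniform
recovery — multiplies the corrected target by a constant, scales both
coefficients equally, and cancels in p. The tests assert this invariance,
which is also why the generator's digestibility constant needs no empirical
justification. Which recovery column corrects an animal is a caller
decision (`correction_diet`); by default it is the animal's own diet, which
presumes the diet is known — for genuinely unknown diets a control-diet
column is the practical choice, and the circularity of choosing a
correction by the very diet being estimated is inherent to the method, not
to this implementation.

## Error decomposition and subset search

Predictions for a group with known truth are scored by

    bias = mean(e),  variance = population var(e),  MSE = mean(e²),
    RMSE = √MSE,     with e_j = p̂_j − truth,

so MSE = bias² + variance is an exact identity (the population variance,
÷n, is the only choice that makes it one; the test suite checks the
identity to 1e-12 on every emitted metric).

The subset search solves the system for every marker subset from
`min_size` (default 2, and never below the number of components) up to the
full panel — 26 subsets for five markers — and ranks subsets by a
configurable criterion, ascending: RMSE by default, |bias| as an
alternative. Since metrics are computed per diet, the ranked scalar is
evaluated on errors pooled across all animals of all diets; per-diet rows
are reported alongside. Subsets whose estimates are all undefined are kept
in the table with a flag and rank last. Highly correlated markers (C27,
C29, C31 in feces) can make larger subsets *worse* than smaller ones, which
is the phenomenon the search exists to expose.

## Classification

Diet classification uses two-class linear discriminant analysis written
from scratch (it is an analysis step here, not a convenience): class means,
pooled within-class covariance (÷(n − g)), LD directions from the
generalized symmetric eigenproblem between·v = λ·within·v, scaled to unit
pooled within-class score variance, sign fixed so the first nonzero
coefficient is positive. Prediction maximises the pooled-covariance
Gaussian discriminant score with priors equal to observed class
frequencies by default; exact ties go to the first class in model order,
with a warning. Confusion matrices are training-set resubstitution by
default (all animals both fit and score the model); a leave-one-out option
exists behind a flag. A singular pooled covariance (e.g. a zero-variance
marker) raises an error suggesting the optional ridge term; in the
per-marker report such a marker becomes an error row without affecting the
others. The implementation is cross-checked in the tests against a
density-ratio oracle and scikit-learn's LDA.

## The synthetic flock generator

The generator is the package's test bed and ships the published reference
tables as defaults: feed and alfalfa alkane profiles (mg/kg DM), the
analyzed 1%-alfalfa mix, and diet-specific true recoveries. Default study
conditions: 24 hens per diet, DM intake ~ N(70, 5²) g/d truncated to
(0, 80] (a restricted daily allowance), diets {feed: 1.0} and
{feed: 0.99, alfalfa: 0.01}, whole-diet digestibility 0.65 (the estimator
is provably invariant to it), and multiplicative lognormal noise on fecal
concentrations with CV 5% and mean exactly 1 (μ = −σ²/2) — assay error on
a positive quantity is relative, and the mean-1 parameterisation keeps the
recovery correction unbiased in expectation to first order. A
`selectivity_shift` (default 0) moves the realized plant fraction away
from the formulated one, emulating hens sorting a mash; negative values
reproduce under-consumption scenarios. Everything is deterministic given
the seed.

What the generator does *not* emulate: soil- or insect-derived alkane
inputs, between-animal recovery heterogeneity beyond assay noise,
correlated noise across markers, or day-to-day intake variation. Passing
tests therefore demonstrate the pipeline's internal consistency and its
behaviour under idealised marker-balance assumptions — not field accuracy.

A note on the packaged reference tables: the analyzed mixed-feed profile
differs slightly from the calculated 99:1 blend of the component profiles
(e.g. C29 blends to 5.44 but assays at 5.69), and the printed panel totals
of the source tables do not equal the column sums. The package always
computes blends and totals from the component values and treats analyzed
values as data, not as arithmetic to reproduce.

## Problem sizes and tolerances

The test suite and the acceptance script run the generator at the default
study scale (48 animals), 20 seeds for the parameter-recovery summary,
1000 random systems for the NNLS-versus-oracle check, and the full
26-subset search; the whole suite completes in a few seconds. Exact
round-trip assertions use 1e-9; identity checks 1e-12; solver-versus-oracle
1e-6.

## Known limitations

* Two components are the primary use case; the design matrix supports more
  columns, but identifiability degrades quickly with correlated profiles.
* Recovery correction assumes the animal's diet (or a caller-chosen proxy)
  indexes the recovery table; recoveries for genuinely novel diets must be
  extrapolated by the user.
* The outlier rule is a screen, not a model; with fewer than ~4 animals per
  diet the MAD term is uninformative.
* Estimates are proportions only; absolute intake (g/d) estimation via
  dosed even-chain alkanes is out of scope.
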