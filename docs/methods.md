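# Methods

## Data model

One row per participant. The six clustering variables are ordinal visit
frequencies over the past 12 months (GP, diabetologist, diabetes nurse,
dietitian, podiatrist, emergency) with levels never < once < 2-3 < 4+.
Covariates, binary process-of-care indicators and outcome scores follow the
machine-readable data dictionary shipped with the package
(`careprofiles/data_dictionary.json`). Missing values are empty CSV cells;
no imputation is performed anywhere — every model and test applies its own
complete-case restriction and reports the `n_used` it actually estimated
on.

Three coding schemes map the ordinal levels to pseudo-counts:

| scheme       | never | once | 2-3 | 4+  | use                             |
|--------------|-------|------|-----|-----|---------------------------------|
| primary      | 0     | 1    | 2   | 4   | Poisson mixture (main analysis) |
| sensitivity  | 0     | 1    | 3   | 4   | robustness re-run               |
| plot_means   | 0     | 1    | 2.5 | 4   | descriptive mean visits only    |

The top category "4 times and more" is treated as the exact pseudo-count 4
(top-coding acknowledged; no truncated-Poisson correction). Only the two
integer schemes may feed the likelihood.

## Poisson mixture and EM

The 6-vector of pseudo-counts is modelled as a K-component mixture of
independent Poissons, P(y) = Σ_k π_k Π_j Pois(y_j; λ_kj). Conditional
independence of the six providers given the profile is a modelling
assumption, not a claim about the data. EM details:

- Initialization: per-record responsibilities drawn from a flat Dirichlet;
  `n_starts` (default 20) independent restarts, best final log-likelihood
  wins. All restart seeds derive from one required seed.
- M-step: π_k = mean responsibility; λ_kj = responsibility-weighted column
  mean, floored at `rate_floor` = 1e-6 to keep the log-pmf finite.
- Convergence: relative log-likelihood change < 1e-8 (default), cap 1000
  iterations. The reported parameters are exactly those that produced the
  final log-likelihood, so the trace is nondecreasing and consistent.
- Degeneracy: a start whose smallest π_k falls below 1/(10n) is redrawn (up
  to 3 times) before being accepted with a `degenerate` flag; an
  all-identical-rows input with K > 1 is likewise flagged rather than
  erroring.
- Label switching: components are reported in descending order of total
  expected visits Σ_j λ_kj, so the heaviest-use profile is always first and
  runs are comparable. MAP assignment breaks posterior ties toward that
  lower index.

## Model selection

BIC = −2 log L + p ln n with p = (K−1) + 6K free parameters, lower is
better. `sweep_k` fits K = 1..k_max (default 6, bracketing the expected 4)
with per-K seeds derived deterministically from the master seed; ties break
toward smaller K. The clustergram reports, per K, each cluster's size and
mean total plot-recoded visits, and the number of observations flowing
between clusters of adjacent K. Selection is by BIC alone; the clustergram
is a visual diagnostic and is emitted as data (and optionally a plot), since
a human judgment step cannot be encoded.

## Composite indicators

Five-process composites (≥4 of 5, all 5) cover eye exam (24 months), foot
exam, microalbuminuria, cholesterol and influenza shot; six-process
composites (≥5 of 6, all 6) add repeated HbA1c measurement and are defined
only for participants who know what HbA1c is. Under partial missingness a
composite is reported whenever the observed components already force its
value (e.g. four observed "yes" of five force ≥4-of-5 = 1) and is missing
otherwise. This decide-if-determinable rule maximizes usable data; it is a
package choice where practice varies.

## Descriptive tables

Percentages use per-variable nonmissing denominators within each group
(e.g. 71 of 192 nonmissing, not of 195 enrolled), rounded half-up to one
decimal — the convention that reproduces published one-decimal descriptive
tables. Counts are always reported alongside.

## Profile comparison

- Kruskal–Wallis (continuous) on mid-ranks with the standard tie correction
  H / (1 − Σ(t³−t)/(N³−N)); the all-tied degenerate case returns H = 0,
  p = 1. Pearson chi-square (categorical) without continuity correction.
- Logistic (ML) and linear (OLS) regressions with the profile as exposure
  factor, reference = largest profile, and the fixed adjustment set: age
  (linear), sex, living arrangement, residential location, education,
  insurance model, insurance subsidies, number of complications (linear).
  Entering age continuously is a package choice; categorical bands are a
  defensible alternative. Coefficient covariance: inverse observed
  information (logistic), σ̂²(XᵀX)⁻¹ (linear).
- Predictive margins: m_g = (1/n) Σ_i ŷ(x_i with profile := g) on the
  response scale; SE by the delta method (∇m_g ᵀ Cov(β̂) ∇m_g); 95% CI =
  m ± 1.96·SE, clipped to [0,1] for probabilities. A nonparametric
  bootstrap of the margins is available as an opt-in cross-check
  (`bootstrap_margins`).
- HbA1c-based rows are restricted to participants who know HbA1c;
  self-efficacy to the 2017 recruitment phase (an explicit
  `recruitment_phase` column is required). Indicators without variation are
  emitted flagged `degenerate` instead of aborting the table.
- p-values are raw (no multiple-testing adjustment) and labelled as such.

## Synthetic cohort generator

The generator emulates the measurement process the analysis assumes: draw a
latent profile from π, draw true annual visit counts Poisson(λ_kj), *bin*
them to the four ordinal levels, then draw covariates, processes and
outcomes from profile-conditional models (categorical probabilities,
truncated normals bounded to each instrument's range: SF-12 0–100, ADDQoL
−9..+3, PACIC 1–5, self-efficacy 1–10), and finally blank visit answers
completely at random for a configurable fraction of records
(default 483/1033 ≈ 46.8%, so roughly half the roster is lost to the
complete-case filter, as in the survey setting being emulated). One seeded
random stream drives everything; identical (config, n) reproduces the
cohort byte-for-byte, and ground-truth labels never enter the cohort CSV.

Default parameters: mixing proportions (86, 195, 96, 173)/550 and rate rows
shaped so the four profiles read GP-with-podiatry, GP-only, high-users and
diabetologist-led; covariate/process/outcome parameters are qualitative
transcriptions of the corresponding published profile descriptions. They
are configurable defaults, not estimates.

What the generator does **not** emulate: joint covariate correlation beyond
profile-conditional independence, informative (non-MCAR) missingness,
item-level instrument scoring, and survey design effects. Passing recovery
tests therefore demonstrates correctness of the pipeline under the stated
generative assumptions, not fidelity to any particular real cohort.

### Binning bias, deliberately kept

Because the model treats coded categories as Poisson counts while the data
are binned counts, the rate estimates target the expected *coded* value
m(λ) = P(Y=1) + 2·P(Y∈{2,3}) + 4·P(Y≥4), not λ itself
(`expected_coded_mean` computes this closed form; λ = 4 gives m ≈ 3.02).
On top of that, overlapping profiles induce soft-assignment bias: members
of one profile with atypical visit patterns pull other components' small
rates. Rates around 1 visit/year and above are recovered well
(≈10–13% relative error at n = 5000 in the test suite's experiments), but
near-zero rates (m < 0.3) can be off by several tens of percent even at
large n — an inherent property of fitting overlapping mixtures to coarsely
binned counts, documented here because the recovery test in the acceptance
suite asserts a uniform ±15% band and fails on exactly those near-zero
entries. Mixing-proportion recovery is accurate to a few percentage points.

## Problem sizes

Test and validation experiments use: parameter recovery at n = 5000 (10
replicates), BIC selection at n = 2000 (20 replicates, 8 EM starts per fit
inside the sweep), bootstrap calibration of margin SEs at n = 2000 with 200
resamples, and a 10⁵-draw permutation null for the Kruskal–Wallis
p-value. These sizes give stable Monte-Carlo estimates for the tolerances
being checked while keeping the full suite quick to run.

## Known limitations

- Exact numerical agreement with analyses run in other statistical systems
  is not claimable for the mixture fit (different optimizers and restarts
  may reach different local maxima); the likelihood, BIC and margins
  formulas themselves are checked against independent oracles.
- The ordinal-logit mixture alternative is deliberately not implemented,
  and no covariate-dependent mixing, zero-inflation or truncation variants
  are offered.
- Household income enters as a carried category and is never recomputed;
  whether income quartiles come from in-sample or external reference
  distributions is upstream of this package.
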