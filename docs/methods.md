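# Methods

This note documents the statistical models, the synthetic-data generator, the
default parameters and the numerical choices behind `traitsynergy`, and what
the simulation-based validation does and does not demonstrate about real data.

## 1. The analysis models

### Moderated regression (module `moderation`)

The adjusted model regresses a standardized outcome on standardized
intelligence `g`, its square, a standardized trait `t`, its square, and the
product:

    E[y] = b0 + b1 g + b2 g^2 + b3 t + b4 t^2 + b5 g·t

Squares and products are formed *from* the standardized variables and are not
re-standardized, so `b1`, `b3`, `b5` stay on the familiar standardized-beta
scale and `b5` is directly comparable between the crude model (no quadratic
terms) and the adjusted one. Inference is classical OLS with t-based
two-sided p-values; no robust covariance is used. The highest-degree code
(ordinal 0–6) is analyzed as a numeric outcome — a deliberate simplification
that keeps all coefficients on one scale; an ordinal model is out of scope.

Each model uses complete cases for its own variable set, so per-row n varies
across the results grid (as it does in survey data where different item
blocks have different coverage). Multiplicity is handled by a configurable
Bonferroni divisor, default m = 195 — the 189 grid cells (21 traits × 9
quantities) plus the intelligence main/quadratic effects and the
meta-regressions; the exact decomposition is configurable because reasonable
counts differ.

Why the adjustment matters: if `corr(g, t) = ρ ≠ 0`, then for jointly normal
predictors `E[t² | g, t·g, …]` contains a `g·t` component, so a purely
quadratic trait effect (`b4 ≠ 0`, `b5 = 0`) loads on the product term
whenever the quadratics are omitted. The crude-model bias has the sign of
`b4·ρ`; fitting both quadratics removes it. A caveat the package's validation
respects: the removal is exact only when `t` is measured without error. With
a noisy trait measure (reliability ω < 1), `E[T² | g, t_obs]` retains a
`g·t_obs` cross term of order `b4·ρ·(1−ω)`, so the Ganzach-recovery checks
run on the generator's latent truth, which is the mechanism those presets
isolate.

### One-factor measurement model (module `psychometrics`)

Intelligence scores are Thurstone (regression-method) factor scores from a
single-factor model of the 12-test battery, fitted by maximum likelihood on
the correlation matrix; a minimum-residual fit is the automatic fallback if
the likelihood optimization fails. Loadings are sign-aligned so their sum is
positive; uniquenesses are floored at 0.005 (Heywood guard). Scores are
computed for rows with at least 8 of 12 indicators, using the weight
subvector implied by the available indicators, then re-standardized.
The fitter is validated against a closed-form three-indicator solution and
against an independent maximum-likelihood factor implementation.

Composite scores are the mean of standardized, reverse-keyed member items
over the non-missing members, re-standardized. The dependable composite uses
items {1R, 3R, 4, 11, 16R}; the conscientious item (2) is excluded for its
very low loading, with the six-item variant available via
`load_item_specs(include_excluded=True)` for sensitivity checks. Reliability
is coefficient omega, ω = (Σλ)²/((Σλ)² + Σθ), computed from a one-factor fit
of the (standardized) member items — standardization is the natural choice
given the mixed 1–5 / 1–7 response scales. Under tau-equivalence omega
coincides with Cronbach's alpha, which the tests verify against an
independent variance-ratio oracle.

### Overlapping windows and attenuation (module `windows`)

Windows have fixed width 0.5 SD of standardized intelligence, with 901
centers evenly spaced on [−2.25, +2.25] (spacing 0.005) — the minimal
symmetric grid consistent with that window count; both count and bounds are
configurable. Windows with fewer than 50 complete cases, or with a
non-convergent within-window factor fit, are flagged invalid and excluded
from meta-regressions (one-factor fits on five items are unstable below
roughly that size). Within a window, omega comes from the within-window item
correlation matrix, while the composite and the outcomes stay on their
full-sample standardized scales so slopes are comparable across windows; no
within-window re-standardization is applied.

The window-level meta-regression of slope on mean intelligence (plus omega
when adjusting) weights windows by the inverse squared standard error of
their slope — the standard meta-analytic weighting. This is a deliberate
choice over unweighted OLS (available via `weights=None`): tail windows hold
only a few hundred respondents, their slope SEs are 5–10× those of central
windows, and mean intelligence and omega are strongly collinear across
windows, so unweighted fits let the noisiest windows dominate the partial
coefficient. Confidence intervals are classical; because overlapping windows
share respondents, these intervals understate uncertainty, and a moving-block
bootstrap over the ordered windows is provided (`ci_method='bootstrap'`) and
labelled as such in outputs. Attenuation percent is computed from unrounded
coefficients.

Under classical measurement error the within-window slope of the outcome on
the composite is proportional to the within-window composite reliability
(Spearman attenuation), and within-window omega estimates exactly that
reliability, so slope/ω is constant across windows when no true interaction
exists. On the true-score metric (unit item loadings, raw item-mean
composite) the law is exact: observed slope = true slope × K/(K + s²), which
is how the disattenuation validation is constructed.

### Cross-trait synergy (module `synergy`)

Across the 21 grid rows, OLS of the (by default quadratic-adjusted)
interaction coefficient on the trait–outcome correlation; slope > 0 with
p < 0.05 labels the pattern synergistic, slope < 0 compensatory, otherwise
indeterminate. The 0.05 label threshold is this package's choice and is
configurable. Rows are unweighted by default (inverse-variance weighting is
available). Because the rows share respondents and — in the simulation — a
single latent trait, the classical slope p-value is anti-conservative: under
the null scenario about 16% of runs get a (direction-symmetric) false label
rather than the nominal 10%. The label should therefore be read as
descriptive; the package's null guarantee is the *absence of directional
bias*, which the test suite checks.

## 2. The synthetic-data generator (module `simulate`)

Per respondent: latent ability `g ~ N(0,1)`; latent trait
`T = ρ·g + √(1−ρ²)·e`, population correlation ρ (default 0.2, the order of
the observed trait–intelligence correlations). Twelve continuous ability
indicators `a_j·g + √(1−a_j²)·ε` (default loadings 0.7). Eighteen Likert
items load on the single trait `T` with generator-metric loading λ_j
(default 0.5), negated for reverse-keyed items; continuous responses are
`±λ_j·T + s(g)·ε` with heteroscedastic error SD

    s(g) = s0 · exp(−k·g)        (s0 default 1.0; k = 0 means homoscedastic)

and are discretized through equal-probability normal-quantile cutpoints
scaled to the item's marginal SD (1–5 scale for items 1–8, 1–7 for 9–18).
The multiplicative log-linear error model was chosen for positivity and a
single interpretable gradient parameter. A second reliability mechanism is a
careless-responding mixture: with probability `expit(c0 + c1·g)` per rating
block (items 1–8 and 9–18), a respondent's responses in that block are
uniform over the scale. A continuous output mode (`likert=False`) bypasses
discretization so closed-form oracles apply exactly.

Outcomes follow `E[y] = b1 g + b2 g² + b3 T + b4 T² + b5 g·T` with Gaussian
noise (default SD 1.0, which puts the intelligence-only R² for GPA near the
observed ~0.2 at b1 = 0.46). GPA is continuous; the degree code discretizes
an independent noisy copy of the linear predictor through thresholds matching
the marginal distribution of the 0–6 credential codes in the study
population. Default n is 8984, the study's cohort size.

### Scenario presets

| scenario | b1 | b3 | b4 | b5 | ρ | k | careless | mechanism |
|---|---|---|---|---|---|---|---|---|
| `null` | 0 | 0 | 0 | 0 | 0.2 | 0 | off | calibration baseline |
| `ganzach_synergistic` | 0.46 | 0.2 | +0.15 | 0 | 0.3 | 0 | off | convex trait effect mimics synergy |
| `ganzach_compensatory` | 0.46 | 0.2 | −0.15 | 0 | 0.3 | 0 | off | concave trait effect mimics compensation |
| `reliability_gradient` | 0.46 | 0.5 | 0 | 0 | 0.2 | 0.15 | expit(−2 − 2g) | reliability-driven pseudo-interaction |

The reliability_gradient preset combines both reliability mechanisms on
purpose. A smooth exponential gradient alone makes omega an almost exactly
*linear* function of window mean intelligence; mean intelligence and omega
are then ~99% collinear across windows and the adjusted meta-regression
cannot apportion the effect between them — the attenuation estimate is
unidentified regardless of sample size in any one realization. The logistic
careless mixture (concentrated at low ability, as carelessness plausibly is)
curves the reliability profile and restores identifiability, and the trait
effect b3 = 0.5 puts the windowed slope signal well above window sampling
noise at the validation scale. The preset is a mechanism demonstration, not a
calibrated replica of any particular survey: its extreme-group omegas
(≈0.13/0.62) bracket a steeper gradient than typical observed values.

## 3. Validation scales and what they show

The property and acceptance tests run at fixed sizes chosen to make
Monte-Carlo noise negligible relative to the asserted tolerances: moment and
correlation recovery, factor-loading recovery (±0.01), Spearman
disattenuation (within 5%), and the reliability-gradient analysis use
n = 100 000 with the full 901-window grid; type-I calibration of the
adjusted interaction test uses 500 replicates of n = 2000 (binomial
3σ ≈ ±2.9%); the null-synergy calibration uses 200 replicates of n = 10 000.
`scripts/acceptance.py` re-runs all of these from scratch with seeds derived
from `--seed`.

Passing these checks shows the pipeline correctly separates the two built-in
artifact mechanisms from genuine interactions *under the generator's
assumptions*: a single common factor for ability and a single latent trait
behind all 18 items, joint normality of the latents, classical (conditionally
independent) item errors, logistic careless mixture, and linear-plus-quadratic
outcome surfaces. Real survey data depart from all of these —
multidimensional traits, non-normal latents, correlated item errors,
item-specific response styles, missingness that is not completely at random,
and possible reverse causation of self-ratings by achievement (explicitly not
modeled). The validation therefore demonstrates correctness of the machinery,
not that reliability gradients explain any particular empirical interaction.

## 4. Numerical details

- One-factor ML fit: L-BFGS-B on (λ, ψ) with the analytic gradient
  `dF/dΣ = Σ⁻¹(Σ−R)Σ⁻¹`, ψ bounded to [0.005, 4], λ to [−1.5, 1.5];
  initialized from the leading eigenpair. Minres fallback minimizes the
  off-diagonal residual sum of squares over λ with ψ = 1−λ² floored.
- Likert discretization uses `searchsorted(..., side='right')`: a value
  exactly on a cutpoint falls in the upper category; values beyond the
  outermost cutpoints saturate at the scale ends.
- Degenerate inputs: constant or all-missing vectors are rejected by
  `standardize`; composites silently drop (with a logged warning) member
  items that cannot be standardized; rank-deficient moderation designs raise;
  grid rows whose model cannot be fitted become missing cells rather than
  aborting the table.
- Extreme-group omegas use closed intervals (z ≤ −cut, z ≥ +cut), so cut = 0
  yields two half-samples sharing any exact zeros.
- Windows are half-open [lo, hi); respondents are sorted by intelligence once
  and windows are contiguous slices, so results are invariant to respondent
  order.
- All randomness flows through `numpy.random.default_rng(seed)` with a fixed
  draw order, making generated tables bitwise reproducible for a given
  configuration.

## 5. Known limitations

- Degree is modeled numerically in OLS; ordinal models may differ near the
  scale ends.
- Classical meta-regression CIs ignore window overlap; use the block
  bootstrap for honest interval statements.
- The synergy label's nominal error rate is inflated by cross-row dependence
  (see §1); treat it as descriptive.
- The attenuation decomposition requires reliability variation that is not
  collinear with mean intelligence; with a perfectly smooth reliability
  gradient the adjusted coefficient is intrinsically ill-identified, and the
  attenuation percent should then be reported with its (bootstrap) interval
  rather than as a point value.
- The generator's single-trait structure overstates dependence among the 21
  grid rows relative to real multi-trait batteries.
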