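# traitsynergy

Do personality traits and intelligence interact **synergistically** in
predicting academic achievement — does the trait–achievement association
strengthen as intelligence rises — or do they **compensate** for one another?
Two statistical artifacts can manufacture (or inflate) such interactions:

1. **Quadratic confounding** (Ganzach): when two predictors are correlated,
   their product term is collinear with their squares, so a purely quadratic
   trait–outcome association masquerades as an interaction unless both
   quadratics are fitted alongside the product.
2. **Intelligence-dependent measurement reliability**: if trait self-reports
   are noisier for less intelligent respondents (e.g. through careless
   responding), observed trait–outcome slopes are more attenuated at low
   intelligence — which *looks* like a synergistic interaction.

`traitsynergy` is a tested pipeline for separating genuine interactions from
both artifacts, aimed at researchers in psychometrics and differential
psychology. It ships a synthetic-data generator with both mechanisms built in
as presets, so every stage is verifiable against known ground truth.

## The models

**Moderated regression with quadratic adjustment.** With standardized
intelligence *g* (factor scores on the first unrotated factor of a 12-test
ability battery), standardized trait *t*, and standardized outcome *y*
(grade point average, or highest degree treated numerically):

    E[y] = b0 + b1·g + b2·g² + b3·t + b4·t² + b5·g·t

The *crude* variant omits `b2`, `b4`; comparing crude and adjusted `b5`
exposes the quadratic confound. Across the 18 single items and 3 composites
(dependable, agreeable, open), a positive cross-trait regression of `b5` on
the trait–outcome correlation labels the overall pattern synergistic.

**Reliability analysis.** Composite reliability is coefficient omega from a
one-factor model, ω = (Σλ)² / ((Σλ)² + Σθ). Respondents enter overlapping
windows of width 0.5 SD on *g* (901 centers from −2.25 to +2.25); per window
we compute mean *g*, ω of the dependable items, and the OLS slope of each
outcome on the composite (full-sample scales). A window-level meta-regression
of slope on mean *g*, with and without ω as covariate, quantifies how much of
the apparent interaction is absorbed by reliability:

    attenuation% = 100 · (1 − b_adjusted / b_unadjusted)

## Worked example

Simulate a survey-sized cohort under the reliability-gradient preset — no
true interaction (`b5 = 0`), but item error SD `s0·exp(−k·g)` and a careless
responding probability that both fall with ability — and run the full
analysis:

```bash
traitsynergy simulate --scenario reliability_gradient --n 8984 --seed 1 \
    --out results/demo
```

Key artifacts (CSV) in `results/demo/`:

```text
meta_fits.csv
outcome  b_unadjusted  b_adjusted  attenuation_pct  b_omega_on_iq  b_slope_on_omega
    gpa        0.0701      0.0172          75.4707         0.1382            0.4877
 degree        0.0969      0.0848          12.4316         0.1382            0.5339

synergy_fits.csv
outcome  slope  p_slope       label
    gpa 0.3015      0.0 synergistic
 degree 0.3491      0.0 synergistic

extreme_group_omega.csv
group  omega
  low  0.127
 high  0.593
```

Reading: the windowed trait→GPA slope rises with mean intelligence
(`b_unadjusted = 0.070` per SD) even though no interaction was simulated;
omega climbs steeply from the low (z ≤ −1) to the high (z ≥ +1) intelligence
group (0.13 → 0.59); and adding omega to the meta-regression absorbs ~75% of
the apparent interaction for GPA. The cross-trait synergy fit labels the
(artifactual) pattern synergistic, exactly as a naive analysis of such data
would. At this cohort size the attenuation estimate is noisy (the adjusted
coefficient's identifying variation is the curvature of ω in mean *g*);
the validation suite runs the same analysis at n = 100 000.

The same pipeline runs on real data with
`traitsynergy analyze --data respondents.csv --out results/real` given a CSV
with `test_1..test_12`, `item_1..item_18` (Likert 1–5 for items 1–8, 1–7 for
9–18), `gpa`, and `degree` (ordinal 0–6).

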