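# Methods

## The scoring model

`alscore` computes a single-sample allostatic load (AL) score as the sum of
an **acute stress score** and a **secondary mediator score**, both built
from cohort-relative, dimensionless mediator scores.

For biomarker *b*, the mediator score of participant *i* is the min-max
normalisation `s_ib = (x_ib − min x_b)/(max x_b − min x_b)` over the whole
cohort, followed by the pseudo-log2 transform `t_ib = log2(s_ib + 1)`. The
transform is not uniquely pinned down by the name "pseudo log2"; `log2(x+1)`
was chosen because it is monotone, maps [0, 1] onto [0, 1] (fixing both
endpoints, so score bounds survive the transform), and compresses the right
tail the way a log transform of positive data would. Both the regression
predictors and the summed scores use the transformed values, since the
transform is applied immediately before summation in the workflow the
package implements.

The acute score weights the three primary mediators (cortisol, epinephrine,
noradrenaline) by their contribution to predicting blood-pressure class in a
proportional-odds (cumulative-logit) ordinal regression. The model is fitted
only on participants with observed BP; the goal is the *relative importance*
of the mediators, not BP prediction, so the fitted object is reduced to
`w_j = |β_j| / Σ|β_k|`. Because all three predictors share the same [0, 1]
transformed scale, the raw coefficients are directly comparable and no
further standardisation is applied. Two class schemes are supported —
normal/elevated/hypertensive (three-class) and normal vs the rest
(two-class) — and both are computed by default. Non-convergent fits are
returned with `fit_converged=False` and, in the CLI, abort the run unless
`--allow-nonconverged` is given.

Secondary mediators carry fixed signed weights: +0.25 for fibrinogen, CRP
and HbA1c, −0.25 for HDL (higher HDL is protective). With unit transformed
scores the secondary score is 0.5; its algebraic range is [−0.25, 0.75].
Note this range admits negative values — a participant with the cohort's
highest HDL and lowest inflammatory markers scores below zero — so the
composite AL = acute + secondary lies in [−0.25, 2], not [0, 2]; the
construction is implemented exactly as the formula states rather than
clipped. AL additivity is exact (no rounding between stages).

### Blood-pressure classification

Raw categories use standard clinical cut-offs (mm Hg), highest severity
winning when a reading satisfies several rules (e.g. 125/85 is stage 1 via
the diastolic rule, not "elevated"): stage 2 if systolic ≥ 140 or diastolic
≥ 90; stage 1 if systolic in [130, 140) or diastolic in [80, 90); elevated
if systolic in [120, 130) and diastolic < 80; else normal. Readings are
treated as reals, printed integer ranges as half-open intervals, so 129.5
falls in the elevated systolic band. Three-class collapses both hypertensive
stages; two-class collapses everything above normal. Participants without BP
keep their biomarker scores and are excluded only from the weight fit.

## Preprocessing

**Completeness filter** — biomarkers observed in fewer than `threshold`
(default 0.25) of participants are dropped before imputation. The filter is
idempotent and reports per-biomarker completeness fractions.

**Left-censored imputation (QRILC-style)** — missing biomarker values are
treated as left-censored (below detection), i.e. missing not at random. Per
biomarker with missingness fraction *c*, on natural-log concentrations:

1. sorted observed values are assigned plotting positions
   `p_i = c + (1−c)(i−0.5)/n_obs` — the observed sample occupies the upper
   `1−c` of the distribution;
2. least-squares regression of the sorted values on `Φ⁻¹(p_i)` yields the
   uncensored distribution's mean μ̂ (intercept) and SD σ̂ (slope);
3. each missing value is drawn from `N(μ̂, (tune_sigma·σ̂)²)` truncated above
   at `min(μ̂ + σ̂·Φ⁻¹(c), log min observed)` — the estimated censoring
   quantile, additionally capped so no imputed value can exceed the observed
   minimum (the cap matters only when the quantile estimate overshoots on a
   noisy fit);
4. values are exponentiated back.

`tune_sigma` (default 1.0) rescales the spread of imputed draws only. A
`raw` scale mode skips the log transform. The RNG is fully determined by a
required, logged seed. Exact replication of any particular imputed values
from another run of the same method is not possible (the draws are
stochastic); only distributional agreement is claimable, and the tests check
exactly that (parameter recovery within ±0.1 on the log scale at n = 500
with 17.5% censoring).

Limitations: one tail model per biomarker (no covariates), single
imputation only — no multiple-imputation pooling, and no kNN/forest/MICE
alternatives.

## Group comparisons

Welch's unequal-variance t-test is used for all two-group contrasts (the
default t-test of the R environment this workflow is usually run in, and
robust to the unequal stratum variances seen in practice). Factor pairs are
analysed with a two-factor linear model with interaction; sums of squares
are Type II by default (well defined on unbalanced designs; Type I/III
selectable), and the model's omnibus F is reported as the headline "overall
p" of a stratified panel. Post-hoc analysis runs all pairwise Welch tests
among the crossed cells with Benjamini–Hochberg adjustment applied within
each outcome × stratification family (matching a per-panel presentation);
cells with fewer than two members are skipped with a warning. All tests are
two-sided. Significance flags: `∎` p<0.1, `*` p<0.05, `**` p<0.01,
`***` p<0.001 (applied to adjusted p where available).

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 63
participants in 8 sex × race × smoking strata (4/8/3/8/12/8/11/9), with
per-stratum biomarker means/SDs encoded from the reference cohort's
summary table. Concentrations are drawn from log-normal marginals
moment-matched to those arithmetic means/SDs (concentrations are positive
and right-skewed); biomarkers are independent within stratum (a correlation
hook exists but has no data-derived default). Epinephrine's lowest 17.5% of
values cohort-wide are set missing — bottom-*k* order statistics, mirroring
an assay detection limit (MNAR). Blood pressure is generated from an
ordinal-logistic latent model on the true (uncensored) transformed primary
mediator scores, with default coefficients 8 × (0.73, 0.22, 0.04) for
(epinephrine, cortisol, noradrenaline) so the generating weight shares equal
the three-class shares the method should recover; 34 randomly chosen
participants receive readings drawn uniformly inside their latent category's
defining mm Hg region, the rest have BP missing. The latent cut-points were
calibrated once, by pooling replicates of the default 63-participant design,
to the marginal category proportions 15:4:11:4, and then frozen; the
summary table does not report BP by stratum, so no stratum-level BP
structure is modelled.

What the generator does **not** emulate: empirical (non-log-normal) marginal
shapes, between-biomarker correlation, assay noise models, or repeated
measures. Two consequences worth knowing. First, heavy log-normal tails
make the cohort maximum large, so min-max scores — and hence absolute AL
levels — sit lower than in the real cohort; passing tests demonstrate the
*machinery* (formulas, recovery, calibration), not agreement of absolute
synthetic score levels with published ones. Second, at the study's own
fitting size (34 BP participants) the ordinal weights are highly variable
across draws; the weight-recovery guarantees are therefore stated at
n = 400 over 20 replicates, where the mean recovered shares land within
±0.08 of the generating proportions. A small attenuation of the dominant
share (a few points) is expected there: `|β̂|` of a near-zero coefficient
is biased upward (folded-normal effect), which drains share from the
largest weight.

## Numerical and design choices

- Min-max bounds are computed on the post-imputation cohort (imputation
  precedes quantification in the pipeline order).
- Weight normalisation uses absolute coefficients; if every coefficient is
  exactly zero the weights fall back to equal shares (degenerate but
  normalised).
- The ordinal fit uses BFGS with up to 500 iterations; convergence status is
  always recorded.
- Secondary weight magnitude is configurable (`1/k` for a k-marker secondary
  panel generalises the default 0.25).
- Problem sizes in the test suite (n = 400 × 20 replicates for weight
  recovery, n = 500 for imputation recovery, 1000 replicates for null
  calibration) were chosen as the smallest sizes at which the recovery
  guarantees above are comfortably identifiable.
- The published-cohort reproduction check requires the study's
  participant-level raw table (convertible to `data/supplementary_s7.csv`);
  only stratum-level summaries are public, so that check cannot run without
  user-supplied data.
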