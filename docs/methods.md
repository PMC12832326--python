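# Methods

This note documents the generative model behind the synthetic cohorts, the
closed-form calibrations that set the generator defaults, and the exact
semantics of the trimming, screening and statistical procedures. All symbols
refer to the three magnification-invariant hand ratios:

* `r43mc` = MC4/MC3, `r53mc` = MC5/MC3 (metacarpals, shared denominator MC3)
* `r53mp` = MP5/MP3 (middle phalanges)

Orientation is fixed globally: **lower ratio = TS-like**.

## 1. Length model (reference cohort)

Each subject carries a bone age `a ~` (mixture over the six bone-age groups
with configurable weights, uniform within group) and a per-hand scale
factor. A bone's length is multiplicative:

```
length_b = L(a) · p_b · exp(h + ε_b) · m
```

* `L(a) = 90 + 6a` — a coarse linear growth curve for MC3 (mm). Its exact
  shape is irrelevant to every downstream quantity because only ratios are
  analyzed; it exists so that emitted lengths look like plausible
  radiogrammetry.
* `p_b` — the bone's proportion relative to MC3 (e.g. `p_mc3 = 1`,
  `p_mp3 = 0.20/0.42` of the MC3 share of `L`). Group-wise proportions
  encode the age structure of the ratio means (below).
* `h ~ N(0, 0.12²)` — per-subject hand scale (body size).
* `ε_b ~ N(0, σ_b²)` — independent per-bone log-noise; this is the only
  source of ratio variance.
* `m ~ U(0.8, 1.25)` — radiographic magnification, drawn on its own RNG
  substream.

Because `h` and `m` multiply every bone of a subject equally, they cancel
**exactly** in every ratio; the test suite asserts frame-level equality of
ratios across different magnification ranges.

### Noise calibration (closed form)

With shared denominator MC3, a log-normal delta-method gives for small σ:

```
CV(r43mc)² = σ3² + σ4²
CV(r53mc)² = σ3² + σ5²
corr(r43mc, r53mc) = σ3² / (CV43 · CV53)
```

`calibrate_reference_noise(cv43, cv53, corr)` inverts this system:

```
σ3² = corr · cv43 · cv53,   σ4² = cv43² − σ3²,   σ5² = cv53² − σ3²
```

For the published pooled CVs (0.019/0.889, 0.022/0.822) and target
correlation 0.49 this yields σ3 = 0.0167, σ4 = 0.0133, σ5 = 0.0209. The
calibration is infeasible when `corr·cv43·cv53` exceeds either squared CV;
the function raises `CalibrationError` naming the violated bone.

The ratio means are hit exactly in expectation by the log-normal mean
correction: the proportion implementing target ratio `t` over noise SDs
`(σ_num, σ_den)` is scaled by `exp(−(σ_num² + σ_den²)/2)`.

### Age structure of the reference means

* MC ratios: groups 1–5 share a common mean; group 6 (bone age ≥ 15) dips
  by δ = 0.008 (growth-plate senescence of the ulnar rays). Groups 1–5 are
  offset by +δ/6 so the **pooled** means remain 0.889 and 0.822.
* MP ratio: group means (0.61, 0.61, 0.61, 0.61, 0.64, 0.64) with
  within-group SD chosen so the pooled SD is 0.0575 — the published pooled
  MP distribution is wider than the MC ones and steps up in adolescence.
* A small reference tail subpopulation (fraction 0.013, `r53mp ~
  N(0.49, 0.008²)`) models the clinically observed ~2% BDA3 prevalence in
  the *post-trim* reference population. A unimodal normal with the pooled
  moments cannot produce a 2% mass below 0.5 once ±2.25 SDS trimming has
  removed the tail, so the tail is explicit. The fraction 0.013 is set so
  that the post-trim prevalence lands at ≈ 2% (trimming removes part of,
  but not all of, the tail because the union rule keys on all three
  ratios).

## 2. TS cohort

Two backends generate TS subjects; both share the same metadata model
(karyotype with monosomy probability 33/81, growth-hormone treatment 0.82,
SHOX wrist signs 0.333/0.235/0.136, height percentile coupled to ratio
severity).

### `ratio_level` (default)

Ratios are drawn directly from calibrated marginals tied together by a
Gaussian copula:

* `r43mc` — a **two-component normal mixture**: an unaffected component at
  the reference mean and an affected component shifted down by Δ. The
  three published targets (pooled mean 0.860, SD 0.050, low-flag
  prevalence 0.272 against the default reference table) are fitted by
  `fit_ts_mixture` (multi-start least squares over logit/log-transformed
  parameters, analytic moments and flag prevalence; `MixtureFitError` with
  residuals if no solution reaches 2%). Typical solution:
  π ≈ 0.26, Δ ≈ 0.108, component SD ≈ 0.015.
* `r53mc ~ N(0.820, 0.040²)`.
* `r53mp ~ N(0.600, 0.090²)` plus a bone-age slope of 0.00586/yr
  (re-centered, so the marginal is preserved) reproducing the published
  age correlation 0.28 with bone age uniform on [3.0, 17.9].

The copula's latent correlations are the published inter-ratio
correlations **corrected for marginal non-linearity**: pushing a normal
score through the mixture quantile function attenuates Pearson r by the
linearity coefficient `cov(G(Z), Z)/σ_G` (computed by trapezoid
quadrature), and the MP age-slope variance share similarly dilutes the MP
correlations. Without the correction the realized Pearson r would fall
~24% short of target on the mixture margin. The corrected latent matrix
must be positive definite (`NotPositiveDefiniteError` otherwise).

Backend subjects also receive synthetic lengths consistent with their
ratios so the measurement layer can run unchanged.

### `length_level`

A mechanistic alternative: a shared severity latent `S ~ N(0,1)` shortens
MC4, MC5 and MP5 with loadings (0.054, 0.041, 0.118) on the log scale (mean-
corrected by `exp(−λ²/2)`), on top of the reference length model. It hits
the TS means and produces severity-coupled ratios, but (by design) not the
exact published SD/prevalence triple — that requires the mixture. It
exists to check that a biologically structured model reproduces the same
qualitative picture.

## 3. Trimmed normative table

`trim_outliers(ratios, trim_limit=2.25)`:

* **single pass** — z-scores use the input-sample mean/SD only; the trim
  is not iterated;
* **union rule** — a subject is excluded if *any* of its three ratios is
  extreme;
* **strict inequality** — exclusion requires `|z| > 2.25`; a subject
  exactly at the limit is retained;
* degenerate (zero-SD) columns exclude nobody; n < 10 is refused.

On i.i.d. normal triples the expected retention is `(2Φ(2.25)−1)³ ≈
92.85%`; the suite asserts this within ±1%. `build_reference` then
computes n/mean/SD (ddof = 1) per bone-age group — [0,6), [6,8), [8,11),
[11,13), [13,15), [15,18] with 18.0 assigned to the last group — plus
pooled rows. Groups with n < 2 store `sd = null` and refuse z-scoring
(`UnavailableGroupError`). Tables serialize to JSON under the format tag
`phalanx-ref/1` with a provenance block (input digest, counts; no
timestamps, so equal inputs give byte-equal files).

## 4. Screening

For a subject with bone age `a`, each ratio is z-scored against its
bone-age group row. Flags (all strict inequalities):

* `flag_mc43_short` — z(r43mc) < −2 (metacarpal sign, MC4)
* `flag_mc53_short` — z(r53mc) < −2 (metacarpal sign, MC5)
* `flag_bda3` — raw `r53mp` < 0.5 (brachydactyly type A3)

`cohort_prevalence` reports per-flag counts/proportions; SHOX wrist-sign
annotations are tri-state booleans and unknowns leave the denominator. The
optional two-cohort comparison uses a Pearson chi-square (no continuity
correction) when all expected counts are ≥ 5, otherwise Fisher's exact
test, two-sided.

## 5. Statistics

* **Empirical AUC** — Mann-Whitney concordance `P(ts < ref) + ½P(ts = ref)`
  via midranks; variance and 95% CI by DeLong's method.
* **Binormal AUC** — `Φ(Δmean / √(σ₁² + σ₂²))`; with the published moments
  this gives 0.706 (4:3 MC) and 0.518 (5:3 MC).
* **Youden cut-off** — scan over midpoints of adjacent distinct pooled
  values; J = sens + spec − 1; ties resolved to the smallest maximizing
  cut-off. At the cut-off value itself, a ratio equal to the cut-off
  counts as negative (`ref ≥ cutoff` is specific).
* **Correlations** — Pearson via scipy; partial correlation by the
  residual method (both variables regressed on the covariate, t-test on
  n − 3 df); near-zero residual variance raises
  `UndefinedCorrelationError`.
* **ANOVA + Scheffé** — one-way ANOVA; pairwise contrasts tested as
  `F = Δ² / (MSW(1/nᵢ+1/nⱼ)(k−1))` against `F(k−1, N−k)`; always ≥ the
  unadjusted p (asserted in the suite).
* **t-tests** — Student and Welch wrappers over scipy with explicit
  zero-variance handling.

Log-transformation of ratios before testing is available as a flag but off
by default: the simulated (and published) ratio distributions are
near-symmetric (|skewness| < 0.25 in the suite's diagnostics).

## 6. Determinism

All randomness flows from one integer seed through named
`SeedSequence(entropy=seed, spawn_key=...)` substreams (ages, hand scale,
MC noise, MP noise, magnification, tail membership, TS marginals,
metadata). Consequences:

* identical config + seed ⇒ byte-identical CSV/JSON outputs (asserted);
* magnification settings cannot perturb any other stream;
* sub-cohorts are reproducible independently of each other.

## 7. What the generator does and does not emulate

Reproduced: pooled ratio moments, inter-ratio correlations, age-group
structure, flag prevalences, the MP-age trend, metadata mix, trimming
retention, and all closed-form statistics.

Not reproduced: true radiographic images or landmarks (emitted landmarks
are geometric, not anatomical); manual-QC exclusions (the published
45-of-4,483 unusable radiographs are not modeled — rejection handling is
tested with synthetic defects instead); longitudinal within-subject
growth; male/female differences (the reference is modeled as a single
population per age group); and any multivariable height/adult-height
modeling.

## 8. Problem sizes and runtime

Default cohorts (4,438 + 81) simulate in well under a second; the 10⁴-
subject TS runs used for prevalence checks take ~1 s; the full test suite
runs in under a minute on one CPU. Memory stays below a few hundred MB
throughout.
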