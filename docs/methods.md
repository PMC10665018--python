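# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know.

## Data model

A *peak table* is a features × samples matrix of nonnegative LC/MS peak
areas. The unit of analysis is the **feature**: a (compound, ionization
mode) pair. Compounds detected in both electrospray modes contribute two
features, because neither mode is known to track the true abundance
better; the two features of a compound are strongly correlated and the
analysis treats that as a property of the data, not something to correct.
Missing cells mean "below the limit of detection" — a measured zero is a
value, not a missing cell. Tables carry a stage tag
(`raw → standard_normalized → tss_normalized → imputed`) and each stage
validates its input, so a mis-ordered pipeline fails loudly rather than
silently.

## Normalization

**Step 1 — internal standards.** Each sample is divided by a scale factor:
the geometric mean of the sample's spiked internal-standard peak areas,
relative to the across-sample geometric mean of the same standards. The
geometric mean is the natural choice for a multiplicative instrument
response; a precomputed per-sample factor vector can be injected instead
for data normalized under a different standards protocol. Standards are
flagged, excluded from every downstream denominator, and dropped after
normalization — they are not biological features.

**Step 2 — total-sum scaling (TSS).** Present values are divided by the
sum of present values so each sample's features are proportions.
The default scope is *per ionization mode within a sample*, since each
mode is a separate acquisition with its own total signal; a pooled
per-sample scope is available (`scope="sample"`). Because missing cells
cannot contribute, TSS runs before imputation and each scope is
re-normalized after imputation.

TSS makes the data **compositional**: a genuinely increased compound
depresses the proportions of everything else in its sample. With ~200
compounds and lognormal abundance spreads this shift is typically
0.1–0.5 on the log₂ scale and common to all features of a line. The
correlation and spectrum analyses are robust to it (a common shift is
absorbed into per-line call probabilities and ranks); absolute per-feature
log₂ fold-changes are not, which is why recovery tests compare planted
effects against each line's median fold-change.

## QRILC imputation

Left-censoring means missingness is value-dependent from below, so
ignoring it (or filling zeros) biases every downstream statistic. Per
scope — by default each (sample, mode) acquisition — the model is:

- log abundances are normal 𝒩(μ, σ²), with the lowest fraction *m*
  (the scope's missing fraction) unobserved;
- the i-th observed order statistic sits at overall quantile
  q_i = m + (1 − m)(i − ½)/n_obs, so regressing the order statistics on
  Φ⁻¹(q_i) estimates μ (intercept) and σ (slope);
- the regression uses observed plotting positions in (0.25, 1.0) —
  the lowest observed quartile sits nearest the censoring boundary and is
  the part most distorted by boundary effects;
- the censoring limit is the fitted quantile at the missing fraction,
  **capped at the smallest observed log value in the scope**: a detection
  limit cannot exceed a value that was detected. The cap is a constraint
  on the limit, not a post-hoc clip of the draws, so the (μ, σ) fit and
  the evaluation harness are unbiased by it — and it makes the method's
  promise (every imputed value falls below the detected values of its
  scope) hold by construction. The imputer still verifies the property
  post hoc and raises if it is ever violated.
- missing values are drawn from 𝒩(μ, (σ·tune_sigma)²) truncated above at
  the limit, by inverse-CDF sampling (exact, no rejection loop, fully
  reproducible under a seed). `tune_sigma` (default 1.0, range (0, 1])
  optionally shrinks the spread of the imputed tail.

Scopes need ≥ 10 observed values; with zero missingness the fitted (μ, σ)
converge to the sample moments of the log data. Fitted parameters, limits
and the per-scope validation report are exposed on the estimator.

**Evaluation harness.** `evaluate_imputation` artificially left-censors a
complete table at given quantiles of the pooled value distribution
(value-based, mirroring a detection limit — hence deterministic; the
"replicates" differ through the stochastic imputation draws) and scores
each method (QRILC, half-minimum, zero-fill) by NRMSE on the log₁₀ scale
over the censored cells, normalized by the SD of the full true log table.
Zero-filled values are floored at a tiny positive constant before the log.

## Fold-changes and significance

fc = (mean over biological replicates of the evolved proportion) /
(mean over replicates of the phase-matched ancestor proportion), per
feature. Averaging is arithmetic on the proportion scale ("averaging
biological replicates" taken literally); a geometric option exists. The
default ancestor map follows the experiment's arms — Ara− lines to REL606
("R06"), Ara+ lines to REL607 ("R07") — and is configurable. A feature is
called altered when |log₂ fc| ≥ τ, default τ = 1, boundary inclusive.
Per-compound summaries report the median fold-change across the 12 lines
both pooled across modes and per mode, because published per-compound
numbers do not consistently pool.

## Correlation parallelism

For one phase, the 66 pairwise Spearman correlations (average-rank ties,
pairwise NA dropping) between the lines' log₂ fold-change profiles
measure how similar evolution was across lines. The null randomizes the
assignment of fold-changes to features *within each line independently*:
this preserves each line's marginal fold-change distribution while
destroying cross-line feature matching, which is exactly the "no
parallelism" hypothesis. Since Spearman's ρ is Pearson on ranks and
permuting values permutes ranks, the engine permutes pre-standardized
rank vectors and takes inner products — 100,000 iterations on a
196-feature, 12-line table take seconds.

Two p-values are reported: a two-tailed Welch t-test of the 66 observed
correlations against the pooled B×66 null values (the as-published
comparison; Welch because the reference analysis was done with R's
`t.test`, whose default is Welch), and an empirical two-sided permutation
p-value on the per-iteration mean ρ, which does not treat pooled
permutation draws as independent observations. The phase contrast is a
two-sided Welch t-test between the observed exponential and stationary
correlation sets. Within- vs across-phase structure of the raw
(imputed) abundances is summarized by Spearman correlations of log₁₀
abundances over all sample pairs, labeled by phase agreement, with a
one-sided Mann–Whitney test (within > across).

## Shared-change spectrum

Per phase and direction, p_i is the fraction of features called altered
in line i. Under independence the number of lines K in which a given
feature is altered is **Poisson-binomial**: K = Σ Bernoulli(p_i). The pmf
is computed exactly by iterative convolution (dynamic programming, O(n²),
absorbing one Bernoulli at a time); the general sum-of-binomials case
(n_i > 1, "SINIB") is implemented by convolving component binomial pmfs
and reduces to the Poisson binomial at n_i = 1. Expected counts are
E_k = N·pmf[k]; both O_k and E_k sum to N, so O − E is a proper
redistribution and excess at high k is the parallelism signal.

Two caveats are inherent to the method, not implementation artifacts:
the p_i are estimated from the same calls being tested, so strong planted
(or real) parallelism inflates them and depresses E at low k; and any
per-feature heterogeneity in call probability (shared ancestor
denominators, censoring near the limit) makes observed counts
overdispersed relative to the homogeneous independence model. Both push
the observed spectrum toward "fewer than expected at low k, more at high
k" — the same qualitative deviation the motivating study reports on real
data.

## Ordination

Per phase: replicate-average each line's proportions, log₁₀-transform,
center features (no unit-variance scaling — the analysis is of
log-abundance structure, and the dominant contributions are expected from
high-variance compounds; a `scale` flag exposes the alternative), SVD.
Scores are per line (ancestors included), the contribution of feature j
to component m is its squared loading (columns sum to 1), and the sign of
each component is fixed so its largest-|loading| feature is positive.
Constant features are dropped with a warning.

## Synthetic data generator

The generator emulates the study design: 2 ancestors + 12 evolved lines
× 2 phases × 2 replicates, every compound in both modes, plus spiked
internal standards. The measured value of compound c, mode m, line l,
phase p, replicate r is

10^( b_c + o_{c,m} + g_{c,p} + log₁₀2 · e_{c,l,p} + ε ) · s_sample

with b_c ~ 𝒩(baseline_log10_mean, baseline_log10_sd²) the compound
baseline, o a compound-specific mode offset, g a compound-specific phase
shift (this is what makes within-phase sample correlations exceed
across-phase ones), e the log₂ effect, ε ~ 𝒩(0, replicate_sd²) per cell,
and s the sample's internal-standard factor (lognormal with CV
`internal_standard_cv`). Censoring is **value-based**: a global detection
limit at the `censor_quantile` of the pooled biological values, matching
the left-censoring model QRILC assumes. Standards are spiked ~2.5 decades
above the typical compound and exempt from censoring.

Effects have two sources. *Planted blocks* (`parallel_spec`) assign a
fixed signed log₂ effect to a set of compounds in a random subset of
k_lines evolved lines — effects act at the compound level (both modes
inherit them), since a real abundance change moves both acquisitions.
*Background effects* are idiosyncratic per (compound, line, phase) draws
~𝒩(0, background_effect_sd²), applied only to non-planted compounds so a
planted block lands at its nominal k. Ancestors carry no effects.

Defaults are the study conditions where stated (196 compounds, 12 + 2
lines, 2 phases, 2 replicates, 2 modes) and plausible round values
elsewhere, chosen once: baseline mean 5.0 and SD 1.0 (log₁₀ — peak areas
span several decades), replicate SD 0.1 (≈ 26% CV), phase shift SD 0.5,
mode offset SD 0.3, background effect SD 0.7 (log₂; ≈ 16% of features
beyond the two-fold threshold per line and direction, giving realistic
per-line call probabilities), censor quantile 0.10 (reproduces a
completeness count close to the study's 168-of-196), standard CV 0.2.
The default planted blocks (10 compounds up ×4 in all 12 lines, 8 up
×2.8 in 10 lines, 8 down ×2.8 in 8 lines) put the parallelism excess at
high k, where the study found it; the magnitudes are arbitrary but within
the 1–3 |log₂| range of plausibly selected metabolic changes.

**What the generator does not emulate:** chromatographic artifacts
(retention-time drift, adducts, isotopes), batch effects, correlated
effect structure within pathways, and mode-specific ionization
efficiencies beyond a static offset. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
generative model, not robustness to all failure modes of real LC/MS data.

## Verification problem sizes and numerical choices

- Poisson-binomial pmfs are checked against full 2ⁿ enumeration for
  n ≤ 12 (tolerance 1e-10; observed agreement is at machine precision).
- Censored-normal recovery uses 50 scopes of n = 1000 with 20%
  censoring; median bias of both parameters is well under 0.05.
- Permutation-null calibration/power use B = 1000 and N = 196 features
  over 100 seeds per arm; the planted alternative is a 12-line common
  effect on 25% of features.
- Spectrum recovery runs on an idealized well-powered configuration
  (600 compounds, no censoring, baseline SD 0.15, phase shift SD 0.2,
  replicate SD 0.05, small planted blocks at ×5.7): at study-like noise
  the structural deviations described above (compositional shifts,
  shared-denominator correlation, p_i inflation) dominate the low-k bins,
  exactly as they would in real data, and no fixed noise band can hold.
  The idealized configuration isolates what the test is meant to show —
  that planted parallelism at k = 8, 10, 12 appears as positive excess at
  exactly those k while an independent background matches its expectation.
- Degenerate inputs: constant profiles yield NaN correlations with a
  warning rather than an error; all-missing samples, too-few observed
  values per scope, nonpositive proportions, and invalid configs raise
  typed errors naming the offender. Ties in ranks use average ranks.
- All stochastic steps (generator, imputer, permutation engine,
  evaluation harness) are driven by explicit seeds through
  `numpy.random.default_rng` and are byte-reproducible for a fixed seed.

## Known limitations

- The internal-standard protocol of the reference data is not fully
  specified upstream; the geometric-mean factor is a reasonable stand-in
  and a factor-injection path is provided.
- Whether the reference analysis pooled ionization modes in its TSS and
  in per-compound medians is not stated; both scopes/summaries are
  implemented and reported side by side where it matters.
- The t-test on pooled permutation values treats B×66 draws as
  independent observations, which overstates the effective sample size;
  it is kept because it is the published comparison, and the empirical
  permutation p-value is reported alongside as the statistically
  conservative alternative.
- Fold-changes on TSS proportions are compositional; no log-ratio
  transformation (CLR/ILR) is applied because the downstream statistics
  are rank- or threshold-based and the reference method works on
  proportions.
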