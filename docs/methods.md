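# Methods

This note documents the models, the synthetic cohort, the numerical choices
and the known limitations of the package. Everything quantitative stated
here is computed by the test suite or the example scripts.

## Encoding models and feature inventory

Each of the five models regresses one or two speech regressors onto EEG via
a lag kernel. The regressors, all sampled at 128 Hz over one stimulus
segment:

| channel | kind | definition |
|---|---|---|
| envelope | continuous | gammatone-filterbank envelope (below) |
| envelope_onsets | continuous | half-wave-rectified envelope derivative |
| word_onsets / phoneme_onsets | impulse | value 1 at the sample nearest each onset |
| word_surprisal | impulse | −log₂ P(word \| left context), pluggable provider |
| word_frequency | impulse | −log₂ relative unigram frequency |
| phoneme_surprisal | impulse | −log₂ P(phoneme \| active cohort) |
| phoneme_entropy | impulse | Shannon entropy of the frequency-weighted cohort |

Envelope chain: downsample to 15 kHz (anti-alias at 5 kHz) → 28 gammatone
bands, centre frequencies 50–5000 Hz equally spaced on the ERB scale →
per-band half-wave rectification and power-0.3 compression → band average →
downsample to 128 Hz (anti-alias at 42.7 Hz) → 0.5–25 Hz order-3 Butterworth
band-pass, applied forward–backward → truncate/zero-pad to the segment
length. All anti-alias filters are order-3 Butterworth at one third of the
target rate, applied forward–backward.

Cohort model: the active cohort before phoneme k of a word is the set of
lexicon entries whose pronunciation begins with the word's first k−1
phonemes (the entire lexicon at k = 1, for entropy and, for consistency,
for surprisal as well). Probabilities are corpus-frequency weighted.
Homophones pool frequency because the cohort operates on pronunciations.
Logarithms are base 2 throughout; after the per-channel z-scoring in the
TRF stage the base cannot affect fits. A strict mode errors on unseen
prefixes; the lenient mode backs off to a uniform distribution over the
phoneme alphabet.

Nuisance sets: each model's nuisance features are all channels outside its
features of interest, except that the two segmentation models are not
residualized against each other. The nuisance regression uses the same
−200..600 ms lagged design as the TRF stage (an instantaneous variant is
available via `nuisance_lags="none"`): a lag-free regression would leave
nearly all time-shifted shared variance in place and defeat the purpose of
the step. The fit pools all segments of a participant, per electrode, with
an intercept; rank-deficient designs fall back to the minimum-norm
solution with a warning.

## Lag axis

The −200..600 ms window at 128 Hz is not integral in samples; it is
realised as integer lags −26..76 (−203.1..593.8 ms), exactly 103 lags.
The RMS window 0–500 ms and the peak-search window −50..600 ms are
evaluated on this axis.

## Boosting estimator

Starting from a zero kernel, each iteration evaluates the training-MSE
change of adding ±0.005 (on the z-scored scale) to every (feature, lag)
weight and applies the single best update; ties break to the lowest column
index, + before −. Validation MSE is tracked after every update; training
stops when no candidate lowers the training error or when the validation
MSE has not reached a new minimum for `patience` consecutive updates, and
the kernel at the validation minimum is returned. Because the returned
kernel is always the validation optimum, a larger patience can only improve
it (at compute cost); the default is 32 — with step 0.005 the single-update
validation changes are of order 10⁻⁶ relative, so very short plateaus occur
long before error reduction has genuinely ceased, and a 2-step rule was
observed to return zero kernels on weak-signal models and to leave the
strong-signal kernels visibly under-converged. Held-out accuracy is flat in
patience over 8–64, and kernel recovery on simulated data saturates by 32.

All per-iteration work runs on sufficient statistics (per-fold Gram
matrices and residual correlations), so one update is O(columns)
independent of the number of samples; the loop is numba-compiled. Feature
channels and targets are z-scored on training-fold statistics; the first
second of every segment is dropped before fitting to avoid onset
transients; returned kernels are fold-averaged and rescaled to target units
per z-scored regressor unit. An optional Hamming-window basis smoothing is
provided with a default width of 1 ms, which is below one sample at 128 Hz
and therefore a no-op.

Cross-validation: segments are partitioned in order into six contiguous
groups, sizes as equal as possible with extras to the earliest groups
(25 → 5,4,4,4,4,4); fold f tests on group f, validates on group f+1 (mod 6)
and trains on the rest. The exact segment-to-group assignment is not
identifiable from the study design; the contiguous in-order rule is the
package's choice and a seed can shuffle the order. Electrodes are fitted
independently (no joint stopping); zero-variance predictions (an all-zero
kernel) score accuracy 0 in the model fit, while the bare
`encoding_accuracy` primitive returns NaN for degenerate inputs.

## Synthetic cohort

The generator emulates the structure of a natural-listening EEG study:
44 participants (25 with MoCA ≥ 26, 19 below), 25 segments of 45 s at
128 Hz, 9 midline electrodes (F3 Fz F4 / C3 Cz C4 / P3 Pz P4). EEG is the
forward model the analysis assumes — per electrode the sum over features of
the lag-kernel convolution of the z-scored regressor, scaled by spatial
weights — plus 1/f noise band-passed to 0.5–25 Hz and scaled so the
band-limited signal-to-noise variance ratio equals the configured `snr`
(default 10). A participant-specific gain `1 + group_effect·[low] +
pta_effect·PTA_z` multiplies the word-onset kernel only, giving the
pipeline a known, signed hearing effect to detect; defaults are
`group_effect = 0` (no cognitive-group effect) and `pta_effect = −0.3`
(word-segmentation response declines as hearing worsens). PTA is
truncated-normal (mean 20, sd 12 dB HL); MoCA scores are uniform within
group bands; ages centre near 69/72 years. The whole dataset is a pure
function of the configuration including its master seed (per-participant
and per-segment streams are spawned deterministically).

Choices made for realism, and what they buy:

- **Lexicon**: 500 random words, pronunciations of geometric length
  (minimum 2, median ~3 phonemes over a 20-symbol alphabet), Zipf
  frequencies with exponent 1.5. This yields a token-level spread of word
  log-frequencies (sd ≈ 3.6 bits) comparable to running text. The spread
  matters: the linguistic channels place value-scaled impulses at the same
  instants as the onset channels, so residualization removes the projection
  of the onset response onto them — with near-constant values almost the
  entire word-onset response would be removed, which real corpora do not do.
- **Transcripts**: words sampled frequency-proportionally; log-normal
  phoneme durations (median 80 ms); small exponential inter-word gaps with
  occasional sentence-like pauses; ~0.47 s initial silence. Segments are
  ≥ 90% speech.
- **Envelope**: band-limited (0.5–25 Hz) flat-spectrum noise. A
  modulation-rich stimulus keeps the lagged acoustic design well
  conditioned; 1/f noise is reserved for the EEG noise term.
- **Word surprisal**: a "contextual" provider — unigram probability
  attenuated by a half-normal number of extra bits (sd 3) — emulating the
  context-driven variance of language-model surprisal. The plain unigram
  provider (the package default for real data without a language model)
  would make word_surprisal identical to word_frequency and the nuisance
  design exactly singular.
- **Ground-truth kernels**: smooth Gaussian composites — a P1–N1–P2 chain
  for the acoustic features, an early positive/late negative pair for the
  onset features, N400-like late negativities for the lexical features —
  with frontal emphasis for acoustic and central emphasis for
  word/phoneme-level responses. The word-onset kernel amplitude (1.5/−1.2)
  is comparable to the envelope kernel; a substantially smaller one would
  leave no detectable word-segmentation signal after residualization, since
  the word-initial phoneme-entropy value is a constant (whole-lexicon
  entropy) and its channel is therefore partly proportional to the
  word-onset train. That collinearity is a property of the analysis design,
  not of the simulation.

What the generator does **not** emulate: real acoustic waveforms (the
envelope is a stochastic process, not derived from audio), per-event neural
amplitude variability, artifacts (ocular, muscular), electrode covariance
of the noise (independent across electrodes), non-stationarity, and any
true coupling between cognition and neural encoding (the default group
effect is zero, matching a null finding). Passing tests therefore show the
pipeline is correct and sensitive under its own forward model, not that
real-data effect sizes would match.

## Statistics

Three mixed-model specifications share one machinery:
`accuracy ~ group × PTA_z × model`, `rms ~ group × PTA_z + feature +
cluster`, `rms ~ group × PTA_z + cluster`, each with a participant random
intercept. Categorical predictors are sum-to-zero coded (reference levels:
acoustic model, cluster F, features envelope / word surprisal / phoneme
surprisal); the MoCA group is coded +1 (low) / −1 (normal), or replaced by
the standardized score in the continuous variant; PTA is standardized.

The REML fit is computed in closed form per participant block (Woodbury)
and profiled to a one-dimensional search over the variance ratio; the
response is internally normalized to unit scale so tiny-variance responses
(RMS values ~10⁻³) remain well conditioned. Satterthwaite degrees of
freedom for a contrast c use 2·f²/(gᵀ A g) with f = Var(cᵀβ̂), g its
finite-difference gradient in (τ², σ²) and A twice the inverse
finite-difference Hessian of the REML criterion; on balanced designs this
reproduces the classical ANOVA df exactly (between 40; within 160, 350 or
745 for the designs above). A zero random-intercept variance is flagged as
singular and the residual df is used as a fallback when the curvature is
unusable. Confidence intervals come from a seed-controlled parametric
bootstrap of the fitted model (default 500 resamples; percentile
intervals; Wald intervals when `n_boot = 0`, the pipeline default for
runtime). Estimated marginal means average over the group factor;
model-vs-acoustic differences at PTA z ∈ {−1, 0, +1} are Tukey-adjusted via
the studentized range with k = number of model levels. The statsmodels
MixedLM implementation serves as an independent cross-check in the tests,
not as the fitter.

Nonparametric layer: Mann–Whitney U (U of the first group; asymptotic p
with continuity correction and tie-corrected variance, exact enumeration
for small samples), signed rank-biserial r = 1 − 2U/(n₁n₂),
Holm–Bonferroni within a family = all clusters of one (feature, window,
measure) combination, and Spearman ρ with Fisher z = atanh(ρ).

Peak analysis: responses are averaged over each 3-electrode cluster,
z-scored over the full lag axis, and peaks of either polarity with
topographic prominence ≥ 0.5 (standard prominence definition on the
z-scored trace — the published gloss of the parameter does not match the
standard definition, so the standard one is used and recorded) are pooled;
latencies below 0 ms are discarded and the two largest by absolute
amplitude kept, amplitudes reported on the original scale. Early/late
boundaries per feature: 1-D K-means (k = 2, 100 restarts, seeded) over
latencies pooled across participants and clusters, boundary = mean of the
two centres. A (feature, cluster, window) cell enters the group comparison
only if ≥ 75% of participants show a peak there (inclusive threshold).

## Problem sizes used by the test suite

Study-scale defaults stay on the generator; the suite scales the cohort,
not the method: kernel-recovery checks keep the full per-participant data
volume (25 × 45 s, 9 electrodes, SNR 10) with 3 participants; the
end-to-end interaction-recovery check runs 20 seeds of 10 participants ×
8 × 25 s segments × 3 electrodes with the default `pta_effect`. The whole
suite runs in about five minutes on one CPU.

## Known limitations

- Only a random-intercept random-effects structure is supported (as in the
  analyses it implements); no random slopes.
- Boosting kernels are step-quantized (multiples of 0.005 before fold
  averaging); correlated features are split greedily, so kernel attribution
  between strongly collinear channels remains slightly biased relative to
  the OLS limit.
- The residualization step inherits the identifiability limits of the
  analysis design itself: responses proportional to nuisance-predictable
  components (e.g. the constant word-initial entropy impulse) are removed
  from every model's target.
- The TextGrid reader covers the interval-tier text formats (long/short,
  UTF-8/16); point tiers are skipped.
- The word-surprisal provider interface accepts any left-context predictor,
  but no pretrained language model is bundled.
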