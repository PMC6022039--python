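# Methods

## Problem setting

Automated acoustic monitoring of anurans classifies short field recordings
into call classes (e.g. mating, release and distress calls of two species).
Each recording is cut into overlapping frames; a frame's spectrum is
summarized by a feature vector; a classifier labels frames; and the
recording receives the majority frame label. The scientific question the
package addresses is *which spectrum representation* — an MPEG-7-style
descriptor signature, raw filter-bank energies, or mel-cepstral
coefficients — supports the best classification at a given feature budget,
and how the eleven extraction options should be set.

## The synthetic corpus

Field corpora of labelled calls are rarely redistributable, so the package
ships a generator whose defaults emulate the statistical structure such a
corpus presents:

* **Classes.** Four call classes mixed 43/7/48/2 % (largest-remainder
  rounding makes counts sum exactly to `n`). Each class is a pulse-train-
  gated harmonic stack: fundamentals 800–3500 Hz, 2–6 harmonics with
  3–8 dB/harmonic roll-off, pulse rates 5–40 /s with duty cycles 0.35–0.8.
  These values are package choices tuned so classes are separable but
  overlap in individual dimensions; they are not measurements of real
  calls. Small seeded jitter (±2 % fundamental, ±5 % pulse rate) makes
  recordings within a class distinct.
* **Durations.** Normal(5 s, 1.5 s), clipped at 0.5 s, matching the ~5 s
  per-recording average of field datasets.
* **Noise.** White (default) or pink (−10 dB/decade shaped) noise added at
  a per-recording target SNR drawn from Normal(35 dB, 8 dB). SNR is
  defined over the whole recording — clean-call power over added-noise
  power — and the mixing scale is exact, so the achieved SNR always sits
  within 0.5 dB of target.
* **Instance selection.** The highest-SNR 10 % of each class (at least one
  recording) become *pattern* recordings, the only data classifiers ever
  train on; their SNRs are rigidly shifted so the pattern median equals
  48 dB, 13 dB above the corpus median, and never drop below the corpus
  median. The remaining recordings split 50/50 per class into validation
  (for option selection) and test (for reporting), always at recording
  level — frames of one recording never straddle splits.

What passing tests on this corpus do **not** show: robustness to
reverberation, overlapping choruses, non-stationary noise, or real
within-class variability of amphibian vocal tracts; the generator has none
of these (deliberately — see Non-goals below).

## Front-end conventions

* **Pre-emphasis** `s'(n) = s(n) − α·s(n−1)` with `s(−1) = 0` is applied to
  the whole signal before framing (time-domain processing precedes
  framing in the pipeline diagram convention).
* **Framing.** `N = round(rate·Tw/1000)` with round-half-up (44.1 kHz,
  30 ms → exactly 1323 samples; 25 ms → 1103). Frame count
  `F = floor((L−N)/S) + 1`; trailing samples that cannot fill a window are
  discarded — no padding. Start times are reported in seconds.
* **Hamming window.** The raised-cosine form `0.54 ± 0.46·cos(2πn/N)`
  admits two phasings; the default is the periodic convention
  `0.54 − 0.46·cos(2πn/N)` over indices 0…N−1 (edges 0.08, centre 1), with
  the centred form available for plotting the window about its peak.
* **Power spectra.** One-sided, `nfft` = next power of two ≥ N with
  zero-padding, normalized so bin powers sum to the windowed frame energy
  (Parseval). FBE uses *power* (not magnitude) spectra; the choice only
  rescales log-energies by a factor of two and is configurable.
* **Mel scale.** `m = c·ln(1 + f/700)`. The conventional anchor — 1000 mel
  at 1 kHz — fixes `c = 1000/ln(1+1000/700) ≈ 1127.01`, the default. A
  legacy constant of 1197, which appears in parts of the literature but
  breaks the anchor (1197·ln(1+1000/700) ≈ 1062), is selectable via
  `mel_constant` for strict comparisons.
* **Filter banks.** Rectangular banks partition `[Lf, Hf]` into `M` equal
  bands (each in-range bin belongs to exactly one band, so total in-band
  power is conserved). Mel banks place `M` unit-peak isosceles triangles
  with centres evenly spaced on the mel axis and 50 % overlap (each
  triangle's feet are its neighbours' centres — the HTK geometry).
* **Log energies** use a floor of 1e−12 × the largest energy in the
  matrix, keeping silent bands finite without compressing useful dynamics.

## Cepstrum

The log-FBE of a frame is expanded on an orthonormal basis over the filter
index: DCT-II (default; suits the even symmetry of spectra and decorrelates
smooth profiles better) or a real DFT with each harmonic's cosine/sine pair
packed into consecutive coefficients. Both bases are orthonormal, so
truncation errors are comparable and reconstruction error is monotone
non-increasing in `C`.

**Coefficient counting.** "C cepstral coefficients" keeps quefrency indices
1…C, excluding the mean term c₀ (the HTK convention — e.g. C = 13 with
M = 20). The corner case C = M cannot mean indices 1…M of an M-point
transform; here it returns the complete orthonormal set *including* the
mean term, so a 20-filter bank yields 20 features and the expansion is
exactly invertible. The mean term is always carried alongside truncated
cepstra so the log-FBE can be approximately reconstructed.

**Liftering** rescales coefficient `i` by `1 + (L/2)·sin(πi/L)` (maximum
gain `1 + L/2` at `i = L/2`); it is exactly invertible and only applied
when `L` is set — the optimized configuration omits it.

## MPEG-7-style descriptors

The 18-value frame signature follows the MPEG-7 low-level audio
descriptors in simplified per-frame form (the module is MPEG-7-*style*,
not conformance-tested):

* five spectral values — total power, in-band ("relevant") power, power
  centroid, power-weighted frequency spread, and flatness
  (geometric/arithmetic mean of in-band powers);
* eleven LPC-derived values — autocorrelation-method LPC (order 12 by
  default, solved via Toeplitz normal equations; roots outside the unit
  circle reflected to radius 1/r). Pole angles/radii give the first three
  formant frequencies `θ·rate/2π` and bandwidths `−(rate/π)·ln r`;
  candidate poles broader than 500 Hz are discarded as envelope poles
  unless no narrow pole exists. Pitch is the normalized-autocorrelation
  peak over a 50–4000 Hz lag band with a 0.3 voicing threshold. Harmonic
  centroid/spread are amplitude-weighted moments over the spectral peaks
  near pitch multiples; harmonic deviation is the mean log-amplitude
  distance from a 3-point smoothed envelope; harmonic variation is one
  minus the normalized correlation with the previous frame's harmonic
  amplitudes;
* two harmonicity values — the harmonicity ratio (maximum normalized
  autocorrelation over candidate pitch lags, in [0, 1]) and the upper
  limit of harmonicity (highest harmonic frequency below which cumulative
  harmonic-band energy keeps ≥ 50 % of cumulative total energy).

Undefined cases (silent or unvoiced frames) yield a numeric sentinel of 0
with a logged note, because downstream classifiers need finite features.
The analysis band for "relevant power" and the LPC order are configuration
with defaults (64 Hz–16 kHz preset band; order 12): assumptions, not
field-standard facts.

## Classifiers

All training uses pattern frames only; the API never exposes validation or
test labels to a model. From scratch: minimum distance (per-class feature
means, squared-Euclidean decision, ties to the lowest class), Gaussian
maximum likelihood (full covariance with an escalating ridge toward scaled
identity; priors from training counts), LBG vector quantization (binary
splitting from the global centroid, k-means refinement, dead cells
reseeded at the farthest sample), and per-class discrete HMMs (Baum–Welch
with floor-smoothed stochastic matrices; classification by scaled forward
log-likelihood). The HMM consumes each recording's frame sequence — the
one sequential classifier; all others label frames independently, followed
by majority vote per recording (ties to the lowest class, logged).

Wrapped scikit-learn learners with pinned registry defaults: decision tree
(Gini), kNN (k = 5), SVM (RBF, one-vs-rest), multinomial logistic
regression, a feed-forward network with one 10-unit hidden layer, linear
discriminant, Gaussian naive Bayes. Distance-based and neural learners
(MinDis, kNN, SVM, the network) are preceded by a z-score standardization
fitted on the pattern frames, because unweighted Euclidean distance is
scale-sensitive. HMM defaults (3 states, 32-codeword codebook) are package
choices recorded in every results file; the codebook halves automatically
when the training data have fewer distinct frames.

## Metrics and model selection

Each class is reduced one-vs-rest to (TP, FN, FP, TN) and scored with ACC,
ERR, PRC, SNS, SPC, ROC = √((SNS²+SPC²)/2), F1 and GM = √(SNS·SPC). Macro
averages are unweighted over classes; per-class values with a zero
denominator are excluded (not zeroed) from the macro mean and the number
of exclusions reported — zeroing would silently penalize rare classes.
GM ≤ ROC always (AM–QM inequality), and ACC + ERR = 1 exactly. The best
classifier is the argmax of macro GM (ACC and ROC selectable), ties broken
by registry order. Headline numbers are recording-level; frame-level
reports are available.

## Option search

The coordinate search starts from a preset, scans the 11 options in the
option-table row order (α, window, Tw, Ts, Lf, Hf, M, scaling, transform,
C, L), evaluates each grid's non-incumbent values, and fixes each winner
before the next scan: `1 + Σ(Oᵢ − 1) = ΣOᵢ − 10` evaluations for 11
options. On an almost-flat scan the incumbent survives unless a candidate
wins by more than 0.1 GM percentage points (configurable), which
reproduces keep-the-default outcomes without hand intervention. Grid
points that violate cross-option constraints mid-scan (e.g. C > M after M
shrinks) are counted against the budget and recorded as infeasible rather
than silently skipped, so the trace length always matches the closed form.
The objective scores the validation split; the search is greedy and
order-dependent by design — exhaustive search over 10¹¹ combinations is
the explicitly rejected alternative.

The eight-stage ladder isolates each ingredient's contribution at a fixed
18-feature budget: MPEG-7 descriptors → linear FBE → log energies → mel
axis → optimized Tw/Lf/Hf → DCT cepstrum (C = M = 18) → optimal Tw →
optimal band. Stages differ by exactly the documented option deltas, which
the tests assert structurally.

## Problem sizes and numerical choices

The reference benchmark (tests and `scripts/acceptance.py`) uses 100
recordings under the default corpus conditions and all ten classifiers —
about 20 s on one CPU. Unit and pipeline tests use 4–30 short (≈1 s)
recordings built from duration-shortened class specs; corpus *conditions*
(class mix, SNR profile, pattern selection) are never altered for tests.
Tolerances: Parseval and partition identities at 1e−6/1e−9 relative;
cepstral inversion at 1e−9; lifter round trip at 1e−12; SNR within 0.5 dB;
seeded statistical checks (LPC pole within 1 %, Gaussian means within 3
standard errors, HMM chain recovery ≥ 95 %) at fixed seeds.

## Known limitations

* The synthesizer models neither vocal-tract filtering, reverberation nor
  multi-animal choruses; benchmark numbers measure pipeline correctness
  and the relative ordering of representations on controlled data, not
  field accuracy.
* MPEG-7 descriptors are simplified per-frame forms, not a certified
  implementation of the standard.
* The coordinate search is greedy; it finds the exhaustive optimum only
  when option effects are approximately separable.
* Wrapped learners inherit scikit-learn's defaults where the registry does
  not pin them; other toolkits' defaults will differ in detail.
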