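# Methods

This note records the models, conventions and numerical choices behind
`hrvcomplexity`, in the spirit of a statistical package's model
documentation: what each component assumes, which parameters matter,
and what the synthetic data can and cannot establish.

## Data model

Two containers cover every analysis path. A `UniformSignal` is an
evenly sampled waveform with a sampling rate in Hz (respiration and EDA
at 32 Hz in the emulated protocol; resampled tachograms at 4 or 10 Hz).
An `EventSeries` is a physiologically timed interval series — RR
intervals in milliseconds or breath intervals in seconds — with each
event stamped at the *end* of its interval, times in seconds from the
recording start. Interval files on disk are unitless one-per-line
numbers; the declared kind assigns units. Times are 0-based and all
segmentation uses half-open `[start, end)` windows, so segment
boundaries are unambiguous.

The tachogram abscissa is the event end-time (each interval plotted at
the beat that closes it), the common HRV convention. Breath-interval
series (IN, OUT, peak-to-peak) are stamped at the peaks/troughs that
close them; because inbreaths and outbreaths interleave, their times
are *not* running sums of their own intervals, and the running-sum
consistency check enforced for RR series is relaxed for them.

## Fractal dimensions

All estimators treat the sequence as the graph of a function with unit
abscissa steps. Non-resampled interval series may be analysed directly
this way; resampling to 4 or 10 Hz gives a different but equally valid
view, and results from the two should not be pooled.

* **Higuchi.** Mean normalised curve length L(k) over the k
  phase-shifted subsampled curves, k = 1..kmax; FD = −slope of a plain
  least-squares line of ln L(k) on ln k, all k included (no scaling
  region selection). Default kmax 10; the tuner can sweep 2..15. The
  estimator is accurate on fBm benchmarks (2 − H within ~0.01 at
  n = 10⁴).
* **Katz.** FD = ln n / (ln n + ln(d/L)) with the curve in the
  (sample-index, amplitude) plane. Katz's mixing of abscissa and
  ordinate units makes the value depend on amplitude calibration; the
  estimator is kept for comparability.
* **Castiglioni variant.** The same formula with L and d measured on
  the ordinate alone (L = Σ|Δx|, d = max|x_i − x_0|). This makes the
  estimate scale-invariant, which is the essence of the criticism of
  Katz's calibration dependence. We initially considered normalising
  the ordinate by the mean absolute successive difference while keeping
  the unit abscissa, but that variant provably cannot distinguish white
  noise from Brownian motion (both have Gaussian increments, and the
  normalisation removes the only scale difference), so the time-free
  form was adopted. Values are not confined to [1, 2]; they are
  reported unclamped, as for all estimators.
* **Petrosian.** Binarisation first (a: above/below mean; b: sign of
  successive differences; c: large successive differences), then
  FD = log N / (log N + log(N/(N + 0.4·NΔ))) with NΔ the number of
  changes in the binary sequence. The a/b/c order follows the order in
  which the three binarisation rules are conventionally listed.
* **Sevcik.** Curve mapped into the unit square;
  FD = 1 + ln L / ln(2(N−1)).
* **Box-count.** The piecewise-linear graph is embedded in the unit
  square; for 2^j boxes per side the graph's vertical span per abscissa
  column (with interpolated column-boundary values — exact for a
  continuous piecewise-linear graph) gives the occupied-box count.
  Scales run from 4 boxes per side to N/4; FD is the least-squares
  slope of log N(ε) against log(1/ε). The `mvdl` variant fits only the
  middle half of the scale range. Finite-size bias is about −0.08 at
  n = 8192 on Weierstrass graphs of dimension 1.5 (the estimate
  converges from below as n grows); the companion Higuchi estimate on
  the same signals reads ≈1.48.
* **NLD.** Amplitude-normalise to [0, 1]; NLD = mean |successive
  difference|; map to FD through a calibration fitted on random-phase
  Weierstrass graphs of known dimension (grid 1.1..1.9, eight
  realisations each, length 1024). Linear form FD = 1 + a·NLD and
  power form FD = 1 + a·NLD^b, both anchored at (NLD 0 → FD 1). The
  frozen constants ship in `DEFAULT_NLD_CALIBRATION`;
  `fit_nld_calibration()` reproduces them, and held-out Weierstrass
  signals validate the power form to ±0.1 at D = 1.5. Because NLD
  depends on sampling density, the calibration is honest only near its
  fitting length; the power form extrapolates better than the linear
  one, which is crude in the mid-range (≈1.31 at D = 1.5) and retained
  only as the documented linear variant. `w` variants average NLD over
  non-overlapping windows (default 128 samples) before mapping — for
  stationary signals this coincides with the whole-series `i` value.
* **Maragos.** Morphological cover areas A(s) = Σ(dilation_s −
  erosion_s) with a flat structuring element of half-width s, both axes
  in sample units; local dimension 2 − slope of ln A on ln s over
  sliding 3-scale windows gives a multiscale profile, reduced by the
  mean (median and max are available; the single-number summary is not
  standardised in the literature, so the reduction is explicit and
  configurable). The smallest scales are discreteness-biased, so the
  default scale list starts at 2; benchmark scale lists starting at 4
  read fBm dimensions to within ±0.15.

Shared contracts: every estimator is invariant under adding a constant;
Higuchi, Sevcik, NLD, box-count (and the Castiglioni variant) are also
invariant under positive amplitude scaling. Degenerate (constant)
inputs yield an explicit undefined flag or a validation error, never a
silent number.

## Heart-rate asymmetry

"Up" always means *above the line of identity*, i.e. decelerations
(RR lengthening), matching the SD1up/SDNNup naming; part of the
literature writes the same quantities with a/d subscripts. The
transverse distances d_i = (x_{i+1} − x_i)/√2 are pooled about zero
(second moment), which is the convention under which
SD1up² + SD1down² = SD1₀², C1a + C1d = 1 and
SDNNup² + SDNNdown² = SDNN² hold exactly; the longitudinal split uses
deviations about the centroid with on-identity points contributing half
weight to each side, preserving the SD2 identity. Guzik's and Porta's
indices exclude on-identity points from their denominators. The
asymmetric spread index is realised as 100·s_up/(s_up + s_down) with s
the RMS transverse distance per side — 50 for mirror-symmetric clouds,
antisymmetric under time reversal, strictly increasing when
deceleration spread grows; these contract properties, rather than a
specific printed constant, are its tested surface. Asymmetry indices
are computed on beat-ordered interval series; resampling destroys beat
ordering, so resampled inputs are scientifically dubious here.

The complex correlation measure is the mean absolute area of triangles
through consecutive lag-m Poincaré points, normalised by π·SD1·SD2 —
zero for collinear plots, undefined when SD1·SD2 = 0.

## Permutation entropy

Windows of order m at lag τ map to the permutation that sorts them
ascending, ties broken by original position (stable argsort) — the
common toolbox convention. Defaults m = 3, τ = 1; orders above 7 are
refused (factorial blowup). The composite index (CPEI) alone uses
explicit tie patterns: order-3 distributions at τ = 1 and τ = 2, with
any window containing a near-equal adjacent pair (|difference| ≤
threshold) diverted to a single tie slot, pooled by summing counts and
normalised by ln 7 (six patterns + tie slot). With a small threshold an
i.i.d. series therefore reads ln 6/ln 7 ≈ 0.921, not 1.0 — the tie slot
is part of the alphabet.

Entropy families: Shannon, Rényi (default α = 2), Tsallis (default
q = 2, normalised by its own maximum), and min-entropy (−ln max p).
Logs are natural; all normalised outputs live in [0, 1]. Plain PE and
min-entropy are invariant under strictly monotone amplitude transforms;
the amplitude-aware (AAPE, window weight A·mean|x| + (1−A)·mean|Δx| on
a scale-normalised series) and edge-weighted variants deliberately are
not. The Jensen–Shannon complexity multiplies normalised Shannon PE by
the Jensen–Shannon divergence from the uniform pattern distribution,
scaled by its analytic maximum.

Multiscale versions coarse-grain by non-overlapping means: `mPE`
re-estimates PE per scale, `ImPE` averages the ordinal distributions
over all coarse-graining offsets before one entropy (lower variance at
large scales), `mPM_E` applies the min-entropy functional.

## Spectra and the resonance-breathing scorecard

The tachogram is resampled by monotone (shape-preserving) piecewise
cubic interpolation — no overshoot beyond the input range — at 4 Hz by
default, then linearly detrended. Welch spectra use 150-s Hann
segments, 50 % overlap and 4× zero-padding; the padding removes
scalloping loss at breathing frequencies that fall between bins, which
otherwise biases peak-power comparisons across paced rates by up to
~15 %. Burg autoregressive spectra (default order 16) are the
smoother alternative; the Lomb–Scargle periodogram handles the
non-resampled beat series directly, rescaled so its integral equals the
series variance (peak locations are unaffected by this calibration).

Bands: LF 0.04–0.15 Hz, HF 0.15–0.40 Hz (configurable); slow paced
breathing at 5–7 breaths/min lies inside LF by design. Band power is a
trapezoidal integral; peak power (PLFP) is the density at the band
argmax times the equivalent noise bandwidth of the estimator, in ms².
Normalised units divide by LF+HF power, so LF nu + HF nu = 100 by
construction. HRMaxMin averages the per-breath-cycle HR excursion;
the HR–respiration phase is the cross-spectral phase at the breathing
frequency, positive when HR lags.

RBR selection is the argmax of PLFP over the externally paced trials,
ties to the slower rate (selection is invariant to any monotone
rescaling of PLFP). The self-paced trial can be admitted with a flag,
since some individuals peak higher there. A full clinical tie-break
would weigh comfort and the other scorecard measures and requires
judgement; the scorecard reports the conflicting quantities and stops
there.

## The synthetic cohort

The generator emulates the study conditions every pipeline stage is
tested against: 44 subjects; Baseline (normal breathing, 12–16
breaths/min), self-paced slow breathing (≈6 breaths/min with jitter),
and five paced trials at 7, 6.5, 6, 5.5 and 5 breaths/min, each 315 s.
Respiratory sinus arrhythmia is modelled as a second-order resonance:
the RR modulation amplitude at breathing frequency f_b is
A = G/√((1 − (f_b/f0)²)² + (f_b/(Q·f0))²), with the subject's
resonance frequency f0 drawn from the paced-rate grid, quality Q = 3,
and gain G = 30 ms. G was calibrated so that the measured within-breath
heart-rate excursion at resonance (~14 bpm) sits at the centre of the
10–20 bpm range typical of slow breathing at resonance; mean RR is
900 ms and pink (1/f) noise of sd 15 ms models intrinsic HRV. Beats
fire by integrate-and-fire on the instantaneous RR duration; paired
respiration uses the pacer waveform (rising half-cosine over 40 % of
the cycle, falling over 60 %, no pause) with mild cycle jitter. EDA is
a decaying tonic level plus sparse bi-exponential phasic events and
white noise at 32 Hz.

What the cohort establishes: that the full chain — beat generation,
resampling, spectra, scorecard, measures, statistics — recovers
built-in structure (resonance rates recovered for ≈94 % of subjects;
RSA-sensitive measures separate trials at Friedman p < 0.001; SD1
rises and FD/entropy measures fall from Baseline to resonance, nearly
unanimously). What it cannot establish: real ectopy and artefacts,
baroreflex nonlinearity, genuine heart-rate asymmetry (the generator
is time-symmetric, so asymmetry indices correctly sit near 50 %), and
measurement noise of physical sensors. Recovery errors concentrate at
f0 = 7 breaths/min, where the resonance gain gap to the 6.5 trial is
only ~3 % and pink-noise interference at the spectral peak can flip
the comparison — a physical limit of these conditions, not an
estimator defect (noise-free runs order all trials correctly).

## Statistics

Friedman uses within-block midranks with the tie-corrected statistic;
Kendall's W = χ²/(N(k−1)). Conover all-pairs post-hoc:
t = |R_j − R_l| / √(2N(A − B)/((N−1)(k−1))) on (N−1)(k−1) degrees of
freedom, Bonferroni-adjusted over the tested pairs (the strict
conventions used throughout: Friedman significance p < 0.001, post-hoc
adjusted p ≤ 0.001, Bonferroni rather than FDR). Perfectly concordant
rankings make the Conover standard error zero; the statistic is then
reported as infinite and pairs are ordered by their rank-sum
differences. Statistics are standardised by dividing by the set
maximum; top-slicing retains entries ≥ 0.8 (the maximum always
survives). ICC is the two-way consistency form
(MSR − MSE)/(MSR + (k−1)·MSE), invariant to column offsets.
Mann–Whitney uses midranks, tie-corrected normal approximation without
continuity correction, effect size |Z|/√N. Direction counts call a
change consistent when the increase proportion exceeds 0.795 or falls
below 0.205 — at n = 44, that is ≥ 35 increases or ≤ 9. Robust
descriptors: RoCV = 1.4826·MAD/|median|, RoSlope = Theil–Sen slope
against sample index.

The parameter tuner evaluates four strategies over a swept grid
(pooled robust CV; median difference between trials; median paired
|difference|; count of per-participant maximal |differences|), takes
the modal selection, and breaks modal ties by preferring the strategy
whose increase/decrease sign ratio is farthest from 1.0 (measured on
the log scale, all-one-direction counting as infinitely far),
reporting "ambiguous" when that also fails to single out a parameter.
All iteration orders are fixed, so the tuner is deterministic.

## Numerical conventions

Sample standard deviations (n−1) for SD1/SD2; second moments (1/n)
for the asymmetry decomposition, as the identities require. Welch ENBW
is fs·Σw²/(Σw)². Spectral floors, zero-variance inputs, constant
series, all-on-identity Poincaré plots and empty grid cells raise
explicit errors or return flagged undefined values. Every random
component takes an integer seed (NumPy `default_rng` / `SeedSequence`
streams), so all generators, noise injections and cohorts are
reproducible bit-for-bit.

## Problem sizes

Benchmarks use n = 10⁴ samples (20 seeds) for fBm/noise fractal
ground truths, n = 8192 for Weierstrass box-count checks, 2000
simulations for the Friedman type-I error, and three to four
44-subject cohorts for resonance-recovery rates; these sizes give
standard errors comfortably inside the tolerances asserted and keep
the full suite around half a minute.

## Known limitations

Box-count and NLD carry finite-size calibration bias documented above.
The Burg spectrum's peak power depends on model order near sharp
peaks. CPEI's tie-pooling (summing the two lag distributions) is one
of several defensible readings of the composite index. The Castiglioni
and ASI realisations are contract-tested interpretations of briefly
published definitions. `.mat`/`.xlsx` ingestion is out of scope
(plain text and CSV cover the supported flows), as are artefact and
ectopic-beat correction, which are assumed done upstream.
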