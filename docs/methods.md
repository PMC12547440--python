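# Methods

This note documents the models and procedures implemented in `esgkit`, the
assumptions behind them, the defaults of the synthetic-data generator, and the
numerical choices made where the underlying methods literature leaves the
design open.

## The problem

Electrospinography (ESG) records spinal cord activity from surface electrodes
on the neck and lower back. Because the electrodes sit close to the heart, the
cardiac field contaminates the recordings with an artefact two to three orders
of magnitude larger than the somatosensory evoked potentials (SEPs) of
interest — on the order of hundreds of microvolts against roughly 1 µV for
the cervical N13 (a negative deflection ~13 ms after median-nerve stimulation)
and the lumbar N22 (~22 ms after tibial-nerve stimulation). The package
implements five cardiac-artefact removal algorithms, two evoked-response
enhancement algorithms, the evaluation metrics used to compare them, and a
ground-truth simulator so the whole suite is testable without access to real
recordings.

## Preprocessing ("Uncleaned" data)

All methods operate on data preprocessed in a fixed order: linear
interpolation of the electrical stimulation artefact between −7 and +7 ms
around each stimulus; polyphase anti-aliased downsampling to 1000 Hz; a
zero-phase FIR notch at 50 Hz; a zero-phase 2nd-order Butterworth bandpass
1–400 Hz. The notch can be deferred until after cardiac cleaning
(`notch_stage="post"`) for workflows where line-noise removal is preferred
late; the default applies it before cleaning. Events are mapped to the new
sampling rate by nearest sample, with strict monotonicity enforced for
R-peaks.

R-peaks are detected on the ECG channel by bandpassing 5–30 Hz, squaring,
thresholding at 0.5× a blockwise (2 s) 95th percentile, enforcing a 300 ms
refractory period, and refining each apex on the raw trace by largest absolute
deviation from the local median (polarity-insensitive). External event TSVs
(`onset_sample`, `kind`, `condition`) can bypass detection entirely.

## Cardiac artefact removal

**PCA-OBS** operates per channel. Occurrences are extracted in windows of
±0.5 × median RR around each R-peak (the window fraction is configurable);
PCA on the mean-removed occurrence matrix yields principal components, and the
mean artefact plus the first four PCs form the optimal basis set. The basis is
fitted to each occurrence by ordinary least squares and subtracted. Fitted
windows are accumulated into a continuous artefact estimate; where consecutive
windows do not abut (RR above the median), the gap is filled by PCHIP
interpolation anchored on the neighbouring fits — without this, islands of
raw artefact between windows dominate the residual. PCHIP likewise maps
fitted windows onto clipped sample grids at the recording edges. An optional
Tukey taper (α = 0.25) on each fitted window softens subtraction edges; it is
off by default because tapering trades residual amplitude at window edges for
a larger overall residual.

**ICA + CTPS**: FastICA (parallel updates, logcosh contrast, full-rank
whitening, tol 1e−6, max 1000 iterations, seeded) with as many components as
ESG channels across both patches. Cardiac components are selected by
cross-trial phase statistics: the analytic-signal phase of each component is
epoched in a 1 s window centred on each R-peak and, per time point, tested
against phase uniformity with the Kuiper statistic, normalised through
Stephens' tail approximation to a score in [0, 1]; a component's score is the
maximum over time points, and components above 0.25 are zeroed before inverse
transformation. The 0.25 default is the established threshold for this
normalisation; under the null (white noise, 500 beats) the score stays far
below it, giving a false-flag rate of effectively zero, while strongly
phase-locked components score near 1.

**SSP** extracts orthonormal projection vectors from the SVD of the
R-peak-locked average (epochs −0.2 to 0.4 s) and removes their span with
I − U_k U_kᵀ. An epoch-covariance source is available as a config switch; the
evoked-average source is the default because the artefact is defined by its
beat-locked repeatability.

**CCA-cardiac** (canonical correlation average regression): X concatenates
single-beat epochs (−0.4 to 0.6 s), Y repeats the beat average; the canonical
weights maximising corr(wxᵀX, wyᵀY) are found by SVD of the whitened
cross-covariance, with shrinkage ε = 1e−9·trace/n on both autocovariances for
conditioning. Filters are normalised so W Cxx Wᵀ = I; mixing patterns
A = Cxx Wᵀ, which for square full-rank filter matrices equals W⁻¹, so zeroing
the top-k components and back-projecting is exact. Components are ranked by
canonical correlation.

**DSS-cardiac** jointly diagonalises the covariance C0 of the continuous data
and the covariance C1 of the beat-averaged data (the bias): whiten by C0,
eigendecompose the whitened C1. Scores are power ratios (biased over raw
variance), descending; the first component is the most beat-repeatable linear
combination of sensors. Singular C0 is handled by the same shrinkage.

**Component counts** for SSP/CCA/DSS are chosen automatically by computing
RI(k), INPSR(k) and SNR(k) for k = 1..20 and combining idxSNR = argmax SNR
with the elbows of the RI and INPSR curves via
(0.5·idxRI + 0.5·idxINPSR + 1·idxSNR)/2, rounded to the nearest integer with
.5 rounded up (tie handling is not prescribed anywhere; this is our choice).
Elbows are found Kneedle-style: normalise both axes to [0, 1], flip a
decreasing curve, and take the point of maximum perpendicular distance to the
endpoint chord — which coincides with the maximum-curvature point for convex
monotone curves and is robust on short discrete grids where finite-difference
curvature is noisy. A constant curve has no elbow and raises an error naming
the metric.

## Evoked-response enhancement

**CCA-SEP** applies the same canonical machinery to stimulus epochs (−0.2 to
0.7 s) of the relevant patch only (median → cervical, tibial → lumbar),
training on short post-stimulus segments (7–37 ms median, 7–47 ms tibial —
long enough to include ~25 ms of post-potential data so the noise covariance
is estimable) and applying the top-ranked filter to the full epoch.
**DSS-SEP** biases DSS with the stimulus-locked average over the entire epoch
and retains the first component. Both are polarity-normalised: if the trial
average of the chosen component shows a positive extremum inside the
expected-latency window (13 ± 5 ms median, 22 ± 10 ms tibial — windows reused
from the SNR metric, since no separate polarity window is prescribed), the
component is inverted so the spinal potentials appear with their conventional
negative sign. The full ranked filter set is retained on the result object
for downstream multi-component workflows.

## Metrics, ranking, statistics

* **Residual intensity (RI, %)**: R-peak-locked epochs (−0.3 to 0.4 s,
  baseline −0.3 to −0.2 s) are averaged into a residual evoked response;
  RI = 100 × RMS(cleaned)/RMS(uncleaned) per channel, averaged over the three
  midline channels of interest (S6/SC6/S14 cervical, S23/L1/S31 lumbar).
* **INPSR**: Welch PSD (10 s Hann segments, 50% overlap, hence 0.1 Hz
  resolution matching the band half-width); band power summed over
  m·f0 ± 0.1 Hz for m = 1..5 with f0 = 1/mean RR; the uncleaned/cleaned power
  ratio is log10-transformed per channel then averaged. The log base is a
  choice (only "log transformed" is prescribed); log10 is configurable.
* **SEP SNR**: stimulus epochs (−0.2 to 0.7 s, baseline −0.1 to −0.01 s) are
  averaged; the strongest negative deflection within the expected-latency
  window across the channels of interest is divided by the standard deviation
  of that channel's average over the baseline. The baseline std is taken on
  the trial average (not pooled single trials) — the pooled reading would
  change the scale but not the method ordering.
* **Single-trial CoV**: per-trial peak-to-peak amplitude (max − min) within
  8–18 ms (median) or 12–32 ms (tibial); CoV = sample std (n−1) / mean.
* **Ranking**: per metric, rank 1 is best (smallest RI, largest INPSR/SNR),
  ties share the mean rank; overall = (0.5·rankRI + 0.5·rankINPSR +
  1·rankSNR)/2, lower is better.
* **Rayleigh locking test**: each stimulus is assigned the angle
  2π(t_stim − t_lastR)/RR of the RR interval containing it (stimuli outside
  the R-peak span are dropped with a count logged); the mean resultant length
  and the standard closed-form p approximation are returned.
* **max-T permutation t-tests**: one-sample two-tailed sign-flip permutation
  of the t statistic (10 000 permutations by default, seeded), with
  family-wise adjustment by the permutation distribution of the maximum |t|
  across comparisons; adjusted p ≥ raw p by construction, and the +1/(n+1)
  convention keeps p-values in (0, 1].

## The synthetic generator

`SimParams` defaults define the study conditions the suite is tested under:

* **Geometry**: 17 channels per patch (cervical + lumbar) plus a clean ECG
  channel; midline channels named S6/SC6/S14 and S23/L1/S31.
* **Cardiac artefact**: a PQRST template built from five Gaussians (R apex at
  t = 0, unit amplitude; T-wave latency/width scale with √RR so faster
  rhythms stay physiological), driven by an RR process of mean 0.85 s,
  SD 0.04 s, with lognormal per-beat amplitude scaling (CV 0.05). The PQRS
  complex and the T-wave get distinct smooth cranio-caudal gain gradients per
  patch — making the artefact spatially rank-2, so subspace methods are
  effective but not trivially rank-1 — calibrated to a −297 µV beat-averaged
  peak on SC6 and +657 µV on L1 (the measured cervical ratio of cardiac peak
  to SEP peak is ~345).
* **SEPs**: a biphasic template (negative Gaussian plus a smaller positive
  rebound) peaking at −0.86 µV, 13 ms on the cervical patch and −0.93 µV,
  22 ms on the lumbar patch; a narrow Gaussian spatial bump centred on
  SC6/L1; lognormal trial amplitudes (CV 0.2) and Gaussian latency jitter
  (1 ms median, 2 ms tibial, reflecting the higher tibial variability).
* **Stimulation**: ISI 763 ms with uniform jitter up to ±50 ms, alternating
  condition blocks. The default duration of 790 s yields ~515 trials per
  condition — enough that trial-averaged metrics are stable — with a default
  block size of 50 so both conditions appear early; a block size of 500
  reproduces the alternating-blocks-of-500 protocol when the duration allows.
* **Noise**: 1/f background (exponent 1, 2 µV RMS), white noise (1.5 µV), and
  50 Hz line noise (~5 µV, removed by the notch). The ECG channel carries the
  clean template train.

The generated recording decomposes exactly (bitwise) into
cardiac + SEP + noise, and all randomness flows from one seed.

What the generator does **not** emulate: waveform-shape drift or
non-stationarity of the cardiac artefact (real cardiac activity drifts;
per-beat variability here is a scalar), myogenic/respiratory artefacts, ECG
pathology, T-wave alternans, bad channels, or electrode-impedance drift.
Passing tests on this simulator therefore demonstrate correctness of the
algorithms under a low-rank, quasi-stationary artefact model — not
performance parity with 90-minute real recordings, whose published metric
values (sub-percent RI after cleaning, SNR ≈ 11 after ICA on ~2000 trials)
are dataset properties we do not assert.

## Numerical choices and degenerate inputs

* Shrinkage ε = 1e−9·trace/n on covariances before whitening (CCA, DSS);
  rank-deficient inputs are thereby handled with a logged regularisation
  rather than failure.
* Epoch windows are inclusive of both endpoints
  (length = round((tmax−tmin)·srate)+1); sample indices are 0-based; all
  windows are specified in seconds.
* Overlapping PCA-OBS windows (short RR) both contribute their fits in the
  overlap; the occurrence matrix is built from the original signal, not
  sequentially cleaned data. Occurrences are not baseline-corrected before
  PCA (the mean-effect regressor absorbs the average offset); this choice can
  shift the mean effect by a constant relative to a baseline-corrected
  variant.
* FastICA on (near-)Gaussian data logs a convergence warning and returns the
  last iterate instead of crashing; component selection is score-based, so
  component order is irrelevant.
* Flat ECG, constant metric curves, zero uncleaned RMS, non-positive mean
  peak-to-peak amplitudes, and stimuli outside the R-peak span all raise (or
  log) explicit, named errors rather than propagating NaNs.

## Problem sizes used in tests

Unit tests run on 20–200 s simulations with 3–5 channels per patch; the
end-to-end direction-of-effect checks and the acceptance script use the full
default conditions (790 s, 35 channels, ~515 trials/condition). These sizes
were chosen so that trial-averaged metrics are statistically stable while the
whole suite stays desk-scale.
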