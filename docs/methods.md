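# Methods

This note documents the models, parameter choices and numerical decisions
behind `pulsebench`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Signal model and processing chain

### Contact chain

A wearable blood-volume-pulse (BVP) recording is treated as a uniformly
sampled 1-D waveform. The preprocessing chain is fixed: Fourier
(band-limited) resampling to the working rate, a Savitzky-Golay smoother
(order 4, 19 frames), then a Butterworth band-pass (order 2, 0.7–7 Hz)
applied forward and backward. Choices worth noting:

* **Resampling method.** Band-limited interpolation rather than
  nearest-neighbor or linear, because beat morphology (and hence peak
  timing) must survive the rate change. Resampling is duration-preserving
  to within one sample period and is the identity when source and target
  rates agree.
* **Working rate 30.30 Hz.** Kept as the configurable default
  (`FilterConfig.target_fs`). It is the rate the benchmarked method runs
  at; nothing in the code depends on its specific value.
* **Zero-phase filtering.** The band-pass is applied forward-backward
  (`sosfiltfilt`), doubling the effective order but introducing no group
  delay. Downstream contact-vs-remote comparisons are peak-*position*
  based, so any phase shift here would bias the peak-matching F1.
* **Savitzky-Golay edges.** The edge windows are evaluated with the fitted
  interpolating polynomial (`mode="interp"`), so polynomials up to the
  filter order are reproduced exactly everywhere, edges included.

### Remote (rPPG) core

The camera-side pipeline is: per-ROI spatial channel means → POS projection
→ 0.7–7 Hz band-pass → matched-template convolution filter.

* **POS windowing.** Window length 1.6 s with a one-sample stride and
  overlap-add of de-meaned window outputs, following the original POS
  formulation; the per-window α = σ(U)/σ(V) weighting is exactly the
  published combination rule. Mean-normalization makes the output invariant
  to static per-channel gain (verified to < 1e-6 relative) and suppresses
  common multiplicative illumination.
* **ROI combination.** The three ROI traces are averaged *before* POS by
  default (`mean_before_pos`); projecting each ROI separately and averaging
  the outputs (`mean_after_pos`) is provided because the order is a genuine
  open choice. On the synthetic optical model both recover heart rate
  equally well.
* **Degenerate windows.** A window with a non-positive channel mean cannot
  be mean-normalized; it is skipped and contributes zeros. If every window
  is degenerate the signal is reported flat rather than silently zero.
* **Template filter.** The single-beat template is the average of
  peak-centered segments of the signal itself, amplitude-normalized
  (max |t| = 1). The half-width K defaults to half the median inter-peak
  distance so the template spans about one beat. The filter is implemented
  in correlation form with zero extension, keeping output length and peak
  alignment; with K = 0 and t = [1] it is the identity. Normalizing the
  template makes the output scale-covariant with the input.

### Peak detection and validity screen

Peaks are local maxima with (a) a prominence above a fraction (default
0.25) of the signal's robust amplitude (10th–90th percentile range) and
(b) a minimum separation. The separation floor is the 210 bpm beat period;
by default it is widened to 60% of the dominant pulse period estimated from
the Welch spectrum, with a subharmonic check (if the half-frequency of the
spectral maximum carries ≥ 10% of its power, the half is taken as the
fundamental). The widening is what rejects dicrotic-notch secondary maxima
at low heart rates, where the notch falls outside a 210 bpm refractory but
well inside the true beat period. Detected positions are refined to
sub-sample precision by fitting a parabola through each maximum and its two
neighbors; at a 30 Hz frame rate whole-sample positions quantize inter-beat
intervals to ±16 ms, which is larger than the 20 ms threshold that the
NNi20 feature counts, so the refinement materially changes short-term HRV
features.

The validity rules are applied in a fixed order: (1) a peak is invalid if
either adjacent IBI falls outside [60000/210, 60000/42] ms =
[285.71, 1428.57] ms — invalidity attaches to *both* endpoints of a bad
interval; (2) an interior peak is invalid if its left and right IBIs differ
by 0.5 s or more (strict inequality for validity); (3) the first and last
peaks are always invalid; (4) in exactly one final pass, every neighbor of
an invalid peak becomes invalid. Consequences used as test oracles: a
uniform in-band train of n ≥ 5 peaks has exactly n − 4 valid peaks, and a
single short IBI produces exactly four invalid peaks around it.

### HRV features

RR intervals are taken only between *adjacent* valid peaks; pairs spanning
an invalid peak are dropped, never bridged or imputed. Feature conventions:

* mean HR = 60000/mean(RR), IBI = mean(RR) — coupled by construction.
* RMSSD over the N−1 successive differences with divisor N−1; SDNN is the
  sample standard deviation (N−1). NNi20/NNi50 are raw counts of successive
  differences exceeding 20/50 ms (the proportions pNN20/pNN50 are also
  registered).
* Sample entropy uses m = 2 and r = 0.2·SDNN with Chebyshev distance and
  self-matches excluded, both template sets limited to the first N − m
  vectors. A series with no m-matches is reported degenerate; no
  (m+1)-matches yields +inf. The implementation is checked against an
  explicit O(n²) template-counting oracle on every series length up to 30.
* Frequency features interpolate the tachogram (RR vs cumulative beat time,
  in seconds) onto a uniform 4 Hz grid by cubic spline and integrate the
  Welch PSD over LF [0.04, 0.15) Hz and HF [0.15, 0.4) Hz, giving band
  powers in s². The estimation pathway (grid rate, interpolation order,
  Welch segmenting) is a documented package choice; published LF/HF
  magnitudes estimated with unknown pathways are therefore not comparable
  at face value.
* Features are assembled through a registry; a feature that cannot be
  computed (short series, zero variance, zero HF power) is reported
  *missing* with a reason, never as zero.

### Evaluation and exclusion

Peak matching is greedy one-to-one nearest matching within ±100 ms (about a
quarter beat at 150 bpm; the tolerance is configurable and echoed in
reports). It always satisfies tp + fn = |truth| and tp + fp = |prediction|.
Confusion metrics are reported in percent, with zero-denominator metrics
flagged undefined (NaN) rather than zero.

The SNR gate is defined as 10·log10 of the power within ±0.1 Hz of the
heart-rate fundamental and its first harmonic over the remaining 0.7–7 Hz
power (Welch PSD, ~0.05 Hz resolution). The reference frequency comes from
the same signal's own validated-peak mean HR — a deliberate, documented
circularity: the gate judges *ground-truth* quality, not remote accuracy.
Note the definition penalizes genuinely irregular rhythms: high RR
variability spreads spectral power away from the fundamental, so very high
HRV recordings can fall under a fixed dB threshold without being noisy.
Exclusion combines three gates on the contact signal only: valid-peak
fraction > 0.60, SNR > 4 dB, and a blacklist manifest standing in for a
manual quality check (non-interactive by design). Raising either threshold
can only shrink the retained set.

### Stress analysis

Labeling: rest-task rows are non-stress; activity rows are stress exactly
when the subject is in the high-difficulty group. On the 26 + 30 subject
cohort this yields 168 rows, 52 stress / 116 non-stress.

Statistical screen: Shapiro-Wilk per feature (retained when p > 0.05;
constant features flagged degenerate), classic one-way ANOVA
(F = MS_between/MS_within, df (k−1, N−k)) verified against brute-force sums
of squares, Tukey HSD pairwise comparisons at α = 0.05. ANOVA is run per
feature without multiple-testing correction, matching the sequential
per-feature workflow it mirrors; a Benjamini-Hochberg option would be a
natural extension but is deliberately not the default.

SMOTE is implemented directly (the interpolation rule is short and fully
specified): each synthetic minority sample is x + u·(x_nn − x) with
u ~ U(0,1) and x_nn one of the k = 5 nearest minority neighbors
(Euclidean). Oversampling the 52-row minority to 116 gives 232 balanced
rows. By default balancing is applied to the whole table *before* the
train/test split, mirroring the workflow it reproduces; this leaks
synthetic neighbors of test rows into training, so classifier scores under
this protocol are optimistic — a split-first mode is available via
`SplitConfig` by balancing only the training partition externally.

Classifiers: random forest (20 trees), linear-kernel SVM, 5-nearest
neighbors, LightGBM (library defaults otherwise), evaluated on a seeded
stratified held-out third (a 232-row table gives a 77-sample test set).
All seeds and the split fraction are recorded in outputs.

## Synthetic-data generator

The generator emulates the *structure* of the benchmark protocol: 56
subjects (26 test / 30 ctrl) × 3 tasks, 3-minute contact recordings at
64 Hz, video traces at 35 FPS.

* **RR process.** Stationary AR(1) on the RR series with mean 60000/HR and
  marginal SD equal to the target SDNN, clipped to 300–1400 ms. The lag-1
  coefficient defaults to 0.7 at cohort level (real RR series are strongly
  autocorrelated; low autocorrelation would push nearly all successive
  differences past 20 ms and saturate NNi20).
* **Waveform.** One asymmetric pulse per beat — a narrow systolic Gaussian
  peak plus a dicrotic hump at 0.32·RR with 0.35 relative amplitude —
  placed at cumulative beat times, plus optional white noise. Ground-truth
  beat times are returned exactly (sub-sample).
* **Optical model.** Channels = skin-tone baseline × (1 + illumination
  drift) + pulse_amplitude × baseline × channel weight × pulse + motion.
  Pulse weights (0.45, 1.0, 0.65 for R, G, B) put the pulsatile energy
  mainly in green; illumination is a ~0.3 Hz sinusoid common to all
  channels; motion artifacts are additive step/ramp transients. Frames are
  flat patches whose channel means equal the trace; geometric motion,
  face appearance and skin segmentation are intentionally out of scope.
* **Cohort profiles.** Rest task: no artifacts. Activity tasks: motion and
  illumination artifacts plus a small HR increase. Stressed records (test
  group, activity tasks) are shifted by `stress_effect_sd` (default 0.5)
  in units of each parameter's between-subject SD: HR up, SDNN down, RR
  autocorrelation up — lowering short-term irregularity and hence NNi20
  and sample entropy, the two features the stress screen should flag.

**What passing tests show — and don't.** The generators implement exactly
the optical and beat-interval assumptions the POS projection and the HRV
formulas rely on. Success on them demonstrates that the pipeline is
internally correct (recovers known ground truth through every stage), not
that it handles real skin, real motion (which is geometric, not additive),
compression artifacts, or sensor-specific noise. Conversely the benchmark
harness numbers (peak F1 > 0.9, HR MAE < 2 bpm on noiseless records) are
property-level mirrors of the published evaluation, not reproductions of
dataset-dependent tables.

## Problem sizes used in the test and acceptance runs

Chosen as the package's own defaults for quick, deterministic verification:
heart-rate recovery uses 120 s records across 48–120 bpm; the benchmark
property uses 20 noiseless 3-minute records; the ANOVA stress-recovery
check uses the full 168-row cohort shape at 120 s per record over 20 seeds;
`scripts/acceptance.py` generates the full 168-row cohort at 120 s per
record. Durations scale linearly in cost and none of the verified
properties depend on record length beyond the ≥ 60 s span the frequency
features require.

## Known limitations

* No face/landmark detection is shipped; the landmark provider is an
  interface (a static-rectangle provider covers patch videos and tests).
* Video files are not decoded; frame stacks and RGB-trace CSVs are the
  inputs.
* The SNR definition and the peak-match tolerance are package choices;
  both are logged with every report and configurable.
* Invalid IBIs are removed, never interpolated; long corrupted stretches
  shrink the usable RR series rather than being repaired.
* LF/HF magnitudes depend on the estimation pathway and should only be
  compared within-pipeline.
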