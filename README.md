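# pulsebench

A benchmark toolkit for **remote photoplethysmography (rPPG)**: extracting
the blood-volume pulse from facial-video color traces, judging it against a
contact sensor, and using the derived heart-rate-variability (HRV) features
for stress recognition.

Ordinary cameras see the tiny frame-to-frame color changes that cardiac
blood-volume waves produce in facial skin. Turning those changes into a
signal that carries the same physiological information as a contact
photoplethysmogram (PPG) — beat positions, inter-beat intervals, HRV —
requires a chain of well-chosen processing steps, and evaluating such a
chain fairly requires ground truth. `pulsebench` implements the full chain,
the evaluation harness, and seeded synthetic-data generators with known
ground truth, so every stage is testable without any video download. It is
aimed at researchers benchmarking camera-based vital-sign methods and at
engineers who need a reproducible, scriptable reference pipeline.

## What it computes

**Pulse extraction (rPPG core).** Per-frame spatial means of R, G, B over
facial regions (forehead, both cheeks) form an RGB trace. The
plane-orthogonal-to-skin (POS) projection mixes the channels inside sliding
windows (1.6 s, one-sample stride, overlap-add): channels are divided by
their window means (C_n = C / mean(C)), projected onto two chrominance axes

    U = G_n − B_n
    V = G_n − R_n + B_n − R_n

and combined as `h = U + α·V` with `α = σ(U)/σ(V)` per window, which nulls
common intensity variation while keeping the pulse. A convolutional matched
filter then cleans the signal: a single-beat template `t[k]`, k = −K..K, is
learned by averaging the signal's own peak-centered segments, and

    s_heart[n] = 1/(2K+1) · Σ_k s_orig[n+k] · t[k].

**Contact (ground-truth) chain.** The wearable BVP signal (64 Hz) is
resampled to the working rate (30.30 Hz), smoothed with a 4th-order,
19-frame Savitzky-Golay filter, and band-passed 0.7–7 Hz with a zero-phase
2nd-order Butterworth filter.

**Peak validity rules.** Each detected peak's adjacent inter-beat intervals
(IBIs) must lie in the band for 42–210 bpm; its left/right IBI difference
must be under 0.5 s; the first and last peaks are invalid; finally, any peak
next to an invalid peak is invalidated in one last pass. A clean record thus
has two invalid peaks at each end, and one bad IBI spoils exactly four peaks.

**HRV features.** From valid RR intervals (ms): mean HR = 60000/mean(RR),
IBI = mean(RR), RMSSD, SDNN, NNi20 (successive differences > 20 ms), sample
entropy (m = 2, r = 0.2·SDNN), and the LF [0.04–0.15 Hz] / HF [0.15–0.4 Hz]
band powers of the 4 Hz-interpolated tachogram, plus a 30 s / 1 s
sliding-window HR series.

**Evaluation.** Valid-peak F1 between contact and remote peak trains
(greedy one-to-one matching, ±100 ms), MAE of HR and of each HRV feature,
spectral SNR, and the exclusion gates for unusable ground truth
(valid-peak fraction > 60%, SNR > 4 dB, manual blacklist).

**Stress recognition.** Task/group labeling (rest = non-stress; activity
tasks = stress only for the high-difficulty group), Shapiro-Wilk normality
screen, one-way ANOVA with Tukey HSD post-hoc tests, SMOTE minority
oversampling, and four classifiers (random forest with 20 trees,
linear-kernel SVM, 5-NN, LightGBM) scored by accuracy, precision,
sensitivity, specificity and F1.

## Worked example

Generate a 3-minute synthetic recording at 72 bpm with illumination drift,
motion transients and sensor noise; run the full remote pipeline; compare
with the generator's ground truth:

```python
import numpy as np
from pulsebench import SynthConfig, synth_ppg, synth_rgb_trace, extract_rppg
from pulsebench.bench import signal_features
from pulsebench.peaks import valid_fraction

cfg = SynthConfig(hr_bpm=72.0, sdnn_ms=50.0, duration_s=180.0,
                  illum_amp=0.1, motion_amp=0.3, noise_amp=0.05, seed=7)
ppg, true_peaks, true_rr = synth_ppg(cfg)
trace = synth_rgb_trace(ppg, cfg)                 # what the camera would see
rppg = extract_rppg(trace)                        # POS + template filter
features, validation = signal_features(rppg)      # peaks -> valid RR -> HRV

print("true mean HR  :", round(60000 / np.mean(true_rr.rr_ms), 2), "bpm")
print("valid fraction:", round(valid_fraction(validation), 3))
for name in ("mean_hr", "ibi", "sdnn", "rmssd", "nni20", "sampen", "lf_hf"):
    print(f"{name:>14}: {features[name]:.3f}")
```

Output:

```
true mean HR  : 72.86 bpm
valid fraction: 0.982
       mean_hr: 72.866
           ibi: 823.431
          sdnn: 43.113
         rmssd: 45.484
         nni20: 130.000
        sampen: 1.926
         lf_hf: 0.753
```

The camera-side estimate (72.866 bpm) matches the generated heart rate to
under 0.01 bpm despite the artifacts; 98.2% of detected peaks pass the
validity rules; SDNN recovers the generator's realized RR variability
(44.4 ms) within a few percent.

The same steps are available from a shell:

```bash
pulsebench synth --preset ubfc-like --seed 7 --with-traces --out data/
pulsebench extract --trace data/s01_T1_trace.csv --fps 35 --out rppg.csv
pulsebench benchmark --gt-dir data/ --rppg-dir data/ \
    --manifest data/manifest.csv --out report.csv
pulsebench stress --features features.csv --manifest data/manifest.csv \
    --seed 17 --out stress_out/
```

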