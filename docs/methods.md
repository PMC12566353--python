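# Methods

This note documents the models implemented in `spikechain`, the default
parameters and why they were chosen, the numerical conventions, and what the
synthetic benchmark does and does not establish about real recordings.

## 1. Front-end stages

Each gain stage (LNA, PGA) is modeled at the behavioral level: a continuous
closed-loop transfer function, discretized by the bilinear transform at the
working sample rate, followed by a sample-synchronous non-linearity module
and preceded by a white input-referred noise source.

### Linear dynamics

LNA: `H(s) = (Cin/Cf) · (−sRfCf)/(1+sRfCf) · 1/(1 + s·CL1/(Gm1·βL))` with
the feedback coefficient taken at its mid-band limit
`βL = Cf/(Cin+Cp1+Cf)` and `CL1 = Cl1 + (1−βL)·Cf`.  The frequency-dependent
β enters only the open-loop form; using the mid-band limit in the
closed-loop low-pass factor mirrors the deep-feedback approximation chain
under which the closed-loop expression is derived in the first place.

PGA: `H(s) = −(C1/C2)/(1 + s·CL2/(Gm2·βP))`, same conventions.

Defaults: LNA `Cin=20 pF, Cf=200 fF` (40 dB), `Cl=1 pF`, `GBW=10 MHz`
(hence `Gm1 = 2π·GBW·Cl ≈ 62.8 µA/V`), pseudo-resistor `Rf=10 GΩ` so the
high-pass corner `1/(2πRfCf) ≈ 79.6 Hz` sits below the 200 Hz analysis
band.  PGA `C1=2 pF, C2=200 fF` (20 dB, the middle of a 0–30 dB
programmable range), `GBW=5 MHz`.  Total chain gain 1000 drives µV-level
spikes to the ±0.35 V converter range.

The bilinear transform preserves low-frequency gain and corner placement,
the only linear properties the analysis uses.  At 24 kHz the closed-loop
pole (~83 kHz) lies above Nyquist; the model warns (the pole's exact
placement is irrelevant in the 200–3000 Hz spike band).

### Slew/settling error injection

The non-linearity module runs per sample.  The quantity it acts on is the
**residual step**: `|vin| = |y_lin[n] − y[n−1]|`, the distance between the
linear-response target and the stage's actual previous output, referred to
the output node.  With the integration constant `τ = 2π·Cin·Cl/(Gm·Cf)`
(equal to midband_gain/GBW) and required slewing time
`t_sl = |vin|/SR − τ`, the settling error after the half-sample `Ts/2` is

* case 1 (`|vin|/τ > SR`, `t_sl ≥ Ts/2`): the stage slews the entire
  half-sample and covers only `SR·Ts/2`, so `error = |vin| − SR·Ts/2`;
* case 2 (`|vin|/τ > SR`, `t_sl < Ts/2`): slewing completes, then linear
  settling for `t_lin = Ts/2 − t_sl`:
  `error = (|vin| − SR·t_sl)·exp(−t_lin/τ)`;
* case 3 (`|vin|/τ ≤ SR`): `error = |vin|·exp(−Ts/(2τ))`.

The three branches are continuous in `|vin|`, the error is clamped to
`[0, |vin|]` (a contraction — the output never overshoots its target), and
it is subtracted in the direction of the step, so the output *lags* the
ideal response and the lag accumulates during fast excursions exactly as a
slewing OTA lags a fast input.  Two conventions deserve emphasis:

* **Residual step, not raw increment.**  Acting on the raw sample-to-sample
  increment of the linear response makes the module memoryless and bounds
  the injectable distortion by the per-sample increment scale
  (≈ 2π·f0/fs of the carrier, about −34 dB for a 1.11 kHz tone at 24 kHz),
  which cannot reach the level-4 operating points.  The residual-step form
  keeps the required property that the error vanishes for slowly varying
  inputs while allowing true rate limiting.
* **Case-1 error is the rate deficit.**  Substituting the *required*
  slewing time into `|vin| − SR·t_sl` collapses to the constant `SR·τ`,
  which removes slew limiting altogether; the implemented form uses the
  *actual* slewing time `Ts/2`, which is also the unique choice continuous
  with case 2.

With `SR=None` the module is disabled and the stage is exactly its
discretized linear response (verified to 1e−9 of full scale).

### Noise

Input-referred white Gaussian noise with one-sided PSD floor `S0` (V²/Hz):
per-sample variance `S0·fs/2`.  1/f noise is deliberately absent — the
200–3000 Hz detection band-pass removes it in practice, leaving thermal
noise dominant.  Default floors are set so a 100 µV tone yields a
single-tone SNR of ≈32.4 dB for the LNA and ≈33.1 dB for the PGA
(measured over the 12 kHz Nyquist band) — representative front-end noise
levels for this signal scale.

## 2. Flash ADC

`2ⁿ−1` mid-rise thresholds `t_i = v_min + i·lsb`; static resistor mismatch
is one Gaussian draw per threshold, σ expressed in LSB, **drawn once per
ladder** and re-sorted (a bubble-corrected flash encoder behaves
monotonically, and counting thresholds below the sample is in any case
order-invariant).  Quantization is the thermometer count; reconstruction is
mid-tread with the *ideal* LSB, because the decoder does not know the
mismatch — this is what converts INL/DNL into distortion.  Thermal noise
(default floor 1e−15 V²/Hz, negligible) is added at the input; sample/hold
is the identity on the already-sampled grid.  Reference range ±0.35 V,
12 bits by default (8–14 supported).

The ideal chain reproduces `SNR = 6.02n + 1.76 dB` within 0.3 dB for
n ∈ {8, 10, 12}; removing bits raises the noise floor ~6 dB/bit.

## 3. Single-tone metrics

Coherent records (integer tone periods — the tone generator rounds the
record length to enforce this) are analyzed with a rectangular window and
single-bin clusters (±1 bin for numerical safety); non-coherent records
fall back to a 4-term Blackman-Harris window with 7-bin clusters.
Fundamental power comes from its bin cluster; harmonic power from clusters
at `k·f0`, k = 2…11 (10 harmonics by default — THD has converged by the
10th at the levels considered), with harmonics above Nyquist folded as in
standard converter testing; noise is the residual after removing DC,
fundamental and harmonics.  `THD = 10·log10(Pharm/Pfund)` (negative =
cleaner), `SNDR` pools noise and harmonics, `SFDR` is fundamental to
largest non-fundamental cluster, `ENOB = (SNDR − 1.76)/6.02`.

NRMSE between waveforms is RMS error normalized by the reference
peak-to-peak range (scale-free across clusters of different amplitude).

## 4. Distortion-level calibration

The standard probe is the 1.11 kHz, 100 µV sine at the LNA input (10 mV at
the PGA input, i.e. the post-LNA scale; 99 % of full scale at the ADC).
All tone tests run on the same 24 kHz grid as the neural simulations: the
sample-synchronous error law couples the distortion scale to the grid, so
calibrating on one grid and simulating on another would decouple the
levels from the signals they are meant to distort.  At 24 kHz only the
11th harmonic of 1.11 kHz folds, and the folded estimator counts it.

* Amplifiers: `(GBW, SR)` are scaled together along a constant `SR/GBW`
  ray (preserving `SR/GBW = 4π·Ids/Gm`).  The ray anchors — 120 V/s at
  10 MHz for the LNA, 4800 V/s at 5 MHz for the PGA, output-referred — put
  the four THD anchors inside the reachable span.  The search is a grid
  scan plus log-bisection; it is deterministic because the injected
  distortion is noise-independent (calibration runs with noise floors off).
* ADC: scalar search over the ladder σ using the median THD over 10 ladder
  seeds.  Beyond σ ≈ 600 LSB the sorted ladder approaches a pure Gaussian
  quantile map and THD turns back down; the search stays below that.
  Achieved THD is required within ±1.5 dB of each anchor.

Level 0 always means the non-linearity switched off (SR unset, σ = 0).

## 5. Synthetic benchmark

`generate_templates` builds biphasic unit templates: a negative Gaussian
trough (σ 0.12–0.20 ms, i.e. trough FWHM ≈ 0.28–0.47 ms) followed by a 3×
wider positive overshoot whose amplitude makes the shape integrate to zero
exactly (AC-coupled), troughs 80–98 µV with 3 % seeded jitter.
`generate_recording` adds homogeneous Poisson trains (2 ms absolute
refractory per unit) and white Gaussian background noise (default 20 µV).
The default study condition is 3 units at 8 Hz total over 60 s
("reduced"; "full-bench" is 600 s), matching the event density of a
14.4 M-sample, ~4800-event annotated benchmark.

Why these numbers: after the 200–3000 Hz band-pass the background is
≈9.5 µV, so the filtered template troughs sit at ≈8–10× the robust noise
estimate σ_N — inside the 3–10× detectability window and high enough that
misses are dominated by genuine spike collisions rather than threshold
luck (the ideal-converter reference point requires ≥99 % accuracy, i.e. a
false-negative budget of a few events per ~500).  The trough widths keep
the spikes' voltage slew rates commensurate with the calibration tone's,
so the calibrated slew levels act on the same rate scale they were defined
on.

What the generator does **not** emulate: colored/1-f background, bursting,
electrode drift, amplitude variability within a unit, overlapping-spike
waveform superposition beyond linear addition, or multi-channel structure.
Passing tests on this benchmark therefore establish the *relative* cost of
front-end distortion under clean, stationary conditions — not absolute
performance on real tissue.

## 6. Detection and sorting pipeline

Band-pass: zero-phase (forward–backward) 4th-order Butterworth, 200–3000 Hz.
Threshold: `Thr = 4σ_N`, `σ_N = median(|x|)/0.6745`.  Detection: downward
peaks of the filtered signal above threshold with a 0.5 ms merge window —
extracellular spikes are negative-led at the electrode, and a two-sided
threshold would double-count the band-pass filter's positive overshoot
lobe.  Extraction: 5 ms windows re-centered on the negative peak within
±0.5 ms; incomplete windows are discarded and counted.  An *echo veto*
drops detections whose window contains a ≥1.5× deeper trough off-center:
those are ringing shadows of a neighboring spike (real same-amplitude
neighbors differ by less than 1.5× by construction of the amplitude range,
so genuine collisions are not vetoed).

Features: eigendecomposition of the mean-centered waveform covariance,
scores are projections on the leading components (k=2).  Sorting: k-means
(scikit-learn, 10 restarts, seeded) on the scores with one extra collector
cluster beyond the putative unit count, then RMS re-evaluation in waveform
space: every spike moves to the cluster whose mean waveform fits it best,
with an **all-zero noise template competing** — a waveform that fits the
flat noise floor better than any template is a threshold crossing of the
background, not a spike.  The pass iterates to a fixed point so cluster
means purge themselves of noise contamination.  Unclustered spikes
(noise-template winners; members with RMS error > 5× their cluster's
median; clusters whose mean is noise-flat, RMS < 1.5σ_N, or positive at
the alignment point) are subtracted from the detected set before scoring.

RMS comparisons use the central ±1 ms of the window (the template
support): a neighboring spike in the outer window must not make its victim
look like an outlier.  The 5× member bound (rather than a tighter 3×)
exists for the same reason; noise rejection is carried by the
noise-template competition, so the member rule is only a gross-artifact
guard.

This rejection stage is load-bearing: threshold crossings of Gaussian noise
at 4σ occur at ≈0.6/s per polarity in a 200–3000 Hz band *independent of
the noise amplitude* (the threshold is adaptive), which would otherwise
cap accuracy near 90 % at the benchmark's 8 Hz spike rate.

Scoring: greedy one-to-one nearest matching within ±1 ms;
`Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`,
`Accuracy = TP/(TP+FP+FN)`; spike-count error is the signed percentage
deviation from the same-repetition level-0 baseline.  Greedy matching
equals optimal bipartite matching whenever events are separated by more
than twice the tolerance (the refractory regime); with arbitrarily close
events it is not optimal, which is why the property is stated for the
sparse regime.

## 7. Sweeps and repetitions

Scenarios: LNA-only, PGA-only, front-end (LNA+PGA), ADC-only, all-stage;
levels 0–4; 10 repetitions per cell with seeds
`base + scenario_index·1000 + rep`.  Recording noise and spike times, the
front-end noise draws, and the ladder mismatch are all redrawn per
repetition (the repetition is meant to capture "variability due to random
white noise and non-linearity differential effects").  The resolution sweep
runs ideal 8/10/12-bit ladders with the linear front end.

A known and deliberate property of the results: at the calibrated anchor
levels, front-end and ADC distortion leave median detection accuracy
essentially unchanged (ties to within one or two borderline events).  The
adaptive 4σ_N threshold is scale- and warp-invariant: the sorted-ladder
mismatch is a smooth monotone transfer warp, and the slew/settling errors
are contractions that cannot inflate the noise floor, so a median-based
detector shrugs both off.  The decoding paradigm, whose binned observation
streams are fast relative to the chain, *does* degrade monotonically with
level (median CC 0.989 → 0.964 from level 0 to 4 on the default model).

## 8. Decoding paradigm

State (x, y, vx, vy) with constant-velocity transition at 50 ms bins;
96 channels with Gaussian loading vectors; isotropic observation noise
sized so a single trial decodes at CC ≈ 0.98; 15 smoothed-random-walk pen
strokes (standardized per axis) stand in for handwriting trials whose
source data is restricted.  Observations are continuous envelope-like
features, not spike counts.  Distortion transfer: each channel's binned
stream is centered, scaled to the 100 µV front-end signal level, pushed
through the LNA→PGA→ADC chain sample-synchronously (256-sample reflected
padding absorbs the high-pass start-up transient), rescaled, and decoded
by the standard Kalman recursion.  Scores are Pearson correlations per
axis, averaged.

## 9. Numerical conventions and edge cases

* All randomness flows through explicit integer seeds; repetition seeds
  derive linearly from a base seed.  The slew recursion is compiled with
  numba (with a pure-Python fallback).
* Coherent tone records are enforced by construction
  (`coherent_length`), so the rectangular-window path needs no leakage
  guard; the windowed path exists for user-supplied records.
* Ladder ties after perturbation (measure-zero) are broken by an
  epsilon-spacing repair; quantization saturates out-of-range samples and
  warns when more than 1 % of samples clip.
* `k-means` uses 10 seeded restarts; sorting is skipped entirely for
  records with fewer than ~7 detections, in which case the raw detected
  set is scored.
* Degenerate inputs raise `ValueError` (flat NRMSE reference, constant
  series in Pearson correlation, empty signals, k > n_spikes, fs below
  the band-pass Nyquist requirement).

## 10. Known limitations

* The three-case error model is sample-synchronous: its distortion scale
  is tied to the simulation grid, which is why calibration and simulation
  share one rate (24 kHz).  It is a behavioral abstraction, not a
  transistor-level settling model.
* Printed GBW/SR pairs from bench characterizations of real amplifiers do
  not transfer literally into this law (their units are also internally
  inconsistent with the stated SR/GBW ratio); distortion levels are
  therefore *defined* by their achieved THD, not by the knob values.
* The sorted-ladder ADC cannot produce sparkle/bubble code errors, so its
  distortion is benign to threshold detection by construction (see §7).
* Detection accuracy near the ceiling is limited by genuine spike
  collisions (two units within ±0.5 ms), which the pipeline does not
  attempt to resolve — overlap resolution is out of scope.
* Single channel only; no crosstalk, temperature, corner or drift
  modeling.
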