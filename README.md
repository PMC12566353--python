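# spikechain

A desk-scale behavioral simulator of an implantable multi-channel neural
recording chain — low-noise amplifier (LNA) → programmable-gain amplifier
(PGA) → flash ADC — with *tunable non-linearity*, plus the evaluation
machinery needed to ask the design question that motivates it: **how much
analog linearity does a brain–machine interface actually need before spike
detection and trajectory decoding stop caring?**

Over-designing the front end (THD below −50 dB, 12+ bit converters) costs
power and silicon area that implants cannot afford. `spikechain` lets you
inject graded, calibrated amounts of distortion into each stage and measure
the downstream cost on concrete tasks: spike detection/sorting accuracy
against ground truth, spike-count error, waveform deformation (NRMSE), and
Pearson correlation of Kalman-decoded 2-D pen trajectories.

## The models

**Front end.** Each capacitive-feedback stage is its closed-loop transfer
function — for the LNA

H(s) = (Cin/Cf) · (−s·Rf·Cf)/(1 + s·Rf·Cf) · 1/(1 + s·CL1/(Gm1·βL)),

with β_L = Cf/(Cin+Cp+Cf), CL1 = Cl1 + (1−βL)Cf — discretized by the
bilinear transform, plus a white input-referred noise source (one-sided PSD
floor in V²/Hz) and a sample-synchronous slew/settling error module.  At
every sample the stage must close the residual step |vin| toward its linear
target; with τ = 2π·Cin·Cl1/(Gm1·Cf) and required slewing time
t_sl = |vin|/SR − τ, the error is dispatched in three cases:

1. slope > SR and t_sl ≥ Ts/2 — slews the whole half-sample:
   error = |vin| − SR·Ts/2;
2. slope > SR and t_sl < Ts/2 — slews, then settles for t_lin = Ts/2 − t_sl:
   error = (|vin| − SR·t_sl)·exp(−t_lin/τ);
3. slope ≤ SR — linear settling: error = |vin|·exp(−Ts/(2τ)).

**ADC.** An n-bit flash converter: 2ⁿ−1 ladder thresholds with static
Gaussian mismatch (re-sorted, as a bubble-corrected encoder behaves),
thermometer-count quantization, mid-tread reconstruction with the ideal LSB.
Mismatch shows up as INL/DNL and hence harmonic distortion; the ideal chain
obeys SNR = 6.02·n + 1.76 dB.

**Distortion levels.** A 1.11 kHz / 100 µV tone calibrates five levels per
stage: level 0 is the linearity reference; levels 1–4 are found by scalar
search — (GBW, SR) moved along a constant SR/GBW ray for the amplifiers,
ladder perturbation σ for the ADC — until the single-tone THD hits the level
anchors (e.g. −34.32 dB for LNA level 3, −57.95 dB for ADC level 2).

**Evaluation.** A synthetic annotated benchmark (24 kHz, 3 biphasic units,
~8 Hz total rate — the density of a 14.4 M-sample / 4800-event recording),
the classic detection pipeline (200–3000 Hz band-pass, threshold at
4·σ_N with σ_N = median(|x|)/0.6745, 5 ms aligned extraction, PCA features
c_i = Σ PC_i(n)·s(n), k-means with waveform-RMS reassignment and
unclustered-spike rejection), precision/recall/accuracy scoring with 1 ms
tolerance, and a 96-channel constant-velocity Kalman decoding paradigm on
synthetic pen strokes.

## Worked example

```python
import numpy as np
from spikechain import AdcParams, adc_chain, tone_metrics, generate_test_tone
from spikechain import experiments as ex, frontend

# 1) ideal 12-bit converter on the standard tone
p = AdcParams(n_bits=12)
amp = 0.99 * (p.v_max - p.v_min) / 2
x = generate_test_tone(1110.0, amp, 24000.0, 1.0)
m = tone_metrics(adc_chain(x, 24000.0, p), 24000.0, 1110.0)
print(f"level 0: SNR {m.snr_db:.2f} dB  THD {m.thd_db:.2f} dB  "
      f"SNDR {m.sndr_db:.2f} dB  ENOB {m.enob_bits:.2f} bits")

# 2) calibrate the ladder mismatch to the level-2 THD anchor
specs = ex.calibrate_levels("ADC", [-57.95], seed=1)
lv2 = specs[1]
print(f"level-2 ladder: perturb_sigma {lv2.knobs['perturb_sigma']:.1f} LSB  "
      f"achieved THD {lv2.achieved.thd_db:.2f} dB")

# 3) spike-detection cost of that distortion on a 60 s benchmark
rec = ex.make_benchmark(ex.BenchmarkConfig.reduced(), seed=1)
res = ex.score_run(rec, frontend.default_lna(), frontend.default_pga(),
                   lv2.adc_params(), seed=1)
r = res["report"]
print(f"detection: {r.tp} TP, {r.fp} FP, {r.fn} FN  ->  accuracy {r.accuracy:.3f}")
```

prints

```
level 0: SNR 74.26 dB  THD -91.64 dB  SNDR 74.18 dB  ENOB 12.03 bits
level-2 ladder: perturb_sigma 30.1 LSB  achieved THD -57.31 dB
detection: 493 TP, 0 FP, 6 FN  ->  accuracy 0.988
```

Read: the unperturbed 12-bit chain sits on the quantization-noise law
(ENOB ≈ 12); a ladder mismatch of ~30 LSB reproduces the −58 dB THD
operating point; and at that operating point spike detection on the
emulated benchmark still finds 493 of 499 ground-truth events with no false
positives — moderate converter non-linearity is essentially free at the
spike-processing level.

## Command line

One entry point with per-stage subcommands:

```bash
spikechain synth --preset reduced --seed 1 --out bench/       # make a benchmark
spikechain frontend --stage lna --level 3 --in x.bin --out y.bin --seed 1
spikechain adc --bits 12 --level 2 --seed 7 --in y.bin --out z.bin
spikechain tone --in z.bin --f0 1110 --json tone.json          # SNR/THD/SNDR/SFDR/ENOB
spikechain spikes --in z.bin --truth bench/truth.csv --report r.json
spikechain decode --level 3 --trials 15 --seed 9 --report cc.json
spikechain bench --preset reduced --base-seed 42 --out results/  # full sweep
```

Signals are raw little-endian float64 with a JSON sidecar (`<file>.json`:
sampling rate, units, sample count); ground truth is a `time_s,unit_label`
CSV; stage parameters load from flat YAML sections.

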