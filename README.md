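# lumipulse

Pulse-counting luminometry in software: a calibrated model of an
open-hardware luminometer built from a light-to-frequency photosensor and a
microcontroller, together with the processing and analysis stack for the
luciferase reporter time courses such a device records.

Luciferase reporter assays read out gene expression, pathway activity,
cytotoxicity and circadian rhythms as light. A cheap real-time luminometer
for growing cell cultures can be built from a TSL237-class sensor — which
emits square-wave pulses at a frequency linear in irradiance,
`f = f_D + R·E` — and a microcontroller that counts pulses per integration
window via interrupts. `lumipulse` is for researchers who build or use such
devices and need to (a) understand the instrument's statistics — dynamic
range, detection limit, shot noise, integration-time trade-offs, interrupt
contention between channels — before or instead of touching hardware, and
(b) process the count logs the instrument produces.

## What it models

- **Sensor** (`SensorSpec`): dark frequency `f_D` (default 0.1 Hz),
  irradiance responsivity `R` (2.3 kHz per µW/cm², the TSL237S-LF value),
  1 MHz ceiling. Calculators: dynamic range `log10(f_max/f_D)` = 7.0
  orders; limit of detection `f_D/R` ≈ 43.5 pW/cm² at 1 s integration.
- **Pulse generation** (`simulate_pulse_train`): an inhomogeneous Poisson
  process with intensity `min(f_D + signal(t), f_max)`, sampled exactly by
  thinning against a constant majorant.
- **Firmware counting** (`mcu_acquire`): all wells share one interrupt
  service routine, modelled as a single dead time τ (default 5 µs) across
  channels — a pulse is counted only if it arrives ≥ τ after the previous
  counted pulse on *any* well. At reporter rates (< 1 Hz) losses are
  ~`f·τ` ≈ 10⁻⁶; a bright channel near `1/τ` starves the others.
- **Signals** (`SignalProfile`): constant, rise–decay activation
  `(1−e^{−u/τ_r})e^{−u/τ_d}` (peak at `τ_r ln(1+τ_d/τ_r)`), substrate
  depletion, damped cosine (default period 30 h), exponential growth; Hill
  inhibition `1/(1+(c/IC50)^n)` as a multiplicative treatment effect.
  Bundled presets emulate six assay classes (growth-factor activation,
  kinase inhibition, Wnt activation, NF-κB induction, cytotoxicity,
  circadian oscillation, substrate depletion).
- **Processing**: rebinning (counts are Poisson, so summing windows is
  lossless), baseline estimation from pre-treatment windows, background
  subtraction or fold-change, replicate mean ± sd.
- **Analysis**: activation kinetics (peak, time-to-peak, fold change,
  onset); fixed-period single cosinor
  `y = M + β cos(2πt/P) + γ sin(2πt/P)`, `A = √(β²+γ²)`,
  `φ = (P/2π)·atan2(γ, β)`, with the classical zero-amplitude F test
  `F = ((SS₀−SS)/2)/(SS/(n−3))`.

## Worked example

```python
import numpy as np
from lumipulse import (preset_design, generate_experiment, read_log,
                       process_counts, kinetics_summary, aggregate_replicates)

design = preset_design("fgf2", seed=11)       # 6 wells, 5-min windows, 12 h
log_text, truth = generate_experiment(design)  # canonical serial log + ground truth
series, header = read_log(log_text)

treated = [process_counts(s, treatment_time=3600.0) for s in series[:3]]
ks = kinetics_summary(treated[0], 3600.0)
print(ks.baseline_counts, ks.peak_value, ks.time_to_peak / 60, ks.fold_change)

agg = aggregate_replicates(treated, group="fgf2")
i = int(np.argmax(agg.mean))
print(agg.mean[i], agg.sd[i], (agg.times[i] - 3600.0) / 60)
```

prints (seed 11):

```
18.166666666666668 145.83333333333334 427.5 8.027522935779816
134.13888888888889 12.053219179646266 287.5
```

i.e. a basal level of ~18 counts per 5-min window (0.06 Hz), a single-well
peak ~146 counts above background reached 427 min after treatment (noisy:
the true curve peaks at 300 min but is nearly flat for hours around it),
and a replicate-averaged peak of 134 ± 12 counts about 290 min after
ligand addition — the transient
pathway activation the assay is designed to catch. The same objects flow
through the CLI:

```sh
lumipulse simulate --preset fgf2 --seed 11 --out out/
lumipulse process  --log out/log.csv --treatment-time 3600 --out out/processed.csv
lumipulse analyze  --input out/processed.csv --mode kinetics \
                   --treatment-time 3600 --out out/kinetics.json
```

The scripts in `examples/` walk through each capability (spec-sheet
arithmetic, activation kinetics, dose–response inhibition, circadian
cosinor fitting, integration-time trade-off, interrupt contention).

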