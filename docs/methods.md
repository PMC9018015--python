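# Methods

## The instrument model

The device modelled here is a multi-well luminometer built from
light-to-frequency converters (one per well) read by a single
microcontroller. The sensor emits square-wave pulses at a frequency linear
in incident irradiance,

    f(E) = min(f_D + R · E, f_max),

with dark frequency `f_D` (spurious pulses with no light), irradiance
responsivity `R`, and a saturation ceiling `f_max`. Defaults are the
TSL237S-LF datasheet values: `f_D = 0.1` Hz, `R = 2300` Hz/(µW/cm²),
`f_max = 1` MHz, spectral response 320–1050 nm. Two figures of merit follow
directly:

* dynamic range `log10(f_max / f_D)` = 7.0 decadic orders per second of
  measurement;
* limit of detection `f_D / R` = 43.478 pW/cm² at 1 s integration — the
  irradiance whose signal equals the dark floor. We treat this as an
  irradiance (pW/cm²) referenced to a 1-s window; both improve linearly
  with integration time.

Note on symbols: device datasheets use `f_D` for the sensor's intrinsic
dark frequency. Measured floors in an actual dish (sensor dark counts plus
residual light and reporter-independent luminescence, e.g. ~0.02 Hz) are
called *baseline frequency* throughout this package and are a property of
the experiment, not the sensor.

## Pulse statistics

Photon arrival at reporter intensities is an inhomogeneous Poisson process.
`simulate_pulse_train` samples it exactly by thinning: candidate events are
drawn as a homogeneous Poisson process at a constant majorant rate `M`, and
a candidate at time `t` is kept with probability `λ(t)/M`, where
`λ(t) = min(f_D + signal(t), f_max)`. Dark pulses are folded into the
intensity additively rather than simulated as a separate stream: in counts
the two are indistinguishable. The majorant is the maximum of the rate
function over a 4097-point grid with 5 % headroom (exact for the smooth
profile classes shipped here); callers with rapidly varying rates should
pass an explicit bound via `rate_max`. Each well gets an independent
generator spawned from the master seed and the well index
(`SeedSequence(seed, spawn_key=(i,))`), so runs are reproducible and wells
are statistically independent.

Integration windows are half-open `[kT, (k+1)T)` with a trailing partial
window dropped, matching the device's integer pulses-per-window output.
Reported frequencies are rounded to significant figures half-away-from-zero
(so 142/300 s prints as 0.47 Hz).

## Interrupt contention

The firmware counts pulses in interrupt service routines; while one
interrupt is serviced the MCU cannot service another, on any channel. We
model this as a single shared dead time τ (default 5 µs, configurable):
events from all wells are merged in time order — exact ties broken by well
index, for determinism — and an event is counted iff it arrives ≥ τ after
the previous counted event on any channel. This is the simplest model with
the two properties the hardware exhibits: reporter-rate signals (< 1 Hz)
lose a fraction ≈ `f·τ` ≈ 10⁻⁶ (negligible), while a channel driven near
`1/τ` monopolises the service routine and starves the others. With τ = 0
the counter reduces to an exact per-window histogram, and total counted
events are non-increasing in τ. We do not model per-channel interrupt
priorities, queueing of pending interrupts, or clock granularity.

## Synthetic signal classes

`SignalProfile` provides closed-form rates (Hz above baseline):

| variant | form | emulates |
|---|---|---|
| `constant` | `c` | basal transactivation |
| `rise_decay` | `peak·s(t−t₀)/s(u*)`, `s(u) = (1−e^{−u/τ_r})e^{−u/τ_d}` | ligand-induced activation |
| `depletion` | same shape from t = 0 | bright reporter, substrate running out |
| `cosine` | `max(M + A e^{−λt} cos(2π(t−φ)/P), 0)` | circadian oscillation |
| `growth_ramp` | `c·2^{t/T_d}` | proliferation readout |

The rise–decay peak sits at `u* = τ_r ln(1 + τ_d/τ_r)`, which the analysis
layer uses as ground truth in recovery tests. Treatments act
multiplicatively: an `inhibit` effect applies Hill scaling
`1/(1+(c/IC50)^n)` from its application time onward (inhibitors act on the
pathway-driven signal, not the baseline); an `activate` effect carries unit
scaling and records the treatment time — the response shape itself lives in
the profile's latency. Mechanistic enzyme kinetics (Km, substrate
diffusion) and cell-growth ODEs are out of scope; the profiles are
phenomenological templates whose default parameters were chosen once to
match the count levels and time scales characteristic of each assay class
(e.g. activation presets: baseline ≈ 18 counts/5 min, peak ≈ 142 counts/
5 min at 300 min post-ligand; circadian preset: 2-h windows over 52 h at a
30-h period). The depletion template cannot produce a near-instant rise
followed by a late peak — its rise and peak time are coupled — so the
substrate-depletion preset rises over ~1 h rather than minutes; the
depletion time constant is a free synthetic parameter, as no measured value
exists for it.

What the generator deliberately does not emulate: drift in dark counts with
temperature, cell-density heterogeneity between replicate wells (replicates
differ only by shot noise), medium depletion except via the explicit
depletion profile, and ambient-light contamination. Passing recovery tests
therefore demonstrates the correctness of the counting and fitting
machinery under shot noise, not robustness to every systematic effect real
cultures produce.

## Log dialects and configs

The firmware's serial line format is not standardised, so the reader
accepts two dialects: a canonical one (commented header carrying device id,
well labels and window length in ms; rows of
`window_index,elapsed_ms,counts...`) for which read∘write is byte-identity,
and a headerless "raw" dialect (comma-separated counts, one row per window)
matching a bare serial-monitor capture, for which the window length must be
supplied. Timestamps are integer elapsed milliseconds, matching an MCU
millisecond clock. Designs are YAML with a strict schema (unknown keys are
errors); a cosine profile without a period defaults to 30 h. Live serial
acquisition from hardware is a documented non-goal.

## Processing

The baseline is the arithmetic mean of counts over pre-treatment windows —
the mean, not the median, because it is unbiased for Poisson counts; the
window set is user-specified or auto-selected as all complete windows
before the first treatment time. Background correction subtracts this
constant (fold-change division is available where a ratio is wanted);
negative corrected values are preserved, since clipping would bias
replicate means upward. No detrending or smoothing is applied beyond the
constant baseline. Rebinning sums blocks of `k` windows (dropping a
non-filling remainder with a warning) and commutes with background
subtraction when the baseline is scaled by `k`. Replicate aggregation
reports pointwise mean and sample sd (n−1); a single replicate reports
sd = 0.

## Kinetics and cosinor

`kinetics_summary` reports the post-treatment maximum, its latency relative
to the treatment, fold change `peak/baseline` (undefined, reported as None,
at zero baseline), and onset: the first post-treatment window exceeding
`z·√baseline` with z = 3, a one-sided ≈99.7 % bound under the Gaussian
approximation to Poisson noise. The onset rule is this package's own
convention — automated summaries need one — and z is tunable.

The cosinor is fitted at a *fixed* period by linearisation:
`y = M + β cos(ωt) + γ sin(ωt)` solved by least squares, then
`A = √(β²+γ²)` and acrophase `φ = (P/2π)·atan2(γ, β)` wrapped into
`[0, P)`, reported in hours after session start (no zeitgeber reference
exists after a serum shock). Linearisation is exact for in-class signals,
deterministic, and needs no initialisation. Period estimation, multi-
component cosinor, and damped-oscillation fitting are out of scope; 30 h is
the conventional fixed period for serum-shocked dermal-fibroblast BMAL1
reporters. Rhythm significance is the classical zero-amplitude F test,
`F = ((SS₀−SS)/2)/(SS/(n−3))` on (2, n−3) df, with p = 0 returned for a
numerically perfect fit. Fits on fewer than 4 points or spans shorter than
one period warn; collinear designs raise.

## Numerical and statistical choices in validation

Validation problem sizes were chosen to give tight Monte-Carlo error at
interactive runtimes: Poisson fidelity uses 10⁴ one-second windows (mean
within `3σ/√n`, index of dispersion in [0.9, 1.1]); cosinor recovery uses
200 shot-noise replicates of a 26-window, 52-h session at ~50 counts/window
(median amplitude error ≈ 6–7 %); the zero-amplitude test's size is
estimated from 1000 null simulations. The contention counter is checked for
exact agreement against an independently written event-by-event replay on
randomized sessions of a few hundred events.

Time-to-peak recovery is verified window-exactly on parameter-randomised
*noiseless* expected-count traces. This is deliberate: the rise–decay curve
is nearly flat for hours around its maximum, so at realistic count levels
(~140/window at peak) shot noise relocates the argmax window by several
windows with high probability — window-exact peak location under Poisson
noise is statistically unattainable for this signal shape, and no estimator
operating on a single noisy trace could promise it. The noiseless check
validates the discretisation and argmax logic; noisy-trace behaviour is
characterised separately (replicate-averaged peaks land within ~±2 h of
truth at the default preset's noise level).

A related caveat applies to peak *heights*: the maximum of a noisy trace is
biased upward (extreme-value statistics over many near-peak windows), so
summary peaks reported by the acceptance script use the replicate-averaged
trace, which reduces but does not remove this bias.

## Known limitations

* The dead-time model is a single shared non-paralysable τ; real MCUs have
  per-pin priorities and may queue one pending interrupt.
* The linear sensor model ignores wavelength dependence within the
  320–1050 nm band, temperature drift and supply-voltage noise.
* Presets are phenomenological: they reproduce count levels and time
  scales, not mechanism; inhibitor IC50s and depletion constants are
  nominal.
* Expected-count ground truth uses the midpoint rate × window length, a
  second-order-accurate approximation to the integral that is slightly
  biased for strongly curved profiles at coarse windows.
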