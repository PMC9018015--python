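"""Fit a fixed-period cosinor to a simulated circadian reporter.

The circadian preset emulates a serum-shocked fibroblast BMAL1 reporter:
three replicate wells, 2-h integration windows over 52 h, true oscillation
period 30 h.  The single cosinor recovers mesor, amplitude and acrophase by
linear least squares at the fixed period, and the zero-amplitude F test
quantifies rhythm significance.
"""

from lumipulse import (
    cosinor_fit,
    generate_experiment,
    preset_design,
    process_counts,
    read_log,
    zero_amplitude_test,
)

design = preset_design("bmal1", seed=17)
true = design.wells[0].profile.params
window = design.acquisition.integration_window
print(f"ground truth: mesor {true['mesor'] * window:.0f} counts/window, "
      f"amplitude {true['amplitude'] * window:.0f}, "
      f"acrophase {true['acrophase'] / 3600:.0f} h, period 30 h")

log_text, _ = generate_experiment(design)
series, _ = read_log(log_text)

for s in series:
    # use the first two windows (pre-oscillation reference) as baseline
    p = process_counts(s, treatment_time=2 * window)
    fit = cosinor_fit(p, period_hours=30.0)
    pval = zero_amplitude_test(fit, p)
    print(f"well {s.well_id}: amplitude {fit.amplitude:5.1f} counts/window, "
          f"acrophase {fit.acrophase_hours:5.1f} h, "
          f"zero-amplitude p = {pval:.2e}")

# Amplitudes near the true 60 counts/window with p << 0.05 mean the rhythm
# is detected well above shot noise; the acrophase gives the clock phase of
# peak reporter expression relative to the serum shock.
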