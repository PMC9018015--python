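"""Simulate a growth-factor activation assay and summarise its kinetics.

Uses the bundled FGF2 preset: six wells (three treated, three controls) on
5-min windows, ligand added 1 h into the session, the treated reporter rate
peaking ~5 h later.  The synthetic serial log is parsed back, background-
subtracted against the pre-treatment windows, replicates are aggregated, and
the kinetics are summarised.
"""

import numpy as np

from lumipulse import (
    aggregate_replicates,
    generate_experiment,
    kinetics_summary,
    preset_design,
    process_counts,
    read_log,
)

TREATMENT_S = 3600.0

design = preset_design("fgf2", seed=11)
log_text, truth = generate_experiment(design)
series, header = read_log(log_text)
print(f"simulated {header.n_wells} wells x {len(series[0])} windows "
      f"of {series[0].window_length:.0f} s")

treated = [process_counts(s, TREATMENT_S) for s in series[:3]]
agg = aggregate_replicates(treated, group="fgf2")

ks = kinetics_summary(treated[0], TREATMENT_S)
print(f"well {treated[0].well_id}: baseline {ks.baseline_counts:.1f} counts/window, "
      f"peak +{ks.peak_value:.0f} counts above background")
print(f"  time to peak: {ks.time_to_peak / 60:.0f} min after treatment "
      f"(fold change {ks.fold_change:.1f}, onset at {ks.onset_time / 60:.0f} min)")

i = int(np.argmax(agg.mean))
print(f"replicate mean trace (n={agg.n}): peak +{agg.mean[i]:.0f} +/- {agg.sd[i]:.0f} "
      f"counts at {(agg.times[i] - TREATMENT_S) / 60:.0f} min post-treatment")

# The baseline (~18 counts/5 min, i.e. ~0.06 Hz) is the basal reporter
# activity; the peak of ~120-140 counts above background ~300 min after
# ligand addition is the transient pathway activation the assay detects.
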