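"""Spec-sheet arithmetic for a light-to-frequency luminometer sensor.

Computes the figures of merit that follow directly from the sensor datasheet
(TSL237-class: dark frequency 0.1 Hz, responsivity 2.3 kHz per uW/cm^2,
1 MHz ceiling) and converts a few per-window pulse counts to frequencies.
"""

from lumipulse import (
    SensorSpec,
    counts_to_frequency,
    detection_limit_irradiance,
    dynamic_range_orders,
    integration_gain,
    round_sig,
)

spec = SensorSpec()
print(f"dynamic range: {dynamic_range_orders(spec):.1f} orders of magnitude (per 1 s)")
lod = detection_limit_irradiance(spec)
print(f"detection limit: {lod:.3f} pW/cm^2 (~{round_sig(lod, 1):.0f} at 1 sig fig)")
print(f"gain from 5 -> 20 min integration: {integration_gain(300, 1200):.0f}x expected counts")

for counts, window, sig, label in [
    (6, 300, 1, "in-dish dark floor"),
    (18, 300, 1, "basal reporter activity"),
    (142, 300, 2, "peak activation signal"),
]:
    f = counts_to_frequency(counts, window, sig)
    print(f"{counts:>4d} pulses / {window} s  ->  {f} Hz   ({label})")

# The dynamic range says the sensor spans 7 decades between its noise floor
# and saturation; the detection limit is the irradiance whose signal equals
# that noise floor at 1 s integration.  Longer windows buy sensitivity
# linearly at the cost of temporal resolution.
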