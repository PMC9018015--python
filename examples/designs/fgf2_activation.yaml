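# Growth-factor activation on 5-min windows: two treated wells and one
# control, ligand added 1 h into a 12-h session.  Run with:
#   lumipulse simulate --design examples/designs/fgf2_activation.yaml --seed 1 --out out/
name: fgf2-activation
sensor:
  dark_frequency: 0.02      # measured in-dish floor, Hz
acquisition:
  total_duration: 43200     # 12 h
  integration_window: 300   # 5 min
  interrupt_dead_time: 5.0e-6
  seed: 0
wells:
  - well_id: T1
    replicate_group: treated
    basal_rate: 0.04        # basal transactivation after luciferin, Hz
    profile: {variant: rise_decay, latency: 3600, rise_tau: 9000,
              peak_rate: 0.4133, decay_tau: 57500}
    treatments:
      - {time: 3600, kind: activate}
  - well_id: T2
    replicate_group: treated
    basal_rate: 0.04
    profile: {variant: rise_decay, latency: 3600, rise_tau: 9000,
              peak_rate: 0.4133, decay_tau: 57500}
    treatments:
      - {time: 3600, kind: activate}
  - well_id: C1
    replicate_group: control
    basal_rate: 0.04
    profile: {variant: constant, level: 0.0}
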