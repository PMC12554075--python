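# Two-condition "binding-mode" simulation: slow ligand association sampled
# over the whole 30 min window (ramp-like occupancy, so no value range is
# artificially rare), 4 independent experiments in duplicate.
#
# - AngII alone: association with heavy-tailed burst fluctuations
#   (spontaneous binding/unbinding transients).
# - AngII+LVV-H7: slightly faster/higher association with reduced noise
#   variance (allosterically stabilized binding).
#
# Calibration choices, not measured constants.
simulation:
  n_experiments: 4
  n_wells: 2
  dt: 30.0
  baseline_duration: 300.0
  total_duration: 2100.0
  seed: 0
  conditions:
    - label: AngII
      baseline: 1.0
      amplitude: 0.05
      rate: 0.001
      noise:
        family: burst_renewal
        sigma: 0.006
        burst_rate_scale: 60.0
        burst_tail: 1.5
        burst_amplitude: 0.01
        burst_decay: 0.02
    - label: AngII+LVV-H7
      baseline: 1.0
      amplitude: 0.06
      rate: 0.0015
      noise:
        family: gaussian_iid
        sigma: 0.002
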