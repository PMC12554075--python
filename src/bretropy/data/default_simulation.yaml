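# Default synthetic BRET experiment: four treatment conditions on the
# standard protocol grid (30 s sampling, 5 min baseline, 30 min response;
# 71 samples/trace), 3 independent experiments x 3 wells per condition.
#
# Condition parameters are calibration choices, not measured constants:
# - vehicle: flat baseline, white noise
# - AngII: moderate mono-exponential rise (orthosteric agonist response)
# - LVV-H7: no net rise, heavy-tailed signaling bursts (allosteric modulator
#   alone -> irregular dynamics, highest sample entropy)
# - AngII+LVV-H7: larger/faster rise with reduced noise (potentiated,
#   stabilized response -> lowest sample entropy)
simulation:
  n_experiments: 3
  n_wells: 3
  dt: 30.0
  baseline_duration: 300.0
  total_duration: 2100.0
  seed: 0
  conditions:
    - label: vehicle
      baseline: 1.0
      amplitude: 0.0
      rate: 0.004
      noise:
        family: gaussian_iid
        sigma: 0.004
    - label: AngII
      baseline: 1.0
      amplitude: 0.05
      rate: 0.004
      noise:
        family: gaussian_iid
        sigma: 0.004
    - label: LVV-H7
      baseline: 1.0
      amplitude: 0.0
      rate: 0.004
      noise:
        family: burst_renewal
        sigma: 0.006
        burst_rate_scale: 60.0
        burst_tail: 1.5
        burst_amplitude: 0.02
        burst_decay: 0.02
    - label: AngII+LVV-H7
      baseline: 1.0
      amplitude: 0.09
      rate: 0.008
      noise:
        family: gaussian_iid
        sigma: 0.002
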