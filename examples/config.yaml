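# Pipeline configuration overrides. Every key is optional; defaults are
# echoed into the run log. Pass with `wcesurv <stage> --config ...`.
simulation:
  n_patients: 2000
  study_start: 2011-01-01
  study_end: 2015-09-30
  initiation_prob: 0.9

cohort:
  study_start: 2011-01-01
  study_end: 2015-09-30
  washout_days: 182
  copd_icd_patterns: ["J43*", "J440", "J441", "J448", "J449"]

wce:
  window: 75
  n_interior_knots: 1
  constrained: true
  ties: efron
  candidates:            # used with `fit-wce --select`
    - [30, 1, true]
    - [60, 1, true]
    - [75, 1, true]
    - [90, 1, true]
    - [180, 1, true]

ncc:
  n_controls: 2
  age_caliper: 2.0
  entry_caliper_days: 30
  window: 75
  n_interior_knots: 1
  constrained: true
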