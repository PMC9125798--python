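# SYNTHETIC calibration fixture, not published growth parameters.
# Forward curves calibrated (least squares on inverted ages) so that the
# two-stage curve reproduces a published set of seven male bowhead
# (body length, age) pairs within rounding, and the single-stage curve
# passes through (14.88 m, 78 yr). Replace with the published parameter
# set for production use.
two_stage:
  model_id: VB_II_two_stage
  asymptotic_length_m: 14.74387
  k: 0.061017
  b: 0.0          # unused: adult-stage scale is fixed by continuity
  stage1_asymptote_m: 14.15501
  stage1_k: 0.078171
  stage1_b: 0.565769
  stage_transition_yr: 22.72835
single_stage:
  model_id: VB_Ia_single_stage
  asymptotic_length_m: 15.1
  k: 0.03
  b: 0.1512498
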