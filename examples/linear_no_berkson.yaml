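# Linear dose-response with classical-only error (no Berkson
# component): the unadjusted regression is biased by the shared
# classical component while regression calibration stays calibrated.
# Desk-scale ensemble sizes; raise n_meta/m_sub for study-scale runs.
ensemble:
  n_meta: 20
  m_sub: 20
  n_cases: 250
seed: 20250901
methods: [unadjusted, regression_calibration]
scenarios:
  - name: linear-classical-20-20
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 3.0
    form: linear
output_dir: results/linear_no_berkson
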