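# Study-scale template covering the shared/unshared Berkson scenarios
# for both risk-model forms with all five estimators.  At these sizes a
# full run takes hours (the MCMC estimator dominates); scale n_meta and
# m_sub down for desk runs.
ensemble:
  n_meta: 500
  m_sub: 1000
  n_cases: 250
seed: 20250901
methods: [unadjusted, regression_calibration, mcml, quasi_2dmc_bma, fma]
mcmc:
  n_chains: 2
  n_burnin: 1000
  n_keep: 1000
fma:
  k_samples: 100
scenarios:
  - name: lq-berkson-00-00
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 0.25
    beta: 2.0
    form: linear-quadratic
  - name: lq-berkson-20-20
    sigma_unshared_berkson: 0.2
    sigma_shared_berkson: 0.2
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 0.25
    beta: 2.0
    form: linear-quadratic
  - name: lq-berkson-20-50
    sigma_unshared_berkson: 0.2
    sigma_shared_berkson: 0.5
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 0.25
    beta: 2.0
    form: linear-quadratic
  - name: lq-berkson-50-50
    sigma_unshared_berkson: 0.5
    sigma_shared_berkson: 0.5
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 0.25
    beta: 2.0
    form: linear-quadratic
  - name: lin-berkson-00-00
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 3.0
    form: linear
  - name: lin-berkson-20-50
    sigma_unshared_berkson: 0.2
    sigma_shared_berkson: 0.5
    sigma_shared_classical: 0.2
    sigma_unshared_classical: 0.2
    alpha: 3.0
    form: linear
output_dir: results/full_study
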