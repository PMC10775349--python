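# doserr

Simulation studies of dose-measurement-error corrections for radiation
dose–response analysis.

Radiation epidemiology fits excess-relative-risk (ERR) models,
`RR(D) = 1 + αD + βD²`, to grouped cohort data whose doses are
uncertain. The error mix matters: *Berkson* error (true dose scatters
around the assigned group dose) and *classical* error (the recorded
surrogate scatters around the true dose) bias fits differently, and
either can be *shared* across the whole cohort (a dosimetry-system
bias) or *unshared* (independent per person). `doserr` generates
synthetic grouped cohorts under a composite shared/unshared
Berkson–classical lognormal error model,

    D_true,i,j = D_cent,k(i) · e^{−(σ²_sB+σ²_uB)/2} · e^{σ_sB ε_j + σ_uB δ_ij}
    D_surr,i,j = D_cent,k(i) · e^{−(σ²_sC+σ²_uC)/2} · e^{σ_sC μ_j + σ_uC ν_ij}

draws cancer cases from a multinomial over individuals with
probabilities ∝ `1 + αD + βD²`, and evaluates five correction
estimators by coverage, bias and predicted-ERR bias:

1. **unadjusted** regression on surrogate doses,
2. **regression calibration** (group-mean true dose),
3. **MCML** — Monte Carlo maximum likelihood over the ensemble of
   per-sub-simulation dose vectors,
4. **quasi-2DMC with BMA** — Bayesian model averaging over dose
   vectors with softmax mixture weights, sampled by
   Metropolis–Hastings,
5. **FMA** — frequentist model averaging with AIC weights
   `e^{−AIC_j/2}/Σ e^{−AIC_k/2}`.

All fits are Poisson linear relative-risk models with person-year
offsets, profile-likelihood 95% intervals and AIC. The default dose
grid mirrors the 5-group bone-marrow-dose structure of the Life Span
Study leukaemia data (0–0.07 to ≥2.5 Gy). It is aimed at
methodologists studying dose-error corrections and at anyone needing a
reproducible shared-error simulation harness.

## Worked example

```python
import numpy as np
from doserr import *

grid = default_grid()
errors = ErrorSpec(sigma_unshared_berkson=0.2, sigma_shared_berkson=0.5,
                   sigma_shared_classical=0.2, sigma_unshared_classical=0.2)
truth = RiskModel(alpha=3.0)

ensemble = simulate_dose_ensemble(grid, errors, m=200, rng_seed=1)
print("dose correlation:", round(true_dose_correlation(ensemble, rng_seed=2), 3),
      "closed form:", round(lognormal_shared_correlation(0.5, 0.2), 3))

cases = simulate_cases(ensemble, truth, n_cases=250, rng_seed=3)
meta = MetaDataset.from_ensemble(ensemble, cases)
for fit in (fit_unadjusted(meta, form="linear"),
            fit_regression_calibration(meta, form="linear"),
            fit_mcml(meta, form="linear")):
    iv = fit.ci_alpha
    print(f"{fit.method_tag:24s} alpha = {fit.alpha_hat:5.2f}"
          f"  95% CI ({iv.lower:.2f}, {iv.upper:.2f})")
```

prints

```
dose correlation: 0.832 closed form: 0.844
unadjusted               alpha =  2.25  95% CI (1.44, 3.35)
regression_calibration   alpha =  2.63  95% CI (1.69, 3.92)
mcml                     alpha =  2.68  95% CI (1.19, 7.35)
```

The 50% shared Berkson component correlates every individual's true
dose (sample Pearson 0.83 vs. the closed form
`(e^{σ²_s}−1)/(e^{σ²_s+σ²_u}−1) = 0.844`); in this meta-simulation the
common dose factor happened to be high, so all three point estimates
fall below α = 3 — shared error moves them together, which is exactly
why it cannot average away and why MCML's interval, which sees the
whole dose-vector ensemble, is the widest and most honest of the
three.

Full scenario ensembles run from YAML steering files through the CLI:

```sh
doserr validate examples/full_study.yaml
doserr run examples/linear_no_berkson.yaml --out results/demo
```

`run` writes tidy CSV tables (`table_coverage.csv`,
`table_coefficients.csv`, `table_err_bias.csv`), a JSON results bundle
and a run log with seeds, per-method failure counts and
Brooks–Gelman–Rubin convergence warnings. `doserr fixtures` emits the
small deterministic datasets used by the test suite. See
`docs/methods.md` for the model, estimator protocols, default study
conditions and known limitations.

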