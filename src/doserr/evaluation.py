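"""Scenario ensembles and evaluation metrics.

A scenario fixes the error magnitudes, the true risk model and the
fitted model form; running it simulates ``n_meta`` meta-simulations
(each with its own dose ensemble, case draw and per-method fits) and
the metrics summarise the results: 95%-interval coverage of each
coefficient, mean coefficients, percentage bias, and percentage bias in
the predicted excess relative risk at chosen prediction doses

    100 * [ (alpha_mean*D + beta_mean*D^2) / (alpha*D + beta*D^2) - 1 ].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import ESTIMATORS, McmcSettings, MetaDataset
from .sim_core import (
    DoseGrid,
    ErrorSpec,
    RiskModel,
    default_grid,
    simulate_cases,
    simulate_dose_ensemble,
    true_dose_correlation,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "coverage",
    "coverage_detail",
    "mean_coefficient",
    "err_bias",
    "build_tables",
]

Form = Literal["linear", "linear-quadratic"]

#: grouped views each estimator needs from a meta-simulation
_NEEDS = {
    "unadjusted": "unadjusted",
    "regression_calibration": "calibrated",
    "mcml": "vectors",
    "quasi_2dmc_bma": "vectors",
    "fma": "vectors",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: error magnitudes, truth, fitted form,
    ensemble sizes and the estimators to run."""

    name: str
    errors: ErrorSpec
    truth: RiskModel
    form: Form
    methods: Tuple[str, ...]
    n_meta: int = 100
    m_sub: int = 100
    n_cases: int = 250
    grid: DoseGrid = field(default_factory=default_grid)
    seed: int = 0
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    fma_k_samples: int = 100
    fma_symmetric_sd: bool = True
    surrogate_index: int = 0

    def __post_init__(self):
        if self.n_meta < 1 or self.m_sub < 1:
            raise ValueError("n_meta and m_sub must be at least 1")
        if not self.methods:
            raise ValueError("at least one estimator must be requested")
        unknown = [m for m in self.methods if m not in ESTIMATORS]
        if unknown:
            raise ValueError(
                f"unknown estimator(s) {unknown}; known: {sorted(ESTIMATORS)}"
            )
        # truth must give positive relative risk over the grid support
        self.truth.validate_positive(self.grid.central_doses)


@dataclass
class ScenarioResult:
    """Per-meta-simulation estimator outputs for one scenario."""

    spec: ScenarioSpec
    results: List[Dict[str, object]]  # one dict per meta-simulation
    failures: List[Dict[str, str]]
    correlation: float = float("nan")

    def method_results(self, method: str) -> List[object]:
        return [r[method] for r in self.results if method in r]

    @property
    def n_meta(self) -> int:
        return len(self.results)

    def failure_count(self, method: str) -> int:
        return sum(1 for f in self.failures if f.get("method") == method)


def _run_one_meta(spec: ScenarioSpec, meta_id: int, seed_seq: np.random.SeedSequence):
    """Simulate one meta-simulation and run every requested estimator."""
    s_dose, s_case, s_bma, s_fma = seed_seq.spawn(4)
    ensemble = simulate_dose_ensemble(spec.grid, spec.errors, spec.m_sub, rng_seed=s_dose)
    cases = simulate_cases(ensemble, spec.truth, spec.n_cases, rng_seed=s_case)
    # plug-in estimators (registered at run time) get the vectors view
    need = sorted({_NEEDS.get(m, "vectors") for m in spec.methods})
    meta = MetaDataset.from_ensemble(
        ensemble, cases, meta_id=meta_id, surrogate_index=spec.surrogate_index, need=need
    )
    out: Dict[str, object] = {}
    failures: List[Dict[str, str]] = []
    for method in spec.methods:
        try:
            if method == "quasi_2dmc_bma":
                out[method] = ESTIMATORS[method](
                    meta,
                    form=spec.form,
                    settings=spec.mcmc,
                    rng_seed=s_bma,
                    store_chains=False,
                )
            elif method == "fma":
                out[method] = ESTIMATORS[method](
                    meta,
                    form=spec.form,
                    k_samples=spec.fma_k_samples,
                    rng_seed=s_fma,
                    symmetric_sd=spec.fma_symmetric_sd,
                )
            else:
                out[method] = ESTIMATORS[method](meta, form=spec.form)
        except Exception as exc:  # recorded, never aborts the ensemble
            failures.append({"meta_id": str(meta_id), "method": method, "error": str(exc)})
    return out, failures


def run_scenario(spec: ScenarioSpec, n_jobs: int = 1, progress: bool = False) -> ScenarioResult:
    """Run a full scenario ensemble.

    Seeds are spawned hierarchically from ``spec.seed`` (one stream per
    meta-simulation, split again per randomness source), so results are
    reproducible and independent of scheduling order under parallel
    execution (``n_jobs != 1`` uses joblib processes).
    """
    root = np.random.SeedSequence(spec.seed)
    meta_seeds = root.spawn(spec.n_meta + 1)
    corr_seed = meta_seeds[-1]

    if n_jobs != 1:
        from joblib import Parallel, delayed

        pairs = Parallel(n_jobs=n_jobs)(
            delayed(_run_one_meta)(spec, i, meta_seeds[i]) for i in range(spec.n_meta)
        )
    else:
        pairs = []
        iterator = range(spec.n_meta)
        if progress:
            try:
                from tqdm import tqdm

                iterator = tqdm(iterator, desc=spec.name)
            except ImportError:
                pass
        for i in iterator:
            pairs.append(_run_one_meta(spec, i, meta_seeds[i]))

    results = [p[0] for p in pairs]
    failures = [f for p in pairs for f in p[1]]

    # scenario-level sample dose correlation from a dedicated ensemble
    corr = float("nan")
    if spec.errors.sigma_shared_berkson > 0 or spec.errors.sigma_unshared_berkson > 0:
        corr_ensemble = simulate_dose_ensemble(
            spec.grid, spec.errors, max(spec.m_sub, 3), rng_seed=corr_seed
        )
        corr = true_dose_correlation(corr_ensemble, n_pairs=100, rng_seed=0)
    return ScenarioResult(spec=spec, results=results, failures=failures, correlation=corr)


# ---------------------------------------------------------------------------
# metrics


def _is_converged(res) -> bool:
    return bool(getattr(res, "converged", True))


def coverage_detail(results: Sequence[object], truth: float, coefficient: str):
    """(coverage %, n total, n non-converged).  Non-converged results
    stay in the denominator but are reported separately."""
    if not results:
        raise ValueError("no results to compute coverage from")
    n = len(results)
    hits = 0
    n_bad = 0
    for r in results:
        if not _is_converged(r):
            n_bad += 1
        iv = r.interval(coefficient)
        if iv.contains(truth):
            hits += 1
    return 100.0 * hits / n, n, n_bad


def coverage(results: Sequence[object], truth: float, coefficient: str) -> float:
    """Percentage of results whose 95% interval contains the truth."""
    return coverage_detail(results, truth, coefficient)[0]


def mean_coefficient(results: Sequence[object], coefficient: str) -> float:
    """Mean point estimate over converged results."""
    vals = [r.estimate(coefficient) for r in results if _is_converged(r)]
    if not vals:
        raise ValueError("no converged results")
    return float(np.mean(vals))


def err_bias(mean_alpha: float, mean_beta: float, truth: RiskModel, d_pred: float) -> float:
    """Percentage bias in the predicted excess relative risk at
    ``d_pred`` implied by the ensemble-mean coefficients."""
    denom = truth.alpha * d_pred + truth.beta * d_pred**2
    if denom == 0:
        raise ValueError("true excess relative risk is zero at the prediction dose")
    numer = mean_alpha * d_pred + mean_beta * d_pred**2
    return 100.0 * (numer / denom - 1.0)


def build_tables(
    scenario_results: Sequence[ScenarioResult],
    d_pred: Sequence[float] = (0.1, 1.0),
) -> Dict[str, pd.DataFrame]:
    """Tidy evaluation tables over completed scenario runs.

    Returns three frames: ``coverage`` (per scenario/method/coefficient),
    ``coefficients`` (mean estimate and % bias) and ``err_bias``
    (per prediction dose, from the ensemble-mean coefficients).
    """
    cov_rows, coef_rows, err_rows = [], [], []
    for sr in scenario_results:
        spec = sr.spec
        base = {
            "scenario": spec.name,
            "form": spec.form,
            "sigma_shared_berkson": spec.errors.sigma_shared_berkson,
            "sigma_unshared_berkson": spec.errors.sigma_unshared_berkson,
            "sigma_shared_classical": spec.errors.sigma_shared_classical,
            "sigma_unshared_classical": spec.errors.sigma_unshared_classical,
            "dose_correlation": sr.correlation,
            "n_meta": spec.n_meta,
            "m_sub": spec.m_sub,
        }
        coefs = ("alpha",) if spec.form == "linear" else ("alpha", "beta")
        truth_of = {"alpha": spec.truth.alpha, "beta": spec.truth.beta}
        for method in spec.methods:
            results = sr.method_results(method)
            n_failed = spec.n_meta - len(results)
            if not results:
                continue
            means = {}
            for coef in coefs:
                cov, n, n_bad = coverage_detail(results, truth_of[coef], coef)
                mean = mean_coefficient(results, coef)
                means[coef] = mean
                truth_val = truth_of[coef]
                cov_rows.append(
                    {
                        **base,
                        "method": method,
                        "coefficient": coef,
                        "coverage_pct": cov,
                        "n_results": n,
                        "n_nonconverged": n_bad,
                        "n_failed": n_failed,
                    }
                )
                coef_rows.append(
                    {
                        **base,
                        "method": method,
                        "coefficient": coef,
                        "mean": mean,
                        "truth": truth_val,
                        "pct_bias": 100.0 * (mean / truth_val - 1.0)
                        if truth_val != 0
                        else float("nan"),
                        "n_failed": n_failed,
                    }
                )
            mean_beta = means.get("beta", 0.0)
            for d in d_pred:
                err_rows.append(
                    {
                        **base,
                        "method": method,
                        "d_pred": d,
                        "err_bias_pct": err_bias(means["alpha"], mean_beta, spec.truth, d),
                        "n_failed": n_failed,
                    }
                )
    return {
        "coverage": pd.DataFrame(cov_rows),
        "coefficients": pd.DataFrame(coef_rows),
        "err_bias": pd.DataFrame(err_rows),
    }
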