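"""Maximum-likelihood fitting of the Poisson linear relative-risk model
to grouped data, with profile-likelihood confidence intervals and AIC.

The model for group g is

    mu_g = exp(kappa) * PY_g * (1 + alpha*d_g [+ beta*d_g^2])

with person-year offset PY_g and the linear-relative-risk positivity
constraint 1 + alpha*d + beta*d^2 > 0 at every observed dose.  The
log-likelihood is sum_g [ y_g log(mu_g) - mu_g ] with additive
constants (log y_g!) dropped consistently.  The intercept ``kappa`` is
profiled out analytically -- exp(kappa) is a pure scale, so its MLE
given (alpha, beta) is total cases / sum_g PY_g * RR_g -- which leaves
a 1- or 2-dimensional numerical optimisation, robust with only a
handful of dose groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .sim_core import GroupedDataset, RiskModel

__all__ = ["FitResult", "Interval", "loglik_linear_rr", "fit_linear_rr", "profile_ci"]

Form = Literal["linear", "linear-quadratic"]

_BIG_PENALTY = 1e12


@dataclass(frozen=True)
class Interval:
    """A two-sided interval; a side whose bound could not be located
    inside the admissible parameter region is flagged unbounded."""

    lower: float
    upper: float
    lower_bounded: bool = True
    upper_bounded: bool = True

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def as_tuple(self) -> Tuple[float, float]:
        return (self.lower, self.upper)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the Poisson linear relative-risk model."""

    alpha_hat: float
    beta_hat: Optional[float]
    kappa_hat: float
    ci_alpha: Optional[Interval]
    ci_beta: Optional[Interval]
    loglik: float
    aic: float
    converged: bool
    method_tag: str = ""
    n_params: int = 2

    def estimate(self, coefficient: str) -> float:
        if coefficient == "alpha":
            return self.alpha_hat
        if coefficient == "beta":
            if self.beta_hat is None:
                raise ValueError("linear fit has no beta coefficient")
            return self.beta_hat
        if coefficient == "kappa":
            return self.kappa_hat
        raise ValueError(f"unknown coefficient {coefficient!r}")

    def interval(self, coefficient: str) -> Interval:
        ci = {"alpha": self.ci_alpha, "beta": self.ci_beta}.get(coefficient)
        if ci is None:
            raise ValueError(f"no interval available for {coefficient!r}")
        return ci

    def to_record(self) -> dict:
        rec = {
            "method": self.method_tag,
            "alpha": self.alpha_hat,
            "beta": self.beta_hat,
            "kappa": self.kappa_hat,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
        }
        for name, ci in (("alpha", self.ci_alpha), ("beta", self.ci_beta)):
            if ci is not None:
                rec[f"{name}_lo"] = ci.lower
                rec[f"{name}_hi"] = ci.upper
        return rec


def _relative_risk(dose: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return 1.0 + alpha * dose + beta * dose * dose


def loglik_linear_rr(
    data: GroupedDataset,
    dose: Sequence[float],
    model: RiskModel,
    form: Form = "linear-quadratic",
) -> float:
    """Poisson log-likelihood (constants dropped) at the given
    parameters; raises if any relative risk is non-positive."""
    d = np.asarray(dose, dtype=float)
    beta = 0.0 if form == "linear" else model.beta
    rr = _relative_risk(d, model.alpha, beta)
    if np.any(rr <= 0):
        raise ValueError(
            f"non-positive relative risk at dose {d[np.argmin(rr)]:.6g} Gy; "
            "parameters outside the admissible region"
        )
    mu = np.exp(model.kappa) * data.offsets * rr
    return float(np.sum(data.cases * np.log(mu) - mu))


def _concentrated_loglik(y: np.ndarray, py: np.ndarray, rr: np.ndarray, s_y: float) -> float:
    """Log-likelihood with kappa profiled out analytically."""
    if np.any(rr <= 0):
        return -np.inf
    t = float(np.dot(py, rr))
    return s_y * np.log(s_y / t) + float(np.dot(y, np.log(py * rr))) - s_y


def _profile_fn(data: GroupedDataset, dose: np.ndarray, form: Form):
    """Return f(alpha, beta) -> concentrated log-likelihood."""
    y = data.cases.astype(float)
    py = data.offsets
    s_y = float(y.sum())
    d = np.asarray(dose, dtype=float)
    d2 = d * d

    def f(alpha: float, beta: float) -> float:
        return _concentrated_loglik(y, py, 1.0 + alpha * d + beta * d2, s_y)

    return f


def _fit_linear(f, dose: np.ndarray, start: Optional[float] = None):
    """Maximise the concentrated log-likelihood over alpha for the
    linear form; the admissible region is alpha > -1/max(dose)."""
    a_min = -1.0 / float(np.max(dose))
    # coarse scan of the admissible region, then local refinement
    grid = a_min + np.geomspace(1e-6, 1e4, 81)
    if start is not None and start > a_min:
        grid = np.append(grid, start)
    vals = np.array([f(a, 0.0) for a in grid])
    a0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda a: -f(a, 0.0) if a > a_min else _BIG_PENALTY,
        bracket=None,
        bounds=(a_min + 1e-12, a0 + 10.0 * (a0 - a_min) + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), 0.0, bool(res.success)


def _fit_lq(f, start: Tuple[float, float]):
    """Maximise over (alpha, beta) with a rejection penalty outside the
    positivity region (Nelder-Mead)."""

    def nll(p):
        v = f(p[0], p[1])
        return -v if np.isfinite(v) else _BIG_PENALTY

    res = optimize.minimize(
        nll,
        np.asarray(start, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000},
    )
    return float(res.x[0]), float(res.x[1]), bool(res.success) and res.fun < _BIG_PENALTY / 2


def fit_linear_rr(
    data: GroupedDataset,
    dose: Optional[Sequence[float]] = None,
    form: Form = "linear-quadratic",
    ci: bool = True,
    level: float = 0.95,
    method_tag: str = "poisson_rr",
    start: Optional[Tuple[float, float]] = None,
) -> FitResult:
    """Fit the Poisson linear relative-risk model by maximum likelihood.

    ``dose`` defaults to the dataset's calibrated dose.  With
    ``ci=True`` profile-likelihood intervals are attached for alpha
    (and beta for the linear-quadratic form).  Non-convergence is
    flagged on the result, never silent.
    """
    d = np.asarray(data.calibrated_dose if dose is None else dose, dtype=float)
    if data.total_cases < 1:
        raise ValueError("need at least one case to fit")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if np.allclose(d, d[0]):
        raise ValueError("all doses equal: the dose-response slope is unidentifiable")

    f = _profile_fn(data, d, form)
    if form == "linear":
        a, b, ok = _fit_linear(f, d, start=None if start is None else start[0])
        n_params = 2
        beta_hat: Optional[float] = None
    elif form == "linear-quadratic":
        if start is None:
            a_lin, _, _ = _fit_linear(f, d)
            start = (a_lin, 1e-8)
        a, b, ok = _fit_lq(f, start)
        n_params = 3
        beta_hat = b
    else:
        raise ValueError(f"unknown model form {form!r}")

    ll = f(a, b)
    s_y = float(data.cases.sum())
    t = float(np.dot(data.offsets, _relative_risk(d, a, b)))
    kappa = float(np.log(s_y / t))
    aic = -2.0 * ll + 2.0 * n_params
    result = FitResult(
        alpha_hat=a,
        beta_hat=beta_hat,
        kappa_hat=kappa,
        ci_alpha=None,
        ci_beta=None,
        loglik=ll,
        aic=aic,
        converged=ok and np.isfinite(ll),
        method_tag=method_tag,
        n_params=n_params,
    )
    if ci:
        ci_a = profile_ci(data, d, form, "alpha", level=level, fit=result)
        ci_b = (
            profile_ci(data, d, form, "beta", level=level, fit=result)
            if form == "linear-quadratic"
            else None
        )
        result = dataclasses.replace(result, ci_alpha=ci_a, ci_beta=ci_b)
    return result


def _max1d(g, x0: float, h: float, tol: float, max_iter: int = 400):
    """Fast 1-D maximiser: pattern search with step expansion plus a
    parabolic refinement once bracketed.  ``g`` may return -inf outside
    the admissible region.  Built for warm starts close to the optimum
    (profile-likelihood inner loops), where it needs ~10 evaluations.
    """
    gx = g(x0)
    if not np.isfinite(gx):  # walk back into the admissible region
        for _ in range(60):
            h *= 0.5
            for cand in (x0 + h, x0 - h):
                gc = g(cand)
                if np.isfinite(gc):
                    x0, gx = cand, gc
                    break
            if np.isfinite(gx):
                break
        else:
            return x0, gx
    for _ in range(max_iter):
        if h < tol:
            break
        gl = g(x0 - h)
        gr = g(x0 + h)
        if gl > gx and gl >= gr:
            x0, gx = x0 - h, gl
            h *= 1.6
            continue
        if gr > gx:
            x0, gx = x0 + h, gr
            h *= 1.6
            continue
        denom = gl - 2.0 * gx + gr
        if np.isfinite(denom) and denom < 0:
            dx = 0.5 * h * (gl - gr) / denom
            if abs(dx) < h:
                gq = g(x0 + dx)
                if gq > gx:
                    x0, gx = x0 + dx, gq
        h *= 0.35
    return x0, gx


def _maximize_over_other(f, coefficient: str, value: float, other_start: float, dose: np.ndarray):
    """Profile value: max over the other coefficient at a fixed one
    (linear-quadratic form)."""

    if coefficient == "alpha":
        def g(b):
            return f(value, b)
    else:
        def g(a):
            return f(a, value)

    scale = max(abs(other_start), 0.1)
    x, gx = _max1d(g, other_start, h=0.05 * scale, tol=1e-6 * scale)
    return gx, x


def profile_ci(
    data: GroupedDataset,
    dose: Optional[Sequence[float]] = None,
    form: Form = "linear-quadratic",
    coefficient: str = "alpha",
    level: float = 0.95,
    fit: Optional[FitResult] = None,
    xtol: float = 1e-6,
    max_expand: int = 60,
) -> Interval:
    """Profile-likelihood confidence interval for one coefficient.

    The interval is the set of values whose profile log-likelihood is
    within chi2_1(level)/2 (1.921 at 95%) of the maximum; each bound is
    located by geometric bracket expansion from the MLE followed by
    root bisection.  A side where the likelihood never drops below the
    threshold inside the admissible region is flagged unbounded.
    """
    d = np.asarray(data.calibrated_dose if dose is None else dose, dtype=float)
    if fit is None:
        fit = fit_linear_rr(data, d, form, ci=False)
    f = _profile_fn(data, d, form)
    drop = stats.chi2.ppf(level, 1) / 2.0

    if form == "linear":
        if coefficient != "alpha":
            raise ValueError("the linear form has only the alpha coefficient")
        mle = fit.alpha_hat
        hard_lb: Optional[float] = -1.0 / float(np.max(d))

        def pll(x: float) -> float:
            return f(x, 0.0)

        other_at = {}
    else:
        mle = fit.estimate(coefficient)
        hard_lb = None
        other_mle = fit.beta_hat if coefficient == "alpha" else fit.alpha_hat
        other_at = {"start": float(other_mle)}

        def pll(x: float) -> float:
            v, o = _maximize_over_other(f, coefficient, x, other_at["start"], d)
            other_at["start"] = o  # warm start for the next evaluation
            return v

    ll_max = pll(mle)
    target = ll_max - drop
    scale = max(abs(mle), 0.05)

    def find_bound(direction: int) -> Tuple[float, bool]:
        step = 0.25 * scale
        x_in = mle
        for _ in range(max_expand):
            x_out = x_in + direction * step
            if hard_lb is not None and direction < 0 and x_out <= hard_lb:
                x_out = hard_lb + 1e-12 * max(1.0, abs(hard_lb))
                if pll(x_out) > target:
                    return x_out, False  # constraint boundary hit before drop
            v = pll(x_out)
            if v < target:
                lo, hi = (x_out, x_in) if direction < 0 else (x_in, x_out)
                root = optimize.brentq(
                    lambda x: pll(x) - target, lo, hi, xtol=xtol * max(1.0, scale)
                )
                return float(root), True
            x_in = x_out
            step *= 2.0
        return x_in, False  # never dropped: effectively unbounded side

    lower, lower_ok = find_bound(-1)
    upper, upper_ok = find_bound(+1)
    return Interval(lower=lower, upper=upper, lower_bounded=lower_ok, upper_bounded=upper_ok)
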