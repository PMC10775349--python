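"""Dose-error-correction estimators.

Each estimator maps one meta-simulation's grouped data
(:class:`MetaDataset`) to a fit summary:

- ``unadjusted``: Poisson linear-RR fit on the surrogate-dose grouped
  data (the only method that sees the surrogate, hence the only one
  affected by classical error);
- ``regression_calibration``: fit at the group-mean true dose averaged
  over individuals and sub-simulations;
- ``mcml``: Monte Carlo maximum likelihood -- maximise the arithmetic
  mean of the per-dose-vector likelihoods over the m sub-simulation
  group-mean dose vectors;
- ``quasi_2dmc_bma``: Bayesian model averaging over the m dose vectors,
  with softmax-parameterised mixture weights and a Metropolis-Hastings
  sampler alternating between the risk parameters (kappa, alpha[, beta])
  and the weight parameters lambda (updated in blocks);
- ``fma``: frequentist model averaging -- per-vector ML fits pooled with
  AIC weights exp(-AIC_j/2)/sum_k exp(-AIC_k/2), coefficient SDs
  recovered from profile-likelihood CIs, and weighted centiles of
  normal resamples giving the interval.

``extended_regression_calibration`` is a named extension slot: the
method lives in a companion body of work and can be plugged in via
:func:`register_estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .poisson_rr import FitResult, Interval, fit_linear_rr, profile_ci
from .sim_core import DoseEnsemble, GroupedDataset, SeedLike, _as_rng, collapse_to_groups

__all__ = [
    "MetaDataset",
    "MixtureWeights",
    "McmcSettings",
    "PosteriorSummary",
    "FmaWeightedSample",
    "fit_unadjusted",
    "fit_regression_calibration",
    "fit_mcml",
    "quasi_2dmc_bma",
    "fma",
    "ESTIMATORS",
    "register_estimator",
]

Form = Literal["linear", "linear-quadratic"]
_BIG = 1e12


# ---------------------------------------------------------------------------
# estimator input


@dataclass(frozen=True)
class MetaDataset:
    """Grouped inputs for one meta-simulation, one per dose summary.

    ``unadjusted`` carries the surrogate-dose collapse, ``calibrated``
    the mean-true-dose collapse, ``vectors`` the per-sub-simulation
    dose-vector collapse.  Any view not needed by the requested
    estimators may be ``None``.
    """

    unadjusted: Optional[GroupedDataset] = None
    calibrated: Optional[GroupedDataset] = None
    vectors: Optional[GroupedDataset] = None
    meta_id: int = 0

    @classmethod
    def from_ensemble(
        cls,
        ensemble: DoseEnsemble,
        cases: np.ndarray,
        meta_id: int = 0,
        surrogate_index: int = 0,
        need: Sequence[str] = ("unadjusted", "calibrated", "vectors"),
    ) -> "MetaDataset":
        kw = {}
        if "unadjusted" in need:
            kw["unadjusted"] = collapse_to_groups(
                ensemble, cases, "single-surrogate-draw", surrogate_index=surrogate_index
            )
        if "calibrated" in need:
            kw["calibrated"] = collapse_to_groups(ensemble, cases, "mean-true")
        if "vectors" in need:
            kw["vectors"] = collapse_to_groups(ensemble, cases, "per-subsim-vectors")
        return cls(meta_id=meta_id, **kw)

    def _require(self, name: str) -> GroupedDataset:
        data = getattr(self, name)
        if data is None:
            raise ValueError(f"meta dataset is missing its {name!r} grouped view")
        return data


# ---------------------------------------------------------------------------
# simple estimators


def fit_unadjusted(meta: MetaDataset, form: Form = "linear-quadratic", **fit_kw) -> FitResult:
    """Plain Poisson linear-RR fit on the surrogate-dose grouped data."""
    data = meta._require("unadjusted")
    return fit_linear_rr(data, form=form, method_tag="unadjusted", **fit_kw)


def fit_regression_calibration(
    meta: MetaDataset, form: Form = "linear-quadratic", **fit_kw
) -> FitResult:
    """Poisson linear-RR fit at the per-group mean true dose."""
    data = meta._require("calibrated")
    return fit_linear_rr(data, form=form, method_tag="regression_calibration", **fit_kw)


# ---------------------------------------------------------------------------
# Monte Carlo maximum likelihood


class _MixtureLoglik:
    """log[(1/m) sum_j L(theta; dose vector j)] for grouped data,
    vectorised over the m dose vectors."""

    def __init__(self, data: GroupedDataset, form: Form):
        if data.dose_vectors is None:
            raise ValueError("dose vectors required (per-subsim-vectors collapse)")
        self.y = data.cases.astype(float)
        self.py = data.offsets
        self.s_y = float(self.y.sum())
        self.ylogpy = float(np.dot(self.y, np.log(self.py)))
        self.d = data.dose_vectors  # (m, G)
        self.d2 = self.d * self.d
        self.m = self.d.shape[0]
        self.form = form
        self.n_params = 2 if form == "linear" else 3

    def loglik_per_vector(self, kappa: float, alpha: float, beta: float) -> Optional[np.ndarray]:
        """(m,) log-likelihoods, or None outside the positivity region."""
        rr = 1.0 + alpha * self.d + (beta * self.d2 if self.form != "linear" else 0.0)
        if np.any(rr <= 0):
            return None
        return (
            self.s_y * kappa
            + self.ylogpy
            + np.log(rr) @ self.y
            - np.exp(kappa) * (rr @ self.py)
        )

    def __call__(self, kappa: float, alpha: float, beta: float = 0.0) -> float:
        ll = self.loglik_per_vector(kappa, alpha, beta)
        if ll is None:
            return -np.inf
        return float(logsumexp(ll)) - np.log(self.m)


def _nm_maximize(fun, x0, xatol=1e-9, fatol=1e-10, maxiter=4000):
    def neg(p):
        v = fun(p)
        return -v if np.isfinite(v) else _BIG

    res = optimize.minimize(
        neg,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
    )
    return res.x, -float(res.fun), bool(res.success)


def fit_mcml(
    meta: MetaDataset,
    form: Form = "linear-quadratic",
    ci: bool = True,
    level: float = 0.95,
) -> FitResult:
    """Monte Carlo maximum likelihood over the ensemble of dose vectors.

    The Monte Carlo likelihood is the arithmetic mean of the
    per-vector Poisson likelihoods; profile-likelihood intervals are
    computed on this averaged likelihood.  With a single vector, or
    identical vectors, the method degenerates to the plain fit.
    """
    data = meta._require("vectors")
    mix = _MixtureLoglik(data, form)

    start_fit = fit_linear_rr(data, form=form, ci=False, method_tag="mcml-start")
    if form == "linear":
        x0 = [start_fit.kappa_hat, start_fit.alpha_hat]
        fun = lambda p: mix(p[0], p[1])
    else:
        x0 = [start_fit.kappa_hat, start_fit.alpha_hat, start_fit.beta_hat]
        fun = lambda p: mix(p[0], p[1], p[2])
    x, ll, ok = _nm_maximize(fun, x0)
    kappa, alpha = float(x[0]), float(x[1])
    beta = float(x[2]) if form != "linear" else None
    aic = -2.0 * ll + 2.0 * mix.n_params

    ci_a = ci_b = None
    if ci:
        ci_a = _profile_ci_mixture(mix, x, coef_index=1, level=level)
        if form != "linear":
            ci_b = _profile_ci_mixture(mix, x, coef_index=2, level=level)
    return FitResult(
        alpha_hat=alpha,
        beta_hat=beta,
        kappa_hat=kappa,
        ci_alpha=ci_a,
        ci_beta=ci_b,
        loglik=ll,
        aic=aic,
        converged=ok and np.isfinite(ll),
        method_tag="mcml",
        n_params=mix.n_params,
    )


def _profile_ci_mixture(
    mix: _MixtureLoglik,
    mle: np.ndarray,
    coef_index: int,
    level: float = 0.95,
    xtol: float = 1e-6,
    max_expand: int = 60,
) -> Interval:
    """Profile-likelihood interval on the Monte Carlo (mixture)
    likelihood, profiling numerically over the remaining parameters."""
    drop = stats.chi2.ppf(level, 1) / 2.0
    free = [i for i in range(len(mle)) if i != coef_index]
    warm = {"x": np.asarray(mle, dtype=float)[free]}

    def pll(value: float) -> float:
        def fun(p_free):
            p = np.empty(len(mle))
            p[coef_index] = value
            p[free] = p_free
            return mix(*p)

        x, v, _ = _nm_maximize(fun, warm["x"], xatol=1e-7, fatol=1e-8, maxiter=1000)
        warm["x"] = x
        return v

    center = float(mle[coef_index])
    ll_max = pll(center)
    target = ll_max - drop
    scale = max(abs(center), 0.05)

    def bound(direction: int) -> Tuple[float, bool]:
        step = 0.25 * scale
        x_in = center
        for _ in range(max_expand):
            x_out = x_in + direction * step
            v = pll(x_out)
            if v < target:
                lo, hi = (x_out, x_in) if direction < 0 else (x_in, x_out)
                root = optimize.brentq(lambda x: pll(x) - target, lo, hi, xtol=xtol * max(1.0, scale))
                return float(root), True
            x_in = x_out
            step *= 2.0
        return x_in, False

    lower, l_ok = bound(-1)
    upper, u_ok = bound(+1)
    return Interval(lower, upper, l_ok, u_ok)


# ---------------------------------------------------------------------------
# quasi-2DMC with Bayesian model averaging


@dataclass(frozen=True)
class MixtureWeights:
    """Softmax-parameterised mixture weights over the m dose vectors.

    With unbounded reals lambda_1..lambda_{m-1}, the probabilities are
    p_j = exp(lambda_j) / (1 + sum_k exp(lambda_k)) for j < m and
    p_m = 1 / (1 + sum_k exp(lambda_k)) -- the last vector is the
    softmax reference category.
    """

    lambdas: np.ndarray

    @property
    def m(self) -> int:
        return len(self.lambdas) + 1

    @property
    def log_probs(self) -> np.ndarray:
        aug = np.append(np.asarray(self.lambdas, dtype=float), 0.0)
        return aug - logsumexp(aug)

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)


@dataclass(frozen=True)
class McmcSettings:
    """Metropolis-Hastings protocol for the BMA sampler."""

    n_chains: int = 2
    n_burnin: int = 1000
    n_keep: int = 1000
    proposal_sd_kappa: float = 0.2
    proposal_sd_coef: float = 1.0  # alpha and beta
    proposal_sd_lambda: float = 2.0
    lambda_block: int = 10
    prior_sd: float = 1000.0
    bgr_threshold: float = 1.05

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for the BGR statistic")
        if self.n_burnin < 0 or self.n_keep < 1:
            raise ValueError("invalid chain lengths")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary of the quasi-2DMC BMA fit."""

    means: Dict[str, float]
    medians: Dict[str, float]
    intervals: Dict[str, Interval]
    bgr: Dict[str, float]
    acceptance_rates: Dict[str, float]
    n_burnin: int
    n_keep: int
    n_chains: int
    converged: bool
    method_tag: str = "quasi_2dmc_bma"
    chains: Optional[np.ndarray] = None  # (n_chains, n_keep, n_params)
    param_names: Tuple[str, ...] = ()

    def estimate(self, coefficient: str) -> float:
        return self.means[coefficient]

    def interval(self, coefficient: str) -> Interval:
        return self.intervals[coefficient]

    def to_record(self) -> dict:
        rec = {"method": self.method_tag, "converged": self.converged}
        for name in self.means:
            rec[name] = self.means[name]
            rec[f"{name}_lo"] = self.intervals[name].lower
            rec[f"{name}_hi"] = self.intervals[name].upper
            rec[f"{name}_bgr"] = self.bgr[name]
        return rec

    def chains_frame(self) -> pd.DataFrame:
        """Kept samples in long format (chain diagnostics export)."""
        if self.chains is None:
            raise ValueError("chains were not stored")
        c, n, p = self.chains.shape
        frames = []
        for i in range(c):
            df = pd.DataFrame(self.chains[i], columns=list(self.param_names))
            df.insert(0, "iteration", np.arange(n))
            df.insert(0, "chain", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor over split half-chains."""
    n = x.shape[1] // 2
    if n < 2:
        return float("nan")
    segs = [seg for c in x for seg in (c[:n], c[n : 2 * n])]
    segs = np.asarray(segs)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    b = n * segs.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def quasi_2dmc_bma(
    meta: MetaDataset,
    form: Form = "linear-quadratic",
    settings: McmcSettings = McmcSettings(),
    rng_seed: SeedLike = None,
    store_chains: bool = True,
) -> PosteriorSummary:
    """Bayesian model averaging over the dose-vector ensemble.

    The posterior for (kappa, alpha[, beta]) is the mixture over dose
    vectors k of single-vector posteriors, weighted by softmax
    probabilities p_k; the sampler alternates Metropolis-Hastings
    updates of the risk parameters against the mixture likelihood
    sum_k p_k L_k with updates of the lambda weight parameters in
    blocks.  All parameters have N(0, prior_sd^2) priors; proposals
    violating relative-risk positivity on any dose vector are rejected
    outright.  Two (or more) chains are run; the split-half
    Brooks-Gelman-Rubin factor above ``settings.bgr_threshold`` flags
    the summary as non-converged.
    """
    data = meta._require("vectors")
    mix = _MixtureLoglik(data, form)
    m = mix.m
    names = ("kappa", "alpha") if form == "linear" else ("kappa", "alpha", "beta")
    p = len(names)
    prop_sd = np.array(
        [settings.proposal_sd_kappa] + [settings.proposal_sd_coef] * (p - 1)
    )
    inv2pv = 1.0 / (2.0 * settings.prior_sd**2)

    start_fit = fit_linear_rr(data, form=form, ci=False, method_tag="bma-start")
    theta_mle = np.array(
        [start_fit.kappa_hat, start_fit.alpha_hat]
        + ([start_fit.beta_hat] if form != "linear" else [])
    )

    rng = _as_rng(rng_seed)
    n_iter = settings.n_burnin + settings.n_keep
    blocks = [
        slice(b, min(b + settings.lambda_block, m - 1))
        for b in range(0, m - 1, settings.lambda_block)
    ]
    kept = np.empty((settings.n_chains, settings.n_keep, p))
    acc_theta = np.zeros(p)
    n_theta = 0
    acc_lam = 0
    n_lam = 0

    # hot loop below avoids scipy/dataclass overhead: hand-rolled stable
    # logsumexp and an in-place lambda-augmented array
    def _lse(a: np.ndarray) -> float:
        hi = a.max()
        return float(hi + np.log(np.exp(a - hi).sum()))

    is_linear = form == "linear"
    d_mat, d2_mat, y, py = mix.d, mix.d2, mix.y, mix.py
    s_y, ylogpy = mix.s_y, mix.ylogpy

    def _llv(theta: np.ndarray) -> Optional[np.ndarray]:
        if is_linear:
            rr = 1.0 + theta[1] * d_mat
        else:
            rr = 1.0 + theta[1] * d_mat + theta[2] * d2_mat
        if rr.min() <= 0.0:
            return None
        return s_y * theta[0] + ylogpy + np.log(rr) @ y - np.exp(theta[0]) * (rr @ py)

    for c in range(settings.n_chains):
        # start at the plain-fit MLE, jittered per chain (proposals
        # violating positivity are re-drawn a few times)
        theta = theta_mle.copy()
        for _ in range(20):
            cand = theta_mle + rng.standard_normal(p) * 0.5 * prop_sd
            if _llv(cand) is not None:
                theta = cand
                break
        lam_aug = np.zeros(m)  # last entry pinned at 0 (reference category)
        llv = _llv(theta)
        logp_lam = lam_aug - _lse(lam_aug)
        mix_ll = _lse(logp_lam + llv)

        for it in range(n_iter):
            for i in range(p):
                cand = theta.copy()
                cand[i] += rng.standard_normal() * prop_sd[i]
                llv_new = _llv(cand)
                n_theta += 1
                if llv_new is None:
                    continue
                mix_new = _lse(logp_lam + llv_new)
                dlp = mix_new - mix_ll + (theta[i] ** 2 - cand[i] ** 2) * inv2pv
                if dlp >= 0 or np.log(rng.random()) < dlp:
                    theta, llv, mix_ll = cand, llv_new, mix_new
                    acc_theta[i] += 1
            for blk in blocks:
                old_blk = lam_aug[blk].copy()
                prop_blk = old_blk + rng.standard_normal(old_blk.shape) * settings.proposal_sd_lambda
                lam_aug[blk] = prop_blk
                logp_new = lam_aug - _lse(lam_aug)
                mix_new = _lse(logp_new + llv)
                dlp = mix_new - mix_ll + (
                    np.dot(old_blk, old_blk) - np.dot(prop_blk, prop_blk)
                ) * inv2pv
                n_lam += 1
                if dlp >= 0 or np.log(rng.random()) < dlp:
                    logp_lam, mix_ll = logp_new, mix_new
                    acc_lam += 1
                else:
                    lam_aug[blk] = old_blk
            if it >= settings.n_burnin:
                kept[c, it - settings.n_burnin] = theta

    pooled = kept.reshape(-1, p)
    means = {n: float(pooled[:, i].mean()) for i, n in enumerate(names)}
    medians = {n: float(np.median(pooled[:, i])) for i, n in enumerate(names)}
    intervals = {
        n: Interval(*np.percentile(pooled[:, i], [2.5, 97.5])) for i, n in enumerate(names)
    }
    bgr = {n: _split_rhat(kept[:, :, i]) for i, n in enumerate(names)}
    acc = {n: float(acc_theta[i] / (n_theta / p)) for i, n in enumerate(names)}
    acc["lambda"] = float(acc_lam / max(n_lam, 1))
    converged = all(np.isnan(v) or v < settings.bgr_threshold for v in bgr.values())
    return PosteriorSummary(
        means=means,
        medians=medians,
        intervals=intervals,
        bgr=bgr,
        acceptance_rates=acc,
        n_burnin=settings.n_burnin,
        n_keep=settings.n_keep,
        n_chains=settings.n_chains,
        converged=converged,
        chains=kept if store_chains else None,
        param_names=names,
    )


def _theta3(theta: np.ndarray, form: Form) -> Tuple[float, float, float]:
    if form == "linear":
        return float(theta[0]), float(theta[1]), 0.0
    return float(theta[0]), float(theta[1]), float(theta[2])


# ---------------------------------------------------------------------------
# frequentist model averaging


@dataclass(frozen=True)
class FmaWeightedSample:
    """AIC-weighted pooled fit over the dose-vector ensemble."""

    central: Dict[str, float]
    intervals: Dict[str, Interval]
    aic_weights: np.ndarray
    per_vector: pd.DataFrame
    k_samples: int
    n_dropped: int
    converged: bool
    method_tag: str = "fma"

    def estimate(self, coefficient: str) -> float:
        return self.central[coefficient]

    def interval(self, coefficient: str) -> Interval:
        return self.intervals[coefficient]

    def to_record(self) -> dict:
        rec = {
            "method": self.method_tag,
            "converged": self.converged,
            "n_dropped": self.n_dropped,
        }
        for name in self.central:
            rec[name] = self.central[name]
            rec[f"{name}_lo"] = self.intervals[name].lower
            rec[f"{name}_hi"] = self.intervals[name].upper
        return rec


def _recover_sd(mle: float, ci: Interval) -> float:
    """SD from a profile CI: min distance from the MLE to either bound,
    divided by 1.96; an unbounded side falls back to the other side."""
    dists = []
    if ci.lower_bounded:
        dists.append(mle - ci.lower)
    if ci.upper_bounded:
        dists.append(ci.upper - mle)
    if not dists:
        return float("nan")
    return max(min(dists), 0.0) / 1.959963984540054


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: Sequence[float]) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cdf = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
    return np.interp(q, cdf, xs)


def fma(
    meta: MetaDataset,
    form: Form = "linear-quadratic",
    k_samples: int = 100,
    rng_seed: SeedLike = None,
    symmetric_sd: bool = True,
    ci_xtol: float = 1e-4,
) -> FmaWeightedSample:
    """Frequentist model averaging over the dose-vector ensemble.

    Each dose vector gets its own ML fit with AIC and profile CIs; the
    coefficient SD is recovered from the CI half-widths; ``k_samples``
    normal draws per coefficient per vector are pooled with AIC weights
    exp(-AIC_j/2) (max-AIC subtracted before exponentiation, so
    overflow cannot occur); the weighted mean is the central estimate
    and the weighted 2.5/97.5 centiles give the interval.

    ``symmetric_sd=False`` switches to the asymmetric-SD variant
    (separate SDs above/below the MLE); it is known to be fragile when
    one CI side is very wide and is off by default.

    Non-converged per-vector fits (or fits with no usable CI side) are
    dropped and counted in ``n_dropped``.
    """
    data = meta._require("vectors")
    vectors = data.dose_vectors
    m = vectors.shape[0]
    coefs = ("alpha",) if form == "linear" else ("alpha", "beta")
    rng = _as_rng(rng_seed)

    rows = []
    warm: Optional[Tuple[float, float]] = None
    for j in range(m):
        d = vectors[j]
        try:
            fit = fit_linear_rr(
                GroupedDataset(data.cases, data.offsets, d),
                form=form,
                ci=False,
                method_tag="fma-vector",
                start=warm,
            )
        except ValueError:
            rows.append(None)
            continue
        if not fit.converged:
            rows.append(None)
            continue
        warm = (fit.alpha_hat, fit.beta_hat if fit.beta_hat is not None else 0.0)
        entry = {"aic": fit.aic, "loglik": fit.loglik}
        usable = True
        for coef in coefs:
            iv = profile_ci(
                GroupedDataset(data.cases, data.offsets, d),
                dose=d,
                form=form,
                coefficient=coef,
                fit=fit,
                xtol=ci_xtol,
            )
            mle = fit.estimate(coef)
            if symmetric_sd:
                sd = _recover_sd(mle, iv)
                if not np.isfinite(sd):
                    usable = False
                entry[f"{coef}_mle"] = mle
                entry[f"{coef}_sd"] = sd
            else:
                sd_lo = (mle - iv.lower) / 1.959963984540054 if iv.lower_bounded else np.nan
                sd_hi = (iv.upper - mle) / 1.959963984540054 if iv.upper_bounded else np.nan
                if not (np.isfinite(sd_lo) and np.isfinite(sd_hi)):
                    usable = False
                entry[f"{coef}_mle"] = mle
                entry[f"{coef}_sd_lo"] = sd_lo
                entry[f"{coef}_sd_hi"] = sd_hi
            entry[f"{coef}_lo"] = iv.lower
            entry[f"{coef}_hi"] = iv.upper
        rows.append(entry if usable else None)

    good = [r for r in rows if r is not None]
    n_dropped = m - len(good)
    if not good:
        raise ValueError("all per-vector fits failed to converge")
    table = pd.DataFrame(good)

    aic = table["aic"].to_numpy()
    logw = -0.5 * (aic - aic.min())
    w = np.exp(logw)
    w = w / w.sum()

    central: Dict[str, float] = {}
    intervals: Dict[str, Interval] = {}
    for coef in coefs:
        mles = table[f"{coef}_mle"].to_numpy()
        if symmetric_sd:
            sds = table[f"{coef}_sd"].to_numpy()
            z = rng.standard_normal((len(good), k_samples))
            samples = mles[:, None] + sds[:, None] * z
        else:
            z = rng.standard_normal((len(good), k_samples))
            sd_lo = table[f"{coef}_sd_lo"].to_numpy()[:, None]
            sd_hi = table[f"{coef}_sd_hi"].to_numpy()[:, None]
            samples = mles[:, None] + np.where(z >= 0, sd_hi, sd_lo) * z
        sw = np.repeat(w / k_samples, k_samples)
        flat = samples.ravel()
        central[coef] = float(np.dot(sw, flat))
        lo, hi = _weighted_quantile(flat, sw, (0.025, 0.975))
        intervals[coef] = Interval(float(lo), float(hi))

    return FmaWeightedSample(
        central=central,
        intervals=intervals,
        aic_weights=w,
        per_vector=table,
        k_samples=k_samples,
        n_dropped=n_dropped,
        converged=True,
    )


# ---------------------------------------------------------------------------
# registry (extension point for plug-in estimators such as extended
# regression calibration)

ESTIMATORS: Dict[str, Callable] = {
    "unadjusted": fit_unadjusted,
    "regression_calibration": fit_regression_calibration,
    "mcml": fit_mcml,
    "quasi_2dmc_bma": quasi_2dmc_bma,
    "fma": fma,
}


def register_estimator(name: str, fn: Callable, overwrite: bool = False) -> None:
    """Register a plug-in estimator ``fn(meta, form, **kw)`` under
    ``name`` (e.g. an extended-regression-calibration implementation)."""
    if name in ESTIMATORS and not overwrite:
        raise ValueError(f"estimator {name!r} already registered")
    ESTIMATORS[name] = fn
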