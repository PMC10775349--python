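"""Nested meta-/sub-simulation of radiation doses under a composite
shared/unshared Berkson-classical lognormal error model.

Individuals sit in dose groups with a central dose estimate per group
(a Life-Span-Study-like 5-group grid by default).  Within one
meta-simulation, ``m`` sub-simulations draw a *true* dose and a
*surrogate* dose for every individual:

    D_true_ij = D_cent_k(i) * exp[-(s_sB^2 + s_uB^2)/2]
                            * exp[s_sB * eps_j + s_uB * delta_ij]
    D_surr_ij = D_cent_k(i) * exp[-(s_sC^2 + s_uC^2)/2]
                            * exp[s_sC * mu_j  + s_uC * nu_ij]

where ``eps_j, mu_j`` are standard-normal draws shared by every
individual within sub-simulation ``j`` (shared Berkson / shared
classical error) and ``delta_ij, nu_ij`` are independent per individual
(unshared error).  The deterministic factors make each dose's
theoretical mean equal the group central dose.  Cancer cases are then
drawn once per meta-simulation from a multinomial whose per-individual
probabilities are proportional to the excess-relative-risk model
``1 + alpha*D + beta*D^2`` averaged over sub-simulations, and the data
are collapsed (summing cases, averaging doses) to the dose groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "ErrorSpec",
    "RiskModel",
    "DoseEnsemble",
    "GroupedDataset",
    "default_grid",
    "simulate_dose_ensemble",
    "true_dose_correlation",
    "lognormal_shared_correlation",
    "simulate_cases",
    "collapse_to_groups",
]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_repr(seed: SeedLike) -> str:
    if isinstance(seed, np.random.Generator):
        return "generator"
    if isinstance(seed, np.random.SeedSequence):
        return f"seedsequence(entropy={seed.entropy}, key={seed.spawn_key})"
    return repr(seed)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DoseGrid:
    """Grouped dose structure: interval bounds, central dose, person-year
    offset and simulated-individual count per group.

    ``group_edges[k]`` is ``(lower, upper)`` in Gy with ``upper=None``
    for an open top group.
    """

    group_edges: tuple
    central_doses: np.ndarray
    person_years: np.ndarray
    n_individuals: np.ndarray

    def __post_init__(self):
        cd = np.asarray(self.central_doses, dtype=float)
        py = np.asarray(self.person_years, dtype=float)
        ni = np.asarray(self.n_individuals, dtype=int)
        object.__setattr__(self, "group_edges", tuple(tuple(e) for e in self.group_edges))
        object.__setattr__(self, "central_doses", cd)
        object.__setattr__(self, "person_years", py)
        object.__setattr__(self, "n_individuals", ni)
        g = len(self.group_edges)
        if not (len(cd) == len(py) == len(ni) == g):
            raise ValueError("grid fields must have one entry per group")
        if g < 2:
            raise ValueError("a dose grid needs at least 2 groups")
        if np.any(cd <= 0):
            raise ValueError("central doses must be positive")
        if np.any(py <= 0):
            raise ValueError("person-year offsets must be positive")
        if np.any(ni < 1):
            raise ValueError("each group needs at least one individual")

    @property
    def n_groups(self) -> int:
        return len(self.central_doses)

    @property
    def total_individuals(self) -> int:
        return int(self.n_individuals.sum())

    def group_of_individual(self) -> np.ndarray:
        """Group index per simulated individual (one assignment each)."""
        return np.repeat(np.arange(self.n_groups), self.n_individuals)


#: Dose-group boundaries (Gy) of the 5-group bone-marrow dose grid.
DEFAULT_GROUP_EDGES = ((0.0, 0.07), (0.08, 0.19), (0.20, 0.99), (1.00, 2.49), (2.50, None))
#: Central dose estimates, close to person-year-weighted group means;
#: the open top group is assigned 2 Gy.
DEFAULT_CENTRAL_DOSES = (0.02, 0.13, 0.45, 1.5, 2.0)
#: Person-year offsets per group, proportional to the published
#: bone-marrow-dose person-year distribution of the LSS cohort.
DEFAULT_PERSON_YEARS = (2.5e6, 3.6e5, 4.5e5, 1.6e5, 5.0e4)
#: Simulated individuals per group: exactly proportional to the
#: person-year offsets (so multinomial case sampling over individuals is
#: consistent with person-year Poisson offsets in the fits) and large
#: enough that unshared error averages out in group means, emulating
#: the person-year-scale populations behind the grouped data.
DEFAULT_N_INDIVIDUALS = (50000, 7200, 9000, 3200, 1000)


def default_grid() -> DoseGrid:
    """The default 5-group dose grid."""
    return DoseGrid(
        group_edges=DEFAULT_GROUP_EDGES,
        central_doses=np.array(DEFAULT_CENTRAL_DOSES),
        person_years=np.array(DEFAULT_PERSON_YEARS),
        n_individuals=np.array(DEFAULT_N_INDIVIDUALS),
    )


@dataclass(frozen=True)
class ErrorSpec:
    """Log-scale standard deviations of the four multiplicative error
    components (shared/unshared x Berkson/classical).

    A log-SD of 0.2 corresponds to a geometric standard deviation of
    exp(0.2), conventionally labelled "20%" error.
    """

    sigma_shared_berkson: float = 0.0
    sigma_unshared_berkson: float = 0.0
    sigma_shared_classical: float = 0.0
    sigma_unshared_classical: float = 0.0

    def __post_init__(self):
        for name in (
            "sigma_shared_berkson",
            "sigma_unshared_berkson",
            "sigma_shared_classical",
            "sigma_unshared_classical",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_percent(
        cls,
        shared_berkson: float = 0.0,
        unshared_berkson: float = 0.0,
        shared_classical: float = 0.0,
        unshared_classical: float = 0.0,
    ) -> "ErrorSpec":
        """Build from GSD-percent labels (20 -> log-SD 0.2)."""
        return cls(
            sigma_shared_berkson=shared_berkson / 100.0,
            sigma_unshared_berkson=unshared_berkson / 100.0,
            sigma_shared_classical=shared_classical / 100.0,
            sigma_unshared_classical=unshared_classical / 100.0,
        )


@dataclass(frozen=True)
class RiskModel:
    """Linear or linear-quadratic excess-relative-risk model.

    Relative risk at dose d is ``1 + alpha*d + beta*d^2``; ``kappa`` is
    the log-scale baseline intercept of the Poisson rate (distinct from
    any noise draw).
    """

    alpha: float
    beta: float = 0.0
    kappa: float = 0.0

    def relative_risk(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return 1.0 + self.alpha * d + self.beta * d * d

    def validate_positive(self, doses) -> None:
        rr = self.relative_risk(doses)
        if np.any(rr <= 0):
            d = np.asarray(doses, dtype=float).ravel()[np.argmin(rr)]
            raise ValueError(
                f"non-positive relative risk ({rr.min():.6g}) at dose {d:.6g} Gy "
                f"for alpha={self.alpha}, beta={self.beta}"
            )


@dataclass(frozen=True)
class DoseEnsemble:
    """True and surrogate dose draws for one meta-simulation.

    Matrices are individuals x sub-simulations; shared draws are
    constant down each column's individuals, unshared draws vary freely.
    """

    true_doses: np.ndarray
    surrogate_doses: np.ndarray
    group_of_individual: np.ndarray
    grid: DoseGrid
    errors: ErrorSpec
    seed_record: str = ""

    def __post_init__(self):
        if self.true_doses.shape != self.surrogate_doses.shape:
            raise ValueError("true and surrogate dose matrices must share dimensions")
        if self.true_doses.shape[0] != len(self.group_of_individual):
            raise ValueError("one group assignment per individual required")
        if np.any(self.true_doses <= 0) or np.any(self.surrogate_doses <= 0):
            raise ValueError("all doses must be positive")

    @property
    def n_individuals(self) -> int:
        return self.true_doses.shape[0]

    @property
    def m(self) -> int:
        """Number of sub-simulations."""
        return self.true_doses.shape[1]

    def to_frame(self, meta_id: int = 0) -> pd.DataFrame:
        """Long-format export: one row per individual per sub-simulation."""
        n, m = self.true_doses.shape
        return pd.DataFrame(
            {
                "meta_id": np.full(n * m, meta_id),
                "sub_id": np.tile(np.arange(m), n),
                "individual_id": np.repeat(np.arange(n), m),
                "group": np.repeat(self.group_of_individual, m),
                "true_dose": self.true_doses.ravel(),
                "surrogate_dose": self.surrogate_doses.ravel(),
            }
        )


@dataclass(frozen=True)
class GroupedDataset:
    """Collapsed per-group data for Poisson linear relative-risk fits."""

    cases: np.ndarray
    offsets: np.ndarray
    calibrated_dose: np.ndarray
    dose_vectors: Optional[np.ndarray] = None  # (m, n_groups) group-mean doses

    def __post_init__(self):
        cases = np.asarray(self.cases)
        object.__setattr__(self, "cases", cases.astype(int))
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "calibrated_dose", np.asarray(self.calibrated_dose, dtype=float))
        if np.any(cases < 0) or np.any(cases != np.round(cases)):
            raise ValueError("cases must be non-negative integers")
        if np.any(self.calibrated_dose <= 0):
            raise ValueError("calibrated doses must be positive")
        if self.dose_vectors is not None:
            dv = np.asarray(self.dose_vectors, dtype=float)
            object.__setattr__(self, "dose_vectors", dv)
            if dv.ndim != 2 or dv.shape[1] != len(self.cases):
                raise ValueError("dose_vectors must be (m, n_groups)")
            if np.any(dv <= 0):
                raise ValueError("dose vectors must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.cases)

    @property
    def total_cases(self) -> int:
        return int(self.cases.sum())


# ---------------------------------------------------------------------------
# operations


def simulate_dose_ensemble(
    grid: DoseGrid,
    errors: ErrorSpec,
    m: int,
    rng_seed: SeedLike = None,
) -> DoseEnsemble:
    """Draw true and surrogate doses for every individual in every
    sub-simulation under the composite lognormal error model.

    Per sub-simulation j there is exactly one shared Berkson draw and
    one shared classical draw applied to all individuals; unshared draws
    are independent per individual per sub-simulation.  The mean-one
    correction factors make each individual's expected dose equal its
    group central dose.
    """
    if m < 1:
        raise ValueError("need at least one sub-simulation (m >= 1)")
    rng = _as_rng(rng_seed)
    group = grid.group_of_individual()
    n = len(group)
    cent = grid.central_doses[group][:, None]  # (n, 1)

    e = errors
    # fixed draw order: shared Berkson, unshared Berkson, shared classical,
    # unshared classical -- part of the reproducibility contract
    eps = rng.standard_normal(m)
    delta = rng.standard_normal((n, m))
    mu = rng.standard_normal(m)
    nu = rng.standard_normal((n, m))

    k_berk = np.exp(-0.5 * (e.sigma_shared_berkson**2 + e.sigma_unshared_berkson**2))
    k_clas = np.exp(-0.5 * (e.sigma_shared_classical**2 + e.sigma_unshared_classical**2))
    true = cent * k_berk * np.exp(e.sigma_shared_berkson * eps[None, :] + e.sigma_unshared_berkson * delta)
    surr = cent * k_clas * np.exp(e.sigma_shared_classical * mu[None, :] + e.sigma_unshared_classical * nu)

    return DoseEnsemble(
        true_doses=true,
        surrogate_doses=surr,
        group_of_individual=group,
        grid=grid,
        errors=errors,
        seed_record=_seed_repr(rng_seed),
    )


def lognormal_shared_correlation(sigma_shared: float, sigma_unshared: float) -> float:
    """Closed-form Pearson correlation between two individuals' doses
    under the lognormal shared/unshared model:
    (exp(s_s^2) - 1) / (exp(s_s^2 + s_u^2) - 1).
    """
    denom = np.expm1(sigma_shared**2 + sigma_unshared**2)
    if denom == 0.0:
        return float("nan")
    return float(np.expm1(sigma_shared**2) / denom)


def true_dose_correlation(
    ensemble: DoseEnsemble,
    n_pairs: int = 100,
    rng_seed: SeedLike = 0,
    pairing: Literal["random", "all"] = "random",
) -> float:
    """Average sample Pearson correlation between distinct individuals'
    true-dose series across sub-simulations.

    ``pairing="random"`` averages over ``n_pairs`` random distinct
    pairs (default protocol); ``"all"`` uses every distinct pair
    (quadratic, for small ensembles only).  Pairs whose series are
    constant (no dose error at all) contribute ``nan``.
    """
    n, m = ensemble.true_doses.shape
    if n < 2:
        raise ValueError("need at least 2 individuals to correlate")
    if m < 3:
        raise ValueError("need at least 3 sub-simulations (m >= 3)")
    if pairing == "all":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif pairing == "random":
        rng = _as_rng(rng_seed)
        pairs = []
        for _ in range(n_pairs):
            i, j = rng.choice(n, size=2, replace=False)
            pairs.append((int(i), int(j)))
    else:
        raise ValueError(f"unknown pairing rule {pairing!r}")

    x = ensemble.true_doses
    rs = []
    for i, j in pairs:
        xi, xj = x[i], x[j]
        si, sj = xi.std(), xj.std()
        if si == 0.0 or sj == 0.0:
            rs.append(np.nan)
            continue
        rs.append(float(np.corrcoef(xi, xj)[0, 1]))
    return float(np.nanmean(rs)) if not np.all(np.isnan(rs)) else float("nan")


def simulate_cases(
    ensemble: DoseEnsemble,
    model: RiskModel,
    n_cases: int = 250,
    rng_seed: SeedLike = None,
) -> np.ndarray:
    """Draw one multinomial sample of ``n_cases`` cases over individuals
    with probabilities proportional to the relative risk averaged over
    the sub-simulations; the case vector is shared by all
    sub-simulations within the meta-simulation.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    rr = model.relative_risk(ensemble.true_doses)
    if np.any(rr <= 0):
        flat = np.argmin(rr)
        bad_dose = ensemble.true_doses.ravel()[flat]
        raise ValueError(
            f"non-positive relative risk ({rr.min():.6g}) at true dose "
            f"{bad_dose:.6g} Gy; the risk model is invalid on this ensemble"
        )
    p = rr.mean(axis=1)
    p = p / p.sum()
    rng = _as_rng(rng_seed)
    return rng.multinomial(n_cases, p)


def case_probabilities(ensemble: DoseEnsemble, model: RiskModel) -> np.ndarray:
    """Exact per-individual case probabilities implied by the ensemble
    (the multinomial parameter used by :func:`simulate_cases`)."""
    rr = model.relative_risk(ensemble.true_doses)
    p = rr.mean(axis=1)
    return p / p.sum()


def collapse_to_groups(
    ensemble: DoseEnsemble,
    cases: np.ndarray,
    dose_choice: Literal["mean-true", "single-surrogate-draw", "per-subsim-vectors"],
    surrogate_index: int = 0,
) -> GroupedDataset:
    """Collapse individual data to the dose groups: cases summed,
    person-year offsets copied from the grid, and one of three dose
    summaries:

    - ``mean-true``: group mean of true doses over individuals and
      sub-simulations (the regression-calibration dose);
    - ``single-surrogate-draw``: group mean of surrogate doses from one
      designated sub-simulation (the unadjusted-regression dose);
    - ``per-subsim-vectors``: all ``m`` per-sub-simulation group-mean
      true-dose vectors (input to MCML / BMA / FMA), with
      ``calibrated_dose`` set to their average.
    """
    cases = np.asarray(cases)
    if len(cases) != ensemble.n_individuals:
        raise ValueError("cases must align with ensemble individuals")
    grid = ensemble.grid
    g = ensemble.group_of_individual
    G = grid.n_groups
    group_cases = np.bincount(g, weights=cases, minlength=G).astype(int)
    counts = np.bincount(g, minlength=G)

    if dose_choice == "mean-true":
        dose = np.bincount(g, weights=ensemble.true_doses.sum(axis=1), minlength=G) / (
            counts * ensemble.m
        )
        return GroupedDataset(group_cases, grid.person_years, dose)
    if dose_choice == "single-surrogate-draw":
        if not (0 <= surrogate_index < ensemble.m):
            raise ValueError("surrogate_index out of range")
        dose = np.bincount(
            g, weights=ensemble.surrogate_doses[:, surrogate_index], minlength=G
        ) / counts
        return GroupedDataset(group_cases, grid.person_years, dose)
    if dose_choice == "per-subsim-vectors":
        sums = np.zeros((ensemble.m, G))
        for k in range(G):
            sums[:, k] = ensemble.true_doses[g == k].sum(axis=0)
        vectors = sums / counts[None, :]
        return GroupedDataset(
            group_cases, grid.person_years, vectors.mean(axis=0), dose_vectors=vectors
        )
    raise ValueError(f"unknown dose_choice {dose_choice!r}")
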