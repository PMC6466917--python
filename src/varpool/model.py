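"""Probability model for regression from pooled (group) test outcomes.

Specimens carry covariates; each specimen j in group i is infected with
probability p_ij = g(X_ij' beta). A group's *true* status is the OR of
its members' statuses, but the assay misclassifies: a truly positive
group tests positive with probability Se (sensitivity) and a truly
negative one tests negative with probability Sp (specificity). With
r = Se + Sp - 1 the marginal probability that group i tests positive is

    P(z_i = 1) = Se - r * prod_j (1 - p_ij),

and the log-likelihood of the group-level outcomes z is the sum of the
corresponding Bernoulli terms. This module houses the data containers,
the likelihood, its analytic gradient, and maximum-likelihood fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .links import LOGIT, LinkFunction

__all__ = [
    "AssaySpec",
    "CovariateMatrix",
    "Coefficients",
    "PoolAssignment",
    "GroupTestData",
    "FitResult",
    "individual_risk",
    "group_positive_probability",
    "log_likelihood",
    "score_vector",
    "fit_mle",
]

# Risks are clipped away from {0, 1} before taking logs; extreme linear
# predictors do occur under heavy-tailed (gamma) covariates.
RISK_EPS = 1e-12


@dataclass(frozen=True)
class AssaySpec:
    """Assay operating characteristics.

    Both sensitivity and specificity must exceed 0.5 so that the Youden
    index r = Se + Sp - 1 is positive; r <= 0 would make the group-level
    outcome uninformative (or anti-informative) about infection.
    """

    sensitivity: float
    specificity: float

    def __post_init__(self):
        se, sp = self.sensitivity, self.specificity
        if not (0.5 < se <= 1.0):
            raise ValueError(f"sensitivity must lie in (0.5, 1], got {se}")
        if not (0.5 < sp <= 1.0):
            raise ValueError(f"specificity must lie in (0.5, 1], got {sp}")
        if se + sp <= 1.0:
            raise ValueError("sensitivity + specificity must exceed 1")

    @property
    def r(self) -> float:
        """Youden index Se + Sp - 1."""
        return self.sensitivity + self.specificity - 1.0


class CovariateMatrix:
    """An N x d design matrix whose first column is the intercept.

    Parameters
    ----------
    values : (N, d) array
        First column must be identically 1; all entries finite.
    specimen_ids : sequence of str, optional
        Defaults to ``s0001``, ``s0002``, ...
    column_names : sequence of str, optional
        Defaults to ``intercept, x1, x2, ...``.
    """

    def __init__(self, values, specimen_ids=None, column_names=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("covariate matrix must be 2-D with N >= 1, d >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("covariate matrix contains non-finite entries")
        if not np.all(values[:, 0] == 1.0):
            raise ValueError("first column must be the intercept (all ones)")
        n, d = values.shape
        if specimen_ids is None:
            width = max(4, len(str(n)))
            specimen_ids = [f"s{i + 1:0{width}d}" for i in range(n)]
        specimen_ids = [str(s) for s in specimen_ids]
        if len(specimen_ids) != n:
            raise ValueError("specimen_ids length does not match row count")
        if len(set(specimen_ids)) != n:
            raise ValueError("specimen_ids must be unique")
        if column_names is None:
            column_names = ["intercept"] + [f"x{j}" for j in range(1, d)]
        column_names = [str(c) for c in column_names]
        if len(column_names) != d:
            raise ValueError("column_names length does not match column count")
        self.values = values
        self.specimen_ids = specimen_ids
        self.column_names = column_names

    @classmethod
    def from_raw(cls, raw, specimen_ids=None, column_names=None):
        """Prepend an intercept column to raw covariates (N x (d-1))."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[0] == 1 and raw.shape[1] > 1 and specimen_ids is not None \
                and len(specimen_ids) == raw.shape[1]:
            raw = raw.T
        ones = np.ones((raw.shape[0], 1))
        names = None
        if column_names is not None:
            names = ["intercept"] + list(column_names)
        return cls(np.hstack([ones, raw]), specimen_ids, names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "id"):
        """Build from a table of numeric covariate columns (no intercept stored)."""
        df = df.copy()
        ids = None
        if id_column in df.columns:
            ids = df[id_column].astype(str).tolist()
            df = df.drop(columns=[id_column])
        if df.shape[1] == 0:
            raise ValueError("no covariate columns found")
        values = df.to_numpy(dtype=float)
        return cls.from_raw(values, specimen_ids=ids, column_names=list(df.columns))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def head(self, n: int) -> "CovariateMatrix":
        """The first ``n`` specimens, in original order."""
        if not 1 <= n <= self.n:
            raise ValueError(f"n must lie in [1, {self.n}]")
        return CovariateMatrix(self.values[:n], self.specimen_ids[:n],
                               self.column_names)

    def __repr__(self):
        return f"CovariateMatrix(n={self.n}, d={self.d})"


@dataclass(frozen=True)
class Coefficients:
    """Regression coefficients (beta_0, ..., beta_{d-1})."""

    beta: np.ndarray

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float).ravel()
        if beta.size < 1 or not np.all(np.isfinite(beta)):
            raise ValueError("coefficients must be a finite, non-empty vector")
        object.__setattr__(self, "beta", beta)

    def __len__(self):
        return self.beta.size


def _as_beta(beta) -> np.ndarray:
    if isinstance(beta, Coefficients):
        return beta.beta
    beta = np.asarray(beta, dtype=float).ravel()
    if not np.all(np.isfinite(beta)):
        raise ValueError("coefficients must be finite")
    return beta


class PoolAssignment:
    """An ordered partition of (a prefix of) risk-sorted specimens into pools.

    ``ordering`` is a permutation of all specimen indices; pools occupy
    contiguous, disjoint slices of its prefix: pool l holds positions
    [n_{l-1}, n_l) of the ordering, where n_l = k_1 + ... + k_l. A strict
    prefix (n_m < N) arises when a design run is truncated to a target
    group count; the unassigned tail is simply not enrolled.
    """

    def __init__(self, ordering, group_sizes, k_max=None):
        ordering = np.asarray(ordering, dtype=np.int64).ravel()
        group_sizes = np.asarray(group_sizes, dtype=np.int64).ravel()
        n = ordering.size
        if n < 1:
            raise ValueError("ordering must be non-empty")
        if not np.array_equal(np.sort(ordering), np.arange(n)):
            raise ValueError("ordering must be a permutation of 0..N-1")
        if group_sizes.size < 1 or np.any(group_sizes < 1):
            raise ValueError("group sizes must be positive")
        if k_max is not None and np.any(group_sizes > k_max):
            raise ValueError(f"group sizes exceed k_max={k_max}")
        if group_sizes.sum() > n:
            raise ValueError("group sizes exceed the number of specimens")
        self.ordering = ordering
        self.group_sizes = group_sizes
        self.k_max = k_max

    @property
    def m(self) -> int:
        """Number of pools."""
        return self.group_sizes.size

    @property
    def n_total(self) -> int:
        return self.ordering.size

    @property
    def n_assigned(self) -> int:
        return int(self.group_sizes.sum())

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative boundaries n_0=0, n_1, ..., n_m."""
        return np.concatenate([[0], np.cumsum(self.group_sizes)])

    @property
    def starts(self) -> np.ndarray:
        """Start offsets of each pool within the ordering."""
        return self.boundaries[:-1]

    @property
    def assigned(self) -> np.ndarray:
        """Specimen indices that belong to some pool, in pool order."""
        return self.ordering[: self.n_assigned]

    def group_members(self, l: int) -> np.ndarray:
        """Specimen indices of pool ``l`` (0-based)."""
        b = self.boundaries
        return self.ordering[b[l] : b[l + 1]]

    def to_frame(self, specimen_ids=None) -> pd.DataFrame:
        """Long-format table: one row per assigned specimen.

        Columns ``specimen_id`` and 1-based dense ``group_id``, ordered
        by group then within-group rank.
        """
        group_id = np.repeat(np.arange(1, self.m + 1), self.group_sizes)
        idx = self.assigned
        if specimen_ids is None:
            sid = idx.astype(str)
        else:
            sid = [specimen_ids[i] for i in idx]
        return pd.DataFrame({"specimen_id": sid, "group_id": group_id})

    def __repr__(self):
        return (
            f"PoolAssignment(m={self.m}, n_assigned={self.n_assigned}, "
            f"sizes {self.group_sizes.min()}..{self.group_sizes.max()})"
        )


@dataclass
class GroupTestData:
    """A pool assignment joined with observed group outcomes and covariates."""

    assignment: PoolAssignment
    outcomes: np.ndarray
    covariates: CovariateMatrix

    def __post_init__(self):
        z = np.asarray(self.outcomes).ravel()
        if z.size != self.assignment.m:
            raise ValueError(
                f"{z.size} outcomes for {self.assignment.m} groups"
            )
        if not np.isin(z, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")
        if self.assignment.n_total != self.covariates.n:
            raise ValueError("assignment and covariates disagree on N")
        self.outcomes = z.astype(np.int8)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the group-testing regression."""

    beta_hat: Coefficients
    information: np.ndarray
    log_likelihood_at_optimum: float
    converged: bool
    iterations: int
    gradient_norm: float = np.nan
    separation: bool = False
    message: str = ""

    def standard_errors(self) -> np.ndarray:
        """Asymptotic standard errors from the inverse information matrix."""
        cov = np.linalg.inv(self.information)
        return np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# Core probability computations
# ---------------------------------------------------------------------------

def individual_risk(X: CovariateMatrix, beta, link: LinkFunction = LOGIT):
    """Per-specimen infection probabilities p_j = g(x_j' beta)."""
    b = _as_beta(beta)
    if b.size != X.d:
        raise ValueError(f"beta has length {b.size}, covariates have d={X.d}")
    return link.evaluate(X.values @ b)


def group_positive_probability(member_risks, assay: AssaySpec) -> float:
    """P(group tests positive) = Se - r * prod_j (1 - p_j).

    The product is the probability that every member is uninfected; a
    truly negative pool still tests positive with rate 1 - Sp.
    """
    p = np.asarray(member_risks, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty pool")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risks must lie in [0, 1]")
    q = np.exp(np.sum(np.log1p(-np.clip(p, 0.0, 1.0 - RISK_EPS))))
    if np.any(p >= 1.0):
        q = 0.0
    return float(assay.sensitivity - assay.r * q)


def _prepare(data: GroupTestData, beta, link):
    """Shared per-group quantities for likelihood/score, vectorised.

    Returns sorted member rows Xs, member risks p, per-group survival
    log Q_i = sum_j log(1-p_ij), group start offsets and sizes.
    """
    b = _as_beta(beta)
    asn = data.assignment
    Xs = data.covariates.values[asn.assigned]
    if b.size != Xs.shape[1]:
        raise ValueError("beta length does not match covariate dimension")
    eta = Xs @ b
    p = np.clip(link.evaluate(eta), RISK_EPS, 1.0 - RISK_EPS)
    logq = np.add.reduceat(np.log1p(-p), asn.starts)
    return b, Xs, eta, p, logq


def log_likelihood(beta, data: GroupTestData, assay: AssaySpec,
                   link: LinkFunction = LOGIT) -> float:
    """Log-likelihood of the observed group outcomes.

    Returns ``-inf`` (never raises) when an observed outcome has
    probability numerically zero under ``beta``.
    """
    _, _, _, _, logq = _prepare(data, beta, link)
    q = np.exp(logq)
    p1 = assay.sensitivity - assay.r * q
    p0 = 1.0 - p1
    z = data.outcomes
    with np.errstate(divide="ignore"):
        terms = np.where(z == 1, np.log(p1), np.log(p0))
    if np.any(np.isneginf(terms)):
        return -np.inf
    return float(terms.sum())


def score_vector(beta, data: GroupTestData, assay: AssaySpec,
                 link: LinkFunction = LOGIT) -> np.ndarray:
    """Analytic gradient of :func:`log_likelihood` in beta.

    d/dbeta P(z_i=1) = r * Q_i * sum_j g'(eta_ij)/(1-p_ij) * x_ij with
    Q_i = prod_j (1-p_ij); the chain rule through the Bernoulli terms
    gives weight (z_i - P_i1)/(P_i1 P_i0) per group.
    """
    b, Xs, eta, p, logq = _prepare(data, beta, link)
    asn = data.assignment
    q = np.exp(logq)
    p1 = assay.sensitivity - assay.r * q
    p0 = 1.0 - p1
    z = data.outcomes
    w_group = (z - p1) / (p1 * p0) * assay.r * q
    # member-level rows g'/(1-p) * x, summed within groups
    u = link.derivative(eta) / (1.0 - p)
    member_rows = Xs * u[:, None]
    group_sums = np.add.reduceat(member_rows, asn.starts, axis=0)
    return group_sums.T @ w_group


def fit_mle(data: GroupTestData, assay: AssaySpec, link: LinkFunction = LOGIT,
            init=None, gtol: float = 1e-6, maxiter: int = 200) -> FitResult:
    """Maximise the group-testing log-likelihood by quasi-Newton ascent.

    BFGS with the analytic score; on failure, a Nelder-Mead restart
    polishes the incumbent. The reported information matrix is the full
    Fisher information evaluated at the optimum.

    Parameters
    ----------
    init : array-like or Coefficients, optional
        Starting value beta^(0); defaults to the zero vector.
    """
    d = data.covariates.d
    if data.assignment.m < d:
        raise ValueError(f"need at least d={d} groups, got {data.assignment.m}")
    x0 = np.zeros(d) if init is None else _as_beta(init).copy()
    if x0.size != d:
        raise ValueError("init length does not match covariate dimension")

    z = data.outcomes
    separation = bool(z.min() == z.max())
    if separation:
        warnings.warn(
            "all group outcomes are identical; the MLE may diverge",
            RuntimeWarning,
            stacklevel=2,
        )

    def nll(b):
        ll = log_likelihood(b, data, assay, link)
        return np.inf if ll == -np.inf else -ll

    def grad(b):
        return -score_vector(b, data, assay, link)

    res = optimize.minimize(
        nll, x0, jac=grad, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    iterations = int(res.nit)
    best = res.x
    if not res.success:
        # smooth likelihood, but BFGS can stall on flat ridges; restart
        res2 = optimize.minimize(
            nll, best, method="Nelder-Mead",
            options={"maxiter": 400 * d, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            best = res2.x
        iterations += int(res2.nit)

    g = score_vector(best, data, assay, link)
    gnorm = float(np.max(np.abs(g)))
    converged = bool(np.isfinite(gnorm) and gnorm < max(gtol * 100, 1e-4)
                     and np.all(np.isfinite(best)) and not separation)

    from .design import fisher_information  # deferred: design imports model

    try:
        info = fisher_information(best, data.assignment, data.covariates,
                                  assay, link)
    except ValueError:
        info = np.full((d, d), np.nan)

    return FitResult(
        beta_hat=Coefficients(best),
        information=info,
        log_likelihood_at_optimum=float(-nll(best)),
        converged=converged,
        iterations=iterations,
        gradient_norm=gnorm,
        separation=separation,
        message=str(res.message),
    )
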