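"""Pool-size design: Fisher information, the size-cap rule, and PSV.

The design problem: given covariates, an initial coefficient vector
beta^(0) and assay operating characteristics, choose pool sizes that
lose as little Fisher information about beta as possible. Writing
Q_i = prod_j (1 - p_ij) for the probability pool i is truly negative,
the information contributed by pool i factorises as G_i G_i' / C_i with

    H_i = -(1/k_i) * sum_j log(1 - p_ij)        (so Q_i = exp(-k_i H_i))
    G_i = dH_i/dbeta
    C_i = P_i1 * P_i0 / (r^2 k_i^2 Q_i^2),

so minimising the scalar cost C_i pool-by-pool is the tractable proxy
for maximising information. PSV (pooling strategy with varying sizes)
walks the risk-sorted specimen list and sizes each pool greedily: the
pool takes the maximal admissible size k_max outright whenever
k_max <= phi0 / W_l, where W_l is the leading specimen's negative log
survival -log(1 - p) and phi0 ~ 1.8414; otherwise it takes the k in
{1..k_max} minimising C_l. Low-risk stretches therefore get large pools
without any cost evaluation, high-risk stretches get small ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .links import LOGIT, LinkFunction
from .model import (
    RISK_EPS,
    AssaySpec,
    Coefficients,
    CovariateMatrix,
    PoolAssignment,
    _as_beta,
)

__all__ = [
    "DesignConfig",
    "RiskOrdering",
    "PoolStatistics",
    "SizeDecision",
    "SingleSizeChoice",
    "pool_H",
    "pool_G",
    "pool_C",
    "pool_statistics",
    "fisher_information",
    "reduced_fisher_information",
    "solve_phi0",
    "size_cap",
    "sort_by_risk",
    "psv_assign",
    "fixed_size_assign",
    "optimal_single_size",
]

#: Size-cap threshold constant used by the published algorithm.
PHI0_DEFAULT = 1.8414


@dataclass(frozen=True)
class DesignConfig:
    """Tunables of a pool-size design run.

    Admissible sizes are {1, ..., k_max}; ``phi0`` is the cap-rule
    threshold (default 1.8414); ``beta_init`` is beta^(0), the working
    coefficient vector from training data or prior knowledge.
    """

    k_max: int
    beta_init: Coefficients
    phi0: float = PHI0_DEFAULT
    tie_break: str = "smallest-k"

    def __post_init__(self):
        if int(self.k_max) < 1:
            raise ValueError("k_max must be >= 1")
        object.__setattr__(self, "k_max", int(self.k_max))
        if not self.phi0 > 0:
            raise ValueError("phi0 must be positive")
        if self.tie_break != "smallest-k":
            raise ValueError("only the 'smallest-k' tie-break is supported")
        if not isinstance(self.beta_init, Coefficients):
            object.__setattr__(self, "beta_init", Coefficients(self.beta_init))


@dataclass(frozen=True)
class RiskOrdering:
    """Specimen indices sorted by working risk, non-increasing."""

    permutation: np.ndarray
    risks: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.risks) > 0):
            raise ValueError("risks must be non-increasing")


@dataclass(frozen=True)
class PoolStatistics:
    """Per-pool design quantities H, G, C plus the reduced-form pieces."""

    H: float
    G: np.ndarray
    C: float
    pool_mean_covariate: np.ndarray
    Z: np.ndarray


@dataclass(frozen=True)
class SizeDecision:
    """Record of one PSV sizing step."""

    W: float
    c0: float
    capped: bool
    chosen_k: int
    cost_curve: np.ndarray | None = None


@dataclass(frozen=True)
class SingleSizeChoice:
    """Variance-optimal single pool size at a given average prevalence."""

    k_star: int
    p_bar: float
    objective_curve: np.ndarray


# ---------------------------------------------------------------------------
# Pool-level quantities (Fisher-information components)
# ---------------------------------------------------------------------------

def _member_risks(beta, members, link):
    b = _as_beta(beta)
    rows = np.atleast_2d(np.asarray(members, dtype=float))
    if rows.shape[0] < 1:
        raise ValueError("empty pool")
    if rows.shape[1] != b.size:
        raise ValueError("member rows and beta disagree on dimension")
    eta = rows @ b
    p = link.evaluate(eta)
    if np.any(p >= 1.0 - RISK_EPS):
        raise ValueError("a member risk is numerically 1; H is infinite")
    return b, rows, eta, p


def pool_H(beta, members, link: LinkFunction = LOGIT) -> float:
    """Mean negative log-survival of a pool: -(1/k) sum_j log(1 - p_j)."""
    _, _, _, p = _member_risks(beta, members, link)
    return float(-np.mean(np.log1p(-p)))


def pool_G(beta, members, link: LinkFunction = LOGIT) -> np.ndarray:
    """Gradient of :func:`pool_H` in beta: (1/k) sum_j g'/(1-p_j) x_j."""
    _, rows, eta, p = _member_risks(beta, members, link)
    u = link.derivative(eta) / (1.0 - p)
    return rows.T @ u / rows.shape[0]


def pool_C(beta, members, assay: AssaySpec, link: LinkFunction = LOGIT) -> float:
    """Scalar information cost of a pool.

    C = P1 * P0 / (r^2 k^2 Q^2) with Q = prod(1-p_j), P1 = Se - r Q.
    Smaller C means the pool's test outcome carries more information.
    """
    _, rows, _, p = _member_risks(beta, members, link)
    k = rows.shape[0]
    return _cost_from_logq(float(np.sum(np.log1p(-p))), k, assay)


def _cost_from_logq(logq: float, k, assay: AssaySpec):
    """C evaluated from log Q = -k H; vectorised over k/logq."""
    q = np.exp(logq)
    p1 = assay.sensitivity - assay.r * q
    return p1 * (1.0 - p1) / (assay.r**2 * k**2 * q**2)


def pool_statistics(beta, members, assay: AssaySpec,
                    link: LinkFunction = LOGIT) -> PoolStatistics:
    """All per-pool design quantities, including the reduced-form Z term."""
    b, rows, eta, p = _member_risks(beta, members, link)
    xbar = rows.mean(axis=0)
    pbar = float(link.evaluate(xbar @ b))
    Z = link.derivative(np.array(xbar @ b)) * xbar / (1.0 - pbar)
    return PoolStatistics(
        H=pool_H(b, rows, link),
        G=pool_G(b, rows, link),
        C=pool_C(b, rows, assay, link),
        pool_mean_covariate=xbar,
        Z=np.asarray(Z, dtype=float),
    )


def _assignment_arrays(assignment: PoolAssignment, X: CovariateMatrix, beta,
                       link):
    b = _as_beta(beta)
    Xs = X.values[assignment.assigned]
    eta = Xs @ b
    p = link.evaluate(eta)
    if np.any(p >= 1.0 - RISK_EPS):
        raise ValueError("a member risk is numerically 1")
    return b, Xs, eta, p


def fisher_information(beta, assignment: PoolAssignment, X: CovariateMatrix,
                       assay: AssaySpec, link: LinkFunction = LOGIT) -> np.ndarray:
    """Fisher information of beta under the assignment: sum G_i G_i' / C_i."""
    if assay.r <= 0:
        raise ValueError("assay must have positive Youden index")
    _, Xs, eta, p = _assignment_arrays(assignment, X, beta, link)
    starts = assignment.starts
    k = assignment.group_sizes.astype(float)
    logq = np.add.reduceat(np.log1p(-p), starts)
    C = _cost_from_logq(logq, k, assay)
    u = link.derivative(eta) / (1.0 - p)
    G = np.add.reduceat(Xs * u[:, None], starts, axis=0) / k[:, None]
    A = G / np.sqrt(C)[:, None]
    info = A.T @ A
    return (info + info.T) / 2.0


def reduced_fisher_information(beta, assignment: PoolAssignment,
                               X: CovariateMatrix, assay: AssaySpec,
                               link: LinkFunction = LOGIT) -> np.ndarray:
    """Homogeneous-pool approximation of :func:`fisher_information`.

    Replaces each pool's member-wise survival product by the pool-mean
    form (1 - g(xbar' beta))^k: Z_i = g'(xbar' beta) xbar / (1 - g),
    and C_i is evaluated with H = -log(1 - g(xbar' beta)). Accurate when
    pools are homogeneous in risk, which risk-sorting encourages.
    """
    if assay.r <= 0:
        raise ValueError("assay must have positive Youden index")
    b, Xs, _, _ = _assignment_arrays(assignment, X, beta, link)
    starts = assignment.starts
    k = assignment.group_sizes.astype(float)
    xbar = np.add.reduceat(Xs, starts, axis=0) / k[:, None]
    eta_bar = xbar @ b
    pbar = link.evaluate(eta_bar)
    if np.any(pbar >= 1.0 - RISK_EPS):
        raise ValueError("a pool-mean risk is numerically 1")
    Z = xbar * (link.derivative(eta_bar) / (1.0 - pbar))[:, None]
    logq = k * np.log1p(-pbar)
    C = _cost_from_logq(logq, k, assay)
    A = Z / np.sqrt(C)[:, None]
    info = A.T @ A
    return (info + info.T) / 2.0


# ---------------------------------------------------------------------------
# The size-cap rule and its threshold constant
# ---------------------------------------------------------------------------

def solve_phi0(assay: AssaySpec) -> float:
    """Root of the cap-threshold equation for the given assay.

    f(phi) = 2 Se (1-Se)(phi-1) e^{2 phi} + r (2 Se - 1)(phi-2) e^phi + 2 r^2.
    Provided as an audit tool: the default design path uses the published
    constant 1.8414 (see :data:`PHI0_DEFAULT`); numerically the equation's
    root drifts with Se and does not reproduce that constant.

    Falls back to the published constant (with a warning) if no sign
    change is found on (0, 10).
    """
    se, r = assay.sensitivity, assay.r

    def f(phi):
        return (2.0 * se * (1.0 - se) * (phi - 1.0) * np.exp(2.0 * phi)
                + r * (2.0 * se - 1.0) * (phi - 2.0) * np.exp(phi)
                + 2.0 * r**2)

    grid = np.linspace(1e-9, 10.0, 2001)
    vals = f(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        warnings.warn(
            "no bracketing interval for the phi0 equation on (0, 10); "
            f"falling back to the published constant {PHI0_DEFAULT}",
            RuntimeWarning,
            stacklevel=2,
        )
        return PHI0_DEFAULT
    i = sign_change[0]
    return float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-12))


def size_cap(leading_row, beta_init, k_max: int,
             link: LinkFunction = LOGIT,
             phi0: float = PHI0_DEFAULT) -> SizeDecision:
    """Evaluate the cap rule for the pool led by ``leading_row``.

    W = -log(1 - g(x' beta)); c0 = phi0 / W. The pool takes k_max
    outright when k_max <= c0. Risk 0 gives W = 0, c0 = +inf: capped by
    convention. Risk numerically 1 is an error.

    ``chosen_k`` is k_max when capped and -1 (undecided: the cost curve
    must be consulted) otherwise.
    """
    b = _as_beta(beta_init)
    x = np.asarray(leading_row, dtype=float).ravel()
    p = float(link.evaluate(x @ b))
    if p >= 1.0 - RISK_EPS:
        raise ValueError("leading risk is numerically 1")
    W = float(-np.log1p(-p))
    c0 = np.inf if W == 0.0 else phi0 / W
    capped = bool(k_max <= c0)
    return SizeDecision(W=W, c0=float(c0), capped=capped,
                        chosen_k=(int(k_max) if capped else -1),
                        cost_curve=None)


def sort_by_risk(X: CovariateMatrix, beta_init,
                 link: LinkFunction = LOGIT) -> RiskOrdering:
    """Stable risk-descending ordering under beta^(0); ties keep input order."""
    b = _as_beta(beta_init)
    risks = link.evaluate(X.values @ b)
    perm = np.argsort(-risks, kind="stable")
    return RiskOrdering(permutation=perm, risks=risks[perm])


# ---------------------------------------------------------------------------
# Assignment algorithms
# ---------------------------------------------------------------------------

def psv_assign(X: CovariateMatrix, config: DesignConfig, assay: AssaySpec,
               link: LinkFunction = LOGIT, max_groups: int | None = None,
               return_decisions: bool = False):
    """Sequential pool-size selection over the risk-sorted cohort.

    At each step the next pool starts at the highest-risk unassigned
    specimen. If k_max <= phi0 / W (W from that leading specimen) the
    pool takes min(k_max, remaining) without evaluating costs; otherwise
    it takes the argmin of C over {1, ..., min(k_max, remaining)}, ties
    to the smaller size. Stops after ``max_groups`` pools if given
    (leaving a tail unassigned), else when every specimen is assigned.
    """
    if X.n < 1:
        raise ValueError("empty cohort")
    if assay.r <= 0:
        raise ValueError("assay must have positive Youden index")
    ordering = sort_by_risk(X, config.beta_init, link)
    p = np.clip(ordering.risks, 0.0, 1.0 - RISK_EPS)
    s = np.log1p(-p)  # log survival per sorted specimen, <= 0
    S = np.concatenate([[0.0], np.cumsum(s)])
    n = X.n
    k_max, phi0 = config.k_max, config.phi0
    se, r = assay.sensitivity, assay.r

    sizes: list[int] = []
    decisions: list[SizeDecision] = []
    t = 0
    while t < n and (max_groups is None or len(sizes) < max_groups):
        remaining = n - t
        k_adm = min(k_max, remaining)
        W = -s[t]
        c0 = np.inf if W == 0.0 else phi0 / W
        capped = k_max <= c0
        if capped:
            k = k_adm
            curve = None
        else:
            ks = np.arange(1, k_adm + 1)
            logq = S[t + ks] - S[t]
            q = np.exp(logq)
            p1 = se - r * q
            curve = p1 * (1.0 - p1) / (r * r * ks.astype(float) ** 2 * q * q)
            k = int(ks[np.argmin(curve)])  # argmin takes the first == smallest k
        sizes.append(k)
        if return_decisions:
            decisions.append(SizeDecision(W=float(W), c0=float(c0),
                                          capped=bool(capped), chosen_k=k,
                                          cost_curve=curve))
        t += k

    assignment = PoolAssignment(ordering.permutation, np.array(sizes),
                                k_max=k_max)
    if return_decisions:
        return assignment, decisions
    return assignment


def fixed_size_assign(X: CovariateMatrix, k: int, beta_init=None,
                      link: LinkFunction = LOGIT, sort: bool = True,
                      max_groups: int | None = None) -> PoolAssignment:
    """Chunk the (optionally risk-sorted) cohort into pools of size k.

    The last pool may be smaller. With ``max_groups`` the sequence is
    truncated and the tail left unassigned.
    """
    if int(k) < 1:
        raise ValueError("k must be >= 1")
    k = int(k)
    if sort:
        if beta_init is None:
            raise ValueError("risk sorting requires beta_init")
        ordering = sort_by_risk(X, beta_init, link).permutation
    else:
        ordering = np.arange(X.n)
    m_full, rem = divmod(X.n, k)
    sizes = [k] * m_full + ([rem] if rem else [])
    if max_groups is not None:
        if len(sizes) < max_groups:
            raise ValueError(
                f"cohort of {X.n} cannot fill {max_groups} pools of size {k}"
            )
        sizes = sizes[:max_groups]
    return PoolAssignment(ordering, np.array(sizes), k_max=k)


def optimal_single_size(p_bar: float, assay: AssaySpec,
                        k_max: int) -> SingleSizeChoice:
    """Variance-optimal single pool size at average prevalence p_bar.

    For a fixed number of pools (a fixed testing budget), the asymptotic
    variance of the pooled prevalence estimator at size k is proportional
    to pi_k (1 - pi_k) / (r^2 k^2 (1-p_bar)^{2k-2}) with
    pi_k = Se - r (1-p_bar)^k. Returns the k in {1..k_max} minimising it;
    ties go to the smaller k.
    """
    if not 0.0 < p_bar < 1.0:
        raise ValueError("p_bar must lie in (0, 1)")
    if assay.r <= 0:
        raise ValueError("assay must have positive Youden index")
    ks = np.arange(1, int(k_max) + 1)
    logq = ks * np.log1p(-p_bar)
    curve = _cost_from_logq(logq, ks.astype(float), assay) * (1.0 - p_bar) ** 2
    k_star = int(ks[np.argmin(curve)])
    return SingleSizeChoice(k_star=k_star, p_bar=float(p_bar),
                            objective_curve=curve)
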