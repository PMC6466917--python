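"""Monte-Carlo evaluation of pooled-testing designs.

Generates synthetic cohorts from simple covariate models, draws true
infection statuses from the logistic risk model, misclassifies pooled
outcomes through the assay, fits the group-testing MLE, and summarises
bias and mean squared error over replications.

The default scenario mirrors a rare-disease screening setting: a single
covariate ~ Normal(2, 1.5) (or Gamma(2.5, 0.8), shape-scale, mean 2.0)
with beta = (-3, 0.4), giving an average individual prevalence near 0.1;
four-covariate variants add a Bernoulli(0.3) and a Normal(1, 0.5) column
with beta = (-3, 0.4, 1, -0.5).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DesignConfig,
    fixed_size_assign,
    optimal_single_size,
    psv_assign,
)
from .links import LOGIT, LinkFunction
from .model import (
    AssaySpec,
    Coefficients,
    CovariateMatrix,
    GroupTestData,
    fit_mle,
    individual_risk,
)

__all__ = [
    "ColumnSpec",
    "normal",
    "gamma",
    "bernoulli",
    "CovariateModel",
    "SINGLE_NORMAL",
    "SINGLE_GAMMA",
    "MODEL_I",
    "MODEL_II",
    "ScenarioConfig",
    "ReplicationResult",
    "MethodSummary",
    "StudyReport",
    "gen_covariates",
    "gen_true_status",
    "gen_group_outcome",
    "run_replication",
    "run_study",
    "metrics_overall_R",
]


@dataclass(frozen=True)
class ColumnSpec:
    """One covariate column: normal(mean, sd), gamma(shape, scale) or
    bernoulli(q)."""

    kind: str
    params: tuple

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, n)
        if self.kind == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, n)
        if self.kind == "bernoulli":
            (q,) = self.params
            return (rng.random(n) < q).astype(float)
        raise ValueError(f"unknown column kind {self.kind!r}")


def normal(mean: float, sd: float) -> ColumnSpec:
    if not sd > 0:
        raise ValueError("sd must be positive")
    return ColumnSpec("normal", (float(mean), float(sd)))


def gamma(shape: float, scale: float) -> ColumnSpec:
    """Gamma in the shape-scale convention (mean = shape * scale)."""
    if not (shape > 0 and scale > 0):
        raise ValueError("shape and scale must be positive")
    return ColumnSpec("gamma", (float(shape), float(scale)))


def bernoulli(q: float) -> ColumnSpec:
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return ColumnSpec("bernoulli", (float(q),))


@dataclass(frozen=True)
class CovariateModel:
    """Independent covariate columns (intercept added at sampling time)."""

    columns: tuple

    def __post_init__(self):
        cols = tuple(self.columns)
        if not cols or not all(isinstance(c, ColumnSpec) for c in cols):
            raise ValueError("columns must be a non-empty list of ColumnSpec")
        object.__setattr__(self, "columns", cols)

    @property
    def d(self) -> int:
        """Model dimension including the intercept."""
        return len(self.columns) + 1

    def sample(self, n: int, rng: np.random.Generator) -> CovariateMatrix:
        if n < 1:
            raise ValueError("n must be >= 1")
        raw = np.column_stack([c.sample(n, rng) for c in self.columns])
        return CovariateMatrix.from_raw(
            raw, column_names=[f"x{j+1}" for j in range(len(self.columns))]
        )


#: Single normal covariate, the benchmark scenario.
SINGLE_NORMAL = CovariateModel((normal(2.0, 1.5),))
#: Single gamma covariate (same mean, right-skewed).
SINGLE_GAMMA = CovariateModel((gamma(2.5, 0.8),))
#: Gamma + Bernoulli(0.3) + Normal(1, 0.5).
MODEL_I = CovariateModel((gamma(2.5, 0.8), bernoulli(0.3), normal(1.0, 0.5)))
#: Normal(2, 1.5) + Bernoulli(0.3) + Normal(1, 0.5).
MODEL_II = CovariateModel((normal(2.0, 1.5), bernoulli(0.3), normal(1.0, 0.5)))

#: True coefficients of the benchmark scenarios.
BETA_SINGLE = (-3.0, 0.4)
BETA_FOUR = (-3.0, 0.4, 1.0, -0.5)


def gen_covariates(model: CovariateModel, n: int,
                   rng: np.random.Generator) -> CovariateMatrix:
    """Draw an n-specimen cohort from the covariate model."""
    return model.sample(n, rng)


def gen_true_status(risks, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p_j) infection indicators."""
    p = np.asarray(risks, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risks must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(np.int8)


def gen_group_outcome(member_statuses, assay: AssaySpec,
                      rng: np.random.Generator) -> int:
    """Observed pooled result: OR of members, then misclassified."""
    s = np.asarray(member_statuses).ravel()
    if s.size == 0:
        raise ValueError("empty group")
    truth = bool(s.any())
    u = rng.random()
    if truth:
        return int(u < assay.sensitivity)
    return int(u < 1.0 - assay.specificity)


_METHOD_RE = re.compile(r"^(PSS|PSF)\((\d+|k\*|kstar)\)$", re.IGNORECASE)


def parse_method(name: str):
    """Parse a method label: 'PSV', 'PSS(k)'/'PSF(k)', or 'PSS(k*)'.

    Returns ("psv", None), ("fixed", k) or ("kstar", None).
    """
    label = name.strip()
    if label.upper() == "PSV":
        return ("psv", None)
    match = _METHOD_RE.match(label)
    if match:
        arg = match.group(2).lower()
        if arg in ("k*", "kstar"):
            return ("kstar", None)
        return ("fixed", int(arg))
    raise ValueError(
        f"unknown method {name!r}; valid: 'PSV', 'PSS(<k>)', 'PSS(k*)'"
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: model, assay, design and replication plan."""

    beta_true: Coefficients
    covariate_model: CovariateModel
    assay: AssaySpec
    m: int                      # pools per replication
    M: int                      # replications
    methods: tuple = ("PSV",)
    design: DesignConfig | None = None
    seed: int = 0
    link: LinkFunction = LOGIT

    def __post_init__(self):
        if not isinstance(self.beta_true, Coefficients):
            object.__setattr__(self, "beta_true", Coefficients(self.beta_true))
        d = self.covariate_model.d
        if len(self.beta_true) != d:
            raise ValueError("beta_true length does not match covariate model")
        if self.m < d + 1:
            raise ValueError("m must exceed the number of coefficients")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        for name in self.methods:
            parse_method(name)
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.design is None:
            # beta^(0) defaults to the truth: isolates design behaviour
            # from initial-estimate error; override for robustness runs.
            object.__setattr__(
                self, "design",
                DesignConfig(k_max=25, beta_init=self.beta_true),
            )


@dataclass(frozen=True)
class ReplicationResult:
    """One replication's fit: the MLE and bookkeeping."""

    beta_hat: np.ndarray
    converged: bool
    excluded: bool
    n_specimens: int
    mean_group_size: float
    k_star: int | None = None


@dataclass(frozen=True)
class MethodSummary:
    """Monte-Carlo summaries of one method over completed replications."""

    method: str
    mc_mean: np.ndarray
    mc_mse: np.ndarray
    relative_bias: np.ndarray
    overall_R: float
    n_completed: int
    n_excluded: int


@dataclass(frozen=True)
class StudyReport:
    """Per-method Monte-Carlo results of a scenario."""

    beta_true: np.ndarray
    summaries: dict

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per method x coefficient."""
        rows = []
        for name, s in self.summaries.items():
            for j in range(self.beta_true.size):
                rows.append({
                    "method": name,
                    "coefficient": f"beta{j}",
                    "true_value": self.beta_true[j],
                    "mc_mean": s.mc_mean[j],
                    "mc_mse": s.mc_mse[j],
                    "relative_bias": s.relative_bias[j],
                    "overall_R": s.overall_R,
                    "n_completed": s.n_completed,
                    "n_excluded": s.n_excluded,
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "beta_true": self.beta_true.tolist(),
            "methods": {
                name: {
                    "mc_mean": s.mc_mean.tolist(),
                    "mc_mse": s.mc_mse.tolist(),
                    "relative_bias": s.relative_bias.tolist(),
                    "overall_R": s.overall_R,
                    "n_completed": s.n_completed,
                    "n_excluded": s.n_excluded,
                }
                for name, s in self.summaries.items()
            },
        }


def metrics_overall_R(mc_mean, beta_true) -> float:
    """Overall relative bias R = (1/d) sum_l |mean(beta_l) - beta_l| / |beta_l|.

    Stated for d = 4 coefficients; generalised to any d as the mean of
    per-coefficient absolute relative biases.
    """
    mean = np.asarray(mc_mean, dtype=float)
    true = np.asarray(beta_true, dtype=float)
    if mean.shape != true.shape:
        raise ValueError("shape mismatch")
    if np.any(true == 0):
        raise ValueError("overall R is undefined for a zero true coefficient")
    return float(np.mean(np.abs(mean - true) / np.abs(true)))


def _assign_for_method(scenario: ScenarioConfig, method: str,
                       X: CovariateMatrix):
    """Enrol a representative cohort from the reservoir and pool it.

    The reservoir ``X`` holds m * k_max i.i.d. specimens in generation
    order. Each method enrols a *prefix in generation order* (an
    unbiased sample) sized to yield m pools, then risk-sorts the
    enrolled cohort and pools it:

    - PSS(k): enrols the first m*k specimens, chunks into m pools.
    - PSS(k*): computes k* from the reservoir's mean working risk,
      then proceeds as PSS(k*).
    - PSV: the needed cohort size depends on the sizes the algorithm
      itself chooses, so it is calibrated by a full assignment of the
      sorted reservoir (yielding m_full pools): enrol
      n0 * m / m_full specimens, assign them all, truncate to at most
      m pools.

    Returns the enrolled covariates, the assignment and (for PSS(k*))
    the chosen k*.
    """
    kind, k = parse_method(method)
    design = scenario.design
    m = scenario.m
    k_star = None
    if kind == "psv":
        full = psv_assign(X, design, scenario.assay, scenario.link)
        n_enrol = min(X.n, max(design.k_max,
                               round(X.n * m / full.m)))
        Xe = X.head(n_enrol)
        asn = psv_assign(Xe, design, scenario.assay, scenario.link,
                         max_groups=m)
    else:
        if kind == "kstar":
            working = individual_risk(X, design.beta_init, scenario.link)
            k = optimal_single_size(float(working.mean()), scenario.assay,
                                    design.k_max).k_star
            k_star = k
        Xe = X.head(m * k)
        asn = fixed_size_assign(Xe, k, beta_init=design.beta_init,
                                link=scenario.link, sort=True, max_groups=m)
    return Xe, asn, k_star


def run_replication(scenario: ScenarioConfig, method: str,
                    rng: np.random.Generator) -> ReplicationResult:
    """One simulated screening round under one pooling method.

    Draws a reservoir of m * k_max specimens, enrols a representative
    cohort sized to yield m pools (see :func:`_assign_for_method`),
    risk-sorts it at beta^(0), draws statuses and misclassified pooled
    outcomes, and fits the MLE initialised at beta^(0). A fit that fails
    to converge (including outcome-separation degeneracies) is flagged
    ``excluded``.
    """
    design = scenario.design
    n = scenario.m * design.k_max
    Xr = gen_covariates(scenario.covariate_model, n, rng)
    X, asn, k_star = _assign_for_method(scenario, method, Xr)

    risks = individual_risk(X, scenario.beta_true, scenario.link)
    statuses = gen_true_status(risks, rng)
    member_status = statuses[asn.assigned]
    truth = np.add.reduceat(member_status, asn.starts) > 0
    u = rng.random(asn.m)
    z = np.where(truth, u < scenario.assay.sensitivity,
                 u < 1.0 - scenario.assay.specificity).astype(np.int8)

    data = GroupTestData(asn, z, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_mle(data, scenario.assay, scenario.link,
                      init=design.beta_init)
    beta_hat = fit.beta_hat.beta
    excluded = (not fit.converged
                or not np.all(np.isfinite(beta_hat))
                or float(np.max(np.abs(beta_hat))) > 1e3)
    return ReplicationResult(
        beta_hat=beta_hat,
        converged=fit.converged,
        excluded=bool(excluded),
        n_specimens=asn.n_assigned,
        mean_group_size=float(asn.group_sizes.mean()),
        k_star=k_star,
    )


def run_study(scenario: ScenarioConfig) -> StudyReport:
    """Run M replications of every method and summarise.

    Seeds: a SeedSequence on ``scenario.seed`` spawns one child per
    method (in the listed order), which spawns one grandchild per
    replication — identical configs give byte-identical reports, and
    each (method, replication) pair has an independent stream.
    """
    beta_true = scenario.beta_true.beta
    root = np.random.SeedSequence(scenario.seed)
    method_seeds = root.spawn(len(scenario.methods))
    summaries = {}
    for method, mss in zip(scenario.methods, method_seeds):
        betas = []
        n_excluded = 0
        for rep_ss in mss.spawn(scenario.M):
            rep = run_replication(scenario, method,
                                  np.random.default_rng(rep_ss))
            if rep.excluded:
                n_excluded += 1
            else:
                betas.append(rep.beta_hat)
        if not betas:
            raise RuntimeError(
                f"all {scenario.M} replications diverged for {method}"
            )
        B = np.vstack(betas)
        mc_mean = B.mean(axis=0)
        mc_mse = ((B - beta_true) ** 2).mean(axis=0)
        summaries[method] = MethodSummary(
            method=method,
            mc_mean=mc_mean,
            mc_mse=mc_mse,
            relative_bias=(mc_mean - beta_true) / beta_true,
            overall_R=metrics_overall_R(mc_mean, beta_true),
            n_completed=B.shape[0],
            n_excluded=n_excluded,
        )
    return StudyReport(beta_true=beta_true.copy(), summaries=summaries)
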