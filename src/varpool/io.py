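"""File interchange, configuration, run manifests and toy fixtures.

Formats (all comma-separated UTF-8 with a header row, "." decimal):

- covariate CSV: optional ``id`` column; every other column is a numeric
  covariate. The intercept is added by the reader, never stored.
- assignment CSV: ``specimen_id, group_id`` with 1-based dense group
  ids, ordered by group then within-group rank.
- outcomes CSV: ``group_id, z`` with z in {0, 1}.
- estimates JSON: coefficients, standard errors, information matrix and
  convergence diagnostics.
- design report JSON: per-pool ``{group_id, size, W, c0, capped,
  chosen_by}``.

Every run function writes a ``manifest.json`` (command, resolved
config, seed, paths, package version, timestamp) alongside its outputs
and never mutates its inputs.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    DesignConfig,
    fixed_size_assign,
    psv_assign,
)
from .links import LOGIT, get_link
from .model import (
    AssaySpec,
    Coefficients,
    CovariateMatrix,
    GroupTestData,
    PoolAssignment,
    fit_mle,
    individual_risk,
)
from .simulate import (
    MODEL_I,
    CovariateModel,
    ScenarioConfig,
    bernoulli,
    gamma,
    normal,
    run_study,
)

__all__ = [
    "read_covariates",
    "write_covariates",
    "read_assignment",
    "write_assignment",
    "read_outcomes",
    "write_outcomes",
    "load_config",
    "design_run",
    "fit_run",
    "simulate_run",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_covariates(path, id_column: str = "id") -> CovariateMatrix:
    """Read a covariate CSV; adds the intercept column."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no specimen rows")
    try:
        return CovariateMatrix.from_dataframe(df, id_column=id_column)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_covariates(X: CovariateMatrix, path) -> None:
    """Write covariates without the stored intercept column."""
    df = pd.DataFrame(X.values[:, 1:], columns=X.column_names[1:])
    df.insert(0, "id", X.specimen_ids)
    df.to_csv(path, index=False)


def write_assignment(assignment: PoolAssignment, specimen_ids, path) -> None:
    assignment.to_frame(specimen_ids).to_csv(path, index=False)


def read_assignment(path, X: CovariateMatrix) -> PoolAssignment:
    """Read an assignment CSV back against a known cohort.

    Validates that group ids are dense and 1-based, every specimen id
    exists in the cohort, and no specimen is assigned twice. Specimens
    of the cohort that are absent from the file form the unassigned
    tail of the ordering.
    """
    df = pd.read_csv(path)
    for col in ("specimen_id", "group_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    index = {sid: i for i, sid in enumerate(X.specimen_ids)}
    seen = set()
    rows = []
    for sid in df["specimen_id"].astype(str):
        if sid not in index:
            raise ValueError(f"{path}: unknown specimen_id {sid!r}")
        if sid in seen:
            raise ValueError(f"{path}: specimen_id {sid!r} assigned twice")
        seen.add(sid)
        rows.append(index[sid])
    gids = df["group_id"].to_numpy()
    uniq = np.unique(gids)
    if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
        raise ValueError(f"{path}: group ids must be dense and 1-based")
    if np.any(np.diff(gids) < 0):
        raise ValueError(f"{path}: rows must be ordered by group")
    sizes = np.bincount(gids)[1:]
    ordering = np.array(rows, dtype=np.int64)
    tail = np.setdiff1d(np.arange(X.n), ordering, assume_unique=False)
    return PoolAssignment(np.concatenate([ordering, tail]), sizes)


def write_outcomes(z, path) -> None:
    z = np.asarray(z).ravel().astype(int)
    pd.DataFrame({"group_id": np.arange(1, z.size + 1), "z": z}).to_csv(
        path, index=False
    )


def read_outcomes(path, m: int | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("group_id", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    gids = df["group_id"].to_numpy()
    if np.unique(gids).size != gids.size:
        dup = int(pd.Series(gids)[pd.Series(gids).duplicated()].iloc[0])
        raise ValueError(f"{path}: duplicated group_id {dup}")
    if not np.array_equal(np.sort(gids), np.arange(1, gids.size + 1)):
        raise ValueError(f"{path}: group ids must be dense and 1-based")
    if m is not None and gids.size != m:
        raise ValueError(f"{path}: {gids.size} outcomes for {m} groups")
    z = df.sort_values("group_id")["z"].to_numpy()
    if not np.isin(z, (0, 1)).all():
        raise ValueError(f"{path}: outcomes must be 0/1")
    return z.astype(np.int8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_COLUMN_BUILDERS = {"normal": normal, "gamma": gamma, "bernoulli": bernoulli}


def _covariate_model_from_config(spec) -> CovariateModel:
    cols = []
    for entry in spec:
        kind = entry["kind"]
        if kind not in _COLUMN_BUILDERS:
            raise ValueError(
                f"unknown distribution {kind!r}; valid: "
                f"{sorted(_COLUMN_BUILDERS)}"
            )
        params = {k: v for k, v in entry.items() if k != "kind"}
        cols.append(_COLUMN_BUILDERS[kind](**params))
    return CovariateModel(tuple(cols))


def load_config(path) -> dict:
    """Load a flat YAML config: k_max, phi0, se, sp, beta_init, link, seed,
    and (for simulations) m, reps, methods, beta_true, covariate_model."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _design_from_config(cfg: dict) -> tuple[DesignConfig, AssaySpec, object]:
    assay = AssaySpec(float(cfg["se"]), float(cfg["sp"]))
    kwargs = {"k_max": int(cfg["k_max"]),
              "beta_init": Coefficients(np.asarray(cfg["beta_init"], float))}
    if "phi0" in cfg:
        kwargs["phi0"] = float(cfg["phi0"])
    link = get_link(cfg.get("link", "logit"))
    return DesignConfig(**kwargs), assay, link


def _write_manifest(out_dir: Path, command: str, config: dict, seed,
                    inputs: dict, outputs: dict) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# Run functions (the library's command surface)
# ---------------------------------------------------------------------------

def design_run(covariates_csv, config, out_dir) -> dict:
    """Pool a cohort with PSV and write the assignment and design report.

    ``config`` is a dict or a YAML path with k_max, se, sp, beta_init
    and optional phi0/link. Returns the output paths.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    design, assay, link = _design_from_config(cfg)
    X = read_covariates(covariates_csv)
    assignment, decisions = psv_assign(X, design, assay, link,
                                       return_decisions=True)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    asn_path = out_dir / "assignment.csv"
    write_assignment(assignment, X.specimen_ids, asn_path)
    report = [
        {
            "group_id": l + 1,
            "size": int(assignment.group_sizes[l]),
            "W": dec.W,
            "c0": dec.c0,
            "capped": dec.capped,
            "chosen_by": "size-cap" if dec.capped else "cost-argmin",
        }
        for l, dec in enumerate(decisions)
    ]
    report_path = out_dir / "design_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    outputs = {"assignment": asn_path, "design_report": report_path}
    _write_manifest(out_dir, "design", cfg, cfg.get("seed"),
                    {"covariates": covariates_csv}, outputs)
    return {k: str(v) for k, v in outputs.items()}


def fit_run(covariates_csv, assignment_csv, outcomes_csv, config,
            out_dir) -> dict:
    """Fit the group-testing MLE from files; writes estimates JSON."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    _, assay, link = _design_from_config(cfg)
    X = read_covariates(covariates_csv)
    assignment = read_assignment(assignment_csv, X)
    z = read_outcomes(outcomes_csv, m=assignment.m)
    data = GroupTestData(assignment, z, X)
    fit = fit_mle(data, assay, link,
                  init=np.asarray(cfg["beta_init"], float))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est = {
        "beta_hat": fit.beta_hat.beta.tolist(),
        "standard_errors": fit.standard_errors().tolist(),
        "information": fit.information.tolist(),
        "log_likelihood": fit.log_likelihood_at_optimum,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "gradient_norm": fit.gradient_norm,
        "separation": fit.separation,
    }
    est_path = out_dir / "estimates.json"
    est_path.write_text(json.dumps(est, indent=2))
    _write_manifest(out_dir, "fit", cfg, cfg.get("seed"),
                    {"covariates": covariates_csv,
                     "assignment": assignment_csv,
                     "outcomes": outcomes_csv},
                    {"estimates": est_path})
    return {"estimates": str(est_path)}


def simulate_run(config, out_dir, reps: int | None = None) -> dict:
    """Run a Monte-Carlo study from a scenario config; writes CSV + JSON.

    ``reps`` overrides the configured replication count for scaled-down
    runs.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    design, assay, link = _design_from_config(cfg)
    model = _covariate_model_from_config(cfg["covariate_model"])
    scenario = ScenarioConfig(
        beta_true=Coefficients(np.asarray(cfg["beta_true"], float)),
        covariate_model=model,
        assay=assay,
        m=int(cfg["m"]),
        M=int(reps if reps is not None else cfg["reps"]),
        methods=tuple(cfg.get("methods", ("PSV",))),
        design=design,
        seed=int(cfg.get("seed", 0)),
        link=link,
    )
    report = run_study(scenario)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "report.csv"
    json_path = out_dir / "report.json"
    report.to_frame().to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(report.to_dict(), indent=2))
    outputs = {"report_csv": csv_path, "report_json": json_path}
    _write_manifest(out_dir, "simulate", cfg, scenario.seed, {}, outputs)
    return {k: str(v) for k, v in outputs.items()}


# ---------------------------------------------------------------------------
# Deterministic toy fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir, seed: int = 20190401) -> dict:
    """Write the deterministic toy datasets used across the test suite.

    - ``design6``: six specimens with working risks (0.30, 0.25, 0.20,
      0.10, 0.05, 0.02) encoded as a single covariate x = logit(p) so
      that beta = (0, 1) reproduces them exactly.
    - ``likelihood3``: a 6-specimen, 3-pool cohort with outcomes, for
      likelihood cross-checks.
    - ``recovery``: a 4000-specimen synthetic cohort drawn from the
      benchmark model for end-to-end recovery runs.

    Repeated invocation with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = {}

    # -- design6: printed working risks
    risks = np.array([0.30, 0.25, 0.20, 0.10, 0.05, 0.02])
    X6 = CovariateMatrix.from_raw(LOGIT.inverse(risks)[:, None],
                                  column_names=["x1"])
    p6 = out_dir / "design6_covariates.csv"
    write_covariates(X6, p6)
    written["design6_covariates"] = p6

    # -- likelihood3: fixed covariates, three pools of two
    x1 = np.array([0.5, 1.8, 2.2, 3.1, 0.2, 4.0])
    X3 = CovariateMatrix.from_raw(x1[:, None], column_names=["x1"])
    p3 = out_dir / "likelihood3_covariates.csv"
    write_covariates(X3, p3)
    asn3 = fixed_size_assign(X3, 2, beta_init=[-1.0, 0.5], sort=True)
    pa = out_dir / "likelihood3_assignment.csv"
    write_assignment(asn3, X3.specimen_ids, pa)
    po = out_dir / "likelihood3_outcomes.csv"
    write_outcomes(np.array([1, 0, 0]), po)
    written.update({"likelihood3_covariates": p3,
                    "likelihood3_assignment": pa,
                    "likelihood3_outcomes": po})

    # -- recovery: a larger synthetic cohort from the benchmark model
    Xr = MODEL_I.sample(4000, rng)
    pr = out_dir / "recovery_covariates.csv"
    write_covariates(Xr, pr)
    written["recovery_covariates"] = pr

    _write_manifest(out_dir, "fixtures", {"seed": seed}, seed, {},
                    dict(written))
    return {k: str(v) for k, v in written.items()}
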