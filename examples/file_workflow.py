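"""File-based workflow: covariates CSV -> pool design -> fit.

Mirrors how the package is used around a lab information system:
covariates arrive as a CSV, the design run writes an assignment table
and a per-pool report, outcomes come back as a CSV, and the fit run
writes the estimates as JSON. Every run leaves a manifest.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

import varpool as vp
from varpool.io import design_run, fit_run, write_covariates, write_outcomes

work = Path(tempfile.mkdtemp(prefix="varpool_"))
rng = np.random.default_rng(3)
beta_true = [-3.0, 0.4, 1.0, -0.5]

X = vp.MODEL_I.sample(1500, rng)
cov_csv = work / "covariates.csv"
write_covariates(X, cov_csv)

cfg = {"k_max": 12, "se": 0.95, "sp": 0.95, "beta_init": beta_true}
design = design_run(cov_csv, cfg, work / "design")
report = json.load(open(design["design_report"]))
sizes = [g["size"] for g in report]
print(f"designed {len(report)} pools "
      f"(sizes {min(sizes)}..{max(sizes)}) -> {design['assignment']}")

# the lab returns one 0/1 result per pool; here we simulate them
from varpool.io import read_assignment, read_covariates
asn = read_assignment(design["assignment"], read_covariates(cov_csv))
statuses = vp.gen_true_status(vp.individual_risk(X, beta_true), rng)
truth = np.add.reduceat(statuses[asn.assigned], asn.starts) > 0
u = rng.random(asn.m)
z = np.where(truth, u < 0.95, u < 0.05).astype(int)
z_csv = work / "outcomes.csv"
write_outcomes(z, z_csv)

fit = fit_run(cov_csv, design["assignment"], z_csv, cfg, work / "fit")
est = json.load(open(fit["estimates"]))
print("estimates (truth in parentheses):")
for j, (b, s) in enumerate(zip(est["beta_hat"], est["standard_errors"])):
    print(f"  beta{j}: {b:+.3f} +/- {s:.3f}  ({beta_true[j]:+.1f})")
print(f"outputs and manifests under {work}")
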