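"""Compare pooling strategies by Monte-Carlo simulation (scaled down).

Replays the benchmark design comparison — PSV against fixed pool sizes
5, 10 and the prevalence-optimal k* — on the single Normal(2, 1.5)
covariate model with beta = (-3, 0.4) and a 99%-accurate assay, at a
reduced replication count so it finishes in seconds.
"""

import varpool as vp

scenario = vp.ScenarioConfig(
    beta_true=vp.BETA_SINGLE,
    covariate_model=vp.SINGLE_NORMAL,
    assay=vp.AssaySpec(0.99, 0.99),
    m=300,          # pools per replication (benchmark uses 1000)
    M=40,           # replications (benchmark uses 5000)
    methods=("PSV", "PSS(5)", "PSS(10)", "PSS(k*)"),
    seed=1,
)
report = vp.run_study(scenario)

frame = report.to_frame()
cols = ["method", "coefficient", "mc_mean", "mc_mse", "relative_bias"]
print(frame[cols].to_string(index=False,
                            float_format=lambda v: f"{v:.4f}"))
print("Every strategy is nearly unbiased; the MSE column ranks designs:")
print("pools of 5 waste tests, while PSV, PSS(10) and PSS(k*) are close")
print("to each other at this prevalence.")
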