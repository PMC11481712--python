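"""Latin-hypercube uncertainty propagation of the 18 respiratory-tract
parameters through the dose-coefficient chain.

Propagates a small design (n = 200 for speed; the full analysis uses 10 000),
summarises the CEDC distribution, ranks candidate distributions by K-S
distance and reports the uncertainty factor around the deterministic value.
"""

import respdose as rd

config = rd.ScenarioConfig(n_samples=200, seed=1, explain_limit=0)
params = rd.reference_parameter_table()
design = rd.lhs_design(params, config.n_samples, seed=config.seed)
sample = rd.propagate(
    design, config.aerosol(), config.worker_scenario(), config.s_pair(),
    params=params, tau_d=config.tau_d,
)

summary = rd.summarize(sample)
print("CEDC sample (synthetic S-table scale):")
for key in ("mean", "sd", "p2.5", "p50", "p97.5"):
    print(f"  {key:6s} {summary[key]:.3e}")

fits = rd.best_fit_distribution(sample)
print(f"best-fit family: {fits[0].family} "
      f"(D = {fits[0].d_statistic:.3f}, p = {fits[0].p_value:.2f})")

_, det = rd.run_deterministic(config)
uf = rd.uncertainty_factor(det.effective, summary["p2.5"], summary["p97.5"])
print(f"UF = max(C/Q_L, Q_U/C) = {uf.rounded:.2f}")
print("A UF near 1 means the 95% interval of the propagated distribution "
      "sits tightly around the deterministic dose coefficient.")
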