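"""Validate the pipeline end to end on simulated data with known truth.

Simulates a full binary-mixture experiment (agents A, B and mixture M,
each assayed at 5 doses x 3 replicates x 30 insects) with a true CTC of
200 (strong synergism), then re-estimates the CTC from the raw counts and
attaches a bootstrap CI.
"""

from mixtox import SimConfig, ctc_bootstrap, recovery_summary, simulate_mixture_experiment

cfg = SimConfig(true_ctc=200.0, seed=7)
rec_a, rec_b, rec_m, truth = simulate_mixture_experiment(cfg)
print(f"latent truth: LC50_A={truth['lc50_a']}, LC50_B={truth['lc50_b']}, "
      f"LC50_M={truth['lc50_m']:.3f} {truth['unit']}, CTC={truth['ctc']}")

res = ctc_bootstrap(rec_a, rec_b, rec_m, cfg.ratio, level=0.95, n_boot=1000, seed=7)
print(f"estimated CTC = {res.ctc:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}] -> {res.label}")

print("\nbias/RMSE over 100 repeated experiments:")
print(recovery_summary(100, cfg).to_string(index=False))
print("\nThe CI should cover the true CTC of 200 in ~95% of experiments;")
print("RMSE shows the precision attainable at the 3x30-insect design.")
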