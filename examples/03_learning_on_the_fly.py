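"""Learning on the fly: replace most oracle calls by gated predictions.

Streams four MD-like runs through the adaptive controller. Each conformer is
either predicted (if its GP predictive variance is below the kappa-quantile of
the training variances) or sent to the oracle and added to the training set.
The kappa knob trades accuracy against the fraction of oracle calls avoided.
"""

import gpconf as g

toy = g.ToyMoleculeSpec()
params = g.default_energy_params(toy)
runs = g.generate_study(toy, params, g.StudyConfig(seed=0))
oracle = g.oracle_for(toy, params)

pool = runs[0]  # the initial 50 training conformers come from the first run
stream = g.concat_ensembles(runs)
cfg = g.AdaptiveConfig(initial_size=50, kappa=0.95, seed=0)
res = g.run_on_the_fly(stream, oracle, cfg, initial_pool=pool)
print(f"stream of {len(res.decisions)} conformers, initial training set of "
      f"{res.initial_size}:")
print(f"  predicted {res.n_predicted}, recomputed "
      f"{res.final_train_size - res.initial_size} "
      f"-> {100 * res.savings:.0f}% of oracle calls avoided")
print(f"  accuracy on the predicted subset: MAE {res.predicted_mae:.2f} kJ/mol, "
      f"RMSE {res.predicted_rmse:.2f} kJ/mol, R^2 {res.predicted_r2:.3f}")
print(f"  (the oracle noise floor is {params.noise_sd} kJ/mol)")

print("\nkappa trade-off (same stream, same initialization):")
df = g.kappa_tradeoff(runs, oracle, [0.5, 0.8, 0.95, 0.99], cfg)
print(df[["kappa", "m_predicted", "mae", "r2", "savings"]].to_string(index=False))
print("higher kappa -> more conformers predicted, slightly larger errors.")
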