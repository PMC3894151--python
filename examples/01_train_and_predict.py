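"""Train a GP surrogate on one conformer run and predict another.

Builds a small synthetic two-run study (one flexible chain molecule, energies
from the analytic oracle), fits the linear-kernel GP on run 1 with a
CV-selected noise level, and predicts run 2 with per-conformer error bars.
"""

import numpy as np

import gpconf as g

toy = g.ToyMoleculeSpec()
params = g.default_energy_params(toy)
run1, run2 = g.generate_study(toy, params, g.StudyConfig(n_runs=2, frames_per_run=60, seed=0))

X1 = g.featurize_ensemble(run1)
y1 = run1.energies()
lam, table = g.select_noise(X1, y1, seed=0)
model = g.fit(X1, y1, lam)
print(f"trained on {len(y1)} conformers ({X1.shape[1]}-dimensional descriptor)")
print(f"noise level lambda = {lam:g} chosen by stratified 10-fold CV MAE")

X2 = g.featurize_ensemble(run2)
pred = g.predict_mean(model, X2)
var = g.predict_variance(model, X2)
err = np.abs(pred - run2.energies())
print(f"\npredicting run 2 ({len(run2)} conformers sampled from a different basin):")
print(f"  MAE  = {err.mean():.2f} kJ/mol   (oracle noise is {params.noise_sd} kJ/mol)")
print(f"  predictive variance spans {var.min():.3g} .. {var.max():.3g}")

# the variance flags exactly the extrapolation problem: out-of-run conformers
# carry much larger variance than the training conformers themselves
thresh = g.variance_threshold(model, kappa=0.95)
inside = var < thresh
print(f"  {inside.sum()}/{len(var)} run-2 conformers fall inside the domain of")
print(f"  applicability (variance below the 0.95 training quantile {thresh:.3g});")
if inside.any() and (~inside).any():
    print(f"  their MAE is {err[inside].mean():.2f} vs {err[~inside].mean():.2f} kJ/mol outside.")
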