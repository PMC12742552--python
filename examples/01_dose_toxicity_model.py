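"""Fit the two-parameter logistic dose-toxicity model to a small trial.

Builds a five-dose escalation dataset, fits the Bayesian logistic regression
model (BLRM) under the weakly informative prior, and prints the posterior
toxicity estimate per dose together with the recommended dose: the one whose
posterior mean DLT probability is closest to the target theta = 0.30.
"""

from doseborrow import (
    TargetConfig,
    TrialOutcome,
    build_weak_prior,
    default_dose_grid,
    fit_blrm,
    recommend_dose,
)
from doseborrow.blrm import posterior_tox_probs

grid = default_dose_grid(reference_dose=50.0)  # doses 12.5 .. 200 mg
data = TrialOutcome(n_per_dose=[8, 8, 8, 8, 8], dlt_per_dose=[0, 1, 2, 4, 5])

posterior = fit_blrm(data, grid, build_weak_prior(), seed=1)
probs = posterior_tox_probs(posterior, grid)

print("dose (mg)   n   DLT   posterior P(DLT)")
for dose, n, y, p in zip(grid.doses, data.n_per_dose, data.dlt_per_dose, probs):
    print(f"{dose:8.1f}  {n:2d}  {y:3d}   {p:.3f}")

target = TargetConfig(theta=0.30)
level = recommend_dose(posterior, grid, target)
print(f"\nrecommended dose level: {level} ({grid.dose_value(level):.1f} mg)")
print(f"max split-R-hat: {posterior.diagnostics.max_rhat():.4f}")
# The recommended level is the dose whose estimated DLT probability is
# closest to the 30% target; the diagnostics line confirms the MCMC mixed.
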