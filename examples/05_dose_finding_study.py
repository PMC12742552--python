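"""A reduced two-stage simulation study comparing borrowing strategies.

Simulates the full workflow on identical source/target curves: per
replicate a fresh 40-patient source trial feeds each strategy's prior, a
12-patient target CRM trial runs, and the selected dose is scored against
the true MTD.  With identical curves, stronger borrowing should win.
"""

import numpy as np

from doseborrow import (
    BorrowingStrategy,
    DoseToxCurve,
    ScenarioSpec,
    run_dose_finding_study,
    run_similarity_study,
)
from doseborrow.simulate import MCMCSettings

curve = DoseToxCurve(-0.84, 0.0)
spec = ScenarioSpec(source_curve=curve, target_curve=curve,
                    similarity_scenario="both_equal")

# informed weights come from a bank of similarity estimates fitted to
# matching synthetic histories (20 compounds, 100 patients per trial)
bank_fit = run_similarity_study(
    "both_equal", "exnex", 6, seed=1, n_compounds=20, n_per_trial=100,
    mcmc=MCMCSettings(draws=600, similarity_warmup=800),
)
bank = np.column_stack([bank_fit.zeta_alpha_hats, bank_fit.zeta_beta_hats])

strategies = [
    BorrowingStrategy("weak"),
    BorrowingStrategy("mixture_fixed"),
    BorrowingStrategy("mixture_informed", zeta_bank=bank),
    BorrowingStrategy("full"),
]
results = run_dose_finding_study(spec, strategies, n_sims=40, seed=2)
print("strategy            accuracy   (MC s.e.)")
for label, r in results.items():
    print(f"{label:18s}   {r.accuracy:.3f}    ({r.mcse:.3f})")
# Accuracy is the fraction of replicates selecting the true MTD.  Informed
# mixture weights (similarity ~ 1 here) approach full borrowing, while the
# weakly informative prior pays for ignoring the source precision.
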