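# doseborrow

**Similarity-informed Bayesian borrowing for model-based dose-finding trials.**

Dose-finding (phase I) trials in small populations — children, or a new
ethnic group — often cannot recruit enough patients to estimate a
dose-toxicity curve on their own. A common remedy is to *borrow* the
posterior of a completed trial in a source population (e.g., adults) as the
prior of the new trial. The open question is **how much** to borrow:
too little wastes the source information, too much steers the trial toward
the wrong dose whenever the two populations differ.

`doseborrow` implements a two-stage answer aimed at trial statisticians:

1. **Estimate similarity from other compounds.** For historical compounds
   with the same mechanism of action that were tested in *both* populations,
   estimate how similar the population-specific dose-toxicity curves tend to
   be. Two Bayesian models are provided, each yielding similarity parameters
   ζα, ζβ ∈ [0, 1] (one per curve parameter):
   * an **ExNex** model — per compound, the (source, target) parameter pair
     is exchangeable (one shared compound mean) with probability ζ, or
     non-exchangeable (two separate means), with ζ ~ Beta(0.5, 0.5);
   * a **hierarchical** model — two variance levels (within-compound spread
     τ between populations, between-compound spread σ), with similarity the
     intraclass correlation ζ = σ²/(τ² + σ²).
2. **Translate similarity into the degree of borrowing** for the new trial's
   prior: robust-mixture weights δ = ζ̂, or variance-inflation factors
   ω = 0.01^(1−ζ̂) which divide the source posterior variances.

The dose-finding machinery around this is the standard continual
reassessment method with a two-parameter Bayesian logistic regression model
(BLRM),

    logit p(D | α, β) = log α + β · log(D / D_R),      α, β > 0,

with a bivariate normal prior on (log α, log β), posterior sampling by MCMC,
and the next cohort assigned to the dose whose posterior mean DLT
probability is closest to the target θ (default 0.30). A full simulator
measures each borrowing strategy's *accuracy* — the proportion of simulated
trials that select the true MTD.

## Worked example

```bash
python examples/03_translate_weights.py
```

```
zeta_hat   delta   omega    prior variance (from 0.3)
  0.1      0.10   0.016    18.93
  0.5      0.50   0.100     3.00
  0.9      0.90   0.631     0.48
```

Reading the middle row: if the historical compounds leave the similarity
undecided (ζ̂ = 0.5), the mixture prior gives the source component weight
0.5, and the inflation route divides a typical source posterior variance of
0.3 by ω = 0.10, i.e., the new trial's prior variance becomes 3.0 — wide
enough that twelve patients can overrule a misleading source posterior.

The full workflow on synthetic data:

```bash
python examples/02_estimate_similarity.py   # fit ExNex + hierarchical models
python examples/04_simulate_trial.py        # source trial -> prior -> CRM trial
python examples/05_dose_finding_study.py    # compare strategies by accuracy
```

Example 2 prints, for 20 compounds whose populations share the intercept but
differ in slope:

```
ExNex         zeta_alpha = 0.950 (95% CrI 0.772-1.000)   zeta_beta = 0.049 (95% CrI 0.000-0.290)
hierarchical  zeta_alpha = 0.951 (95% CrI 0.733-1.000)   zeta_beta = 0.026 (95% CrI 0.000-0.145)
```

— borrow the intercept, not the slope.

A thin CLI wraps the same functions (`doseborrow generate-data`,
`estimate-similarity`, `build-prior`, `simulate-trial`, `run-study`); every
command is deterministic given `--seed`.

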