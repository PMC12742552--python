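# Methods

This note records the models implemented in `doseborrow`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## Dose-toxicity model and trial algorithm

The number of dose-limiting toxicities (DLTs) at dose level k follows
Y_k ~ Bin(n_k, p_k) with the two-parameter logistic model
logit p(D) = log α + β log(D/D_R). Working on (log α, log β) keeps β > 0,
hence curves strictly increasing in dose; no further truncation is applied.
The intercept log α is the log-odds of a DLT at the reference dose D_R.

The weakly informative prior uses sd(log α) = 2, sd(log β) = 1.5, zero
covariance. Default prior means are (−0.84, 0): invlogit(−0.84) ≈ 0.30, so
the prior centers the reference-dose DLT rate on the default target
θ = 0.30 with unit slope. In the simulation study the weak prior is
centered at the moment-matched source posterior means — location is
borrowed, precision is not.

Trial conduct (continual reassessment): start at the lowest dose, treat
cohorts of 2, refit after every cohort, assign the next cohort to
argmin_k |p̂_k − θ| where p̂_k is the posterior mean DLT probability.
Choices the trial literature leaves open, fixed here as defaults:

* θ = 0.30 (configurable; nothing in the model depends on this choice).
* Ties in |p̂_k − θ| break toward the lower dose (safety-conservative).
* `no_skip` escalation is on by default: the recommendation is capped at one
  level above the highest dose tried so far.
* Final MTD selection uses the last posterior over the full grid;
  restriction to tried doses is available as an option.
* Trials start at dose level 1 and run to n = 12 with no early stopping.
* The posterior summary for dose selection is the mean of p_k over draws
  (not the median).

## Prior constructions for the target trial

* **Full borrowing**: the source posterior, moment-matched to a bivariate
  normal (means, variances, covariance of the MCMC draws), used unchanged.
* **Robust mixture**: per parameter independently,
  δ·N(source marginal) + (1−δ)·N(weak marginal). The independent
  formulation deliberately drops the prior covariance; in exchange the two
  parameters get separate degrees of borrowing. The mixture density enters
  the MCMC directly as a log-sum-exp of the two component densities — no
  latent component indicator — so any sampler targets the same posterior.
* **Variance inflation**: source variances divided by ω ∈ (0, 1], covariance
  rescaled so the source correlation is preserved exactly.

Degenerate settings are algebraically tied together (and tested): δ = (1,1)
matches full borrowing marginally, ω = (1,1) matches it exactly, δ = (0,0)
is the weak prior.

## Similarity models

Both models consume per-compound source/target dose-toxicity tables; all
modeling is on the log(D/D_R) scale so compounds with different grids and
reference doses are commensurable. Neither model shares curve *location*
across compounds — only the typical degree of source/target agreement.

**ExNex.** Per compound j and per parameter family, the pair
(x_S, x_T) is exchangeable with probability ζ (both drawn around one
compound-specific mean, sd σ) or non-exchangeable (two separate means).
Weights: ζα, ζβ ~ Beta(0.5, 0.5). Component sds: σα, σβ ~ Gamma(1, rate
1/10) — mean 10, deliberately vague. Compound-level means (shared and
separate alike) get the same weak hyperpriors as the hierarchical global
means, N(−0.84, 2²) for intercepts and N(0, 1.5²) for slopes; these
hyperpriors are configurable because the literature does not pin them down.
The compound means are integrated out analytically (normal-normal), leaving
per pair a two-component bivariate-normal mixture: the exchangeable
component is correlated (shared mean), the non-exchangeable one is not.

**Hierarchical.** Population-and-compound-specific parameters scatter
around compound means with covariance built from (τα, τβ, ρτ) — the
within-compound, i.e., between-population, level — and compound means
scatter around global means with covariance from (σα, σβ, ρσ). Global
means: μα ~ N(−0.84, 2²), μβ ~ N(0, 1.5²); all sds Gamma(1, rate 1/10);
correlations uniform on (−1, 1). Compound means are again marginalized
analytically. Similarity is computed per draw as the intraclass correlation

    ζ = σ² / (τ² + σ²),

the between-compound share of total variance: it tends to **1** when the
two populations of each compound have identical curves (τ → 0) and to 0
when within-compound differences dominate. Note the orientation: part of
the literature writes the ratio with τ² in the numerator while
simultaneously describing estimates that approach 1 for identical
population curves; only the σ²-numerator form has that behavior, so that is
what is implemented (the two forms sum to 1, so no information differs).

Point estimates are posterior means of ζ per draw, with equal-tailed 95%
credible intervals.

**Translation.** Mixture weights are the similarity estimates themselves,
δ = ζ̂. Inflation factors use ω = base^(1−ζ̂) with base = 0.01 (so
ζ̂ = 0.1, 0.5, 0.9 → ω ≈ 0.016, 0.10, 0.63): the identity map inflates too
little — at ζ̂ = 0.5 ("no tendency") it would leave a typical 0.3 source
variance at 0.6, still quite informative. The right base depends on how
much source information is in play, so it is exposed as a parameter.

## Posterior computation

No general-purpose probabilistic-programming backend is part of the
dependency set; the samplers are purpose-built for these posteriors and are
validated against independent oracles in the test suite (dense 2-d grid
quadrature, and the `emcee` ensemble sampler).

* **BLRM (2 parameters):** adaptive random-walk Metropolis, vectorized
  across chains, proposal covariance re-estimated during warmup from the
  pooled chain history (chains are initialized from the prior, so mixture
  priors with separated components start in both modes and the pooled
  covariance spans them). After warmup the kernel alternates random-walk
  steps with independence-Metropolis steps from a heavy-tailed
  multivariate-t fitted to the warmup history, giving near-iid draws.
  Defaults: 4 chains × 1000 post-warmup draws (the enforced minimum),
  500 warmup.
* **Similarity models:** blocked Metropolis-within-Gibbs over the
  marginalized state (per-compound population-level parameters plus global
  hyperparameters). Per-compound blocks are conditionally independent given
  the hyperparameters and are updated in one vectorized proposal; each
  compound's update is split into a *shift* move (source and target
  together) and a *split* move (apart), with separately adapted scales,
  because near-exchangeable posteriors constrain the difference far more
  tightly than the location. A dedicated *scaling* move multiplies a spread
  hyperparameter and all the differences it governs by a common factor
  (with the J·log c Jacobian); without it the sampler crawls along the
  ridge that couples small spreads to small differences. Defaults: 4 chains
  × 1000 draws, 1000 warmup.

Every fit attaches split-R̂ and autocorrelation-based effective sample
sizes; any split-R̂ > 1.01 is recorded as an explicit warning on the fit
(never silent). Because similarity posteriors concentrate near the ζ
boundaries in decisive scenarios, flags there are common at reduced chain
lengths while the posterior means themselves are stable across seeds to
about ±0.01; the study drivers report the flag rate alongside the
estimates.

Numerical guards: slope exponentials are clipped at e^±40 in likelihoods;
covariance constructions add 1e-9 jitter before Cholesky; correlation
parameters are sampled through tanh with the uniform-prior Jacobian;
spread parameters through log with the Gamma Jacobian. Non-finite proposal
log-densities are treated as rejections.

## Synthetic data generator

`generate_compounds` emulates the study conditions used throughout: all
trials test the same 5 doses — geometric grid (0.25, 0.5, 1, 2, 4)·D_R with
D_R the middle dose, chosen so log(D/D_R) is symmetric — with equal patient
allocation (remainder to the lowest doses). Each compound's source curve
takes one of four combinations of log α ∈ {−2.5, −0.84} and
log β ∈ {0, 1.5}, assigned uniformly at random; the target curve equals the
source curve or flips the designated parameter(s) to the other element of
its two-point set, per the similarity scenario (both equal / α equal,
β different / α different, β equal / both different). DLT counts are
binomial draws from the true curves. A hook accepts user-supplied parameter
samplers in place of the two-point sets.

What the generator does *not* emulate: patient-level covariates,
over-dispersion relative to the binomial, inter-trial differences in design
or assessment, non-monotone toxicity. Passing tests therefore demonstrate
internal consistency of the method under its own assumptions, not
performance on real trial data. `generate_case_study_like` adds realistic
irregularities — 4–9 dose levels, unequal grids, doses present in only one
population, source sample sizes in [21, 67] and target in [14, 27] — to
exercise readers and models; it is a synthetic stand-in, not real data.

## Simulation study and problem sizes

The two-stage study design: per replicate, a 40-patient source trial
(equal allocation) is simulated and moment-matched; each borrowing strategy
builds its prior from that same source posterior (so source estimation
noise propagates identically into every arm); a 12-patient target CRM trial
runs; accuracy is scored against the true MTD. Strategies: weak, full,
mixture/inflation with fixed weight 0.5, and informed mixture/inflation
whose weights are drawn per replicate from a pre-computed bank of
similarity estimates fitted to matching synthetic histories —
distributionally equivalent to refitting the similarity model inside every
replicate at a fraction of the cost.

The package's own study sizes, chosen so the full suite runs on one CPU in
well under half an hour: similarity-recovery medians use 25 replicates per
condition (the medians compare to bands 0.3–0.6 wide, for which the
replicate-median sampling error at 25 replicates is below 0.05);
dose-finding orderings use 60 replicates per arm (the orderings tested have
true accuracy gaps of 0.2–0.5, an order of magnitude above the binomial
MC error of ±0.06); similarity fits inside studies use 4 chains × 600
draws after 800 warmup sweeps. Larger runs are a matter of changing
`n_sims` and `MCMCSettings`.

## Known limitations

* With 3 compounds of 30 patients the estimates stay loosely around the
  prior mean 0.5, but more decisively than one might hope: under
  *equal*-parameter scenarios replicate medians drift to ≈ 0.66 (and up to
  ≈ 0.77 for the hierarchical slope similarity), and under
  different-parameter scenarios the hierarchical slope similarity median
  reaches ≈ 0.32 — three identical (or clearly different) pairs are already
  mild evidence under these hyperpriors. Exactly where these medians sit is
  sensitive to the compound-level mean hyperpriors, a choice the primary
  literature defers to supplementary material; the cross-check against an
  independent ensemble sampler confirms the numbers are properties of the
  posterior, not of the sampler.
* Under different-parameter scenarios the ExNex intercept similarity is
  noticeably dataset-dependent (replicate spread roughly 0.1–0.5 at 20
  compounds): when the random source/target assignment is unbalanced, an
  exchangeable component with a large within-compound spread becomes
  partially competitive. The slope similarity does not show this.
* The variance-inflation route is sensitive to its transformation base, as
  the translation section explains; the mixture route is the more robust
  default.
* Accuracy differences between strategies at 60 replicates resolve only
  gaps above ~0.12; the orderings tested are well above that, but small
  effects (e.g., ExNex- vs hierarchical-informed weights) are not resolved
  at these sizes.
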