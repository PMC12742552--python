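"""Two-parameter Bayesian logistic regression model (BLRM) for dose-finding.

The dose-toxicity relationship is

    logit p(D | alpha, beta) = log(alpha) + beta * log(D / D_R),   alpha, beta > 0

with D_R a reference dose.  Priors are placed on (log alpha, log beta), which
keeps beta positive and hence the curve strictly increasing in dose.  The
intercept log(alpha) is the log-odds of a dose-limiting toxicity (DLT) at the
reference dose; beta scales how fast the odds change with dose.

Posterior inference uses MCMC (adaptive random-walk Metropolis, vectorized
across chains) under a binomial likelihood for the per-dose DLT counts, and
every fit carries convergence diagnostics.  Dose recommendation follows the
continual reassessment principle: the next dose is the one whose posterior
mean DLT probability is closest to the target theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.special import expit

from ._samplers import (
    ConvergenceDiagnostics,
    adaptive_rw_metropolis,
    diagnostics_from_chains,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .priors import PriorSpec

__all__ = [
    "DoseGrid",
    "TrialOutcome",
    "DoseToxCurve",
    "BivariateNormalParams",
    "TargetConfig",
    "PosteriorSamples",
    "dose_toxicity",
    "fit_blrm",
    "recommend_dose",
    "moment_match",
    "true_mtd",
]


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose levels and the reference dose D_R.

    Dose levels are addressed by 1-based ordinal labels 1..K throughout the
    package (level 1 is the lowest dose).
    """

    doses: tuple[float, ...]
    reference_dose: float

    def __init__(self, doses: Sequence[float], reference_dose: float):
        doses = tuple(float(d) for d in doses)
        if len(doses) < 2:
            raise ValueError("a dose grid needs at least two dose levels")
        if any(d <= 0 for d in doses):
            raise ValueError("dose levels must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("dose levels must be strictly increasing")
        if reference_dose <= 0:
            raise ValueError("reference dose must be positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "reference_dose", float(reference_dose))

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def log_ratio(self) -> np.ndarray:
        """log(D_k / D_R) for every dose level."""
        return np.log(np.asarray(self.doses) / self.reference_dose)

    def dose_value(self, level: int) -> float:
        """Dose value for a 1-based dose level."""
        if not 1 <= level <= self.n_doses:
            raise ValueError(f"dose level {level} outside 1..{self.n_doses}")
        return self.doses[level - 1]


def default_dose_grid(reference_dose: float = 1.0) -> DoseGrid:
    """Five geometrically spaced doses (0.25, 0.5, 1, 2, 4) x D_R.

    The reference dose is the middle dose so log(D/D_R) is symmetric about 0.
    """
    multipliers = (0.25, 0.5, 1.0, 2.0, 4.0)
    return DoseGrid([m * reference_dose for m in multipliers], reference_dose)


@dataclass(frozen=True)
class TrialOutcome:
    """Per-dose patient counts n_k and DLT counts Y_k, with Y_k ~ Bin(n_k, p_k)."""

    n_per_dose: tuple[int, ...]
    dlt_per_dose: tuple[int, ...]

    def __init__(self, n_per_dose: Sequence[int], dlt_per_dose: Sequence[int]):
        n = tuple(int(v) for v in n_per_dose)
        y = tuple(int(v) for v in dlt_per_dose)
        if len(n) != len(y):
            raise ValueError("n_per_dose and dlt_per_dose must have equal length")
        if any(v < 0 for v in n) or any(v < 0 for v in y):
            raise ValueError("counts must be non-negative")
        if any(yi > ni for ni, yi in zip(n, y)):
            raise ValueError("DLT count exceeds patient count at some dose level")
        object.__setattr__(self, "n_per_dose", n)
        object.__setattr__(self, "dlt_per_dose", y)

    @property
    def n_doses(self) -> int:
        return len(self.n_per_dose)

    @property
    def n_total(self) -> int:
        return sum(self.n_per_dose)

    @property
    def dlt_total(self) -> int:
        return sum(self.dlt_per_dose)

    @staticmethod
    def empty(n_doses: int) -> "TrialOutcome":
        return TrialOutcome([0] * n_doses, [0] * n_doses)

    def add_cohort(self, level: int, n: int, dlt: int) -> "TrialOutcome":
        """Return a new outcome with ``n`` patients (``dlt`` DLTs) added at a 1-based level."""
        idx = level - 1
        if not 0 <= idx < self.n_doses:
            raise ValueError(f"dose level {level} outside grid")
        new_n = list(self.n_per_dose)
        new_y = list(self.dlt_per_dose)
        new_n[idx] += n
        new_y[idx] += dlt
        return TrialOutcome(new_n, new_y)


@dataclass(frozen=True)
class DoseToxCurve:
    """A true dose-toxicity curve, given by its (log alpha, log beta) pair."""

    log_alpha: float
    log_beta: float

    def prob(self, doses, reference_dose: float) -> np.ndarray:
        return dose_toxicity(self.log_alpha, self.log_beta, doses, reference_dose)

    def prob_on_grid(self, grid: DoseGrid) -> np.ndarray:
        return self.prob(np.asarray(grid.doses), grid.reference_dose)


@dataclass(frozen=True)
class BivariateNormalParams:
    """Means, variances and covariance of a bivariate normal on (log alpha, log beta).

    This is the common currency of the package: weakly informative priors,
    moment-matched source posteriors, and variance-inflated priors are all
    expressed this way.
    """

    mu_alpha: float
    mu_beta: float
    var_alpha: float
    var_beta: float
    cov_ab: float = 0.0

    def __post_init__(self):
        if self.var_alpha <= 0 or self.var_beta <= 0:
            raise ValueError("variances must be positive")
        if self.cov_ab**2 > self.var_alpha * self.var_beta * (1 + 1e-12):
            raise ValueError("covariance violates Cauchy-Schwarz")

    @property
    def corr(self) -> float:
        return self.cov_ab / np.sqrt(self.var_alpha * self.var_beta)

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_alpha, self.mu_beta])

    @property
    def cov(self) -> np.ndarray:
        return np.array(
            [[self.var_alpha, self.cov_ab], [self.cov_ab, self.var_beta]]
        )


@dataclass(frozen=True)
class TargetConfig:
    """Dose-selection settings: target DLT probability and escalation constraint."""

    theta: float = 0.30
    no_skip: bool = True
    mtd_rule: str = "closest_to_theta"

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie strictly between 0 and 1")
        if self.mtd_rule != "closest_to_theta":
            raise ValueError(f"unknown MTD rule: {self.mtd_rule!r}")


@dataclass
class PosteriorSamples:
    """MCMC draws of (log alpha, log beta) with convergence diagnostics.

    ``chains`` has shape (n_chains, n_draws, 2); the flattened per-parameter
    views pool all chains.
    """

    chains: np.ndarray
    diagnostics: ConvergenceDiagnostics = field(repr=False)

    @property
    def log_alpha_draws(self) -> np.ndarray:
        return self.chains[..., 0].reshape(-1)

    @property
    def log_beta_draws(self) -> np.ndarray:
        return self.chains[..., 1].reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]


def dose_toxicity(log_alpha, log_beta, dose, reference_dose):
    """DLT probability of the two-parameter logistic model.

    Computes ``invlogit(log_alpha + exp(log_beta) * log(dose / reference_dose))``;
    at the reference dose this reduces to ``invlogit(log_alpha)``.  Broadcasts
    over array inputs.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive")
    if np.any(np.asarray(reference_dose, dtype=float) <= 0):
        raise ValueError("reference dose must be positive")
    eta = np.asarray(log_alpha) + np.exp(np.asarray(log_beta)) * np.log(
        dose / reference_dose
    )
    out = expit(eta)
    return float(out) if np.isscalar(log_alpha) and out.ndim == 0 else out


def _binomial_loglik(grid: DoseGrid, data: TrialOutcome):
    """Vectorized binomial log-likelihood factory: maps (C, 2) states to (C,)."""
    logr = grid.log_ratio
    y = np.asarray(data.dlt_per_dose, dtype=float)
    n = np.asarray(data.n_per_dose, dtype=float)

    def loglik(x: np.ndarray) -> np.ndarray:
        eta = x[:, 0:1] + np.exp(np.clip(x[:, 1:2], -40, 40)) * logr[None, :]
        return np.sum(y * eta - n * np.logaddexp(0.0, eta), axis=1)

    return loglik


def fit_blrm(
    data: TrialOutcome,
    grid: DoseGrid,
    prior: "PriorSpec",
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 500,
) -> PosteriorSamples:
    """Sample the BLRM posterior of (log alpha, log beta) by MCMC.

    Works for prior-only fits (all counts zero).  Chains are initialized from
    the prior (over-dispersed across mixture components where applicable) and
    a warning is recorded in the diagnostics if any split-R-hat exceeds 1.01.
    Deterministic for a given seed.
    """
    if data.n_doses != grid.n_doses:
        raise ValueError("outcome and grid dose counts differ")
    if chains < 4:
        raise ValueError("at least 4 chains are required")
    if draws < 1000:
        raise ValueError("at least 1000 post-warmup draws per chain are required")
    if rng is None:
        rng = np.random.default_rng(seed)
    loglik = _binomial_loglik(grid, data)
    prior_logpdf = prior.logpdf

    def log_post(x: np.ndarray) -> np.ndarray:
        return loglik(x) + prior_logpdf(x[:, 0], x[:, 1])

    x0 = prior.sample(rng, chains)
    chain_draws = adaptive_rw_metropolis(
        log_post, x0, n_warmup=warmup, n_draws=draws, rng=rng
    )
    diag = diagnostics_from_chains(
        {"log_alpha": chain_draws[..., 0], "log_beta": chain_draws[..., 1]}
    )
    return PosteriorSamples(chains=chain_draws, diagnostics=diag)


def posterior_tox_probs(posterior: PosteriorSamples, grid: DoseGrid) -> np.ndarray:
    """Posterior mean DLT probability at every dose level."""
    la = posterior.log_alpha_draws[:, None]
    beta = np.exp(posterior.log_beta_draws)[:, None]
    eta = la + beta * grid.log_ratio[None, :]
    return expit(eta).mean(axis=0)


def select_closest_dose(
    probs: np.ndarray, theta: float, cap: Optional[int] = None
) -> int:
    """1-based index of the dose with DLT probability closest to theta.

    Exact ties break toward the lower dose (safety-conservative).  If ``cap``
    is given, the selection is truncated at that level.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty dose grid")
    if cap is not None:
        probs = probs[: max(cap, 1)]
    level = int(np.argmin(np.abs(probs - theta))) + 1
    return level


def recommend_dose(
    posterior: PosteriorSamples,
    grid: DoseGrid,
    target: TargetConfig,
    current_highest_tried: Optional[int] = None,
) -> int:
    """Recommend the next dose level (1-based) under the CRM rule.

    The recommendation is argmin_k |p_hat_k - theta| over posterior mean
    toxicity probabilities; when ``target.no_skip`` is set and a highest tried
    level is given, the recommendation is capped at one level above it.
    """
    probs = posterior_tox_probs(posterior, grid)
    cap = None
    if target.no_skip and current_highest_tried is not None:
        cap = min(current_highest_tried + 1, grid.n_doses)
    return select_closest_dose(probs, target.theta, cap=cap)


def true_mtd(curve: DoseToxCurve, grid: DoseGrid, theta: float) -> int:
    """1-based dose level whose true DLT probability is closest to theta."""
    return select_closest_dose(curve.prob_on_grid(grid), theta)


def moment_match(posterior: PosteriorSamples) -> BivariateNormalParams:
    """Bivariate normal approximation of a posterior by moment matching.

    Returns sample means, variances and covariance of the (log alpha,
    log beta) draws; the induced correlation is available as ``.corr`` and is
    the rho_source used by variance-inflated priors.
    """
    if posterior.n_draws < 1000:
        raise ValueError("moment matching requires at least 1000 draws")
    la = posterior.log_alpha_draws
    lb = posterior.log_beta_draws
    var_a = la.var(ddof=1)
    var_b = lb.var(ddof=1)
    if var_a <= 0 or var_b <= 0:
        raise ValueError("degenerate (zero-variance) posterior draws")
    cov = float(np.cov(la, lb, ddof=1)[0, 1])
    return BivariateNormalParams(
        mu_alpha=float(la.mean()),
        mu_beta=float(lb.mean()),
        var_alpha=float(var_a),
        var_beta=float(var_b),
        cov_ab=cov,
    )
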