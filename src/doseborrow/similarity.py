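"""Estimating the similarity of source/target dose-toxicity curves.

Given dose-toxicity data from several compounds, each tested in a source and
a target population, two models estimate similarity parameters
``zeta_alpha, zeta_beta`` in [0, 1] — one per parameter of the two-parameter
logistic dose-toxicity model:

* **ExNex** — per compound and per parameter, the (target, source) pair is
  either exchangeable (drawn around one shared compound-specific mean, with
  probability zeta) or non-exchangeable (two separate compound-specific
  means).  The mixture weights get Beta(0.5, 0.5) priors, the component
  standard deviations Gamma(1, rate 1/10) priors.
* **Hierarchical** — a two-level normal model: population-level curve
  parameters scatter around compound means with within-compound (between
  population) spread tau, and compound means scatter around global means with
  between-compound spread sigma.  Similarity is the intraclass correlation
  ``zeta = sigma^2 / (tau^2 + sigma^2)``, the share of variability explained
  by the compound: it tends to 1 when the two populations of a compound have
  identical curves (tau -> 0) and to 0 when within-compound differences
  dominate.

Neither model borrows curve *location* across compounds: only the typical
degree of source/target agreement is shared.  All modeling is on the
log(D / D_R) scale, so compounds with different dose grids and reference
doses are commensurable.

Compound-specific location parameters are marginalized analytically
(normal-normal), so the MCMC state is just the per-compound population-level
curve parameters plus the global hyperparameters; sampling uses blocked
Metropolis-within-Gibbs, vectorized across chains and compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from ._samplers import (
    LOG_2PI,
    ConvergenceDiagnostics,
    ScaleAdapter,
    diagnostics_from_chains,
)
from .blrm import DoseGrid, TrialOutcome

__all__ = [
    "ArmData",
    "CompoundDataset",
    "ExNexHyperParams",
    "HierarchicalHyperParams",
    "SimilarityEstimate",
    "fit_exnex",
    "fit_hierarchical",
]


@dataclass(frozen=True)
class ArmData:
    """Dose grid and outcome for one population of one compound."""

    grid: DoseGrid
    outcome: TrialOutcome

    def __post_init__(self):
        if self.grid.n_doses != self.outcome.n_doses:
            raise ValueError("grid and outcome dose counts differ")


@dataclass(frozen=True)
class CompoundDataset:
    """Paired source/target dose-toxicity data for one compound.

    The two populations may be tested on different dose grids (some doses in
    only one population), but must share the compound's reference dose.
    Synthetic datasets may carry their generating curves (``true_*_curve``);
    real data leaves them None.
    """

    compound_id: str
    source: ArmData
    target: ArmData
    true_source_curve: Optional[object] = None
    true_target_curve: Optional[object] = None

    def __post_init__(self):
        if not np.isclose(
            self.source.grid.reference_dose, self.target.grid.reference_dose
        ):
            raise ValueError(
                f"compound {self.compound_id!r}: source and target reference doses differ"
            )

    @property
    def reference_dose(self) -> float:
        return self.source.grid.reference_dose


@dataclass(frozen=True)
class ExNexHyperParams:
    """Hyperparameters of the ExNex similarity model.

    ``weight_prior`` are the Beta shapes of the exchangeability weights;
    ``variance_prior`` is (shape, rate) of the Gamma prior on the component
    standard deviations (default mean 10, deliberately vague); the mean
    hyperpriors apply to both the shared (Ex) and separate (Nex)
    compound-level location parameters.
    """

    weight_prior: tuple[float, float] = (0.5, 0.5)
    variance_prior: tuple[float, float] = (1.0, 0.1)
    mean_hyper_alpha: tuple[float, float] = (-0.84, 2.0)  # (mean, sd)
    mean_hyper_beta: tuple[float, float] = (0.0, 1.5)

    def __post_init__(self):
        if min(self.weight_prior) <= 0 or min(self.variance_prior) <= 0:
            raise ValueError("prior shapes and rates must be positive")
        if self.mean_hyper_alpha[1] <= 0 or self.mean_hyper_beta[1] <= 0:
            raise ValueError("hyperprior scales must be positive")


@dataclass(frozen=True)
class HierarchicalHyperParams:
    """Hyperparameters of the hierarchical (intraclass correlation) model."""

    global_mean_alpha: tuple[float, float] = (-0.84, 2.0)  # (mean, sd)
    global_mean_beta: tuple[float, float] = (0.0, 1.5)
    sd_prior: tuple[float, float] = (1.0, 0.1)  # Gamma (shape, rate) on all SDs

    def __post_init__(self):
        if self.global_mean_alpha[1] <= 0 or self.global_mean_beta[1] <= 0:
            raise ValueError("hyperprior scales must be positive")
        if min(self.sd_prior) <= 0:
            raise ValueError("Gamma shape and rate must be positive")


@dataclass
class SimilarityEstimate:
    """Posterior summary of the similarity parameters from one model fit."""

    zeta_alpha_mean: float
    zeta_beta_mean: float
    zeta_alpha_ci: tuple[float, float]
    zeta_beta_ci: tuple[float, float]
    model: str
    diagnostics: ConvergenceDiagnostics = field(repr=False)
    zeta_alpha_draws: np.ndarray = field(repr=False, default=None)
    zeta_beta_draws: np.ndarray = field(repr=False, default=None)
    n_compounds: int = 0

    def __post_init__(self):
        for mean, ci, name in [
            (self.zeta_alpha_mean, self.zeta_alpha_ci, "zeta_alpha"),
            (self.zeta_beta_mean, self.zeta_beta_ci, "zeta_beta"),
        ]:
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"{name} mean outside [0, 1]")
            if not ci[0] <= mean <= ci[1]:
                raise ValueError(f"{name} mean outside its credible interval")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _stack_datasets(datasets: Sequence[CompoundDataset]):
    """Pad per-compound arms to a common dose count.

    Returns Y, N, LOGR of shape (J, 2, Kmax); axis 1 is (source, target).
    Padded slots carry n = 0 and contribute nothing to the likelihood.
    """
    if len(datasets) < 2:
        raise ValueError(
            "similarity estimation requires at least 2 compounds (no pooling otherwise)"
        )
    kmax = max(
        max(ds.source.grid.n_doses, ds.target.grid.n_doses) for ds in datasets
    )
    J = len(datasets)
    Y = np.zeros((J, 2, kmax))
    N = np.zeros((J, 2, kmax))
    LOGR = np.zeros((J, 2, kmax))
    for j, ds in enumerate(datasets):
        for a, arm in enumerate((ds.source, ds.target)):
            k = arm.grid.n_doses
            Y[j, a, :k] = arm.outcome.dlt_per_dose
            N[j, a, :k] = arm.outcome.n_per_dose
            LOGR[j, a, :k] = arm.grid.log_ratio
    return Y, N, LOGR


def _empirical_curve_init(y, n, logr) -> tuple[float, float]:
    """Crude (log alpha, log beta) start values from empirical logits."""
    mask = n > 0
    if not np.any(mask):
        return -0.84, 0.0
    eta = logit((y[mask] + 0.5) / (n[mask] + 1.0))
    x = logr[mask]
    if np.unique(x).size >= 2:
        slope, intercept = np.polyfit(x, eta, 1)
    else:
        slope, intercept = 1.0, float(np.mean(eta))
    slope = max(float(slope), 0.05)
    intercept = float(np.clip(intercept, -6.0, 3.0))
    return intercept, float(np.log(slope))


def _init_theta(Y, N, LOGR, chains: int, rng: np.random.Generator) -> np.ndarray:
    """Per-chain, per-compound start values; layout (laS, lbS, laT, lbT)."""
    J = Y.shape[0]
    base = np.empty((J, 4))
    for j in range(J):
        for a in range(2):
            la, lb = _empirical_curve_init(Y[j, a], N[j, a], LOGR[j, a])
            base[j, 2 * a] = la
            base[j, 2 * a + 1] = lb
    return base[None] + 0.2 * rng.standard_normal((chains, J, 4))


def _make_loglik(Y, N, LOGR):
    def loglik(theta: np.ndarray) -> np.ndarray:
        # theta: (C, J, 4) -> (C, J); arms: source cols (0,1), target cols (2,3)
        la = theta[..., 0::2]  # (C, J, 2)
        lb = theta[..., 1::2]
        eta = la[..., None] + np.exp(np.clip(lb, -40, 40))[..., None] * LOGR[None]
        return np.sum(Y * eta - N * np.logaddexp(0.0, eta), axis=(-1, -2))

    return loglik


# ---------------------------------------------------------------------------
# blocked Metropolis-within-Gibbs driver
# ---------------------------------------------------------------------------


def _run_blocked_mh(
    loglik,
    prior_theta,
    hyper_logprior,
    theta0: np.ndarray,
    hyper0: np.ndarray,
    hyper_blocks: Sequence[Sequence[int]],
    scale_moves: Sequence[tuple[int, int, int]] = (),
    *,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternate per-compound 4-d parameter updates with hyperparameter blocks.

    Compound blocks are conditionally independent given the hyperparameters,
    so all compounds (and chains) are updated in one vectorized proposal.
    Returns the hyperparameter draws, shape (C, n_draws, H).
    """
    theta = theta0.copy()
    hyper = hyper0.copy()
    C, J, _ = theta.shape
    ll = loglik(theta)
    pt = prior_theta(theta, hyper)
    hlp = hyper_logprior(hyper)
    if not (np.all(np.isfinite(ll)) and np.all(np.isfinite(pt)) and np.all(np.isfinite(hlp))):
        raise ValueError("non-finite log posterior at initialization")

    # Per-compound parameters are updated in two moves with separately adapted
    # scales: a "shift" that moves the source and target values of a parameter
    # together (the compound's location) and a "split" that moves them apart.
    # When the populations are nearly exchangeable the posterior constrains the
    # difference far more tightly than the location; one shared proposal scale
    # would mix poorly in exactly the high-similarity cases of interest.
    s_shift = ScaleAdapter(0.3, target_accept=0.35)
    s_split = ScaleAdapter(0.3, target_accept=0.35)
    s_hyper = [ScaleAdapter(0.3, target_accept=0.40) for _ in hyper_blocks]
    s_scale = [ScaleAdapter(0.3, target_accept=0.40) for _ in scale_moves]
    blocks = [np.asarray(b, dtype=int) for b in hyper_blocks]
    draws = np.empty((C, n_draws, hyper.shape[1]))
    # layout (laS, lbS, laT, lbT): source cols (0, 1) pair with target cols (2, 3)
    shift_dirs = 0.5 * np.array(
        [[1.0, 0, 1.0, 0], [0, 1.0, 0, 1.0]]
    )  # move S and T together
    split_dirs = 0.5 * np.array(
        [[1.0, 0, -1.0, 0], [0, 1.0, 0, -1.0]]
    )  # move S and T apart

    def _theta_move(theta, ll, pt, dirs, adapter, warm):
        eps = rng.standard_normal(theta.shape[:2] + (2,))
        prop = theta + adapter.scale * (eps @ dirs)
        ll_p = loglik(prop)
        pt_p = prior_theta(prop, hyper)
        delta = ll_p + pt_p - ll - pt
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        acc = np.log(rng.random(delta.shape)) < delta
        theta = np.where(acc[..., None], prop, theta)
        ll = np.where(acc, ll_p, ll)
        pt = np.where(acc, pt_p, pt)
        if warm:
            adapter.update(acc.mean(), acc.size)
        return theta, ll, pt

    for step in range(n_warmup + n_draws):
        warm = step < n_warmup
        theta, ll, pt = _theta_move(theta, ll, pt, shift_dirs, s_shift, warm)
        theta, ll, pt = _theta_move(theta, ll, pt, split_dirs, s_split, warm)
        # --- joint rescaling of a spread hyperparameter and all the
        # source/target differences it governs.  The posterior couples the
        # within-compound SD tightly to the differences (small SD forces
        # small differences), so componentwise moves crawl; this move walks
        # along that ridge.  Proposal: multiply every difference and the SD
        # by a common factor c; the log-Jacobian of v -> c v over J
        # compounds is J log c.
        for mi, (cs, ct, hcol) in enumerate(scale_moves):
            c = np.exp(s_scale[mi].scale * rng.standard_normal(C))
            hp = hyper.copy()
            hp[:, hcol] += np.log(c)
            prop = theta.copy()
            mid = 0.5 * (theta[..., cs] + theta[..., ct])
            half = 0.5 * c[:, None] * (theta[..., cs] - theta[..., ct])
            prop[..., cs] = mid + half
            prop[..., ct] = mid - half
            ll_p = loglik(prop)
            pt_p = prior_theta(prop, hp)
            hlp_p = hyper_logprior(hp)
            delta = (
                (ll_p + pt_p - ll - pt).sum(axis=1)
                + hlp_p
                - hlp
                + J * np.log(c)
            )
            delta = np.where(np.isfinite(delta), delta, -np.inf)
            acc1 = np.log(rng.random(C)) < delta
            theta = np.where(acc1[:, None, None], prop, theta)
            hyper = np.where(acc1[:, None], hp, hyper)
            ll = np.where(acc1[:, None], ll_p, ll)
            pt = np.where(acc1[:, None], pt_p, pt)
            hlp = np.where(acc1, hlp_p, hlp)
            if warm:
                s_scale[mi].update(acc1.mean(), C)
        # --- hyperparameter blocks, chain-wise
        for bi, idx in enumerate(blocks):
            hp = hyper.copy()
            hp[:, idx] += s_hyper[bi].scale * rng.standard_normal((C, idx.size))
            pt_p = prior_theta(theta, hp)
            hlp_p = hyper_logprior(hp)
            delta = pt_p.sum(axis=1) + hlp_p - pt.sum(axis=1) - hlp
            delta = np.where(np.isfinite(delta), delta, -np.inf)
            acc1 = np.log(rng.random(C)) < delta
            hyper = np.where(acc1[:, None], hp, hyper)
            pt = np.where(acc1[:, None], pt_p, pt)
            hlp = np.where(acc1, hlp_p, hlp)
            if warm:
                s_hyper[bi].update(acc1.mean(), C)
        if not warm:
            draws[:, step - n_warmup] = hyper
    return draws


def _gamma_sd_logprior(log_sd: np.ndarray, shape: float, rate: float) -> np.ndarray:
    """Gamma(shape, rate) prior on an SD, evaluated on the log-SD scale (with Jacobian)."""
    return shape * log_sd - rate * np.exp(log_sd)


def _summarize(
    zeta_a: np.ndarray,
    zeta_b: np.ndarray,
    model: str,
    n_compounds: int,
) -> SimilarityEstimate:
    """Build a SimilarityEstimate from per-chain zeta draws (C, n_draws)."""
    diag = diagnostics_from_chains({"zeta_alpha": zeta_a, "zeta_beta": zeta_b})
    za = zeta_a.reshape(-1)
    zb = zeta_b.reshape(-1)
    return SimilarityEstimate(
        zeta_alpha_mean=float(za.mean()),
        zeta_beta_mean=float(zb.mean()),
        zeta_alpha_ci=tuple(np.percentile(za, [2.5, 97.5])),
        zeta_beta_ci=tuple(np.percentile(zb, [2.5, 97.5])),
        model=model,
        diagnostics=diag,
        zeta_alpha_draws=za,
        zeta_beta_draws=zb,
        n_compounds=n_compounds,
    )


# ---------------------------------------------------------------------------
# ExNex model
# ---------------------------------------------------------------------------


def fit_exnex(
    datasets: Sequence[CompoundDataset],
    hyper: Optional[ExNexHyperParams] = None,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
) -> SimilarityEstimate:
    """Fit the ExNex similarity model by MCMC.

    Per compound j and per curve parameter, the (target, source) pair is
    exchangeable with probability zeta (one shared compound mean) or
    non-exchangeable (two separate means).  The compound-level means are
    integrated out analytically, leaving a two-component bivariate-normal
    mixture prior on each (source, target) parameter pair whose weights are
    the global similarity parameters.
    """
    hp = hyper or ExNexHyperParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    Y, N, LOGR = _stack_datasets(datasets)
    loglik = _make_loglik(Y, N, LOGR)

    m0a, s0a = hp.mean_hyper_alpha
    m0b, s0b = hp.mean_hyper_beta
    s0a2, s0b2 = s0a**2, s0b**2
    wa, wb = hp.weight_prior
    gshape, grate = hp.variance_prior

    def _pair_mixture_lp(x_s, x_t, zeta, v, m0, s02):
        # Marginal over the compound means: Ex -> correlated bivariate normal
        # (shared mean integrated out), Nex -> independent normals.
        a = v + s02
        det = a * a - s02 * s02
        d1 = x_s - m0
        d2 = x_t - m0
        ssq = d1 * d1 + d2 * d2
        lp_ex = -LOG_2PI - 0.5 * np.log(det)[:, None] - 0.5 * (
            a[:, None] * ssq - 2.0 * s02 * d1 * d2
        ) / det[:, None]
        lp_nex = -LOG_2PI - np.log(a)[:, None] - 0.5 * ssq / a[:, None]
        zc = np.clip(zeta, 1e-12, 1 - 1e-12)
        return np.logaddexp(
            np.log(zc)[:, None] + lp_ex, np.log1p(-zc)[:, None] + lp_nex
        )

    def prior_theta(theta, h):
        zeta_a = expit(h[:, 0])
        zeta_b = expit(h[:, 1])
        va = np.exp(2.0 * np.clip(h[:, 2], -10, 10))
        vb = np.exp(2.0 * np.clip(h[:, 3], -10, 10))
        return _pair_mixture_lp(
            theta[..., 0], theta[..., 2], zeta_a, va, m0a, s0a2
        ) + _pair_mixture_lp(theta[..., 1], theta[..., 3], zeta_b, vb, m0b, s0b2)

    def hyper_logprior(h):
        # Beta prior on zeta, with the logit-transform Jacobian folded in
        za = expit(h[:, 0])
        zb = expit(h[:, 1])
        lp = (
            wa * np.log(za)
            + wb * np.log1p(-za)
            + wa * np.log(zb)
            + wb * np.log1p(-zb)
        )
        lp += _gamma_sd_logprior(np.clip(h[:, 2], -10, 10), gshape, grate)
        lp += _gamma_sd_logprior(np.clip(h[:, 3], -10, 10), gshape, grate)
        return lp

    theta0 = _init_theta(Y, N, LOGR, chains, rng)
    hyper0 = np.column_stack(
        [
            0.3 * rng.standard_normal(chains),
            0.3 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
        ]
    )
    hdraws = _run_blocked_mh(
        loglik,
        prior_theta,
        hyper_logprior,
        theta0,
        hyper0,
        hyper_blocks=[[0], [1], [2], [3]],
        scale_moves=[(0, 2, 2), (1, 3, 3)],
        n_warmup=warmup,
        n_draws=draws,
        rng=rng,
    )
    return _summarize(
        expit(hdraws[..., 0]), expit(hdraws[..., 1]), "exnex", len(datasets)
    )


# ---------------------------------------------------------------------------
# hierarchical (intraclass correlation) model
# ---------------------------------------------------------------------------


def fit_hierarchical(
    datasets: Sequence[CompoundDataset],
    hyper: Optional[HierarchicalHyperParams] = None,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
) -> SimilarityEstimate:
    """Fit the hierarchical similarity model by MCMC.

    Population-level curve parameters scatter around compound means with
    covariance built from (tau_alpha, tau_beta, rho_tau); compound means
    scatter around global means with covariance from (sigma_alpha,
    sigma_beta, rho_sigma).  Compound means are marginalized analytically.
    Similarity is computed per draw as the intraclass correlation
    zeta = sigma^2 / (tau^2 + sigma^2) and summarized by its posterior mean.
    """
    hp = hyper or HierarchicalHyperParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    Y, N, LOGR = _stack_datasets(datasets)
    loglik = _make_loglik(Y, N, LOGR)

    ma0, sa0 = hp.global_mean_alpha
    mb0, sb0 = hp.global_mean_beta
    gshape, grate = hp.sd_prior

    def _unpack(h):
        ta = np.exp(np.clip(h[:, 2], -8, 8))
        tb = np.exp(np.clip(h[:, 3], -8, 8))
        rt = 0.999 * np.tanh(h[:, 4])
        sa = np.exp(np.clip(h[:, 5], -8, 8))
        sb = np.exp(np.clip(h[:, 6], -8, 8))
        rs = 0.999 * np.tanh(h[:, 7])
        return ta, tb, rt, sa, sb, rs

    def prior_theta(theta, h):
        C = h.shape[0]
        ta, tb, rt, sa, sb, rs = _unpack(h)
        # within-compound and between-compound 2x2 covariance blocks
        St = np.empty((C, 2, 2))
        St[:, 0, 0] = ta**2
        St[:, 1, 1] = tb**2
        St[:, 0, 1] = St[:, 1, 0] = rt * ta * tb
        Ss = np.empty((C, 2, 2))
        Ss[:, 0, 0] = sa**2
        Ss[:, 1, 1] = sb**2
        Ss[:, 0, 1] = Ss[:, 1, 0] = rs * sa * sb
        A = St + Ss  # marginal covariance of each population's pair
        sigma = np.empty((C, 4, 4))
        sigma[:, :2, :2] = A
        sigma[:, 2:, 2:] = A
        sigma[:, :2, 2:] = Ss  # shared compound mean induces cross-population cov
        sigma[:, 2:, :2] = Ss
        sigma += 1e-9 * np.eye(4)
        chol = np.linalg.cholesky(sigma)
        logdet = np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        mean = np.stack([h[:, 0], h[:, 1], h[:, 0], h[:, 1]], axis=1)
        dev = theta - mean[:, None, :]
        z = np.linalg.solve(chol[:, None], dev[..., None])[..., 0]
        return -2.0 * LOG_2PI - logdet[:, None] - 0.5 * np.sum(z * z, axis=-1)

    def hyper_logprior(h):
        ta, tb, rt, sa, sb, rs = _unpack(h)
        lp = -0.5 * (h[:, 0] - ma0) ** 2 / sa0**2
        lp += -0.5 * (h[:, 1] - mb0) ** 2 / sb0**2
        for col in (2, 3, 5, 6):
            lp += _gamma_sd_logprior(np.clip(h[:, col], -8, 8), gshape, grate)
        # Uniform(-1, 1) priors on the correlations; tanh-transform Jacobian
        lp += np.log1p(-np.tanh(h[:, 4]) ** 2 + 1e-300)
        lp += np.log1p(-np.tanh(h[:, 7]) ** 2 + 1e-300)
        return lp

    theta0 = _init_theta(Y, N, LOGR, chains, rng)
    hyper0 = np.column_stack(
        [
            ma0 + 0.3 * rng.standard_normal(chains),
            mb0 + 0.3 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
            0.2 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
            np.log(0.5) + 0.3 * rng.standard_normal(chains),
            0.2 * rng.standard_normal(chains),
        ]
    )
    hdraws = _run_blocked_mh(
        loglik,
        prior_theta,
        hyper_logprior,
        theta0,
        hyper0,
        hyper_blocks=[[0, 1], [2, 3, 4], [5, 6, 7]],
        scale_moves=[(0, 2, 2), (1, 3, 3)],
        n_warmup=warmup,
        n_draws=draws,
        rng=rng,
    )
    ta2 = np.exp(2.0 * np.clip(hdraws[..., 2], -8, 8))
    tb2 = np.exp(2.0 * np.clip(hdraws[..., 3], -8, 8))
    sa2 = np.exp(2.0 * np.clip(hdraws[..., 5], -8, 8))
    sb2 = np.exp(2.0 * np.clip(hdraws[..., 6], -8, 8))
    zeta_a = sa2 / (ta2 + sa2)
    zeta_b = sb2 / (tb2 + sb2)
    return _summarize(zeta_a, zeta_b, "hierarchical", len(datasets))
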