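"""Shared fixtures and independent oracles for the test suite.

The quadrature oracle computes BLRM posterior means by dense two-dimensional
grid integration, completely independently of the package's MCMC machinery;
it is the reference that sampler-based results are checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from doseborrow import TrialOutcome, default_dose_grid

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def quadrature_posterior_means(
    data,
    grid,
    prior,
    n: int = 401,
    la_lim=(-9.0, 5.0),
    lb_lim=(-7.0, 5.0),
):
    """Posterior means of (log alpha, log beta) by dense grid integration."""
    la = np.linspace(*la_lim, n)
    lb = np.linspace(*lb_lim, n)
    LA, LB = np.meshgrid(la, lb, indexing="ij")
    logr = grid.log_ratio
    y = np.asarray(data.dlt_per_dose, dtype=float)
    m = np.asarray(data.n_per_dose, dtype=float)
    eta = LA[..., None] + np.exp(np.clip(LB, -40, 40))[..., None] * logr
    loglik = np.sum(y * eta - m * np.logaddexp(0.0, eta), axis=-1)
    lp = loglik + prior.logpdf(LA, LB)
    w = np.exp(lp - lp.max())
    norm = np.trapezoid(np.trapezoid(w, lb, axis=1), la)
    mean_la = np.trapezoid(np.trapezoid(w * LA, lb, axis=1), la) / norm
    mean_lb = np.trapezoid(np.trapezoid(w * LB, lb, axis=1), la) / norm
    return float(mean_la), float(mean_lb)


@pytest.fixture(scope="session")
def grid():
    return default_dose_grid()


@pytest.fixture(scope="session")
def moderate_outcome():
    """A realistic escalation outcome: 8 patients per dose, rising DLT counts."""
    return TrialOutcome([8, 8, 8, 8, 8], [0, 1, 2, 4, 5])
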