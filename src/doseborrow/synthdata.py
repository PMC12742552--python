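"""Synthetic multi-compound two-population dose-toxicity data.

``generate_compounds`` reproduces the study conditions used throughout the
package's simulations: every trial tests the same 5 doses with equal patient
allocation; each compound's source curve takes one of the four
(log alpha, log beta) combinations from log alpha in {-2.5, -0.84} and
log beta in {0, 1.5}; the target curve is equal to the source curve or
differs in one or both parameters depending on the similarity scenario, where
a "different" parameter switches to the other element of its two-point set.
DLT counts are binomial draws from the true curves.

``generate_case_study_like`` produces messier datasets in the shape of real
ethnic-bridging dose-escalation data: 4-9 dose levels per compound,
population-specific sample sizes between 14 and 67, and some doses tested in
only one population.  It exercises the readers and models under irregular
grids; it is a synthetic stand-in, not real trial data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .blrm import DoseGrid, DoseToxCurve, TrialOutcome, default_dose_grid
from .similarity import ArmData, CompoundDataset

__all__ = [
    "SIMILARITY_SCENARIOS",
    "GeneratorConfig",
    "generate_compounds",
    "generate_case_study_like",
]

#: scenario name -> (alpha differs between populations, beta differs)
SIMILARITY_SCENARIOS: dict[str, tuple[bool, bool]] = {
    "both_equal": (False, False),
    "alpha_equal_beta_diff": (False, True),
    "alpha_diff_beta_equal": (True, False),
    "both_diff": (True, True),
}

LOG_ALPHA_VALUES = (-2.5, -0.84)
LOG_BETA_VALUES = (0.0, 1.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Data-generating process for a set of historical compounds."""

    scenario: str
    n_compounds: int = 20
    n_per_trial: int = 100
    grid: DoseGrid = field(default_factory=default_dose_grid)
    log_alpha_values: tuple[float, float] = LOG_ALPHA_VALUES
    log_beta_values: tuple[float, float] = LOG_BETA_VALUES
    seed: Optional[int] = None
    #: optional hook replacing the two-point parameter sets with user samplers,
    #: each mapping an rng to a (source_value, other_value) pair
    alpha_sampler: Optional[Callable[[np.random.Generator], tuple[float, float]]] = None
    beta_sampler: Optional[Callable[[np.random.Generator], tuple[float, float]]] = None

    def __post_init__(self):
        if self.scenario not in SIMILARITY_SCENARIOS:
            raise ValueError(
                f"unknown similarity scenario {self.scenario!r}; "
                f"expected one of {sorted(SIMILARITY_SCENARIOS)}"
            )
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be at least 1")
        if self.n_per_trial < 1:
            raise ValueError("n_per_trial must be at least 1")


def equal_allocation(n_total: int, n_doses: int) -> np.ndarray:
    """Split n_total patients over dose levels, remainder to the lowest doses."""
    base = n_total // n_doses
    alloc = np.full(n_doses, base, dtype=int)
    alloc[: n_total % n_doses] += 1
    return alloc


def _simulate_arm(
    curve: DoseToxCurve, grid: DoseGrid, n_total: int, rng: np.random.Generator
) -> ArmData:
    n = equal_allocation(n_total, grid.n_doses)
    p = curve.prob_on_grid(grid)
    y = rng.binomial(n, p)
    return ArmData(grid=grid, outcome=TrialOutcome(n, y))


def _pick_pair(
    values: tuple[float, float],
    differs: bool,
    rng: np.random.Generator,
    sampler,
) -> tuple[float, float]:
    if sampler is not None:
        source, other = sampler(rng)
    else:
        idx = rng.integers(2)
        source, other = values[idx], values[1 - idx]
    return (source, other if differs else source)


def generate_compounds(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> list[CompoundDataset]:
    """Generate the historical-compound datasets for one similarity scenario.

    Deterministic given ``config.seed`` (or an explicit ``rng``).  Also
    returns the generating curves via each dataset's ``source``/``target``
    arm data only; the true parameters are recoverable from the scenario
    contract (equality pattern) if needed by tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alpha_diff, beta_diff = SIMILARITY_SCENARIOS[config.scenario]
    datasets = []
    for j in range(config.n_compounds):
        la_s, la_t = _pick_pair(
            config.log_alpha_values, alpha_diff, rng, config.alpha_sampler
        )
        lb_s, lb_t = _pick_pair(
            config.log_beta_values, beta_diff, rng, config.beta_sampler
        )
        curve_s = DoseToxCurve(la_s, lb_s)
        curve_t = DoseToxCurve(la_t, lb_t)
        source = _simulate_arm(curve_s, config.grid, config.n_per_trial, rng)
        target = _simulate_arm(curve_t, config.grid, config.n_per_trial, rng)
        datasets.append(
            CompoundDataset(
                compound_id=f"compound_{j + 1:02d}",
                source=source,
                target=target,
                true_source_curve=curve_s,
                true_target_curve=curve_t,
            )
        )
    return datasets


def generate_case_study_like(
    n_compounds: int = 6, seed: Optional[int] = None
) -> list[CompoundDataset]:
    """Synthetic datasets shaped like real two-ethnicity dose-escalation data.

    Per compound: 4-9 dose levels on an irregular increasing grid, reference
    dose near the middle, source sample size in [21, 67] and target in
    [14, 27], and (for at least the first compound, usually several) doses
    tested in only one population.  Curves vary across compounds with mild
    source/target differences.
    """
    rng = np.random.default_rng(seed)
    datasets = []
    for j in range(n_compounds):
        k = int(rng.integers(4, 10))
        steps = rng.uniform(1.25, 2.0, size=k - 1)
        doses = 10.0 * np.concatenate([[1.0], np.cumprod(steps)])
        ref = float(doses[k // 2])
        la_s = float(rng.normal(-0.84, 0.7))
        lb_s = float(rng.normal(0.0, 0.5))
        la_t = la_s + float(rng.normal(0.0, 0.3))
        lb_t = lb_s + float(rng.normal(0.0, 0.2))
        n_source = int(rng.integers(21, 68))
        n_target = int(rng.integers(14, 28))

        # drop some dose levels from one population (always at least one
        # exclusive dose for the first compound)
        drop_from_target = rng.random(k) < 0.2
        drop_from_source = (rng.random(k) < 0.2) & ~drop_from_target
        if j == 0 and not drop_from_target.any():
            drop_from_target[-1] = True
        keep_s = np.flatnonzero(~drop_from_source)
        keep_t = np.flatnonzero(~drop_from_target)
        # keep at least two doses per arm
        if keep_s.size < 2:
            keep_s = np.arange(k)[:2]
        if keep_t.size < 2:
            keep_t = np.arange(k)[:2]

        arms = {}
        for name, keep, curve, n_tot in [
            ("source", keep_s, DoseToxCurve(la_s, lb_s), n_source),
            ("target", keep_t, DoseToxCurve(la_t, lb_t), n_target),
        ]:
            grid = DoseGrid(doses[keep], ref)
            arms[name] = _simulate_arm(curve, grid, n_tot, rng)
        datasets.append(
            CompoundDataset(
                compound_id=f"casestudy_{j + 1}",
                source=arms["source"],
                target=arms["target"],
                true_source_curve=DoseToxCurve(la_s, lb_s),
                true_target_curve=DoseToxCurve(la_t, lb_t),
            )
        )
    return datasets
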