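"""Tests for the ExNex and hierarchical similarity models."""

import numpy as np
import pytest

from doseborrow import (
    ArmData,
    CompoundDataset,
    DoseGrid,
    GeneratorConfig,
    TrialOutcome,
    default_dose_grid,
    fit_exnex,
    fit_hierarchical,
    generate_case_study_like,
    generate_compounds,
)

# reduced-but-adequate sampler settings for unit tests
FAST = dict(chains=4, draws=600, warmup=800)

FITTERS = [fit_exnex, fit_hierarchical]


def _datasets(scenario, J=20, n=100, seed=101):
    return generate_compounds(
        GeneratorConfig(scenario=scenario, n_compounds=J, n_per_trial=n, seed=seed)
    )


def _swap_labels(ds: CompoundDataset) -> CompoundDataset:
    return CompoundDataset(
        compound_id=ds.compound_id, source=ds.target, target=ds.source
    )


@pytest.fixture(scope="module", params=FITTERS, ids=["exnex", "hierarchical"])
def recovery_fits(request):
    """One fit per similarity scenario for each model (shared across tests)."""
    fit = request.param
    return {
        scenario: fit(_datasets(scenario), seed=1, **FAST)
        for scenario in ("both_equal", "both_diff", "alpha_equal_beta_diff")
    }


class TestRecovery:
    """Single-dataset recovery at J=20, n=100.

    The sharp replicate-median thresholds live in the acceptance suite; a
    single dataset can legitimately leave the intercept similarity ambiguous
    (the compound-mean pattern is a random assignment), so here the checks
    are high similarity under equal curves and clear separation otherwise.
    """

    def test_identical_curves_give_high_similarity(self, recovery_fits):
        est = recovery_fits["both_equal"]
        assert est.zeta_alpha_mean > 0.8
        assert est.zeta_beta_mean > 0.8

    def test_different_curves_give_clearly_lower_similarity(self, recovery_fits):
        eq, diff = recovery_fits["both_equal"], recovery_fits["both_diff"]
        assert diff.zeta_alpha_mean < eq.zeta_alpha_mean - 0.3
        assert diff.zeta_beta_mean < eq.zeta_beta_mean - 0.3
        assert diff.zeta_beta_mean < 0.2

    def test_mixed_scenario_separates_parameters(self, recovery_fits):
        est = recovery_fits["alpha_equal_beta_diff"]
        assert est.zeta_alpha_mean > 0.8
        assert est.zeta_beta_mean < 0.2


@pytest.mark.parametrize("fit", FITTERS, ids=["exnex", "hierarchical"])
class TestEstimateContract:
    def test_prior_only_fit_returns_prior_mean(self, fit):
        # no data: the similarity posterior equals its prior, mean 0.5
        grid = default_dose_grid()
        empty = ArmData(grid=grid, outcome=TrialOutcome.empty(5))
        datasets = [
            CompoundDataset(compound_id=f"c{j}", source=empty, target=empty)
            for j in range(3)
        ]
        est = fit(datasets, seed=4, **FAST)
        assert est.zeta_alpha_mean == pytest.approx(0.5, abs=0.06)
        assert est.zeta_beta_mean == pytest.approx(0.5, abs=0.06)

    def test_single_compound_rejected(self, fit):
        with pytest.raises(ValueError):
            fit(_datasets("both_equal")[:1], seed=5, **FAST)

    def test_estimate_invariants(self, fit):
        est = fit(_datasets("both_equal", J=5, n=30), seed=6, **FAST)
        for mean, ci in [
            (est.zeta_alpha_mean, est.zeta_alpha_ci),
            (est.zeta_beta_mean, est.zeta_beta_ci),
        ]:
            assert 0.0 <= ci[0] <= mean <= ci[1] <= 1.0
        assert est.diagnostics.n_chains == 4

    def test_deterministic_given_seed(self, fit):
        data = _datasets("both_equal", J=4, n=30)
        a = fit(data, seed=7, **FAST)
        b = fit(data, seed=7, **FAST)
        assert a.zeta_alpha_mean == b.zeta_alpha_mean
        np.testing.assert_array_equal(a.zeta_beta_draws, b.zeta_beta_draws)


class TestSymmetries:
    def test_compound_permutation_invariance(self):
        data = _datasets("alpha_diff_beta_equal", J=8, n=100, seed=8)
        a = fit_exnex(data, seed=9, **FAST)
        b = fit_exnex(list(reversed(data)), seed=10, **FAST)
        assert a.zeta_alpha_mean == pytest.approx(b.zeta_alpha_mean, abs=0.07)
        assert a.zeta_beta_mean == pytest.approx(b.zeta_beta_mean, abs=0.07)

    def test_source_target_label_symmetry(self):
        data = _datasets("both_equal", J=8, n=100, seed=11)
        a = fit_hierarchical(data, seed=12, **FAST)
        b = fit_hierarchical([_swap_labels(d) for d in data], seed=13, **FAST)
        assert a.zeta_alpha_mean == pytest.approx(b.zeta_alpha_mean, abs=0.07)
        assert a.zeta_beta_mean == pytest.approx(b.zeta_beta_mean, abs=0.07)


class TestIrregularData:
    def test_fits_case_study_shaped_data(self):
        # unequal grids, missing doses per population, unequal sample sizes
        data = generate_case_study_like(n_compounds=6, seed=14)
        est = fit_exnex(data, seed=15, **FAST)
        assert 0.0 <= est.zeta_alpha_mean <= 1.0
        est2 = fit_hierarchical(data, seed=16, **FAST)
        assert 0.0 <= est2.zeta_beta_mean <= 1.0

    def test_mismatched_reference_doses_rejected(self):
        g1 = DoseGrid([1, 2, 4], 2.0)
        g2 = DoseGrid([1, 2, 4], 4.0)
        arm1 = ArmData(grid=g1, outcome=TrialOutcome([5, 5, 5], [0, 1, 2]))
        arm2 = ArmData(grid=g2, outcome=TrialOutcome([5, 5, 5], [0, 1, 2]))
        with pytest.raises(ValueError):
            CompoundDataset(compound_id="x", source=arm1, target=arm2)
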