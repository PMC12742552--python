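"""Tests for the CRM trial simulator and study drivers."""

import numpy as np
import pytest

from doseborrow import (
    BivariateNormalParams,
    BorrowingStrategy,
    DoseToxCurve,
    ScenarioSpec,
    TargetConfig,
    build_full_borrowing_prior,
    build_mixture_prior,
    build_weak_prior,
    default_dose_grid,
    run_dose_finding_study,
    simulate_source_trial,
    simulate_target_trial,
    true_mtd,
)
from doseborrow.simulate import StudyResult


class TestSourceTrial:
    def test_zero_toxicity_curve_yields_zero_dlts(self, grid):
        outcome, post = simulate_source_trial(DoseToxCurve(-30.0, 0.0), grid, seed=1)
        assert outcome.dlt_total == 0
        assert sum(outcome.n_per_dose) == 40
        # with no DLTs the estimated reference-dose toxicity shrinks low
        assert post.mu_alpha < -0.84

    def test_equal_allocation_of_40(self, grid):
        outcome, _ = simulate_source_trial(DoseToxCurve(-0.84, 0.0), grid, seed=2)
        assert outcome.n_per_dose == (8, 8, 8, 8, 8)

    def test_deterministic_given_seed(self, grid):
        a, pa = simulate_source_trial(DoseToxCurve(-0.84, 0.0), grid, seed=3)
        b, pb = simulate_source_trial(DoseToxCurve(-0.84, 0.0), grid, seed=3)
        assert a == b
        assert pa == pb

    def test_large_trial_recovers_truth(self, grid):
        # consistency: with 4000 patients the moment-matched posterior means
        # approach the generating parameters
        curve = DoseToxCurve(-0.84, 0.5)
        _, post = simulate_source_trial(curve, grid, n=4000, seed=4)
        assert post.mu_alpha == pytest.approx(-0.84, abs=0.15)
        assert post.mu_beta == pytest.approx(0.5, abs=0.15)


class TestTargetTrial:
    def test_zero_toxicity_escalates_one_level_per_cohort(self, grid):
        record = simulate_target_trial(
            DoseToxCurve(-30.0, 0.0), grid, build_weak_prior(), TargetConfig(), seed=5
        )
        assert record.dose_path == [1, 2, 3, 4, 5, 5]
        assert record.n_total == 12
        assert record.dlt_total == 0

    def test_record_invariants_and_no_skip_legality(self, grid):
        rng_seeds = range(6, 16)
        for seed in rng_seeds:
            record = simulate_target_trial(
                DoseToxCurve(-0.84, 0.0),
                grid,
                build_weak_prior(),
                TargetConfig(),
                seed=seed,
            )
            assert record.n_total == 12
            assert all(n == 2 for _, n, _ in record.cohort_log)
            highest = 0
            for level in record.dose_path:
                assert 1 <= level <= grid.n_doses
                assert level <= highest + 1  # never skips an untried level
                highest = max(highest, level)
            assert 1 <= record.selected_mtd <= grid.n_doses

    def test_zero_weight_mixture_reproduces_weak_prior_run(self, grid):
        # delta = (0, 0) makes the mixture density equal the weak prior;
        # with the same seed the whole trial replays identically
        source = BivariateNormalParams(-1.5, 0.3, 0.2, 0.15, 0.05)
        weak = build_weak_prior(means=(-1.5, 0.3))
        mix = build_mixture_prior(source, weak.weak_part, 0.0, 0.0)
        curve = DoseToxCurve(-0.84, 0.0)
        a = simulate_target_trial(curve, grid, weak, TargetConfig(), seed=17)
        b = simulate_target_trial(curve, grid, mix, TargetConfig(), seed=17)
        assert a.cohort_log == b.cohort_log
        assert a.selected_mtd == b.selected_mtd


class TestStudyDriver:
    def test_empty_study(self, grid):
        spec = ScenarioSpec(
            source_curve=DoseToxCurve(-0.84, 0.0), target_curve=DoseToxCurve(-0.84, 0.0)
        )
        res = run_dose_finding_study(spec, [BorrowingStrategy("weak")], 0, seed=18)
        assert res["weak"].n_sims == 0
        assert np.isnan(res["weak"].accuracy)

    def test_selection_frequencies_sum_to_one(self, grid):
        spec = ScenarioSpec(
            source_curve=DoseToxCurve(-0.84, 0.0), target_curve=DoseToxCurve(-0.84, 0.0)
        )
        res = run_dose_finding_study(spec, [BorrowingStrategy("full")], 6, seed=19)
        r = res["full"]
        assert r.n_sims == 6
        assert r.selection_freq.sum() == pytest.approx(1.0)
        assert 0.0 <= r.accuracy <= 1.0

    def test_informed_strategy_requires_bank(self):
        with pytest.raises(ValueError):
            BorrowingStrategy("mixture_informed")

    def test_informed_strategy_builds_prior_from_bank(self, grid):
        bank = np.array([[0.9, 0.1]])
        strat = BorrowingStrategy("inflated_informed", zeta_bank=bank)
        source = BivariateNormalParams(-1.0, 0.0, 0.3, 0.2, 0.0)
        prior = strat.build_prior(source, np.random.default_rng(0))
        # zeta 0.9 -> omega 0.631 -> variance 0.3 / 0.631 = 0.475
        assert prior.gaussian_part.var_alpha == pytest.approx(0.4754, abs=1e-3)
        # zeta 0.1 -> omega 0.0158 -> variance 0.2 / 0.0158 = 12.6
        assert prior.gaussian_part.var_beta == pytest.approx(12.62, abs=0.05)

    def test_study_result_from_records_empty(self):
        r = StudyResult.from_records([], true_level=3, n_doses=5)
        assert r.n_sims == 0


class TestTrueMtdScenarios:
    def test_study_scenario_truths(self, grid):
        # the canonical curves used in the dose-finding scenarios
        assert true_mtd(DoseToxCurve(-0.84, 0.0), grid, 0.30) == 3
        assert true_mtd(DoseToxCurve(-2.5, 0.0), grid, 0.30) == 5
        assert true_mtd(DoseToxCurve(-2.5, 1.5), grid, 0.30) == 3
        assert true_mtd(DoseToxCurve(-0.84, 1.5), grid, 0.30) == 3
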