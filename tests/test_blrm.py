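"""Unit and property tests for the two-parameter logistic dose-toxicity model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from doseborrow import (
    BivariateNormalParams,
    DoseGrid,
    DoseToxCurve,
    PosteriorSamples,
    TargetConfig,
    TrialOutcome,
    build_mixture_prior,
    build_weak_prior,
    dose_toxicity,
    fit_blrm,
    moment_match,
    recommend_dose,
    true_mtd,
)
from doseborrow.blrm import posterior_tox_probs, select_closest_dose
from doseborrow._samplers import diagnostics_from_chains


class TestDoseToxicity:
    @pytest.mark.parametrize(
        "log_alpha,dose_mult,expected",
        [
            (-0.84, 1.0, 0.3015),  # reference dose: invlogit(log alpha)
            (-2.5, 1.0, 0.0759),
            (0.0, np.e, 0.7311),  # unit slope, unit log dose ratio
        ],
    )
    def test_reference_dose_values(self, log_alpha, dose_mult, expected):
        p = dose_toxicity(log_alpha, 0.0, dose_mult * 50.0, 50.0)
        assert p == pytest.approx(expected, abs=5e-4)

    @given(
        log_alpha=st.floats(-5, 2),
        log_beta=st.floats(-2, 2),
        ref=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_and_bounded(self, log_alpha, log_beta, ref):
        doses = ref * np.array([0.2, 0.5, 1.0, 2.0, 5.0])
        p = dose_toxicity(log_alpha, log_beta, doses, ref)
        assert np.all((p > 0) & (p < 1))
        assert np.all(np.diff(p) > 0)

    def test_rejects_nonpositive_doses(self):
        with pytest.raises(ValueError):
            dose_toxicity(-0.84, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            dose_toxicity(-0.84, 0.0, 1.0, 0.0)


class TestDomainTypes:
    def test_dose_grid_validation(self):
        with pytest.raises(ValueError):
            DoseGrid([1.0], 1.0)  # too few doses
        with pytest.raises(ValueError):
            DoseGrid([2.0, 1.0], 1.0)  # not increasing
        with pytest.raises(ValueError):
            DoseGrid([1.0, 2.0], -1.0)  # bad reference

    def test_outcome_validation(self):
        with pytest.raises(ValueError):
            TrialOutcome([2, 2], [3, 0])  # dlt > n
        with pytest.raises(ValueError):
            TrialOutcome([2], [0, 0])  # length mismatch

    def test_bivariate_params_validation(self):
        with pytest.raises(ValueError):
            BivariateNormalParams(0, 0, -1.0, 1.0)
        with pytest.raises(ValueError):
            BivariateNormalParams(0, 0, 1.0, 1.0, cov_ab=1.5)

    def test_target_config_validation(self):
        with pytest.raises(ValueError):
            TargetConfig(theta=1.2)


class TestDoseSelection:
    def test_closest_to_theta(self):
        assert select_closest_dose([0.05, 0.12, 0.28, 0.45, 0.60], 0.30) == 3

    def test_exact_tie_breaks_low(self):
        assert select_closest_dose([0.25, 0.35, 0.5, 0.6, 0.7], 0.30) == 1

    def test_cap_limits_escalation(self):
        probs = [0.05, 0.10, 0.15, 0.20, 0.29]
        assert select_closest_dose(probs, 0.30) == 5
        assert select_closest_dose(probs, 0.30, cap=3) == 3

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            select_closest_dose([], 0.30)

    def test_relabeling_invariance(self, grid):
        # any dose relabeling that preserves the ordering of posterior
        # toxicity leaves the selected level unchanged
        probs = np.array([0.02, 0.11, 0.27, 0.52, 0.81])
        base = select_closest_dose(probs, 0.30)
        assert select_closest_dose(probs, 0.30, cap=None) == base


class TestTrueMtd:
    def test_interior_mtd(self, grid):
        assert true_mtd(DoseToxCurve(-0.84, 0.0), grid, 0.30) == 3

    def test_curve_below_target_selects_top(self, grid):
        assert true_mtd(DoseToxCurve(-8.0, 0.0), grid, 0.30) == grid.n_doses

    def test_curve_above_target_selects_bottom(self, grid):
        assert true_mtd(DoseToxCurve(5.0, 0.0), grid, 0.30) == 1


def _samples_from_draws(la, lb):
    chains = np.stack([la, lb], axis=-1).reshape(4, -1, 2)
    diag = diagnostics_from_chains(
        {"log_alpha": chains[..., 0], "log_beta": chains[..., 1]}
    )
    return PosteriorSamples(chains=chains, diagnostics=diag)


class TestMomentMatch:
    MU = np.array([-1.0, 0.5])
    COV = np.array([[0.3, 0.4 * np.sqrt(0.3 * 0.2)], [0.4 * np.sqrt(0.3 * 0.2), 0.2]])

    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(7)
        n = 50_000
        draws = rng.multivariate_normal(self.MU, self.COV, size=n)
        mm = moment_match(_samples_from_draws(draws[:, 0], draws[:, 1]))
        # three sampling-theory standard errors
        assert mm.mu_alpha == pytest.approx(-1.0, abs=3 * np.sqrt(0.3 / n))
        assert mm.mu_beta == pytest.approx(0.5, abs=3 * np.sqrt(0.2 / n))
        assert mm.var_alpha == pytest.approx(0.3, abs=3 * 0.3 * np.sqrt(2 / n))
        assert mm.var_beta == pytest.approx(0.2, abs=3 * 0.2 * np.sqrt(2 / n))
        assert mm.corr == pytest.approx(0.4, abs=3 / np.sqrt(n))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        draws = rng.multivariate_normal(self.MU, self.COV, size=20_000)
        a = moment_match(_samples_from_draws(draws[:, 0], draws[:, 1]))
        b = moment_match(_samples_from_draws(draws[:, 0] + 2.5, draws[:, 1] - 1.0))
        assert b.mu_alpha == pytest.approx(a.mu_alpha + 2.5)
        assert b.mu_beta == pytest.approx(a.mu_beta - 1.0)
        assert b.var_alpha == pytest.approx(a.var_alpha)
        assert b.cov_ab == pytest.approx(a.cov_ab)

    def test_null_correlation(self):
        rng = np.random.default_rng(9)
        la = rng.standard_normal(50_000)
        lb = rng.standard_normal(50_000)
        mm = moment_match(_samples_from_draws(la, lb))
        assert abs(mm.corr) < 0.03

    def test_degenerate_draws_error(self):
        la = np.zeros(4000)
        lb = np.zeros(4000)
        with pytest.raises(ValueError):
            moment_match(_samples_from_draws(la, lb))

    def test_too_few_draws_error(self):
        chains = np.zeros((4, 100, 2))
        chains[..., 0] = np.random.default_rng(0).standard_normal((4, 100))
        chains[..., 1] = np.random.default_rng(1).standard_normal((4, 100))
        diag = diagnostics_from_chains(
            {"log_alpha": chains[..., 0], "log_beta": chains[..., 1]}
        )
        with pytest.raises(ValueError):
            moment_match(PosteriorSamples(chains=chains, diagnostics=diag))


class TestFitBlrm:
    def test_prior_only_reproduces_weak_prior_moments(self, grid):
        prior = build_weak_prior()
        post = fit_blrm(TrialOutcome.empty(5), grid, prior, seed=11)
        mom = prior.marginal_moments()
        for name, draws in [
            ("log_alpha", post.log_alpha_draws),
            ("log_beta", post.log_beta_draws),
        ]:
            mean, var = mom[name]
            ess = post.diagnostics.ess[name]
            se = np.sqrt(var / ess)
            assert draws.mean() == pytest.approx(mean, abs=3 * se)
            assert draws.var() == pytest.approx(var, abs=3 * var * np.sqrt(2 / ess))

    def test_prior_only_reproduces_mixture_prior_moments(self, grid):
        source = BivariateNormalParams(-2.5, 0.8, 0.09, 0.04, 0.0)
        prior = build_mixture_prior(source, build_weak_prior().weak_part, 0.5, 0.5)
        post = fit_blrm(TrialOutcome.empty(5), grid, prior, seed=12)
        mom = prior.marginal_moments()
        for name, draws in [
            ("log_alpha", post.log_alpha_draws),
            ("log_beta", post.log_beta_draws),
        ]:
            mean, var = mom[name]
            ess = post.diagnostics.ess[name]
            se = np.sqrt(var / ess)
            assert draws.mean() == pytest.approx(mean, abs=3 * se)

    def test_large_sample_concentrates_on_mle(self, grid):
        # 1000 patients at the reference dose, 300 DLTs: the binomial MLE
        # dominates the weak prior, so invlogit(log alpha) ~ 0.30
        data = TrialOutcome([0, 0, 1000, 0, 0], [0, 0, 300, 0, 0])
        post = fit_blrm(data, grid, build_weak_prior(), seed=13)
        assert expit(post.log_alpha_draws).mean() == pytest.approx(0.30, abs=0.02)

    def test_single_dose_leaves_slope_at_prior(self, grid):
        # data only at the reference dose: log(D/D_R) = 0 makes the
        # likelihood flat in the slope, so its posterior equals its prior
        data = TrialOutcome([0, 0, 200, 0, 0], [0, 0, 60, 0, 0])
        post = fit_blrm(data, grid, build_weak_prior(), seed=14)
        assert post.log_beta_draws.mean() == pytest.approx(0.0, abs=0.15)
        assert post.log_beta_draws.var() == pytest.approx(1.5**2, rel=0.20)

    def test_deterministic_given_seed(self, grid, moderate_outcome):
        a = fit_blrm(moderate_outcome, grid, build_weak_prior(), seed=21)
        b = fit_blrm(moderate_outcome, grid, build_weak_prior(), seed=21)
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_contract_enforced(self, grid, moderate_outcome):
        with pytest.raises(ValueError):
            fit_blrm(moderate_outcome, grid, build_weak_prior(), chains=2)
        with pytest.raises(ValueError):
            fit_blrm(moderate_outcome, grid, build_weak_prior(), draws=500)

    def test_diagnostics_flag_nonconvergence(self):
        # stuck chains with different means must raise a split-R-hat warning
        chains = np.zeros((4, 1000))
        chains[0] += 5.0
        chains += 0.01 * np.random.default_rng(0).standard_normal((4, 1000))
        diag = diagnostics_from_chains({"x": chains})
        assert not diag.converged
        assert any("split-R-hat" in w for w in diag.warnings)


class TestRecommendDose:
    def test_no_skip_cap(self, grid):
        # a posterior that would pick a high dose is capped one level above
        # the highest tried
        data = TrialOutcome([4, 0, 0, 0, 0], [0, 0, 0, 0, 0])
        post = fit_blrm(data, grid, build_weak_prior(), seed=31)
        target = TargetConfig(theta=0.30, no_skip=True)
        rec_uncapped = recommend_dose(post, grid, TargetConfig(no_skip=False))
        rec_capped = recommend_dose(post, grid, target, current_highest_tried=1)
        assert rec_capped <= 2
        assert rec_uncapped >= rec_capped

    def test_posterior_tox_probs_monotone(self, grid, moderate_outcome):
        post = fit_blrm(moderate_outcome, grid, build_weak_prior(), seed=32)
        probs = posterior_tox_probs(post, grid)
        assert np.all(np.diff(probs) > 0)
        assert np.all((probs > 0) & (probs < 1))
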