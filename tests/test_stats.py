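"""Interaction model and RERI machinery against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest

import smokegxe as sg
from smokegxe.stats import Z95, LogisticFit

from .conftest import truth_frame
from .oracles import cross_product_or, newton_logistic


def _random_design(rng, n=200, k=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
    beta = rng.normal(0, 0.8, k + 1)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    return X, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = sg.fit_logistic(np.ones((100, 1)), y, labels=("const",))
        assert fit.params[0] == pytest.approx(np.log(25 / 75), abs=1e-10)

    def test_two_by_two_slope_is_log_crude_or(self):
        # single binary predictor: slope equals the cross-product OR
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [30, 70, 20, 80])
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(20), np.zeros(80)])
        fit = sg.fit_logistic(
            np.column_stack([np.ones(200), x]), y, labels=("const", "x")
        )
        assert np.exp(fit.coef("x")) == pytest.approx(
            cross_product_or(30, 100, 20, 100), rel=1e-10
        )

    def test_matches_newton_oracle_on_random_designs(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            X, y = _random_design(rng)
            fit = sg.fit_logistic(X, y)
            np.testing.assert_allclose(fit.params, newton_logistic(X, y), atol=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X, y = _random_design(rng, n=400)
        fit = sg.fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.cov, ref.cov_params(), rtol=1e-4, atol=1e-8)

    def test_separation_is_surfaced(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()  # outcome perfectly predicted
        with pytest.raises(sg.SeparationError):
            sg.fit_logistic(np.column_stack([np.ones(40), x]), y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        n = 50
        x = rng.standard_normal(n)
        X = pd.DataFrame({"const": 1.0, "x": x, "x_dup": x})
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(sg.RankDeficiencyError, match="x_dup|x"):
            sg.fit_logistic(X, y)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            sg.fit_logistic(np.ones((3, 1)), [0.0, 0.5, 1.0])


class TestCrudeOr:
    def test_published_joint_cell_arithmetic(self, ea_warmth_block):
        # joint-exposure cell vs doubly unexposed cell from printed counts
        or_, lo, hi = sg.crude_cell_or(ea_warmth_block.cells, 1, 1)
        assert or_ == pytest.approx((248 / 137) / (1574 / 1489), rel=1e-12)
        assert or_ == pytest.approx(1.712, abs=5e-4)
        assert lo < or_ < hi

    def test_balanced_table_is_null(self):
        assert sg.crude_or_2x2(10, 10, 10, 10)[0] == pytest.approx(1.0)

    def test_swapping_exposure_inverts(self):
        a = sg.crude_or_2x2(12, 30, 7, 45)
        b = sg.crude_or_2x2(7, 45, 12, 30)
        assert a[0] == pytest.approx(1 / b[0], rel=1e-12)
        assert a[1] == pytest.approx(1 / b[2], rel=1e-12)

    def test_zero_cell_errors_unless_corrected(self):
        with pytest.raises(ValueError, match="zero cell"):
            sg.crude_or_2x2(0, 10, 5, 5)
        or_, _, _ = sg.crude_or_2x2(0, 10, 5, 5, continuity=True)
        assert or_ == pytest.approx((0.5 / 10.5) / (5.5 / 5.5))


class TestInteractionAnalysis:
    def test_exact_count_cohort_matches_crude_arithmetic(self, exact_cohort, ea_warmth_block):
        res = sg.interaction_analysis(
            sg.harmonize_cohort(exact_cohort), "maternal_warmth", group="EA"
        )
        cells = ea_warmth_block.cells
        for ors, (g, e) in ((res.or10, (1, 0)), (res.or01, (0, 1)), (res.or11, (1, 1))):
            crude = sg.crude_cell_or(cells, g, e)
            assert ors[0] == pytest.approx(crude[0], abs=1e-10)

    def test_algebraic_identities_hold_exactly(self, sim_complete):
        res = sg.interaction_analysis(sim_complete, "maternal_warmth")
        or10, or01, or11 = res.or10[0], res.or01[0], res.or11[0]
        assert res.reri.estimate == pytest.approx(or11 - or10 - or01 + 1, abs=1e-12)
        assert res.multiplicative[0] == pytest.approx(or11 / (or10 * or01), abs=1e-12)
        assert res.stratum_g_in_e1[0] * or01 == pytest.approx(or11, abs=1e-12)
        assert res.stratum_e_in_g1[0] * or10 == pytest.approx(or11, abs=1e-12)

    def test_multiplicative_null_recovered(self):
        # main effects large enough that the implied RERI
        # (e^bG - 1)(e^bE - 1) ~ 0.66 clears the single-replicate noise
        params = sg.SimulationParams(
            n_participants=100_000, seed=77, beta_G=0.5, beta_E=0.7,
            beta_GxE=0.0, beta0=-0.3, beta_age=0.0, beta_gender=0.0,
            missing_rates={},
        )
        df = truth_frame(sg.simulate_cohort(params))
        res = sg.interaction_analysis(df, "maternal_warmth")
        log_ratio = np.log(res.multiplicative[0])
        se = res.fit.se("G:E")
        assert abs(log_ratio) < 3 * se
        # multiplicative null with positive main effects implies RERI > 0
        assert res.reri.estimate > 0

    def test_degenerate_cell_reported(self):
        cells = sg.CellCounts(
            {(0, 0): (5, 10), (0, 1): (4, 10), (1, 0): (3, 10), (1, 1): (0, 10)}
        )
        cohort = sg.cohort_from_cell_counts(cells, seed=0)
        with pytest.raises(ValueError, match=r"\(G,E\)=\(1, 1\)"):
            sg.interaction_analysis(sg.harmonize_cohort(cohort), "maternal_warmth")


class TestReri:
    @pytest.mark.parametrize(
        "ors, expected",
        [
            ((1.73, 1.10, 1.21), 0.42),
            ((1.54, 1.28, 1.41), -0.15),
            ((1.0, 1.0, 1.0), 0.0),
        ],
    )
    def test_reri_from_ors(self, ors, expected):
        assert sg.reri_from_ors(*ors) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError, match="or10"):
            sg.reri_from_ors(1.5, 0.0, 1.2)

    def test_null_fit_gradient_and_p(self):
        fit = LogisticFit(
            params=np.zeros(4), cov=np.eye(4), labels=("const", "G", "E", "G:E"),
            n=10, llf=0.0, converged=True, n_iter=1,
        )
        res = sg.reri_delta_ci(fit)
        assert res.estimate == 0.0
        # gradient at the null is (0, 0, 1): variance is the G:E variance
        assert res.variance == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_delta_variance_matches_finite_differences(self, sim_complete):
        res = sg.interaction_analysis(sim_complete, "maternal_warmth")
        fit = res.fit
        ix = [fit.idx(t) for t in ("G", "E", "G:E")]

        def reri_of(b3):
            bg, be, bge = b3
            return np.exp(bg + be + bge) - np.exp(bg) - np.exp(be) + 1

        b0 = fit.params[ix]
        h = 1e-6
        grad = np.array(
            [
                (reri_of(b0 + h * np.eye(3)[j]) - reri_of(b0 - h * np.eye(3)[j])) / (2 * h)
                for j in range(3)
            ]
        )
        var_fd = grad @ fit.cov[np.ix_(ix, ix)] @ grad
        assert res.reri.variance == pytest.approx(var_fd, rel=1e-6)

    def test_wald_ci_uses_z95(self, sim_complete):
        res = sg.interaction_analysis(sim_complete, "maternal_warmth").reri
        assert res.ci_high - res.estimate == pytest.approx(Z95 * res.se, rel=1e-12)


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self, sim_complete):
        a = sg.reri_bootstrap_ci(sim_complete, "maternal_warmth", n_boot=200, seed=9)
        b = sg.reri_bootstrap_ci(sim_complete, "maternal_warmth", n_boot=200, seed=9)
        assert a == b
        c = sg.reri_bootstrap_ci(sim_complete, "maternal_warmth", n_boot=200, seed=10)
        assert a != c

    def test_small_n_boot_rejected(self, sim_complete):
        with pytest.raises(ValueError, match="200"):
            sg.reri_bootstrap_ci(sim_complete, "maternal_warmth", n_boot=50)


class TestContinuousPgs:
    def test_interaction_coefficient_recovery(self):
        rng = np.random.default_rng(99)
        n = 5000
        pgs = rng.standard_normal(n)
        e = (rng.random(n) < 0.3).astype(float)
        eta = 0.1 + 0.2 * pgs + 0.3 * e + 0.3 * pgs * e
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"Y": y, "pgs": pgs, "E_maternal_warmth": e})
        coef, p, fit = sg.continuous_pgs_interaction(df, "maternal_warmth")
        assert abs(coef - 0.3) < 3 * fit.se("pgs:E")
        assert p < 0.05

    def test_constant_exposure_is_rank_deficient(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "Y": (rng.random(100) < 0.5).astype(float),
                "pgs": rng.standard_normal(100),
                "E_maternal_warmth": np.ones(100),
            }
        )
        with pytest.raises(sg.RankDeficiencyError):
            sg.continuous_pgs_interaction(df, "maternal_warmth")
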