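import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from snplast.stats import (
    SeparationError,
    build_design_eq1,
    build_design_eq2,
    days_to_criterion,
    fit_logistic_irls,
    kruskal_wallis,
    success_curve,
    validate_records,
)


def _records(subject="m1", group="GFP", outcomes=None):
    rows = []
    k = 0
    for stage, days in ((0, 8), (1, 12)):
        for day in range(1, days + 1):
            for trial in range(1, 11):
                y = 1 if outcomes is None else outcomes[k]
                rows.append((subject, group, stage, day, trial, y))
                k += 1
    return pd.DataFrame(
        rows, columns=["subject", "group", "stage", "day", "trial", "outcome"]
    )


class TestSchema:
    def test_valid_frame_passes(self):
        validate_records(_records())

    def test_bad_group_rejected(self):
        df = _records()
        df.loc[0, "group"] = "sham"
        with pytest.raises(ValueError):
            validate_records(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            validate_records(_records().drop(columns=["day"]))


class TestSuccessCurve:
    def test_all_wins_everywhere(self):
        assert np.allclose(success_curve(_records()), 100.0)

    def test_eight_of_ten(self):
        y = np.ones(200, int)
        y[8:10] = 0  # two losses on initial day 1
        c = success_curve(_records(outcomes=y))
        assert c[0] == 80.0 and np.allclose(c[1:], 100.0)

    def test_matches_session_bookkeeping(self, network):
        from snplast.plasticity import PlasticityParams
        from snplast.simulate import run_session
        from snplast.stats import records_from_session

        sess = run_session(
            PlasticityParams(eta_ach=0.0, eta_da=0.0), seed=1, network=network
        )
        rec = records_from_session(sess, "a1", "GFP")
        assert np.allclose(success_curve(rec), sess.daily_success)


class TestDaysToCriterion:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([100] * 8, 1),
            ([70, 90, 70, 90, 90, 90, 90, 90], 4),
            ([50] * 8, 9),  # censored: stage length + 1
            ([90, 90, 70], 4),  # criterion must be *maintained*
        ],
    )
    def test_reach_and_maintain(self, curve, expected):
        assert days_to_criterion(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            days_to_criterion([])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12), st.integers(0, 11))
    def test_monotone_in_daily_success(self, curve, idx):
        """Raising any single day's success never delays the criterion."""
        idx = idx % len(curve)
        better = list(curve)
        better[idx] = 100.0
        assert days_to_criterion(better) <= days_to_criterion(curve)


class TestDesignEq1:
    def test_reference_level_rows_all_zero(self):
        X, y, names = build_design_eq1(_records(group="light_on"))
        X0 = X[X[:, names.index("stage")] == 0]
        for col in (
            "group_light_off", "group_GFP",
            "group_light_off_x_stage", "group_GFP_x_stage",
        ):
            assert np.all(X[:, names.index(col)] == 0.0)
        assert np.all(X0[:, names.index("trial_x_stage")] == 0.0)

    def test_row_count_and_trial_coding(self):
        X, y, names = build_design_eq1(_records())
        assert X.shape == (200, 8) and len(y) == 200
        trial = X[:, names.index("trial")]
        stage = X[:, names.index("stage")]
        # running index restarts at the stage switch
        assert trial[stage == 0].max() == 80
        assert trial[stage == 1].min() == 1 and trial[stage == 1].max() == 120

    def test_eq2_exports_subject_columns(self):
        X, y, names, subjects, trial = build_design_eq2(_records())
        assert len(subjects) == len(y) == len(trial)
        assert set(subjects) == {"m1"}


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = np.ones((100, 1))
        fit = fit_logistic_irls(X, y)
        assert fit.params[0] == pytest.approx(np.log(30 / 70), rel=1e-6)

    def test_two_by_two_log_odds_ratio(self):
        # balanced 2x2 table: odds ratio from counts
        a, b, c, d = 40, 10, 20, 30  # exposed win/loss, unexposed win/loss
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic_irls(X, y)
        assert fit.params[1] == pytest.approx(np.log(a * d / (b * c)), rel=1e-6)

    def test_matches_direct_likelihood_maximisation(self):
        """Two-parameter toy: IRLS equals a derivative-free maximiser of the
        exact log-likelihood to 1e-6."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        X = np.column_stack([np.ones(400), x])
        y = (rng.random(400) < expit(-0.4 + 0.9 * x)).astype(float)

        def nll(b):
            p = expit(X @ b)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        ref = minimize(nll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12}).x
        fit = fit_logistic_irls(X, y)
        assert np.allclose(fit.params, ref, atol=1e-6)

    def test_all_successes_is_separation(self):
        with pytest.raises(SeparationError):
            fit_logistic_irls(np.ones((50, 1)), np.ones(50))

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.ones(50), np.ones(50)])
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.raises(ValueError):
            fit_logistic_irls(X, y)

    def test_aic_identity(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = (rng.random(200) < 0.5).astype(float)
        fit = fit_logistic_irls(X, y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)


class TestKruskalWallis:
    def test_shifted_groups_detected(self):
        g = [np.arange(10), np.arange(10) + 100, np.arange(10) + 200]
        h, p = kruskal_wallis(g)
        assert p < 1e-3

    def test_identical_values_degenerate(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(7)])
        assert h == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3), np.array([])])
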