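import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from esmnet.dataset import EsmDataset
from esmnet.preprocess import (
    KPSS_CRITICAL_VALUES,
    KpssResult,
    build_lagged_rows,
    cronbach_alpha_daily,
    default_kpss_lags,
    filter_attention_checks,
    impute_dataset,
    kpss_decision,
    kpss_report,
    kpss_statistic,
    moving_average_impute,
    within_person_center,
)
from esmnet.synthetic import inject_missingness


def panel(rows, names=("a", "b")):
    df = pd.DataFrame(rows, columns=["person_id", "day", *names, "attention_pass"])
    return EsmDataset(df, list(names), likert_bounds=None)


# ---------------------------------------------------------------- attention
class TestAttentionFilter:
    def test_all_pass_unchanged(self, small_dataset):
        out = filter_attention_checks(small_dataset)
        assert len(out.data) == len(small_dataset.data)

    def test_single_failure_drops_one_record(self, small_dataset):
        ds = small_dataset.copy()
        ds.data.loc[5, "attention_pass"] = False
        out = filter_attention_checks(ds)
        assert len(out.data) == len(ds.data) - 1

    def test_person_with_all_failures_contributes_nothing(self):
        ds = panel(
            [(1, 1, 2.0, 2.0, False), (1, 2, 3.0, 3.0, False), (2, 1, 4.0, 4.0, True)]
        )
        out = filter_attention_checks(ds)
        assert out.data["person_id"].tolist() == [2]

    def test_missing_attention_field_treated_as_failing(self):
        df = pd.DataFrame(
            {
                "person_id": [1, 1],
                "day": [1, 2],
                "a": [2.0, 3.0],
                "b": [2.0, 3.0],
                "attention_pass": [None, True],
            }
        )
        out = filter_attention_checks(EsmDataset(df, ["a", "b"], likert_bounds=None))
        assert out.data["day"].tolist() == [2]


# ---------------------------------------------------------------- imputation
class TestMovingAverageImpute:
    def test_mean_of_neighbours(self):
        np.testing.assert_array_equal(
            moving_average_impute(np.array([1.0, np.nan, 3.0]), window=1), [1, 2, 3]
        )

    def test_no_missing_identity(self):
        np.testing.assert_array_equal(
            moving_average_impute(np.array([5.0, 6.0, 7.0]), window=1), [5, 6, 7]
        )

    def test_edge_rule_only_right_neighbour(self):
        # idx 0, window 1: positions {0, 1}; only position 1 observed -> 2
        np.testing.assert_array_equal(
            moving_average_impute(np.array([np.nan, 2.0, 4.0]), window=1), [2, 2, 4]
        )

    def test_window_expansion_when_empty(self):
        # idx 0 with window 1 sees only NaN at idx 1; expands to reach 6.0
        out = moving_average_impute(np.array([np.nan, np.nan, 6.0]), window=1)
        np.testing.assert_array_equal(out, [6, 6, 6])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="all-missing"):
            moving_average_impute(np.array([np.nan, np.nan]), window=1)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            moving_average_impute(np.array([1.0]), window=0)

    @given(
        arrays(
            float,
            st.integers(min_value=3, max_value=25),
            elements=st.one_of(st.just(np.nan), st.floats(1, 7)),
        ).filter(lambda a: np.isfinite(a).any())
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotence_and_totality(self, series):
        once = moving_average_impute(series, window=2)
        assert not np.isnan(once).any()
        twice = moving_average_impute(once, window=2)
        np.testing.assert_array_equal(once, twice)
        # observed entries never altered
        obs = ~np.isnan(series)
        np.testing.assert_array_equal(once[obs], series[obs])


# ---------------------------------------------------------------- lagged rows
class TestBuildLaggedRows:
    def test_three_full_days_two_rows(self):
        ds = panel([(1, 1, 2.0, 2.0, True), (1, 2, 3.0, 3.0, True), (1, 3, 4.0, 4.0, True)])
        design = build_lagged_rows(ds)
        assert design.n_rows == 2
        assert design.frame["day"].tolist() == [2, 3]

    def test_calendar_gap_breaks_transition(self):
        ds = panel(
            [(1, 1, 2.0, 2.0, True), (1, 2, 3.0, 3.0, True), (1, 4, 4.0, 4.0, True), (1, 5, 5.0, 5.0, True)]
        )
        design = build_lagged_rows(ds)
        assert design.frame["day"].tolist() == [2, 5]

    def test_listwise_drops_row_with_any_missing_predictor(self):
        ds = panel([(1, 1, 2.0, 2.0, True), (1, 2, np.nan, 3.0, True), (1, 3, 4.0, 4.0, True)])
        design = build_lagged_rows(ds, "listwise")
        # day-2 cell missing: kills both the 1->2 row (outcome) and 2->3 row (predictor)
        assert design.n_rows == 0

    def test_person_with_one_day_contributes_nothing(self):
        ds = panel([(1, 1, 2.0, 2.0, True), (2, 1, 3.0, 3.0, True), (2, 2, 4.0, 4.0, True)])
        design = build_lagged_rows(ds)
        assert design.frame["person_id"].tolist() == [2]

    def test_unknown_mode_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            build_lagged_rows(small_dataset, "magic")

    def test_lag_validity_audit(self, small_dataset):
        ds = inject_missingness(small_dataset, 0.1, seed=13)
        design = build_lagged_rows(ds)
        assert design.audit_lag_validity(ds)

    def test_deletion_monotonicity(self, small_dataset):
        base = inject_missingness(small_dataset, 0.05, seed=1)
        rows_base = build_lagged_rows(base).n_rows
        more = inject_missingness(base, 0.2, seed=2)
        rows_more = build_lagged_rows(more).n_rows
        assert rows_more <= rows_base

    def test_imputed_mode_keeps_all_transitions(self, small_dataset):
        ds = inject_missingness(small_dataset, 0.1, seed=13)
        imputed = impute_dataset(ds)
        design = build_lagged_rows(imputed, "imputed")
        full = build_lagged_rows(small_dataset)
        assert design.n_rows == full.n_rows


# ---------------------------------------------------------------- centering
class TestWithinPersonCenter:
    def test_constant_person_centers_to_zero(self):
        ds = panel([(1, d, 4.0, 4.0, True) for d in range(1, 6)])
        design = within_person_center(build_lagged_rows(ds))
        assert (design.frame[["xc_a", "xc_b"]].to_numpy() == 0).all()

    def test_identical_deviations_identical_centered(self):
        rows = []
        for pid, mean in ((1, 3.0), (2, 5.0)):
            for d, dev in enumerate([-1.0, 0.0, 1.0, 0.0], start=1):
                rows.append((pid, d, mean + dev, mean - dev, True))
        design = within_person_center(build_lagged_rows(panel(rows)))
        g1 = design.frame[design.frame.person_id == 1][["xc_a", "xc_b"]].to_numpy()
        g2 = design.frame[design.frame.person_id == 2][["xc_a", "xc_b"]].to_numpy()
        np.testing.assert_allclose(g1, g2)

    def test_per_person_centered_mean_zero(self, small_dataset):
        ds = inject_missingness(small_dataset, 0.1, seed=3)
        design = within_person_center(build_lagged_rows(ds))
        for _, grp in design.frame.groupby("person_id"):
            means = grp[design.predictor_columns()].mean()
            np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-10)

    def test_balanced_grand_mean_zero(self):
        rows = [(pid, d, float(pid + d % 3), float(d % 2), True) for pid in (1, 2) for d in range(1, 7)]
        design = within_person_center(build_lagged_rows(panel(rows)))
        np.testing.assert_allclose(
            design.frame[design.predictor_columns()].to_numpy().mean(axis=0), 0.0, atol=1e-10
        )

    def test_person_means_recorded(self, small_dataset):
        design = within_person_center(build_lagged_rows(small_dataset))
        assert design.person_means is not None
        assert list(design.person_means.columns) == small_dataset.variable_names


# ---------------------------------------------------------------- KPSS
def kpss_oracle(y, lags):
    """Independent direct-summation KPSS oracle (level stationarity)."""
    y = np.asarray(y, float)
    T = len(y)
    e = y - sum(y) / T
    num = 0.0
    for t in range(1, T + 1):
        S_t = sum(e[:t])
        num += S_t * S_t
    lrv = sum(ei * ei for ei in e) / T
    for lag in range(1, lags + 1):
        gamma = sum(e[s] * e[s - lag] for s in range(lag, T)) / T
        lrv += 2.0 * (1.0 - lag / (lags + 1.0)) * gamma
    return num / (T * T * lrv)


class TestKpss:
    def test_constant_series_statistic_zero(self):
        res = kpss_statistic(np.full(50, 3.0), lag_truncation=4)
        assert res.statistic == 0.0

    def test_deterministic_trend_rejects(self):
        res = kpss_statistic(np.arange(1, 201, dtype=float))
        assert res.statistic > KPSS_CRITICAL_VALUES[0.05]
        assert not kpss_decision(res, 0.05)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=rng.integers(20, 120))
            lags = int(rng.integers(0, 8))
            res = kpss_statistic(y, lags)
            assert abs(res.statistic - kpss_oracle(y, lags)) < 1e-10

    def test_matches_statsmodels(self):
        from statsmodels.tsa.stattools import kpss as sm_kpss

        rng = np.random.default_rng(1)
        y = rng.normal(size=150)
        lags = 6
        stat, *_ = sm_kpss(y, regression="c", nlags=lags)
        res = kpss_statistic(y, lags)
        assert abs(res.statistic - stat) < 1e-10

    def test_monte_carlo_size(self):
        rng = np.random.default_rng(2026)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            y = rng.standard_normal(200)
            res = kpss_statistic(y)
            if not kpss_decision(res, 0.05):
                rejections += 1
        assert abs(rejections / n_reps - 0.05) < 0.02

    def test_decision_examples(self):
        assert kpss_decision(KpssResult(0.0, 4, 50), 0.05)
        assert not kpss_decision(KpssResult(0.463, 4, 50), 0.05)  # tie rejects
        assert kpss_decision(KpssResult(0.40, 4, 50), 0.01)

    def test_unsupported_level_rejected(self):
        with pytest.raises(ValueError):
            kpss_decision(KpssResult(0.1, 4, 50), 0.20)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            kpss_statistic(np.arange(5, dtype=float))

    def test_default_lags_rule(self):
        assert default_kpss_lags(100) == 4
        assert default_kpss_lags(50) == int(np.floor(4 * 0.5**0.25))

    def test_report_structure(self, small_dataset):
        report = kpss_report(small_dataset)
        assert set(report.columns) >= {"variable", "person_id", "statistic", "stationary", "variable_pass"}
        assert (report["statistic"] >= 0).all()
        # stationary generator: the vast majority of person-series pass
        assert report["stationary"].mean() > 0.8


# ---------------------------------------------------------------- reliability
def cronbach_oracle(items):
    """Brute-force Cronbach's alpha on a complete person x item table."""
    k = items.shape[1]
    item_vars = [np.var(items[:, j], ddof=1) for j in range(k)]
    total = np.var(items.sum(axis=1), ddof=1)
    return (k / (k - 1)) * (1 - sum(item_vars) / total)


class TestCronbachAlpha:
    def test_perfectly_parallel_items_alpha_one(self):
        rows = [(pid, 1, float(pid), float(pid), True) for pid in range(1, 6)]
        ds = panel(rows)
        alpha = cronbach_alpha_daily(ds)
        np.testing.assert_allclose(alpha.loc[1], 1.0, atol=1e-12)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(3)
        n = 4000
        rows = [(pid, 1, *rng.normal(size=2), True) for pid in range(1, n + 1)]
        ds = panel(rows)
        alpha = cronbach_alpha_daily(ds)
        assert abs(alpha.loc[1]) < 0.1

    def test_hand_computed_toy_table(self):
        # 3 items, 4 persons
        items = np.array(
            [[2.0, 3.0, 4.0], [3.0, 3.0, 5.0], [4.0, 5.0, 6.0], [5.0, 6.0, 6.0]]
        )
        rows = [(pid + 1, 1, *items[pid], True) for pid in range(4)]
        df = pd.DataFrame(rows, columns=["person_id", "day", "i1", "i2", "i3", "attention_pass"])
        ds = EsmDataset(df, ["i1", "i2", "i3"], likert_bounds=None)
        alpha = cronbach_alpha_daily(ds)
        assert abs(alpha.loc[1] - cronbach_oracle(items)) < 1e-12

    def test_day_with_single_responder_is_nan(self):
        rows = [(1, 1, 2.0, 3.0, True), (2, 1, 4.0, 5.0, True), (1, 2, 2.0, 3.0, True)]
        alpha = cronbach_alpha_daily(panel(rows))
        assert np.isnan(alpha.loc[2])

    def test_study_scale_alpha_range(self, small_dataset):
        alpha = cronbach_alpha_daily(small_dataset)
        assert alpha.notna().any()
        assert ((alpha.dropna() > -1) & (alpha.dropna() <= 1)).all()
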