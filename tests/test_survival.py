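"""Capped Cox hazard ratios, meta-pooling, resampling tests, KM export."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from ersig import (
    ClinicalTable,
    ERCallSet,
    HazardEstimate,
    SimulationConfig,
    cap_follow_up,
    cox_hr,
    flip_null_test,
    interaction_model,
    km_export,
    meta_pool,
    resample_comparison,
    simulate_cohort,
    stratified_mki67,
)
from ersig.survival import _BinaryCoxData


def _clinical(times, events, **cols):
    n = len(times)
    df = pd.DataFrame({
        "ihc_er": cols.get("ihc_er", ["positive"] * n),
        "time_years": times,
        "event": events,
    }, index=[f"s{j}" for j in range(n)])
    for k, v in cols.items():
        df[k] = v
    return ClinicalTable(df)


def _truth_calls(truth) -> ERCallSet:
    return ERCallSet.from_labels(
        truth.latent_er.map({True: "positive", False: "negative"}), method="truth")


def _small_cfg(seed, **kw):
    return SimulationConfig(seed=seed, n_genes=60, n_stromal_genes=5, **kw)


class TestCapFollowUp:
    def test_censoring_rule(self):
        clin = _clinical([5.0, 1.5, 2.0], [1, 1, 1])
        capped = cap_follow_up(clin, 2.0)
        assert capped.df.loc["s0", "time_years"] == 2.0
        assert capped.df.loc["s0", "event"] == 0
        assert capped.df.loc["s1", "time_years"] == 1.5
        assert capped.df.loc["s1", "event"] == 1
        assert capped.df.loc["s2", "event"] == 1  # exactly at the cap: kept

    def test_event_count_equals_events_within_cap(self):
        times = [0.5, 1.0, 1.9, 2.5, 3.0, 4.0]
        events = [1, 0, 1, 1, 1, 0]
        capped = cap_follow_up(_clinical(times, events), 2.0)
        expected = sum(e for t, e in zip(times, events) if t <= 2.0)
        assert capped.df["event"].sum() == expected

    def test_idempotent_and_never_increases_events(self):
        rng = np.random.default_rng(0)
        clin = _clinical(rng.exponential(3, 50), (rng.random(50) < 0.6).astype(int))
        once = cap_follow_up(clin, 2.0)
        twice = cap_follow_up(once, 2.0)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert once.df["event"].sum() <= clin.df["event"].sum()


class TestCoxHr:
    def test_flipped_covariate_inverts_hr(self):
        cfg = _small_cfg(30)
        _, clin, truth = simulate_cohort(cfg)
        x = (~truth.latent_er).astype(int)
        a = cox_hr(clin, x, cap_years=2.0)
        b = cox_hr(clin, 1 - x, cap_years=2.0)
        assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-6)

    def test_constant_covariate_rejected(self):
        clin = _clinical([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(ValueError, match="degenerate covariate"):
            cox_hr(clin, pd.Series(1.0, index=clin.df.index))

    def test_no_events_rejected(self):
        clin = _clinical([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            cox_hr(clin, pd.Series([0, 1, 0, 1], index=clin.df.index))

    def test_hazard_estimate_consistency(self):
        cfg = _small_cfg(31)
        _, clin, truth = simulate_cohort(cfg)
        est = cox_hr(clin, (~truth.latent_er).astype(int), cap_years=2.0)
        assert est.hr == pytest.approx(np.exp(est.log_hr))
        assert est.ci_low < est.hr < est.ci_high
        assert est.n_events <= est.n


class TestFastCoxSolver:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 250
            x = (rng.random(n) < 0.3).astype(float)
            t = np.round(rng.exponential(5 / np.exp(0.7 * x)), 2)  # induce ties
            e = (rng.random(n) < 0.7).astype(int)
            beta, se = _BinaryCoxData(t, e).fit(x)
            df = pd.DataFrame({"t": t, "e": e, "x": x})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert beta == pytest.approx(cph.summary["coef"].iloc[0], abs=1e-3)
            assert se == pytest.approx(cph.summary["se(coef)"].iloc[0], abs=1e-4)

    def test_batch_equals_single(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(3, 200)
        e = (rng.random(200) < 0.6).astype(int)
        X = (rng.random((10, 200)) < 0.4).astype(float)
        data = _BinaryCoxData(t, e)
        betas, ses = data.fit(X)
        for i in range(10):
            b1, s1 = data.fit(X[i])
            assert betas[i] == pytest.approx(b1, abs=1e-10)
            assert ses[i] == pytest.approx(s1, abs=1e-10)


class TestMetaPool:
    def _est(self, log_hr, se):
        return HazardEstimate(log_hr=log_hr, se=se, n=100, n_events=30, cap_years=2.0)

    def test_identical_estimates(self):
        meta = meta_pool({"a": self._est(0.7, 0.2), "b": self._est(0.7, 0.2)})
        assert meta.pooled.log_hr == pytest.approx(0.7)
        assert meta.pooled.se == pytest.approx(0.2 / np.sqrt(2))
        assert meta.heterogeneity_q == pytest.approx(0.0, abs=1e-12)

    def test_weighted_average_oracle(self):
        meta = meta_pool({"a": self._est(0.6, 0.1), "b": self._est(1.0, 0.3)})
        expected = (0.6 / 0.01 + 1.0 / 0.09) / (1 / 0.01 + 1 / 0.09)
        assert meta.pooled.log_hr == pytest.approx(expected)
        assert abs(meta.pooled.log_hr - 0.64) < 0.001

    def test_pooled_variance_not_larger_than_best_cohort(self):
        meta = meta_pool({"a": self._est(0.4, 0.15), "b": self._est(0.9, 0.3),
                          "c": self._est(0.6, 0.2)})
        assert meta.pooled.se <= 0.15
        assert sum(meta.weights.values()) == pytest.approx(1.0)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError, match="nothing to pool"):
            meta_pool({"a": self._est(0.7, 0.2)})


class TestFlipNull:
    def test_identical_calls_give_p_one(self):
        cfg = _small_cfg(32)
        _, clin, _ = simulate_cohort(cfg)
        ihc = ERCallSet.from_labels(clin.df["ihc_er"])
        with pytest.warns(UserWarning, match="identical"):
            assert flip_null_test(clin, ihc, ihc, B=100, seed=0) == 1.0

    def test_reproducible_and_never_zero(self):
        cfg = _small_cfg(33)
        m, clin, truth = simulate_cohort(cfg)
        ihc = ERCallSet.from_labels(clin.df["ihc_er"])
        expr = _truth_calls(truth)
        p1 = flip_null_test(clin, ihc, expr, B=200, seed=9)
        p2 = flip_null_test(clin, ihc, expr, B=200, seed=9)
        assert p1 == p2
        assert 0 < p1 <= 1
        assert p1 >= 1 / 201

    def test_power_against_planted_mislabels(self):
        """Correcting a 15% IHC false-negative rate is detected in most
        replicates once the cohort is large enough to estimate the 2-year
        hazard ratio precisely (n = 1200, ER effect only)."""
        rejections = 0
        reps = 10
        for rep in range(reps):
            cfg = _small_cfg(3000 + rep, hr_mki67_within_erpos=1.0, n_samples=1200)
            _, clin, truth = simulate_cohort(cfg)
            ihc = ERCallSet.from_labels(clin.df["ihc_er"])
            expr = _truth_calls(truth)
            p = flip_null_test(clin, ihc, expr, B=500, seed=rep)
            rejections += p < 0.05
        assert rejections >= 8


class TestResampleComparison:
    def _cohorts(self, base_seed, n_cohorts=3):
        cohorts, ihc, truth_calls = {}, {}, {}
        for c in range(n_cohorts):
            cfg = _small_cfg(base_seed + c, hr_mki67_within_erpos=1.0)
            _, clin, truth = simulate_cohort(cfg)
            cohorts[str(c)] = clin
            ihc[str(c)] = ERCallSet.from_labels(clin.df["ihc_er"])
            truth_calls[str(c)] = _truth_calls(truth)
        return cohorts, ihc, truth_calls

    def test_identical_classifications_split_ties(self):
        cohorts, ihc, _ = self._cohorts(40)
        p = resample_comparison(cohorts, ihc, ihc, B=200, seed=1)
        assert p == pytest.approx(0.5)

    def test_corrected_calls_beat_ihc(self):
        cohorts, ihc, truth_calls = self._cohorts(41)
        p = resample_comparison(cohorts, ihc, truth_calls, B=300, seed=2)
        assert 0 <= p <= 1
        assert p < 0.1

    def test_small_b_warns(self):
        cohorts, ihc, _ = self._cohorts(42, n_cohorts=2)
        with pytest.warns(UserWarning, match="unstable p"):
            resample_comparison(cohorts, ihc, ihc, B=50, seed=3)


class TestStratifiedMki67:
    def test_planted_effect_confined_to_er_positive(self):
        cfg = _small_cfg(43, n_samples=800)
        matrix, clin, truth = simulate_cohort(cfg)
        est_pos, est_neg = stratified_mki67(clin, matrix, "MKI67", _truth_calls(truth))
        assert est_pos.ci_low > 1.0
        assert est_neg.ci_low <= 1.0 <= est_neg.ci_high

    def test_shuffled_mki67_loses_prognostic_power(self):
        cover = 0
        reps = 10
        for rep in range(reps):
            cfg = _small_cfg(4400 + rep)
            matrix, clin, truth = simulate_cohort(cfg)
            rng = np.random.default_rng(rep)
            vals = matrix.values.copy()
            vals.loc["MKI67"] = rng.permutation(vals.loc["MKI67"].to_numpy())
            from ersig import ExpressionMatrix
            est_pos, est_neg = stratified_mki67(clin, ExpressionMatrix(vals), "MKI67",
                                                _truth_calls(truth))
            cover += (est_pos.ci_low <= 1.0 <= est_pos.ci_high
                      and est_neg.ci_low <= 1.0 <= est_neg.ci_high)
        assert cover >= 0.9 * reps

    def test_stratum_without_events_returns_none(self):
        cfg = _small_cfg(45)
        matrix, clin, truth = simulate_cohort(cfg)
        df = clin.df.copy()
        neg = ~truth.latent_er.reindex(df.index)
        df.loc[neg, "event"] = 0  # wipe out all ER-negative events
        with pytest.warns(UserWarning, match="insufficient events"):
            est_pos, est_neg = stratified_mki67(ClinicalTable(df), matrix, "MKI67",
                                                _truth_calls(truth))
        assert est_pos is not None
        assert est_neg is None


class TestInteractionModel:
    def test_signs_of_planted_model(self):
        cfg = _small_cfg(46, n_samples=1000)
        matrix, clin, truth = simulate_cohort(cfg)
        res = interaction_model(clin, matrix, _truth_calls(truth), "MKI67")
        assert set(res) == {"ln_positive", "er_negative", "mki67", "er_negative:mki67"}
        assert res["er_negative"].hr > 1.0
        assert res["mki67"].hr > 1.0
        # proliferation effect confined to ER+ disease -> interaction < 1
        assert res["er_negative:mki67"].ci_high < 1.0

    def test_ln_independent_of_hazard_covers_one(self):
        cover = 0
        reps = 10
        for rep in range(reps):
            cfg = _small_cfg(4700 + rep, n_samples=800)
            matrix, clin, truth = simulate_cohort(cfg)
            e = interaction_model(clin, matrix, _truth_calls(truth), "MKI67")["ln_positive"]
            cover += e.ci_low <= 1.0 <= e.ci_high
        assert cover >= 8

    def test_collinear_design_rejected(self):
        cfg = _small_cfg(48)
        matrix, clin, truth = simulate_cohort(cfg)
        all_pos = ERCallSet.from_labels(pd.Series("positive", index=clin.df.index))
        with pytest.raises(ValueError, match="collinear covariates"):
            interaction_model(clin, matrix, all_pos, "MKI67")


class TestKmExport:
    def test_hand_worked_product_limit(self):
        # events at 1 and 3, censored at 2, 4; survivors to 5
        clin = _clinical([1.0, 2.0, 3.0, 4.0, 5.0], [1, 0, 1, 0, 0])
        table, _ = km_export(clin, pd.Series("all", index=clin.df.index))
        surv = table.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(4 / 5)
        assert surv.loc[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert surv.loc[5.0] == pytest.approx(4 / 5 * 2 / 3)

    def test_no_events_survival_stays_one(self):
        clin = _clinical([1, 2, 3], [0, 0, 0])
        table, p = km_export(clin, pd.Series("g", index=clin.df.index))
        assert (table["survival"] == 1.0).all()
        assert np.isnan(p)

    def test_identical_groups_logrank_near_one(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 0, 1, 1, 0, 1]
        clin = _clinical(times * 2, events * 2)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=clin.df.index)
        _, p = km_export(clin, groups)
        assert p > 0.95
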