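import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats

from conftest import expr_matrix
from ctscreen.io import ClinicalTable, ValidationError
from ctscreen.simulate import gen_survival, gen_tumor_cohort
from ctscreen.survival import (
    assign_groups,
    km_estimator,
    logrank_test,
    q_values,
    screen_prognosis,
    three_tier_pattern,
)
from naive_survival import naive_km, naive_km_eval, naive_logrank, naive_rmst


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimator([5, 8, 13], [0, 0, 0])
        assert km(0) == 1.0 and km(100) == 1.0

    def test_hand_worked_product_limit(self):
        # t=1: risk 3, death 1 -> 2/3; t=2 censored; t=3: risk 1, death 1 -> 0
        km = km_estimator([1, 2, 3], [1, 0, 1])
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(2 / 3)
        assert km(3) == pytest.approx(0.0)
        assert km(0.5) == 1.0

    def test_duplicating_observations_leaves_curve_unchanged(self):
        t, e = [2, 4, 7, 9], [1, 0, 1, 1]
        km1 = km_estimator(t, e)
        km2 = km_estimator(t * 2, e * 2)
        grid = np.linspace(0, 10, 50)
        assert np.allclose(km1(grid), km2(grid))

    def test_curve_in_unit_interval_and_non_increasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        km = km_estimator(t, e)
        assert ((km.survival >= 0) & (km.survival <= 1)).all()
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimator([], [])

    def test_agrees_with_naive_and_lifelines(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            t = np.round(rng.exponential(10, n), 1)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            km = km_estimator(t, e)
            for tq in np.linspace(0, t.max(), 7):
                assert km(tq) == pytest.approx(naive_km_eval(t, e, tq), abs=1e-10)
            kmf = KaplanMeierFitter().fit(t, e)
            for tq in km.times:
                assert km(tq) == pytest.approx(
                    float(kmf.predict(tq)), abs=1e-9)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = [True, True, True, False, False, False]
        res = logrank_test(g, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.o_minus_e == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_six_subjects_vs_independent_codings(self):
        # A: times 1,3,5 all events; B: times 6,7,8 all events
        g = np.array([True, True, True, False, False, False])
        t = np.array([1, 3, 5, 6, 7, 8], dtype=float)
        e = np.ones(6, dtype=int)
        res = logrank_test(g, t, e)
        chi2, ome, var = naive_logrank(g, t, e)
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.o_minus_e == pytest.approx(ome, abs=1e-10)
        # group A dies first at every event time: observed > expected
        assert res.o_minus_e > 0
        ll = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-10)

    def test_label_swap_negates_o_minus_e(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.random(30) < 0.5
        if g.all() or (~g).all():
            g[0] = ~g[0]
        a = logrank_test(g, t, e)
        b = logrank_test(~g, t, e)
        assert a.o_minus_e == pytest.approx(-b.o_minus_e, abs=1e-12)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([True, True], [1, 2], [1, 1])

    def test_zero_events_flagged_undefined(self):
        res = logrank_test([True, False], [1, 2], [0, 0])
        assert not res.defined

    def test_oracle_agreement_on_random_datasets(self):
        """chi2 and O-E match the naive O(n^2) coding and lifelines to 1e-10
        on random small datasets (tied times included)."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            t = np.round(rng.exponential(10, n), 0) + 1
            e = rng.integers(0, 2, n)
            g = rng.random(n) < 0.5
            if e.sum() == 0 or g.all() or (~g).all():
                continue
            res = logrank_test(g, t, e)
            chi2, ome, _ = naive_logrank(g, t, e)
            if not res.defined:
                continue
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)
            assert res.o_minus_e == pytest.approx(ome, abs=1e-10)
            ll = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-8)


class TestQValues:
    def test_single_p_equals_itself_under_bh_fallback(self):
        assert q_values([0.04]) == pytest.approx([0.04])

    def test_bh_step_up_by_hand(self):
        # p = {0.01, 0.02, 0.03}, pi0 = 1: q_i = min over j>=i of p_j * 3 / j
        q = q_values([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(250)
        q = q_values(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_never_exceeds_one_and_bounded_by_bh(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.random(300) ** 3, rng.random(300)])
        q = q_values(p)
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(p, method="fdr_bh")[1]
        assert (q <= bh + 1e-12).all()
        assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            q_values([0.5, 1.5])


class TestGroups:
    def test_strict_cutoff_and_median_tie_below(self):
        v = [0.0, 1.0, 2.0, 4.0, 6.0]
        g2 = assign_groups(v, 1.0, 2)
        assert list(g2) == ["not_expressed", "not_expressed", "expressed",
                            "expressed", "expressed"]
        g3 = assign_groups(v, 1.0, 3)
        # median of expressers {2,4,6} = 4; ties at the median go below
        assert list(g3) == ["not_expressed", "not_expressed", "below_median",
                            "below_median", "above_median"]


class TestScreenPrognosis:
    def _clinical(self, samples, t, e):
        return ClinicalTable(pd.DataFrame(
            {"time_days": t, "event": e}, index=pd.Index(samples)))

    def test_gene_expressed_in_29_samples_skipped(self):
        rng = np.random.default_rng(0)
        n = 100
        vals = np.zeros((1, n))
        vals[0, :29] = 5.0
        samples = [f"S{i}" for i in range(n)]
        m = expr_matrix(vals, ["G"], samples, context="T1")
        clin = self._clinical(samples, rng.exponential(100, n),
                              np.ones(n, dtype=int))
        out = screen_prognosis(["G"], {"T1": m}, {"T1": clin})
        row = out.iloc[0]
        assert not row["tested"] and row["skip_reason"] == "min_expressed"

    def test_no_overlapping_samples_rejected(self):
        m = expr_matrix([[2.0]], ["G"], ["S1"], context="T1")
        clin = self._clinical(["X1"], [10.0], [1])
        with pytest.raises(ValidationError, match="overlap"):
            screen_prognosis(["G"], {"T1": m}, {"T1": clin})

    def test_planted_hazard_detected_with_direction(self):
        genes = [f"G{i}" for i in range(12)]
        design = {g: 0.5 for g in genes}
        m = gen_tumor_cohort(genes, 300, design, seed=21, tumor_type="T1")
        clin = gen_survival(m, {"G0": ("poor", 3.0)}, seed=21)
        out = screen_prognosis(genes, {"T1": m}, {"T1": clin})
        row = out[out["gene_id"] == "G0"].iloc[0]
        assert row["tested"]
        assert row["q_value"] <= 0.05
        assert row["direction"] == "poor"

    def test_null_data_rarely_called(self):
        genes = [f"G{i}" for i in range(60)]
        m = gen_tumor_cohort(genes, 150, {g: 0.5 for g in genes}, seed=31)
        clin = gen_survival(m, {}, seed=31)
        out = screen_prognosis(genes, {"T1": m}, {"T1": clin})
        frac = (out["q_value"] <= 0.05).mean()
        assert frac <= 0.05


class TestThreeTierPattern:
    def test_identical_tiers_no_pattern(self):
        rng = np.random.default_rng(6)
        t = np.tile(rng.exponential(50, 30), 3)
        e = np.ones(90, dtype=int)
        v = np.concatenate([np.zeros(30), np.full(30, 2.0), np.full(30, 10.0)])
        assert three_tier_pattern(v, t, e, "good") is False

    def test_dose_response_protective_detected(self):
        """Hazards 1.0 / 0.6 / 0.3 across none/below/above: monotone pattern
        recovered (simulation at the planted ordering)."""
        rng = np.random.default_rng(17)
        hits = 0
        runs = 20
        for _ in range(runs):
            n = 100
            v = np.concatenate([np.zeros(n), np.full(n, 2.0), np.full(n, 10.0)])
            haz = np.concatenate([np.full(n, 1.0), np.full(n, 0.6), np.full(n, 0.3)])
            t = rng.exponential(1.0 / haz)
            e = np.ones(3 * n, dtype=int)
            if three_tier_pattern(v, t, e, "good"):
                hits += 1
        assert hits / runs >= 0.9

    def test_non_monotone_effect_rejected(self):
        rng = np.random.default_rng(23)
        hits = 0
        runs = 20
        for _ in range(runs):
            n = 100
            v = np.concatenate([np.zeros(n), np.full(n, 2.0), np.full(n, 10.0)])
            haz = np.concatenate([np.full(n, 1.0), np.full(n, 0.4), np.full(n, 0.8)])
            t = rng.exponential(1.0 / haz)
            e = np.ones(3 * n, dtype=int)
            if three_tier_pattern(v, t, e, "good"):
                hits += 1
        assert hits / runs <= 0.2

    def test_small_tier_undefined(self):
        v = np.array([0.0] * 20 + [2.0] * 3 + [10.0] * 20)
        t = np.arange(43, dtype=float) + 1
        e = np.ones(43, dtype=int)
        assert three_tier_pattern(v, t, e, "good", min_tier_size=10) is None

    def test_rmst_matches_naive_integration(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(20, 40)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        km = km_estimator(t, e)
        for tau in (5.0, 15.0, 40.0):
            assert km.rmst(tau) == pytest.approx(naive_rmst(t, e, tau), abs=1e-10)
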