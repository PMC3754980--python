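"""Presence filtering, per-feature tests, BH step-up, and the dual screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mzmwas.containers import FeatureTable, ValidationError
from mzmwas.cohort_stats import t_test_two_sided
from mzmwas.mwas import (
    MwasConfig,
    bh_fdr,
    feature_tests,
    manhattan_export,
    presence_filter,
    run_mwas,
)


def bh_brute_force(pvals, q):
    """Direct evaluation of the step-up definition (quadratic, tiny m)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


def make_table(values, n_samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    n_feat, n_samp = values.shape
    fids = [f"f{i}" for i in range(n_feat)]
    return FeatureTable(
        data=pd.DataFrame(values, index=fids,
                          columns=[f"s{j}" for j in range(n_samp)]),
        mz=pd.Series(np.linspace(100, 800, n_feat), index=fids),
        rt=pd.Series(np.arange(n_feat, dtype=float) + 1, index=fids),
    )


class TestPresenceFilter:
    def test_fifty_percent_boundary_of_45_samples(self):
        row_kept = [1.0] * 23 + [np.nan] * 22   # 51.1% present
        row_drop = [1.0] * 22 + [np.nan] * 23   # 48.9% present
        table = make_table([row_kept, row_drop])
        out = presence_filter(table, 0.5)
        assert out.feature_ids == ["f0"]

    def test_fully_present_is_identity(self, small_table):
        out = presence_filter(small_table.subset(["100.00000@10.00"]), 0.5)
        assert out.n_features == 1

    def test_kept_set_equals_direct_recount(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 1, size=(60, 45))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        table = make_table(vals)
        kept = set(presence_filter(table, 0.5).feature_ids)
        recount = {
            fid
            for fid, row in table.data.iterrows()
            if row.notna().sum() / 45 >= 0.5
        }
        assert kept == recount

    def test_empty_table_passthrough(self):
        table = make_table(np.empty((0, 4)))
        assert presence_filter(table, 0.5).n_features == 0

    def test_threshold_must_be_fractional(self, small_table):
        with pytest.raises(ValidationError):
            presence_filter(small_table, 1.5)


class TestFeatureTests:
    def test_matches_cohort_t_test_per_feature(self, simulated):
        _, table, samples, _ = simulated
        sub = table.subset(table.feature_ids[:20])
        res = feature_tests(sub, samples, "log2")
        case_ids = samples.index[samples.group == "case"]
        ctrl_ids = samples.index[samples.group == "control"]
        log2d = sub.log2()
        for fid in sub.feature_ids:
            x = log2d.loc[fid, case_ids].dropna().to_numpy()
            y = log2d.loc[fid, ctrl_ids].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                assert not res.loc[fid, "testable"]
                continue
            ref = t_test_two_sided(x, y, "welch")
            assert res.loc[fid, "p"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_planted_large_shift_is_detected(self, four_samples):
        table = make_table([[10.0, 10.1, 20.0, 20.2]] * 1)
        # widen groups: 8 samples, 4-SD shift
        vals = np.concatenate([np.random.default_rng(0).normal(0, 1, 10) + 100,
                               np.random.default_rng(1).normal(0, 1, 10) + 104])
        table = make_table(vals.reshape(1, -1))
        samples = pd.DataFrame(
            {"group": ["case"] * 10 + ["control"] * 10},
            index=table.sample_ids,
        )
        res = feature_tests(table, samples, "raw")
        assert res["p"].iloc[0] < 1e-4

    def test_null_p_values_roughly_uniform(self, synthetic_db):
        from mzmwas.synthetic_cohort import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_chemicals=250, differential_fraction=0.0, dropout_rate=0.0,
            lod_quantile=0.0, seed=5,
        )
        table, samples, _ = simulate_dataset(cfg, synthetic_db)
        res = feature_tests(table, samples, "log2")
        p = res["p"].dropna()
        assert abs(p.median() - 0.5) < 0.06

    def test_untestable_feature_flagged(self):
        table = make_table([[np.nan, 1.0, 2.0, 3.0]])
        samples = pd.DataFrame(
            {"group": ["case", "case", "control", "control"]},
            index=table.sample_ids,
        )
        res = feature_tests(table, samples, "raw")
        assert not res["testable"].iloc[0]
        assert np.isnan(res["p"].iloc[0])


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not reject.any()

    def test_single_small_p_rejected(self):
        qv, reject = bh_fdr([0.04], 0.05)
        assert reject[0] and qv[0] == pytest.approx(0.04)

    def test_adjusted_never_below_p_and_flags_match_qvalues(self):
        rng = np.random.default_rng(8)
        p = rng.random(300)
        for q in (0.05, 0.1, 0.2):
            qv, reject = bh_fdr(p, q)
            assert (qv >= p - 1e-15).all()
            np.testing.assert_array_equal(reject, qv <= q)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200),
        st.sampled_from([0.05, 0.1, 0.2]),
    )
    def test_step_up_equals_brute_force(self, pvals, q):
        _, reject = bh_fdr(pvals, q)
        np.testing.assert_array_equal(reject, bh_brute_force(pvals, q))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        p = rng.beta(0.4, 3.0, 150)
        qv, reject = bh_fdr(p, 0.05)
        ref_rej, ref_q, *_ = multipletests(p, 0.05, method="fdr_bh")
        np.testing.assert_allclose(qv, ref_q, rtol=1e-12)
        np.testing.assert_array_equal(reject, ref_rej)

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(6)
        p = rng.beta(0.3, 4.0, 500)
        counts = [bh_fdr(p, q)[1].sum() for q in (0.05, 0.1, 0.2)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_nan_excluded_from_denominator(self):
        p = [0.01, np.nan, 0.02]
        qv, reject = bh_fdr(p, 0.05)
        assert np.isnan(qv[1]) and not reject[1]
        # m = 2, not 3: q-values use the testable count
        assert qv[0] == pytest.approx(0.02)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5], 1.5)


class TestRunMwas:
    def test_intersection_is_conjunction_of_flags(self, simulated):
        _, table, samples, _ = simulated
        res = run_mwas(presence_filter(table, 0.5), samples)
        t = res.table
        np.testing.assert_array_equal(
            t["in_intersection"], t["sig_raw"] & t["sig_log2"]
        )
        assert set(res.intersection) <= set(res.significant_raw)
        assert set(res.intersection) <= set(res.significant_log2)

    def test_direction_of_planted_up_chemical(self, simulated):
        _, table, samples, truth = simulated
        res = run_mwas(presence_filter(table, 0.5), samples)
        up = [c for c, (flag, b) in truth.chemical_effects.items() if flag and b > 0]
        feats = [
            f for c in up for f in truth.chemical_features[c]
            if f in res.table.index
        ]
        assert feats
        assert (res.table.loc[feats, "direction"] == "higher").mean() > 0.9

    def test_scale_equivariance_under_global_rescaling(self, simulated):
        _, table, samples, _ = simulated
        filt = presence_filter(table, 0.5)
        res1 = run_mwas(filt, samples)
        scaled = FeatureTable(data=filt.data * 7.3, mz=filt.mz, rt=filt.rt)
        res2 = run_mwas(scaled, samples)
        np.testing.assert_allclose(
            res1.table["p_log2"], res2.table["p_log2"], rtol=1e-8
        )
        np.testing.assert_allclose(
            res1.table["t_raw"], res2.table["t_raw"], rtol=1e-8
        )


class TestManhattanExport:
    def test_neglog_arithmetic_order_and_count(self, simulated):
        _, table, samples, _ = simulated
        filt = presence_filter(table, 0.5)
        res = run_mwas(filt, samples)
        man = manhattan_export(res)
        assert len(man) == res.table["p_raw"].notna().sum()
        assert man["mz"].is_monotonic_increasing
        row = res.table["p_raw"].dropna()
        fid = row.index[0]
        assert man.loc[fid, "neg_log10_p"] == pytest.approx(
            -np.log10(row.iloc[0])
        )

    def test_reference_points(self):
        table = make_table(
            np.vstack([
                np.concatenate([np.zeros(5) + 1, np.zeros(5) + 1]),
            ])
        )
        samples = pd.DataFrame(
            {"group": ["case"] * 5 + ["control"] * 5}, index=table.sample_ids
        )
        res = run_mwas(table, samples)
        man = manhattan_export(res)
        assert man["neg_log10_p"].iloc[0] == pytest.approx(0.0)  # p = 1
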