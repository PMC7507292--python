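import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import grouped_sites, small_sim_config
from methdmr.dmr import (
    DmrParams,
    adjust_fdr,
    call_dmrs,
    finalize_dmrs,
    fisher_exact_2x2,
    region_chi2,
    site_test,
)
from methdmr.methcore import pool_and_select_candidates
from methdmr.simulate import simulate_methylomes
from oracles import bh_stepup, fisher_two_sided_exact


class TestFisher:
    @pytest.mark.parametrize("table", [(2, 18, 18, 2), (5, 5, 50, 50), (0, 10, 10, 0), (3, 2, 2, 3), (1, 1, 1, 1)])
    def test_matches_exact_enumeration(self, table):
        p = fisher_exact_2x2(*table)
        assert p == pytest.approx(float(fisher_two_sided_exact(*table)), abs=1e-12)

    def test_random_tables_match_scipy(self):
        rng = np.random.default_rng(7)
        cells = rng.integers(0, 30, size=(200, 4))
        cells = cells[(cells[:, :2].sum(1) > 0) & (cells[:, 2:].sum(1) > 0)]
        mine = fisher_exact_2x2(*cells.T)
        theirs = np.array([stats.fisher_exact(c.reshape(2, 2))[1] for c in cells])
        assert np.max(np.abs(np.atleast_1d(mine) - theirs)) < 1e-10


class TestSiteTest:
    def test_identical_tables(self):
        out = site_test(grouped_sites([10], [20], [10], [20]))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert out["direction"].iloc[0] == "none"

    def test_extreme_table_matches_hypergeometric_sum(self):
        out = site_test(grouped_sites([2], [20], [18], [20]))
        assert out["p_value"].iloc[0] == pytest.approx(float(fisher_two_sided_exact(2, 18, 18, 2)), abs=1e-12)
        assert out["direction"].iloc[0] == "hyper"

    def test_same_proportion_different_depth(self):
        out = site_test(grouped_sites([5], [10], [50], [100]))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        df = grouped_sites([0], [1], [0], [1])
        df["total_A"] = 0
        with pytest.raises(ValueError):
            site_test(df)


class TestRegionChi2:
    def test_no_association(self):
        assert region_chi2(50, 50, 50, 50) == pytest.approx(1.0)

    def test_textbook_statistic(self):
        # [[90,10],[10,90]]: expected 50 everywhere, chi2 = 4*40^2/50 = 128
        p = region_chi2(90, 10, 10, 90)
        assert p == pytest.approx(stats.chi2.sf(128.0, df=1))
        assert p < 1e-15

    def test_fisher_fallback_small_expected(self):
        p = region_chi2(3, 2, 2, 3)
        assert p == pytest.approx(float(fisher_two_sided_exact(3, 2, 2, 3)), abs=1e-12)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert region_chi2(0, 10, 0, 10) == 1.0


def _tested(meth_A, total_A, meth_B, total_B, **kw):
    return site_test(grouped_sites(meth_A, total_A, meth_B, total_B, **kw))


class TestCallDmrs:
    def test_six_hyper_sites_merge_into_one_dmr(self):
        n = 6
        t = _tested([6] * n, [30] * n, [24] * n, [30] * n, spacing=50)
        dmrs = call_dmrs(t)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["n_sites"] == 6
        assert d["direction"] == "hyper"
        assert d["level_A"] == pytest.approx(0.2)
        assert d["level_B"] == pytest.approx(0.8)
        assert d["start"] == t["pos"].iloc[0] - 1 and d["end"] == t["pos"].iloc[-1]

    def test_four_sites_fail_min_sites(self):
        t = _tested([6] * 4, [30] * 4, [24] * 4, [30] * 4, spacing=50)
        assert len(call_dmrs(t)) == 0

    def test_gap_violation_splits_into_short_chains(self):
        pos = [1000, 1050, 1100, 1500, 1550, 1600]  # 400 bp gap after site 3
        t = _tested([6] * 6, [30] * 6, [24] * 6, [30] * 6)
        t["pos"] = pos
        assert len(call_dmrs(t)) == 0

    def test_direction_flip_breaks_chain(self):
        t = _tested([6, 6, 6, 24, 6, 6], [30] * 6, [24, 24, 24, 6, 24, 24], [30] * 6, spacing=50)
        assert len(call_dmrs(t)) == 0  # flip at site 4 leaves chains of 3 and 2

    def test_nonsignificant_candidate_terminates_chain(self):
        mA = [6, 6, 6, 15, 6, 6, 6]
        mB = [24, 24, 24, 15, 24, 24, 24]
        t = _tested(mA, [30] * 7, mB, [30] * 7, spacing=50)
        assert len(call_dmrs(t)) == 0
        # skip-over mode bridges the gap site
        dmrs = call_dmrs(t, DmrParams(allow_nonsig_gaps=True))
        assert len(dmrs) == 1 and dmrs["n_sites"].iloc[0] == 6

    def test_delta_filter(self):
        # significant but small effect: |delta| = 0.15 < 0.20
        t = _tested([100] * 6, [400] * 6, [160] * 6, [400] * 6, spacing=50)
        assert (t["p_value"] < 0.05).all()
        assert len(call_dmrs(t)) == 0

    def test_unsorted_input_rejected(self):
        t = _tested([6] * 6, [30] * 6, [24] * 6, [30] * 6)
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(t.iloc[::-1].reset_index(drop=True))

    def test_idempotence_on_member_sites(self):
        cfg = small_sim_config(seed=3)
        tables, _ = simulate_methylomes(cfg)
        groups = {s: ("A" if s.startswith("CON") else "B") for s in tables}
        sites = pool_and_select_candidates(tables, groups, group_order=["A", "B"])
        tested = site_test(sites)
        dmrs = call_dmrs(tested)
        assert len(dmrs) > 0
        for _, d in dmrs.iterrows():
            m = tested[(tested["chrom"] == d["chrom"]) & (tested["pos"] - 1 >= d["start"]) & (tested["pos"] - 1 < d["end"])]
            again = call_dmrs(m.reset_index(drop=True))
            assert len(again) == 1
            pd.testing.assert_series_equal(again.iloc[0], d, check_names=False)

    def test_monotone_in_thresholds(self):
        cfg = small_sim_config(seed=5)
        tables, _ = simulate_methylomes(cfg)
        groups = {s: ("A" if s.startswith("CON") else "B") for s in tables}
        tested = site_test(pool_and_select_candidates(tables, groups, group_order=["A", "B"]))
        base = len(call_dmrs(tested))
        assert len(call_dmrs(tested, DmrParams(min_delta=0.35))) <= base
        assert len(call_dmrs(tested, DmrParams(min_sites=8))) <= base


class TestAdjustFdr:
    def test_hand_computed_stepup(self):
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert adjust_fdr([0.05]) == pytest.approx([0.05])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = rng.uniform(0.001, 1, size=rng.integers(1, 30)).tolist()
            assert adjust_fdr(p) == pytest.approx(bh_stepup(p), abs=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1, size=50)
        assert (adjust_fdr(p) >= p - 1e-15).all()

    def test_empty(self):
        assert len(adjust_fdr([])) == 0


class TestFinalize:
    def test_threshold_application(self):
        dmrs = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [100, 600], "n_sites": [5, 5],
             "direction": ["hyper", "hypo"], "level_A": [0.2, 0.8], "level_B": [0.8, 0.2],
             "delta": [0.6, -0.6], "chi2_p": [1e-6, 0.04]}
        )
        out = finalize_dmrs(dmrs, q_threshold=0.01)
        # q = [2e-6, 0.04]; only the first survives q < 0.01
        assert list(out["start"]) == [0]

    def test_empty_set(self):
        out = finalize_dmrs(pd.DataFrame(columns=["chrom", "start", "end", "chi2_p"]))
        assert len(out) == 0 and "q_value" in out.columns
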