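import io

import numpy as np
import pandas as pd
import pytest

from methdmr.methcore import (
    MethcallParseError,
    conversion_rate,
    methylation_level,
    parse_methcall_table,
    pool_and_select_candidates,
)


class TestParse:
    def test_basic_row_mapping(self):
        df = parse_methcall_table(io.StringIO("chr1\t100\t+\tCpG\t7\t10\n"))
        row = df.iloc[0]
        assert (row["chrom"], row["pos"], row["strand"], row["meth_reads"], row["total_reads"]) == ("chr1", 100, "+", 7, 10)

    def test_methratio_dialect_with_ratio_column_and_header(self):
        text = "chr\tpos\tstrand\tcontext\tratio\tmeth\ttotal\nchr2\t55\t-\tCpG\t0.5\t3\t6\nchr2\t60\t-\tCHH\t0.0\t0\t6\n"
        df = parse_methcall_table(io.StringIO(text), sample_id="s1")
        assert len(df) == 1  # non-CpG context dropped
        assert df["sample"].iloc[0] == "s1"

    def test_invariant_violation_names_line(self):
        with pytest.raises(MethcallParseError, match="line 2"):
            parse_methcall_table(io.StringIO("chr1\t100\t+\tCpG\t7\t10\nchr1\t101\t+\tCpG\t12\t10\n"))

    def test_malformed_row_names_line(self):
        with pytest.raises(MethcallParseError, match="line 1"):
            parse_methcall_table(io.StringIO("chr1\tNA\t+\tCpG\t7\t10\n"))

    def test_empty_file(self):
        df = parse_methcall_table(io.StringIO(""))
        assert len(df) == 0

    def test_sorted_output(self):
        text = "chr2\t5\t+\tCpG\t1\t5\nchr1\t9\t+\tCpG\t1\t5\nchr1\t2\t+\tCpG\t1\t5\n"
        df = parse_methcall_table(io.StringIO(text))
        assert list(df["chrom"]) == ["chr1", "chr1", "chr2"]
        assert list(df["pos"]) == [2, 9, 5]


class TestMethylationLevel:
    @pytest.mark.parametrize("m,t,expected", [(7, 10, 0.7), (0, 25, 0.0), (25, 25, 1.0)])
    def test_formula(self, m, t, expected):
        assert methylation_level(m, t) == expected

    def test_scale_free(self):
        assert methylation_level(3, 8) == methylation_level(30, 80)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            methylation_level(0, 0)


class TestConversionRate:
    def test_simple_counts(self):
        calls = pd.DataFrame({"chrom": "L", "pos": [1, 2], "strand": "+", "context": "CHH",
                              "meth_reads": [10, 5], "total_reads": [600, 400]})
        assert conversion_rate(calls).conversion_rate == pytest.approx(1 - 15 / 1000)

    def test_perfect_conversion(self):
        calls = pd.DataFrame({"chrom": "L", "pos": [1], "strand": "+", "context": "CpG",
                              "meth_reads": [0], "total_reads": [500]})
        assert conversion_rate(calls).conversion_rate == 1.0

    def test_no_control_calls(self):
        calls = pd.DataFrame(columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"])
        with pytest.raises(ValueError, match="QC unavailable"):
            conversion_rate(calls)

    def test_binomial_sampling_recovers_failure_rate(self):
        # per-read failure prob 0.0123 over ~1e5 reads: rate within 3 SE of 0.9877
        rng = np.random.default_rng(42)
        depth = np.full(2000, 50)
        meth = rng.binomial(depth, 0.0123)
        calls = pd.DataFrame({"chrom": "L", "pos": np.arange(2000) + 1, "strand": "+",
                              "context": "CHH", "meth_reads": meth, "total_reads": depth})
        rate = conversion_rate(calls).conversion_rate
        n_reads = depth.sum()
        se = np.sqrt(0.0123 * (1 - 0.0123) / n_reads)
        assert abs(rate - 0.9877) < 3 * se


def _calls(counts, start=100, spacing=10):
    rows = []
    for i, (m, t) in enumerate(counts):
        rows.append(("chr1", start + i * spacing, "+", "CpG", m, t))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"])


class TestPooling:
    def test_hand_summed_pooling(self):
        samples = {
            "a1": _calls([(3, 6)]), "a2": _calls([(2, 6)]),
            "b1": _calls([(5, 6)]), "b2": _calls([(6, 6)]),
        }
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = pool_and_select_candidates(samples, groups, min_depth=5)
        assert len(out) == 1
        assert out["level_A"].iloc[0] == pytest.approx(5 / 12)
        assert out["level_B"].iloc[0] == pytest.approx(11 / 12)
        assert out["total_A"].iloc[0] == 12 and out["total_B"].iloc[0] == 12

    def test_depth_boundary_drops_site(self):
        # 4x in one sample, >=6x elsewhere: dropped at min_depth=5
        samples = {
            "a1": _calls([(2, 4), (3, 6)]), "a2": _calls([(2, 6), (3, 6)]),
            "b1": _calls([(5, 6), (3, 6)]), "b2": _calls([(6, 6), (3, 6)]),
        }
        groups = {s: s[0].upper() for s in samples}
        out = pool_and_select_candidates(samples, groups, min_depth=5)
        assert list(out["pos"]) == [110]

    def test_per_group_pool_mode_is_laxer(self):
        samples = {
            "a1": _calls([(2, 4)]), "a2": _calls([(2, 6)]),
            "b1": _calls([(5, 6)]), "b2": _calls([(6, 6)]),
        }
        groups = {s: s[0].upper() for s in samples}
        strict = pool_and_select_candidates(samples, groups, min_depth=5)
        lax = pool_and_select_candidates(samples, groups, min_depth=5, depth_mode="per-group-pool")
        assert len(strict) == 0 and len(lax) == 1

    def test_site_must_be_commonly_covered(self):
        samples = {
            "a1": _calls([(3, 6), (3, 6)]), "a2": _calls([(2, 6)]),
            "b1": _calls([(5, 6), (3, 6)]), "b2": _calls([(6, 6), (3, 6)]),
        }
        groups = {s: s[0].upper() for s in samples}
        out = pool_and_select_candidates(samples, groups, min_depth=5)
        # second site absent from a2: excluded
        assert list(out["pos"]) == [100]
        # pooled totals equal per-sample sums at retained sites
        assert out["total_A"].iloc[0] == 12

    def test_unknown_sample_in_groups(self):
        samples = {"a1": _calls([(3, 6)])}
        with pytest.raises(ValueError, match="unknown"):
            pool_and_select_candidates(samples, {"a1": "A", "zz": "B"})
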