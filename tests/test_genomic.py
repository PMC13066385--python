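"""Association-test layer: SEG mapping, Wilcoxon, Fisher, Pearson, enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccdeconv import io as ccio
from ccdeconv.datatypes import ExpressionMatrix
from ccdeconv.genomic import (
    abundance_filter,
    carriers_from_maf,
    cna_expression_correlation,
    map_segments_to_genes,
    mutation_fisher_test,
    pathway_enrichment,
    two_group_locus_test,
)


def _segments(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_mean"])


def _coords(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")


class TestSegmentMapping:
    def test_gene_inside_single_segment_inherits_mean(self):
        seg = _segments([("s1", "chr1", 0, 1000, -0.5)])
        coords = _coords([("g1", "chr1", 100, 200)])
        assert map_segments_to_genes(seg, coords).loc["g1", "s1"] == -0.5

    def test_split_gene_overlap_weighted_mean(self):
        # gene [100, 200): 25% in segment with mean 0.0, 75% in segment -1.0
        seg = _segments([("s1", "chr1", 0, 125, 0.0), ("s1", "chr1", 125, 500, -1.0)])
        coords = _coords([("g1", "chr1", 100, 200)])
        assert map_segments_to_genes(seg, coords).loc["g1", "s1"] == pytest.approx(-0.75)

    def test_unsegmented_gap_is_na(self):
        seg = _segments([("s1", "chr1", 0, 50, 0.2)])
        coords = _coords([("g1", "chr1", 100, 200), ("g2", "chr2", 0, 10)])
        out = map_segments_to_genes(seg, coords)
        assert out["s1"].isna().all()

    def test_seg_reader_converts_one_based_inclusive(self, tmp_path):
        path = tmp_path / "t.seg"
        path.write_text("ID\tchrom\tloc.start\tloc.end\tseg.mean\ns1\tchr1\t1\t100\t-0.3\n")
        seg = ccio.read_seg(path)
        assert seg.loc[0, "start"] == 0 and seg.loc[0, "end"] == 100

    def test_malformed_seg_rejected(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("a\tb\tc\ns1\tchr1\t5\n")
        with pytest.raises(ValueError, match="malformed SEG"):
            ccio.read_seg(path)


def _exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p over all assignments of ranks."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(combined)
    obs = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2
    total, extreme = 0, 0
    for idx in itertools.combinations(range(len(combined)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestWilcoxon:
    def test_textbook_separated_groups(self):
        res = two_group_locus_test(
            pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["r"],
                         columns=list("abcdef")).astype(float),
            pd.Series(["X"] * 3 + ["Y"] * 3, index=list("abcdef")),
            ("X", "Y"),
        )
        assert res.loc["r", "p"] == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        values = pd.DataFrame([[1, 1, 2, 1, 1, 2]], index=["r"], columns=list("abcdef"))
        labels = pd.Series(["X"] * 3 + ["Y"] * 3, index=list("abcdef"))
        res = two_group_locus_test(values.astype(float), labels, ("X", "Y"))
        assert res.loc["r", "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(loc=rng.uniform(0, 2), size=n2)
        cols = [f"s{i}" for i in range(n1 + n2)]
        values = pd.DataFrame([np.concatenate([x, y])], index=["r"], columns=cols)
        labels = pd.Series(["X"] * n1 + ["Y"] * n2, index=cols)
        res = two_group_locus_test(values, labels, ("X", "Y"))
        assert res.loc["r", "p"] == pytest.approx(_exact_rank_sum_p(x, y), abs=1e-10)

    def test_abundance_filter_rule(self):
        values = pd.DataFrame(
            {
                "kept": [0.2] * 5 + [0.0] * 5,     # >10% in exactly 5 samples
                "dropped": [0.2] * 4 + [0.0] * 6,  # only 4 samples above 10%
            }
        ).T
        out = abundance_filter(values)
        assert list(out.index) == ["kept"]

    def test_groups_too_small_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        labels = pd.Series(["X", "X", "Y"], index=list("abc"))
        with pytest.raises(ValueError):
            two_group_locus_test(values, labels, ("X", "Y"))


def _fisher_oracle(a, b, c, d):
    """Two-sided point-probability Fisher p by full enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return comb(row1, k) * comb(n - row1, col1 - k) / comb(n, col1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_mm_vs_in_carrier_table_worked_example(self):
        """4/44 vs 0/68 non-silent carriers gives p = 0.022 to 2 s.f."""
        mut = pd.DataFrame(
            [[1] * 4 + [0] * 108], index=["FREM1"],
            columns=[f"m{i}" for i in range(44)] + [f"i{i}" for i in range(68)],
        )
        labels = pd.Series(["MM"] * 44 + ["IN"] * 68, index=mut.columns)
        res = mutation_fisher_test(mut, labels, ("MM", "IN"))
        assert res.loc["FREM1", "p"] == pytest.approx(0.022, abs=5e-4)
        assert float(f"{res.loc['FREM1', 'p']:.2g}") == 0.022

    def test_empty_margin_p_one(self):
        mut = pd.DataFrame([[0] * 10], index=["g"], columns=[f"s{i}" for i in range(10)])
        labels = pd.Series(["A"] * 4 + ["B"] * 6, index=mut.columns)
        assert mutation_fisher_test(mut, labels, ("A", "B")).loc["g", "p"] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 15, size=4)
        if a + b == 0 or c + d == 0:
            a, d = a + 1, d + 1
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)

    def test_carriers_from_maf_variant_class_filter(self):
        maf = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3"],
                "gene": ["g1", "g1", "g1"],
                "variant_class": ["Missense_Mutation", "Silent", "Frame_Shift_Del"],
            }
        )
        mat = carriers_from_maf(maf, ["s1", "s2", "s3", "s4"])
        assert mat.loc["g1"].tolist() == [1, 0, 1, 0]


class TestCNAExpressionCorrelation:
    def _expr(self, values, samples):
        return ExpressionMatrix(pd.DataFrame([values], index=["g"], columns=samples))

    def test_perfect_linearity(self):
        cna = pd.DataFrame([[0, 1, 2, 3.0]], index=["g"], columns=list("abcd"))
        expr = self._expr([1, 3, 5, 7.0], list("abcd"))
        assert cna_expression_correlation(cna, expr).loc["g", "r_all"] == pytest.approx(1.0)

    def test_hand_computed_covariance(self):
        # r = 5.5 / sqrt(5 * 8.75) = 0.8315...
        cna = pd.DataFrame([[0, 1, 2, 3.0]], index=["g"], columns=list("abcd"))
        expr = self._expr([1, 3, 2, 5.0], list("abcd"))
        out = cna_expression_correlation(cna, expr)
        assert out.loc["g", "r_all"] == pytest.approx(5.5 / np.sqrt(5 * 8.75), abs=1e-9)

    def test_constant_cna_yields_na(self):
        cna = pd.DataFrame([[1, 1, 1, 1.0]], index=["g"], columns=list("abcd"))
        expr = self._expr([1, 3, 2, 5.0], list("abcd"))
        assert np.isnan(cna_expression_correlation(cna, expr).loc["g", "r_all"])

    def test_per_cohort_columns_present(self):
        cna = pd.DataFrame([[0, 1, 2, 3, 1, 2.0]], index=["g"], columns=list("abcdef"))
        expr = self._expr([1, 3, 2, 5, 2, 4.0], list("abcdef"))
        labels = pd.Series(["IN"] * 3 + ["MM"] * 3, index=list("abcdef"))
        out = cna_expression_correlation(cna, expr, labels)
        assert {"r_all", "r_IN", "r_MM"} <= set(out.columns)


class TestPathwayEnrichment:
    def test_hand_computed_hypergeometric_tail(self):
        # N=10, K=4, n=5, k=2 -> P(X >= 2) = 186/252
        background = [f"b{i}" for i in range(10)]
        collection = {"set1": set(background[:4])}
        sig = background[2:7]  # overlap with set1 = {b2, b3} -> k=2
        out = pathway_enrichment(sig, collection, background)
        assert out.loc["set1", "p"] == pytest.approx(186 / 252)
        assert out.loc["set1", "overlap"] == 2

    def test_empty_significant_list_p_one(self):
        background = [f"b{i}" for i in range(10)]
        out = pathway_enrichment([], {"s": set(background[:3])}, background)
        assert out["p"].eq(1.0).all()

    def test_genes_outside_background_excluded(self):
        background = ["a", "b", "c", "d"]
        out = pathway_enrichment(["a", "zzz"], {"s": {"a", "b"}}, background)
        # only "a" counted: P(X >= 1) with N=4, K=2, n=1 = 1/2
        assert out.loc["s", "p"] == pytest.approx(0.5)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            pathway_enrichment(["a"], {"s": {"a"}}, [])
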