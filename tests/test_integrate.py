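import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexmeth.core_io import DEGRecord, GeneModel, OrthologMap
from sexmeth.integrate import (
    ContingencyTable2x2,
    assign_proximal_genes,
    deg_enrichment,
    deg_filter,
    directional_association,
    hypergeom_overlap,
    ortholog_overlap_test,
    tss_distance_distribution,
)
from sexmeth.intervals import GenomicInterval


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def gene(gene_id, start, end, chrom="chr1", strand="+"):
    tss = start if strand == "+" else end
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                     start=start, end=end,
                     exons=[GenomicInterval(chrom, start, end, strand,
                                            gene_id)])


class TestAssignProximal:
    def test_3kb_upstream_assigned(self):
        g = gene("g", 50_000, 60_000)
        (a,) = assign_proximal_genes([iv(46_900, 47_200)], [g])
        assert a.gene_id == "g"
        assert a.feature == "upstream_1to5kb"

    def test_6kb_upstream_unassigned(self):
        g = gene("g", 50_000, 60_000)
        assert assign_proximal_genes([iv(43_700, 44_000)], [g]) == []

    def test_region_spanning_two_genes(self):
        a = gene("a", 10_000, 20_000)
        b = gene("b", 20_500, 30_000)
        out = assign_proximal_genes([iv(19_800, 20_100)], [a, b])
        assert {(x.gene_id, x.feature) for x in out} == {
            ("a", "exon"), ("b", "promoter")}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(10)
        genes = [gene(f"g{i}", int(s), int(s) + int(rng.integers(2000, 9000)),
                      strand=("+" if rng.random() < 0.5 else "-"))
                 for i, s in enumerate(rng.integers(10_000, 900_000, 20))]
        regions = [iv(int(s), int(s) + 300)
                   for s in rng.integers(0, 950_000, 100)]
        got = {(a.start, a.gene_id)
               for a in assign_proximal_genes(regions, genes)}
        expected = set()
        for r in regions:
            for g in genes:
                if g.strand == "+":
                    lo, hi = g.start - 5000, g.end
                else:
                    lo, hi = g.start, g.end + 5000
                if r.start < hi and max(lo, 0) < r.end:
                    expected.add((r.start, g.gene_id))
        assert got == expected


class TestDegFilter:
    def _recs(self, rows):
        return [DEGRecord(f"g{i}", fc, p, "chr1")
                for i, (fc, p) in enumerate(rows)]

    def test_lfc_boundary_strict(self):
        assert deg_filter(self._recs([(1.5, 0.01)])) == set()

    def test_included(self):
        assert deg_filter(self._recs([(-2.0, 0.01)])) == {"g0"}

    def test_padj_boundary_strict(self):
        assert deg_filter(self._recs([(2.0, 0.05)])) == set()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rows = [(float(rng.uniform(-4, 4)), float(rng.uniform(0, 1)))
                for _ in range(200)]
        got = deg_filter(self._recs(rows))
        expected = {f"g{i}" for i, (fc, p) in enumerate(rows)
                    if abs(fc) > 1.5 and p < 0.05}
        assert got == expected


class TestHypergeometric:
    def test_disjoint_sets(self):
        uni = {f"g{i}" for i in range(100)}
        res = deg_enrichment({"g1", "g2"}, {"g50", "g51"}, uni)
        assert res.observed == 0
        assert res.p_enrichment == pytest.approx(1.0, abs=1e-9)

    def test_saturation(self):
        uni = {f"g{i}" for i in range(50)}
        degs = {f"g{i}" for i in range(10)}
        res = deg_enrichment(uni, degs, uni)
        assert res.observed == len(degs)
        assert res.expected == pytest.approx(len(degs))

    def test_subset_violation(self):
        with pytest.raises(ValueError):
            deg_enrichment({"zz"}, set(), {"g1"})

    def test_paper_expected_value(self):
        res = hypergeom_overlap(1087, 2128, 15_212, 266)
        assert round(res.expected, 2) == 152.06

    @settings(deadline=None, max_examples=30)
    @given(st.integers(1, 60), st.integers(1, 60), st.integers(60, 200),
           st.integers(0, 2**31))
    def test_tail_matches_brute_force_sum(self, n1, n2, universe, seed):
        rng = np.random.default_rng(seed)
        observed = int(rng.integers(0, min(n1, n2) + 1))
        res = hypergeom_overlap(n1, n2, universe, observed)
        # brute-force tail over the hypergeometric pmf
        def pmf(k):
            return (math.comb(n1, k) * math.comb(universe - n1, n2 - k)
                    / math.comb(universe, n2)) if 0 <= n2 - k <= universe - n1 \
                else 0.0
        upper = sum(pmf(k) for k in range(observed, min(n1, n2) + 1))
        assert res.p_enrichment == pytest.approx(upper, rel=1e-9, abs=1e-12)
        assert res.expected == pytest.approx(n1 * n2 / universe)


class TestDirectionalAssociation:
    def test_paper_table_xxf_vs_xym(self):
        table = ContingencyTable2x2(42, 4, 1, 21)
        chi2, p = directional_association(table)
        assert p == pytest.approx(2.511e-11, rel=1e-3)

    def test_paper_table_xyf_vs_xym(self):
        table = ContingencyTable2x2(37, 2, 0, 9)
        chi2, p = directional_association(table)
        assert p == pytest.approx(1.478e-8, rel=1e-3)

    def test_balanced_table_floored(self):
        chi2, p = directional_association(ContingencyTable2x2(10, 10, 10, 10))
        assert chi2 == 0.0
        assert p == 1.0

    def test_invariant_under_double_swap(self):
        a = directional_association(ContingencyTable2x2(42, 4, 1, 21))
        b = directional_association(ContingencyTable2x2(21, 1, 4, 42))
        assert a == pytest.approx(b)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 5)


class TestTssDistance:
    def test_inside_region_zero(self):
        df = tss_distance_distribution([("chr1", 12_100)],
                                       [iv(12_000, 12_300)])
        assert df["distance"].iloc[0] == 0

    def test_distance_to_nearest(self):
        df = tss_distance_distribution([("chr1", 10_000)],
                                       [iv(12_000, 12_300)])
        assert df["distance"].iloc[0] == 2_000

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        sdmrs = [iv(int(s), int(s) + 300)
                 for s in rng.integers(0, 500_000, 30)]
        tss = [("chr1", int(p)) for p in rng.integers(1, 500_000, 50)]
        df = tss_distance_distribution(tss, sdmrs)
        for (_, pos), d in zip(tss, df["distance"]):
            best = min(
                0 if r.start <= pos - 1 < r.end
                else (r.start - pos if r.start >= pos
                      else pos - 1 - r.end)
                for r in sdmrs
            )
            assert d == max(0, best)

    def test_cdf_monotone(self):
        df = tss_distance_distribution(
            [("chr1", p) for p in (10, 5_000, 100_000)],
            [iv(0, 100)])
        ranked = df.sort_values("distance")
        assert ranked["cdf"].is_monotonic_increasing


def make_ortholog_map(n_autosomal, n_x):
    rows = [(f"m{i}", f"h{i}", "autosomal") for i in range(n_autosomal)]
    rows += [(f"mx{i}", f"hx{i}", "X") for i in range(n_x)]
    return OrthologMap(pd.DataFrame(
        rows, columns=["mouse_gene", "human_gene", "chrom_class"]))


class TestOrthologOverlap:
    def test_paper_x_expected(self):
        omap = make_ortholog_map(0, 567)
        mouse = {f"mx{i}" for i in range(403)}
        human = {f"hx{i}" for i in range(550)}
        res = ortholog_overlap_test(mouse, human, omap, "X")
        assert round(res.expected, 2) == 390.92

    def test_paper_autosomal_expected(self):
        omap = make_ortholog_map(15_212, 0)
        mouse = {f"m{i}" for i in range(313)}
        human = {f"h{i}" for i in range(361)}
        res = ortholog_overlap_test(mouse, human, omap, "autosomal")
        assert round(res.expected, 2) == 7.43

    def test_empty_set(self):
        omap = make_ortholog_map(100, 10)
        res = ortholog_overlap_test(set(), {"h1"}, omap, "autosomal")
        assert res.observed == 0
        assert res.expected == 0.0
        assert res.p_enrichment == 1.0

    def test_non_orthologs_ignored(self):
        omap = make_ortholog_map(10, 0)
        res = ortholog_overlap_test({"m0", "not_a_gene"}, {"h0"}, omap,
                                    "autosomal")
        assert res.n1 == 1
        assert res.observed == 1

    def test_bad_class(self):
        omap = make_ortholog_map(10, 0)
        with pytest.raises(ValueError):
            ortholog_overlap_test(set(), set(), omap, "Y")
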