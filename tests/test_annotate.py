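import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexmeth.annotate import (
    DISTANCE_BIN_EDGES,
    MatchedRegionError,
    _distance_bin,
    annotate_regions,
    build_cgi_geography,
    enrichment_call,
    generate_matched_random_regions,
    nearest_gene_distances,
    repeat_enrichment,
)
from sexmeth.core_io import GeneModel
from sexmeth.intervals import GenomicInterval, total_length
from sexmeth.simulate import EffectSpec, SimulationConfig, simulate_cohort

GENOME = {"chr1": 1_000_000}


def iv(start, end, chrom="chr1", label=""):
    return GenomicInterval(chrom, start, end, ".", label)


def simple_gene(gene_id, start, end, chrom="chr1", strand="+"):
    tss = start if strand == "+" else end
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                     start=start, end=end,
                     exons=[GenomicInterval(chrom, start, end, strand, gene_id)])


class TestCgiGeography:
    def test_interior_island(self):
        geo = build_cgi_geography([iv(100_000, 101_000)], GENOME)
        assert [(s.start, s.end) for s in geo.shores] == [
            (98_000, 100_000), (101_000, 103_000)]
        assert [(s.start, s.end) for s in geo.shelves] == [
            (96_000, 98_000), (103_000, 105_000)]

    def test_island_at_chromosome_start(self):
        geo = build_cgi_geography([iv(0, 500)], GENOME)
        assert [(s.start, s.end) for s in geo.shores] == [(500, 2_500)]
        assert [(s.start, s.end) for s in geo.shelves] == [(2_500, 4_500)]

    def test_nearby_islands_nearest_priority(self):
        # islands 3 kb apart: the whole gap is within 2 kb of one island or
        # the other, so it is all shore and no shelf appears between them
        geo = build_cgi_geography([iv(10_000, 11_000), iv(14_000, 15_000)],
                                  GENOME)
        between_shore = sum(
            max(0, min(s.end, 14_000) - max(s.start, 11_000))
            for s in geo.shores)
        assert between_shore == 3_000
        for sh in geo.shelves:
            assert sh.end <= 11_000 - 2000 + 1 or sh.start >= 14_000 + 2000 - 1 \
                or not (11_000 <= sh.start and sh.end <= 14_000)

    def test_out_of_bounds_island_rejected(self):
        with pytest.raises(ValueError):
            build_cgi_geography([iv(999_900, 1_000_200)], GENOME)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.tuples(st.integers(0, 180_000), st.integers(200, 2_000)),
        min_size=0, max_size=6,
    ))
    def test_partition_covers_genome(self, raw):
        genome = {"chr1": 200_000}
        islands = [iv(s, min(s + w, 200_000)) for s, w in raw
                   if min(s + w, 200_000) > s]
        geo = build_cgi_geography(islands, genome)
        pieces = (geo.islands + geo.shores + geo.shelves + geo.inter_cgi)
        assert total_length(pieces) == 200_000
        # disjointness: every base covered exactly once
        covered = np.zeros(200_000, dtype=np.int8)
        for p in pieces:
            covered[p.start:p.end] += 1
        assert (covered == 1).all()


class TestAnnotateRegions:
    def test_multi_label_exon_and_promoter(self):
        gene_a = simple_gene("a", 10_000, 20_000)
        gene_b = simple_gene("b", 15_500, 30_000)
        region = [iv(15_100, 15_300)]  # inside exon of a, <1kb upstream of b
        counts = annotate_regions(region, genes=[gene_a, gene_b])
        assert counts["genic:exon"] == 1
        assert counts["genic:promoter"] == 1
        assert counts["genic:intergenic"] == 0

    def test_nothing_overlapping(self):
        geo = build_cgi_geography([iv(500_000, 501_000)], GENOME)
        counts = annotate_regions([iv(100, 200)], cgi=geo,
                                  genes=[simple_gene("a", 700_000, 710_000)])
        assert counts["genic:intergenic"] == 1
        assert counts["cgi:inter_cgi"] == 1
        assert counts["cgi:island"] == 0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(4)
        genes = [simple_gene(f"g{i}", int(s), int(s) + 5_000)
                 for i, s in enumerate(rng.integers(0, 900_000, 15))]
        geo = build_cgi_geography(
            [iv(int(s), int(s) + 800) for s in rng.integers(0, 990_000, 10)],
            GENOME)
        regions = [iv(int(s), int(s) + 300)
                   for s in rng.integers(0, 990_000, 100)]
        counts = annotate_regions(regions, cgi=geo, genes=genes)

        def overlaps_any(r, ivs):
            return any(r.start < x.end and x.start < r.end
                       for x in ivs if x.chrom == r.chrom)

        for name, ivs in geo.categories().items():
            brute = sum(1 for r in regions if overlaps_any(r, ivs))
            assert counts[f"cgi:{name}"] == brute
        exon_ivs = [e for g in genes for e in g.exons]
        brute_exon = sum(1 for r in regions if overlaps_any(r, exon_ivs))
        assert counts["genic:exon"] == brute_exon


class TestMatchedRegions:
    GENES = [simple_gene("g1", 200_000, 250_000),
             simple_gene("g2", 600_000, 640_000)]

    def test_size_matches_query(self):
        query = [iv(100_000, 100_300), iv(300_000, 300_300)]
        out = generate_matched_random_regions(query, self.GENES, GENOME,
                                              seed=0)
        assert len(out) == len(query)

    def test_overlapping_queries_match_bin_zero(self):
        query = [iv(210_000, 210_300), iv(620_000, 620_300)]
        out = generate_matched_random_regions(query, self.GENES, GENOME,
                                              seed=1)
        for r in out:
            assert nearest_gene_distances([r], self.GENES)[0] == 0

    def test_bin_histogram_equality(self):
        rng = np.random.default_rng(7)
        query = [iv(int(s), int(s) + 300)
                 for s in rng.integers(0, 990_000, 40)]
        out = generate_matched_random_regions(query, self.GENES, GENOME,
                                              seed=2)
        qb = np.sort(_distance_bin(nearest_gene_distances(query, self.GENES)))
        ob = np.sort(_distance_bin(nearest_gene_distances(out, self.GENES)))
        np.testing.assert_array_equal(qb, ob)

    def test_deterministic_under_seed(self):
        query = [iv(100_000, 100_300)]
        a = generate_matched_random_regions(query, self.GENES, GENOME, seed=3)
        b = generate_matched_random_regions(query, self.GENES, GENOME, seed=3)
        assert a == b

    def test_query_chromosome_without_genes_raises(self):
        genes = [simple_gene("g", 0, 10_000)]
        query = [iv(400_000, 400_300, chrom="chr2")]
        with pytest.raises(MatchedRegionError):
            generate_matched_random_regions(
                query, genes, {"chr1": 10_000, "chr2": 500_000}, seed=0)

    def test_unsatisfiable_bin_names_bin(self):
        from sexmeth.annotate import _sample_regions_in_bins
        # genome saturated by one gene: the farthest distance bin can never
        # be produced by random sampling
        genes = [simple_gene("g", 0, 10_000)]
        with pytest.raises(MatchedRegionError, match="bin 4"):
            _sample_regions_in_bins(
                np.random.default_rng(0), {4: 1}, genes, {"chr1": 10_000},
                300, max_batches=5)


class TestEnrichmentCall:
    def test_strict_boundary(self):
        assert enrichment_call(996, 1000)
        assert not enrichment_call(995, 1000)

    def test_bad_incidence(self):
        with pytest.raises(ValueError):
            enrichment_call(1001, 1000)


def _repeat_cohort(seed):
    cfg = SimulationConfig.from_dict({
        "chroms": (("chr1", 3_000_000), ("chrX", 1_500_000)),
        "effects": ({"effect_class": "phenotype", "n_regions": 40},
                    {"effect_class": "x_dosage", "n_regions": 20}),
        "repeats": ({"family": "Alu", "n_elements": 800, "length": 300},
                    {"family": "L1", "n_elements": 800, "length": 300}),
        "repeat_bias": {"Alu": 3.0},
        "dispersion_rho": 0.01,
        "seed": seed,
    })
    return simulate_cohort(cfg)


class TestRepeatEnrichment:
    def test_null_queries_not_flagged(self):
        cohort = _repeat_cohort(31)
        genes = cohort.tracks["genes"]
        # queries drawn from the null generator itself
        rng = np.random.default_rng(12)
        queries = generate_matched_random_regions(
            [r.interval for r in cohort.truth.planted_regions][:30],
            genes, cohort.genome, seed=rng)
        enr = repeat_enrichment(queries, cohort.tracks["repeats"], genes,
                                cohort.genome, n_perm=400, seed=13)
        assert not enr["enriched"].any()
        mid = enr["incidence_over"] / 400
        assert ((mid > 0.01) & (mid < 0.99)).all()

    def test_planted_bias_recovered(self):
        cohort = _repeat_cohort(32)
        enr = repeat_enrichment(
            [r.interval for r in cohort.truth.planted_regions],
            cohort.tracks["repeats"], cohort.tracks["genes"], cohort.genome,
            n_perm=1000, seed=14)
        enr = enr.set_index("family")
        assert enr.loc["Alu", "enriched"]
        assert not enr.loc["L1", "enriched"]

    def test_deterministic(self):
        cohort = _repeat_cohort(33)
        args = ([r.interval for r in cohort.truth.planted_regions][:10],
                cohort.tracks["repeats"], cohort.tracks["genes"],
                cohort.genome)
        a = repeat_enrichment(*args, n_perm=100, seed=9)
        b = repeat_enrichment(*args, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_subfamily_level(self):
        cohort = _repeat_cohort(34)
        enr = repeat_enrichment(
            [r.interval for r in cohort.truth.planted_regions][:10],
            cohort.tracks["repeats"], cohort.tracks["genes"], cohort.genome,
            n_perm=50, seed=2, level="subfamily")
        assert set(enr["subfamily"]) == {"sub1", "sub2"}
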