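"""Region annotation and distance-matched permutation enrichment.

CGI geography partitions the genome into island / shore (2 kb flanks) /
shelf (next 2 kb) / inter-CGI, with overlapping flanks of nearby islands
resolved by distance (a flank base belongs to the nearer island's category,
which the distance construction yields automatically).  Genic and chromatin
annotation are multi-label frequency tables against a background set.

Repeat enrichment compares observed sDMR/repeat overlap counts to a null of
random 300 bp regions matched on distance-to-nearest-gene (log-spaced bins),
with the >995/1000 incidence rule for calling enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel
from .intervals import (
    GenomicInterval,
    IntervalIndex,
    NearestIntervalFinder,
    clip_to_genome,
    merge_intervals,
    subtract_intervals,
)

GENIC_CATEGORIES = (
    "upstream_1to5kb", "promoter", "5utr", "exon", "intron", "3utr",
    "intergenic",
)

#: distance-to-gene bins for matched random regions: 0 (overlapping),
#: (0, 1 kb], (1, 10 kb], (10, 100 kb], > 100 kb
DISTANCE_BIN_EDGES = (0, 1_000, 10_000, 100_000)


class MatchedRegionError(RuntimeError):
    """A distance bin could not be satisfied on the given genome."""


def enrichment_call(incidence: int, n_perm: int = 1000) -> bool:
    """Strict over-representation rule: incidence must exceed 99.5% of
    permutations (996/1000 is enriched, 995/1000 is not)."""
    if not (0 <= incidence <= n_perm):
        raise ValueError("incidence must lie in [0, n_perm]")
    return incidence > int(round(0.995 * n_perm))


@dataclass
class CgiGeography:
    islands: list[GenomicInterval]
    shores: list[GenomicInterval]
    shelves: list[GenomicInterval]
    inter_cgi: list[GenomicInterval]

    def categories(self) -> dict[str, list[GenomicInterval]]:
        return {
            "island": self.islands, "shore": self.shores,
            "shelf": self.shelves, "inter_cgi": self.inter_cgi,
        }


def build_cgi_geography(
    islands: Sequence[GenomicInterval], genome: dict[str, int]
) -> CgiGeography:
    """Island / shore / shelf / inter-CGI partition of the genome."""
    for iv in islands:
        if iv.chrom not in genome:
            raise ValueError(f"island on unknown chromosome {iv.chrom}")
        if iv.end > genome[iv.chrom]:
            raise ValueError(
                f"island [{iv.start},{iv.end}) exceeds {iv.chrom} length")
    whole = [GenomicInterval(c, 0, l) for c, l in genome.items() if l > 0]
    isl = clip_to_genome(merge_intervals(islands), genome) if islands else []
    shore_halo = clip_to_genome(
        [GenomicInterval(iv.chrom, max(0, iv.start - 2000), iv.end + 2000)
         for iv in isl], genome)
    shelf_halo = clip_to_genome(
        [GenomicInterval(iv.chrom, max(0, iv.start - 4000), iv.end + 4000)
         for iv in isl], genome)
    shores = subtract_intervals(shore_halo, isl) if isl else []
    shelves = subtract_intervals(shelf_halo, shore_halo) if isl else []
    inter = subtract_intervals(whole, shelf_halo) if isl else whole
    return CgiGeography(isl, shores, shelves, inter)


def gene_feature_tracks(
    genes: Sequence[GeneModel],
) -> dict[str, list[GenomicInterval]]:
    tracks: dict[str, list[GenomicInterval]] = {c: [] for c in GENIC_CATEGORIES
                                                if c != "intergenic"}
    for g in genes:
        if g.upstream is not None:
            tracks["upstream_1to5kb"].append(g.upstream)
        if g.promoter is not None:
            tracks["promoter"].append(g.promoter)
        tracks["5utr"].extend(g.utr5)
        tracks["exon"].extend(g.exons)
        tracks["intron"].extend(g.introns)
        tracks["3utr"].extend(g.utr3)
    return tracks


def annotate_regions(
    regions: Sequence[GenomicInterval],
    cgi: CgiGeography | None = None,
    genes: Sequence[GeneModel] | None = None,
    chromatin: Sequence[GenomicInterval] | None = None,
) -> pd.Series:
    """Multi-label annotation frequencies.

    Each region contributes one count to every category it overlaps by
    >= 1 bp; regions overlapping no genic feature count as intergenic.
    Returns a Series indexed by category name.
    """
    counts: dict[str, int] = {}

    def tally(name: str, index: IntervalIndex) -> np.ndarray:
        hit = np.zeros(len(regions), dtype=bool)
        for i, r in enumerate(regions):
            hit[i] = bool(index.overlaps_any(r.chrom, r.start, r.end))
        counts[name] = int(hit.sum())
        return hit

    if cgi is not None:
        for name, ivs in cgi.categories().items():
            tally(f"cgi:{name}", IntervalIndex(ivs))
    if genes is not None:
        any_genic = np.zeros(len(regions), dtype=bool)
        for name, ivs in gene_feature_tracks(genes).items():
            any_genic |= tally(f"genic:{name}", IntervalIndex(ivs))
        counts["genic:intergenic"] = int((~any_genic).sum())
    if chromatin is not None:
        labels = sorted({iv.label for iv in chromatin})
        for label in labels:
            tally(f"chromatin:{label}",
                  IntervalIndex([iv for iv in chromatin if iv.label == label]))
    return pd.Series(counts, dtype=int)


def annotation_table(
    region_sets: dict[str, Sequence[GenomicInterval]],
    background: Sequence[GenomicInterval],
    cgi: CgiGeography | None = None,
    genes: Sequence[GeneModel] | None = None,
    chromatin: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Per-comparison annotation frequencies with a background column."""
    cols = {"background": annotate_regions(background, cgi, genes, chromatin)}
    for name, regions in region_sets.items():
        cols[name] = annotate_regions(regions, cgi, genes, chromatin)
    return pd.DataFrame(cols).fillna(0).astype(int)


def _distance_bin(distance: np.ndarray) -> np.ndarray:
    """0 for overlap, then log-spaced distance bins 1..len(edges)."""
    return np.searchsorted(np.asarray(DISTANCE_BIN_EDGES), distance, side="left")


def nearest_gene_distances(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Distance from each region to the nearest gene body (0 if overlapping)."""
    finder = NearestIntervalFinder([g.body() for g in genes])
    out = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        out[i] = finder.distance(r.chrom, r.start, r.end)
    if (out < 0).any():
        raise MatchedRegionError(
            "some query regions lie on chromosomes with no genes")
    return out


def _sample_regions_in_bins(
    rng: np.random.Generator,
    need: dict[int, int],
    genes: Sequence[GeneModel],
    genome: dict[str, int],
    length: int,
    max_batches: int = 10_000,
) -> dict[int, np.ndarray]:
    """Uniform random fixed-length regions stratified by nearest-gene bin.

    Returns, per bin, an array of (chrom_index, start) rows; raises
    :class:`MatchedRegionError` if a bin stays unsatisfied after
    ``max_batches`` rounds of batched rejection sampling.
    """
    chroms = [c for c, l in genome.items() if l > length]
    if not chroms:
        raise MatchedRegionError("no chromosome longer than the region length")
    lengths = np.array([genome[c] - length for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    finder = NearestIntervalFinder([g.body() for g in genes])
    got: dict[int, list[np.ndarray]] = {b: [] for b in need}
    remaining = {b: n for b, n in need.items() if n > 0}
    total_needed = sum(remaining.values())
    batch = max(4096, 4 * total_needed)
    for _round in range(max_batches):
        if not remaining:
            break
        ci = rng.choice(len(chroms), size=batch, p=weights)
        starts = (rng.random(batch) * lengths[ci]).astype(np.int64)
        dist = np.empty(batch, dtype=np.int64)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if sel.any():
                dist[sel] = finder.distance(chrom, starts[sel],
                                            starts[sel] + length)
        dist = np.where(dist < 0, np.iinfo(np.int64).max // 2, dist)
        bins = _distance_bin(dist)
        for b in list(remaining):
            sel = np.flatnonzero(bins == b)[: remaining[b]]
            if len(sel):
                got[b].append(np.column_stack([ci[sel], starts[sel]]))
                remaining[b] -= len(sel)
                if remaining[b] == 0:
                    del remaining[b]
    if remaining:
        bad = min(remaining)
        raise MatchedRegionError(
            f"could not satisfy distance bin {bad} "
            f"(still missing {remaining[bad]} regions)"
        )
    return {
        b: (np.concatenate(parts) if parts
            else np.empty((0, 2), dtype=np.int64))
        for b, parts in got.items()
    }, chroms


def generate_matched_random_regions(
    query: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    genome: dict[str, int],
    length: int = 300,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """One random region per query, matched on nearest-gene distance bin."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if not query:
        return []
    bins = _distance_bin(nearest_gene_distances(query, genes))
    need = {int(b): int(n) for b, n in zip(*np.unique(bins, return_counts=True))}
    sampled, chroms = _sample_regions_in_bins(rng, need, genes, genome, length)
    cursor = {b: 0 for b in sampled}
    out = []
    for b in bins:
        row = sampled[int(b)][cursor[int(b)]]
        cursor[int(b)] += 1
        chrom = chroms[int(row[0])]
        out.append(GenomicInterval(chrom, int(row[1]), int(row[1]) + length))
    return out


class _FamilyCounter:
    """Counts (region, element) overlapping pairs per repeat label."""

    def __init__(self, repeats: pd.DataFrame, key: str):
        self.labels = sorted(repeats[key].unique())
        self._idx = {
            label: IntervalIndex([
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in repeats[repeats[key] == label].itertuples(index=False)
            ])
            for label in self.labels
        }

    def count(self, regions: Sequence[GenomicInterval]) -> dict[str, int]:
        out = {}
        for label, idx in self._idx.items():
            total = 0
            for r in regions:
                total += int(idx.count_overlaps(r.chrom, r.start, r.end))
            out[label] = total
        return out

    def count_arrays(
        self, chrom_arr: list[str], starts: np.ndarray, ends: np.ndarray,
        perm_ids: np.ndarray, n_perm: int,
    ) -> dict[str, np.ndarray]:
        """Per-permutation pair counts for a flat batch of regions."""
        out = {}
        chrom_arr = np.asarray(chrom_arr)
        for label, idx in self._idx.items():
            counts = np.zeros(len(starts), dtype=np.int64)
            for chrom in np.unique(chrom_arr):
                sel = chrom_arr == chrom
                counts[sel] = idx.count_overlaps(chrom, starts[sel], ends[sel])
            out[label] = np.bincount(perm_ids, weights=counts,
                                     minlength=n_perm).astype(np.int64)
        return out


def repeat_enrichment(
    sdmrs: Sequence[GenomicInterval],
    repeats: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    length: int = 300,
    level: str = "family",
    count_elements: bool = True,
) -> pd.DataFrame:
    """Distance-matched permutation test of repeat family over-representation.

    For each of ``n_perm`` permutations a fresh random region set, matched to
    the queries' nearest-gene distance-bin histogram, is generated and its
    overlap count per repeat label computed.  A label is enriched when the
    observed count exceeds the null in more than 99.5% of permutations
    (strictly more than 995/1000 at the default), and depleted symmetrically.

    ``count_elements=True`` counts (region, element) pairs; ``False`` counts
    each query region at most once per label.
    """
    if level not in ("family", "subfamily"):
        raise ValueError("level must be 'family' or 'subfamily'")
    rng = np.random.default_rng(seed)
    key = "family" if level == "family" else "subfamily"
    counter = _FamilyCounter(repeats, key)

    def observed_counts(regions):
        if count_elements:
            return counter.count(regions)
        out = {}
        for label, idx in counter._idx.items():
            out[label] = sum(
                1 for r in regions if idx.overlaps_any(r.chrom, r.start, r.end))
        return out

    observed = observed_counts(list(sdmrs))

    bins = _distance_bin(nearest_gene_distances(list(sdmrs), genes))
    bin_ids, bin_counts = np.unique(bins, return_counts=True)
    need = {int(b): int(n) * n_perm for b, n in zip(bin_ids, bin_counts)}
    sampled, chroms = _sample_regions_in_bins(rng, need, genes, genome, length)

    # flatten all permutations into one batch, tracking permutation ids
    all_rows = []
    all_perm = []
    for b, n in zip(bin_ids, bin_counts):
        rows = sampled[int(b)]
        perm = np.repeat(np.arange(n_perm), n)
        all_rows.append(rows)
        all_perm.append(perm)
    rows = np.concatenate(all_rows)
    perm_ids = np.concatenate(all_perm)
    chrom_arr = [chroms[int(k)] for k in rows[:, 0]]
    starts = rows[:, 1]
    ends = starts + length

    if count_elements:
        null = counter.count_arrays(chrom_arr, starts, ends, perm_ids, n_perm)
    else:
        null = {}
        chrom_np = np.asarray(chrom_arr)
        for label, idx in counter._idx.items():
            hits = np.zeros(len(starts), dtype=np.int64)
            for chrom in np.unique(chrom_np):
                sel = chrom_np == chrom
                hits[sel] = (idx.count_overlaps(chrom, starts[sel], ends[sel])
                             > 0).astype(np.int64)
            null[label] = np.bincount(perm_ids, weights=hits,
                                      minlength=n_perm).astype(np.int64)

    rows_out = []
    for label in counter.labels:
        nulls = null[label]
        over = int((observed[label] > nulls).sum())
        under = int((observed[label] < nulls).sum())
        rows_out.append({
            level: label,
            "observed": observed[label],
            "null_mean": float(nulls.mean()),
            "incidence_over": over,
            "incidence_under": under,
            "enriched": enrichment_call(over, n_perm),
            "depleted": enrichment_call(under, n_perm),
        })
    return pd.DataFrame(rows_out)
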