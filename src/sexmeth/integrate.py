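"""Methylation-expression integration and cross-species overlap tests.

Regions are assigned to every gene whose genic-plus-5-kb-upstream footprint
they overlap by >= 1 bp (intergenic regions stay unassigned).  Enrichment of
differentially expressed genes among region-proximal genes uses the
upper-tail hypergeometric test; the direction of the methylation-expression
association uses a continuity-corrected chi-square on a 2x2 table; ortholog
overlap between species runs the same hypergeometric machinery on the
ortholog-pair universe of the requested chromosome class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DEGRecord, GeneModel, OrthologMap
from .intervals import GenomicInterval, NearestIntervalFinder

#: feature priority when a region overlaps several features of one gene
FEATURE_PRIORITY = ("promoter", "5utr", "exon", "intron", "3utr",
                    "upstream_1to5kb")


@dataclass(frozen=True)
class ProximalGeneAssignment:
    chrom: str
    start: int
    end: int
    gene_id: str
    feature: str


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: methylation direction in the focal group (lower, higher);
    columns: expression direction (higher, lower)."""

    lower_meth_higher_expr: int
    lower_meth_lower_expr: int
    higher_meth_higher_expr: int
    higher_meth_lower_expr: int

    def __post_init__(self) -> None:
        for v in self.as_array().ravel():
            if v < 0:
                raise ValueError("contingency counts must be non-negative")
        if self.as_array().sum() == 0:
            raise ValueError("contingency table must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.array([
            [self.lower_meth_higher_expr, self.lower_meth_lower_expr],
            [self.higher_meth_higher_expr, self.higher_meth_lower_expr],
        ])


@dataclass(frozen=True)
class OverlapTestResult:
    n1: int
    n2: int
    universe: int
    observed: int
    expected: float
    p_enrichment: float  # upper tail P(X >= observed)
    p_depletion: float  # lower tail P(X <= observed)

    def __post_init__(self) -> None:
        if self.observed > min(self.n1, self.n2):
            raise ValueError("observed overlap exceeds the smaller set")


def _gene_features(gene: GeneModel) -> list[tuple[str, GenomicInterval]]:
    out: list[tuple[str, GenomicInterval]] = []
    if gene.promoter is not None:
        out.append(("promoter", gene.promoter))
    for iv in gene.utr5:
        out.append(("5utr", iv))
    for iv in gene.exons:
        out.append(("exon", iv))
    for iv in gene.introns:
        out.append(("intron", iv))
    for iv in gene.utr3:
        out.append(("3utr", iv))
    if gene.upstream is not None:
        out.append(("upstream_1to5kb", gene.upstream))
    return out


def assign_proximal_genes(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> list[ProximalGeneAssignment]:
    """Assign each region to every gene whose footprint it overlaps.

    The reported feature is the highest-priority overlapped feature of that
    gene (promoter > 5utr > exon > intron > 3utr > upstream).  Regions
    overlapping no footprint yield no assignment.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for r in regions:
        for g in by_chrom.get(r.chrom, []):
            fp = g.footprint()
            if not (r.start < fp.end and fp.start < r.end):
                continue
            feature = None
            for name, iv in sorted(
                _gene_features(g),
                key=lambda t: FEATURE_PRIORITY.index(t[0]),
            ):
                if r.start < iv.end and iv.start < r.end:
                    feature = name
                    break
            if feature is None:
                # overlap hit the footprint but no explicit feature interval
                # (gene body gap); treat as intron-like body overlap
                feature = "intron"
            out.append(ProximalGeneAssignment(r.chrom, r.start, r.end,
                                              g.gene_id, feature))
    return out


def deg_filter(
    degs: Iterable[DEGRecord],
    lfc_threshold: float = 1.5,
    padj_threshold: float = 0.05,
) -> set[str]:
    """Strictly thresholded DEG set: |log2fc| > lfc and padj < padj."""
    return {
        d.gene_id for d in degs
        if abs(d.log2fc) > lfc_threshold and d.padj < padj_threshold
    }


def hypergeom_overlap(n1: int, n2: int, universe: int,
                      observed: int) -> OverlapTestResult:
    """Hypergeometric overlap test; expected = n1 * n2 / universe."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    if n1 > universe or n2 > universe:
        raise ValueError("set sizes cannot exceed the universe")
    expected = n1 * n2 / universe
    rv = stats.hypergeom(universe, n1, n2)
    p_enr = float(rv.sf(observed - 1))  # P(X >= observed)
    p_dep = float(rv.cdf(observed))
    return OverlapTestResult(n1, n2, universe, observed, expected,
                             min(p_enr, 1.0), min(p_dep, 1.0))


def deg_enrichment(
    proximal_genes: set[str], degs: set[str], universe: set[str]
) -> OverlapTestResult:
    """Enrichment of DEGs among region-proximal genes (hypergeometric)."""
    if not degs <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    if not proximal_genes <= universe:
        raise ValueError("proximal gene set must be a subset of the universe")
    observed = len(proximal_genes & degs)
    return hypergeom_overlap(len(proximal_genes), len(degs), len(universe),
                             observed)


def directional_association(table: ContingencyTable2x2) -> tuple[float, float]:
    """Continuity-corrected chi-square (df=1, two-sided) on the 2x2 table.

    Returns (statistic, p).  A perfectly balanced table yields statistic 0
    and p = 1 after the correction floor.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(chi2), float(p)


def tss_distance_distribution(
    tss: Sequence[tuple[str, int]],
    sdmrs: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Unsigned distance from each TSS (1-based position) to the nearest
    region (0 if inside), with the empirical CDF over the list.

    Distance counts the bases strictly between the TSS and the region
    boundary (a TSS at 10,000 and a region starting at 0-based 12,000 are
    2,000 bp apart); a TSS immediately adjacent to a region is 0 bp away.
    """
    finder = NearestIntervalFinder(list(sdmrs))
    rows = []
    for chrom, pos in tss:
        d = finder.distance(chrom, pos - 1, pos)
        rows.append((chrom, pos, max(0, d - 1) if d > 0 else d))
    df = pd.DataFrame(rows, columns=["chrom", "tss", "distance"])
    if len(df):
        order = df["distance"].rank(method="max")
        df["cdf"] = order / len(df)
    else:
        df["cdf"] = pd.Series(dtype=float)
    return df


def ortholog_overlap_test(
    mouse_genes: set[str],
    human_genes: set[str],
    orthologs: OrthologMap,
    chrom_class: str,
) -> OverlapTestResult:
    """Mouse-human set overlap on the ortholog universe of one class.

    Both input sets are mapped through the ortholog pairs of the requested
    class; the universe is the pair count of that class.
    """
    if chrom_class not in ("autosomal", "X"):
        raise ValueError("chrom_class must be 'autosomal' or 'X'")
    pairs = orthologs.subset(chrom_class)
    universe = len(pairs)
    if universe == 0:
        raise ValueError(f"no ortholog pairs of class {chrom_class!r}")
    mouse_hit = pairs["mouse_gene"].isin(mouse_genes)
    human_hit = pairs["human_gene"].isin(human_genes)
    n1 = int(mouse_hit.sum())
    n2 = int(human_hit.sum())
    if n1 == 0 or n2 == 0:
        return OverlapTestResult(n1, n2, universe, 0, 0.0, 1.0, 1.0)
    observed = int((mouse_hit & human_hit).sum())
    return hypergeom_overlap(n1, n2, universe, observed)
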