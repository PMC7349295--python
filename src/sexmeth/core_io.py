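"""Readers/writers for on-disk formats and pre-call filtering.

Formats handled here:

* per-CpG call report: TSV ``chrom  pos  meth_count  total_count`` with an
  optional header, gzip-transparent, positions 1-based;
* BED3/BED6(+label) annotation tracks, 0-based half-open;
* gene models as BED12 or minimal GTF (promoter/upstream derived from TSS
  and strand);
* differential-expression tables and mouse-human ortholog maps as TSV.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, merge_intervals

KNOWN_GROUPS = ("XX.F", "XY.F", "XY.M", "XO.F", "XXPaf.F")

#: group -> (phenotypic male, number of X chromosomes, carries Y)
GROUP_ATTRS: dict[str, dict[str, object]] = {
    "XX.F": {"male": False, "n_x": 2, "has_y": False},
    "XY.F": {"male": False, "n_x": 1, "has_y": True},
    "XY.M": {"male": True, "n_x": 1, "has_y": True},
    "XO.F": {"male": False, "n_x": 1, "has_y": False},
    "XXPaf.F": {"male": False, "n_x": 2, "has_y": False},
}

SITE_COLUMNS = ["chrom", "pos", "meth", "total"]


class ParseError(ValueError):
    """Malformed row in an input file; message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (counts, ordering, duplicates)."""


@dataclass
class MethylomeSample:
    """One sample's per-CpG methylated/total counts.

    ``sites`` is a DataFrame with columns chrom, pos (1-based), meth, total,
    sorted by (chrom, pos) and free of duplicate positions.
    """

    sample_id: str
    group: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites
        if list(df.columns) != SITE_COLUMNS:
            raise ValidationError(f"site columns must be {SITE_COLUMNS}")
        if len(df):
            if (df["meth"] > df["total"]).any():
                bad = df.index[(df["meth"] > df["total"])][0]
                raise ValidationError(
                    f"meth_count > total_count at row {bad} "
                    f"({df.loc[bad, 'chrom']}:{df.loc[bad, 'pos']})"
                )
            if (df["total"] <= 0).any():
                raise ValidationError("total_count must be positive at every site")
            if (df["pos"] <= 0).any():
                raise ValidationError("positions are 1-based and must be positive")
            key = df[["chrom", "pos"]]
            if key.duplicated().any():
                dup = key[key.duplicated()].iloc[0]
                raise ValidationError(
                    f"duplicate position {dup['chrom']}:{dup['pos']} "
                    f"in sample {self.sample_id}"
                )
            sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort")
            if not (sorted_df.index == df.index).all():
                self.sites = sorted_df.reset_index(drop=True)
            else:
                self.sites = df.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def levels(self) -> pd.Series:
        """Per-site methylation level meth/total, in [0, 1]."""
        return self.sites["meth"] / self.sites["total"]

    def _replace_sites(self, df: pd.DataFrame) -> "MethylomeSample":
        return MethylomeSample(self.sample_id, self.group, df.reset_index(drop=True))


@dataclass
class GeneModel:
    """A gene with strand-aware promoter/upstream windows and exon structure.

    Promoter is the <1 kb window upstream of the TSS; ``upstream`` the 1-5 kb
    window; the two abut exactly at 1 kb from the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based coordinate of the transcription start
    start: int
    end: int
    promoter: GenomicInterval | None = None
    upstream: GenomicInterval | None = None
    utr5: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.promoter is None or self.upstream is None:
            self.promoter, self.upstream = derive_flanks(
                self.chrom, self.tss, self.strand
            )
        for iv in self.feature_intervals():
            if iv.chrom != self.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: interval on {iv.chrom} != {self.chrom}"
                )

    def feature_intervals(self) -> list[GenomicInterval]:
        out = []
        if self.promoter is not None:
            out.append(self.promoter)
        if self.upstream is not None:
            out.append(self.upstream)
        out.extend(self.utr5 + self.exons + self.introns + self.utr3)
        return out

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.gene_id)

    def footprint(self) -> GenomicInterval:
        """Gene body plus the 5 kb upstream window, as one interval."""
        if self.strand == "+":
            lo = self.upstream.start if self.upstream else self.start
            return GenomicInterval(self.chrom, min(lo, self.start), self.end,
                                   self.strand, self.gene_id)
        hi = self.upstream.end if self.upstream else self.end
        return GenomicInterval(self.chrom, self.start, max(hi, self.end),
                               self.strand, self.gene_id)


def derive_flanks(
    chrom: str, tss: int, strand: str
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Promoter (<1 kb) and upstream (1-5 kb) windows from TSS and strand.

    Truncated at position 0; an entirely out-of-bounds window becomes None.
    """
    if strand == "+":
        prom = (max(0, tss - 1000), tss)
        ups = (max(0, tss - 5000), max(0, tss - 1000))
    else:
        prom = (tss, tss + 1000)
        ups = (tss + 1000, tss + 5000)
    prom_iv = GenomicInterval(chrom, *prom) if prom[1] > prom[0] else None
    ups_iv = GenomicInterval(chrom, *ups) if ups[1] > ups[0] else None
    return prom_iv, ups_iv


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    padj: float
    chrom: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id}: padj {self.padj} outside [0, 1]"
            )


@dataclass
class OrthologMap:
    """Mouse-human ortholog pairs, each labeled autosomal or X."""

    pairs: pd.DataFrame  # columns mouse_gene, human_gene, chrom_class

    def __post_init__(self) -> None:
        required = ["mouse_gene", "human_gene", "chrom_class"]
        if list(self.pairs.columns) != required:
            raise ValidationError(f"ortholog map columns must be {required}")
        bad = set(self.pairs["chrom_class"]) - {"autosomal", "X"}
        if bad:
            raise ValidationError(f"unknown chrom_class values: {sorted(bad)}")

    def counts(self) -> tuple[int, int]:
        vc = self.pairs["chrom_class"].value_counts()
        return int(vc.get("autosomal", 0)), int(vc.get("X", 0))

    def subset(self, chrom_class: str) -> pd.DataFrame:
        return self.pairs[self.pairs["chrom_class"] == chrom_class]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cpg_report(path, sample_id: str, group: str) -> MethylomeSample:
    """Read a per-CpG call report into a validated :class:`MethylomeSample`."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                pos, meth, total = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: non-integer field in {fields[1:4]}"
                ) from None
            rows.append((fields[0], pos, meth, total))
    if rows:
        df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    else:
        df = pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
             "meth": pd.Series(dtype=np.int64), "total": pd.Series(dtype=np.int64)}
        )
    return MethylomeSample(sample_id, group, df)


def write_cpg_report(sample: MethylomeSample, path, header: bool = True) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        if header:
            fh.write("chrom\tpos\tmeth_count\ttotal_count\n")
        for row in sample.sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.meth}\t{row.total}\n")


def mask_snps(
    sample: MethylomeSample, snps: Sequence[GenomicInterval]
) -> MethylomeSample:
    """Drop every site whose 1-based position falls inside a SNP interval."""
    if not snps:
        return sample
    index = IntervalIndex(snps)
    keep = np.ones(sample.n_sites, dtype=bool)
    for chrom, sub in sample.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        hit = index.count_overlaps(chrom, pos - 1, pos) > 0
        keep[sub.index.to_numpy()] = ~hit
    return sample._replace_sites(sample.sites[keep])


def filter_coverage(
    sample: MethylomeSample, min_depth: int, max_depth: int
) -> MethylomeSample:
    """Retain sites with min_depth <= total <= max_depth (both inclusive)."""
    if min_depth <= 0:
        raise ValueError(f"min_depth must be positive, got {min_depth}")
    if min_depth > max_depth:
        raise ValueError(f"min_depth {min_depth} > max_depth {max_depth}")
    total = sample.sites["total"]
    keep = (total >= min_depth) & (total <= max_depth)
    return sample._replace_sites(sample.sites[keep])


def read_bed(path, labeled: bool = False) -> list[GenomicInterval]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            label = fields[3] if len(fields) > 3 else ""
            if labeled and not label:
                raise ParseError(f"{path}: line {lineno}: missing label column")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, label))
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_repeat_track(path) -> pd.DataFrame:
    """RepeatMasker-style BED: chrom, start, end, family, subfamily."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: repeat track needs 5 columns"
                )
            rows.append(
                (fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4])
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "family", "subfamily"]
    )


def _bed12_to_gene(fields: Sequence[str], where: str) -> GeneModel:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    gene_id = fields[3]
    strand = fields[5]
    thick_s, thick_e = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{where}: block count mismatch for {gene_id}")
    exons = [
        GenomicInterval(chrom, start + off, start + off + size, strand, gene_id)
        for off, size in zip(offsets, sizes)
    ]
    introns = [
        GenomicInterval(chrom, exons[i].end, exons[i + 1].start, strand, gene_id)
        for i in range(len(exons) - 1)
        if exons[i + 1].start > exons[i].end
    ]
    utr5: list[GenomicInterval] = []
    utr3: list[GenomicInterval] = []
    if thick_e > thick_s:  # coding: split exon parts outside the CDS into UTRs
        for ex in exons:
            if ex.start < thick_s:
                left = GenomicInterval(chrom, ex.start, min(ex.end, thick_s),
                                       strand, gene_id)
                (utr5 if strand == "+" else utr3).append(left)
            if ex.end > thick_e:
                right = GenomicInterval(chrom, max(ex.start, thick_e), ex.end,
                                        strand, gene_id)
                (utr3 if strand == "+" else utr5).append(right)
    tss = start if strand == "+" else end
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
        start=start, end=end, exons=exons, introns=introns,
        utr5=utr5, utr3=utr3,
    )


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED12 or minimal GTF (by extension)."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    if name.endswith((".gtf", ".gff")):
        return _read_gtf_genes(path)
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: gene models need BED12 (12 columns)"
                )
            genes.append(_bed12_to_gene(fields, f"{path}: line {lineno}"))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def _read_gtf_genes(path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id")
            rec = spans.setdefault(
                gid, {"chrom": chrom, "strand": strand, "start": None,
                      "end": None, "exons": []}
            )
            s0, e0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature == "gene":
                rec["start"], rec["end"] = s0, e0
            elif feature == "exon":
                rec["exons"].append(
                    GenomicInterval(chrom, s0, e0, strand, gid)
                )
    genes = []
    for gid, rec in spans.items():
        exons = sorted(rec["exons"], key=lambda iv: iv.start)
        start = rec["start"] if rec["start"] is not None else exons[0].start
        end = rec["end"] if rec["end"] is not None else exons[-1].end
        if not exons:
            exons = [GenomicInterval(rec["chrom"], start, end, rec["strand"], gid)]
        introns = [
            GenomicInterval(rec["chrom"], exons[i].end, exons[i + 1].start,
                            rec["strand"], gid)
            for i in range(len(exons) - 1)
            if exons[i + 1].start > exons[i].end
        ]
        tss = start if rec["strand"] == "+" else end
        genes.append(GeneModel(
            gene_id=gid, chrom=rec["chrom"], strand=rec["strand"], tss=tss,
            start=start, end=end, exons=exons, introns=introns,
        ))
    return genes


def read_deg_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj", "chrom"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: DEG table needs columns {sorted(required)}")
    return [
        DEGRecord(str(r.gene_id), float(r.log2fc), float(r.padj), str(r.chrom))
        for r in df.itertuples(index=False)
    ]


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    required = ["mouse_gene", "human_gene", "chrom_class"]
    if list(df.columns) != required:
        raise ParseError(f"{path}: ortholog map needs columns {required}")
    return OrthologMap(df)


_TRACK_READERS = {
    "bed": lambda p: read_bed(p, labeled=False),
    "bed_labeled": lambda p: read_bed(p, labeled=True),
    "repeats": read_repeat_track,
    "gene_models": read_gene_models,
    "deg_table": read_deg_table,
    "ortholog_map": read_ortholog_map,
}


def read_track(path, kind: str):
    """Dispatching reader for annotation and table inputs."""
    try:
        reader = _TRACK_READERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown track kind {kind!r}; expected one of {sorted(_TRACK_READERS)}"
        ) from None
    return reader(path)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            if iv.label or iv.strand != ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            exons = sorted(g.exons, key=lambda iv: iv.start) or [g.body()]
            sizes = ",".join(str(len(e)) for e in exons)
            offsets = ",".join(str(e.start - g.start) for e in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )
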