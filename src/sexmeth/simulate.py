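"""Synthetic five-group WGBS-like cohort generator.

Generates per-sample per-CpG counts with planted effect regions in three
classes (sex phenotype, X dosage, Y linkage), coupled expression effects,
annotation tracks, and a ground-truth table for recovery testing.  All
randomness flows from ``SimulationConfig.seed``.

Effect classes map onto group attributes: phenotype effects shift
phenotypic males (XY.M); X-dosage effects shift two-X groups (XX.F and
XXPaf.F); Y-linked effects shift Y-carriers (XY.M and XY.F).  chrY sites
exist only in Y-carrier samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEGRecord,
    GROUP_ATTRS,
    GeneModel,
    MethylomeSample,
    SITE_COLUMNS,
    write_bed,
    write_cpg_report,
    write_gene_models_bed12,
)
from .intervals import GenomicInterval

EFFECT_CLASSES = ("phenotype", "x_dosage", "y_linked")

#: which groups an effect class shifts
def group_affected(effect_class: str, group: str) -> bool:
    attrs = GROUP_ATTRS[group]
    if effect_class == "phenotype":
        return bool(attrs["male"])
    if effect_class == "x_dosage":
        return attrs["n_x"] == 2
    if effect_class == "y_linked":
        return bool(attrs["has_y"])
    raise ValueError(f"unknown effect class {effect_class!r}")


DEFAULT_CHROMATIN_STATES = (
    "Enh", "EnhLo", "EnhPois", "HetCons", "HetFac", "Quies", "TssA",
    "TssAFlnk", "TssBiv", "Tx",
)


@dataclass
class EffectSpec:
    """A batch of planted regions of one effect class."""

    effect_class: str
    n_regions: int
    width: int = 300
    delta: float = 0.30
    sign: int = -1
    n_cpg: int = 6
    chroms: tuple[str, ...] | None = None  # default chosen per class

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class RepeatFamilySpec:
    family: str
    n_elements: int = 300
    length: int = 300
    subfamilies: tuple[str, ...] = ("sub1", "sub2")


@dataclass
class ExpressionConfig:
    n_background_genes: int = 40
    coupling_prob: float = 0.9
    lfc_mean: float = 2.5
    lfc_sd: float = 0.4
    null_lfc_sd: float = 0.3


@dataclass
class SimulationConfig:
    chroms: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000), ("chrX", 1_500_000), ("chrY", 300_000),
    )
    cpg_per_kb: float = 10.0
    island_cpg_per_kb: float = 80.0
    n_islands: int = 40
    island_width: int = 800
    groups: dict[str, int] = field(default_factory=lambda: {
        "XX.F": 3, "XY.F": 3, "XY.M": 3, "XO.F": 3, "XXPaf.F": 2,
    })
    coverage_mean: float = 20.0
    island_level: float = 0.10
    background_level: float = 0.85
    dispersion_rho: float = 0.05
    paf_rho_multiplier: float = 1.0  # 2.0 emulates mixed-background variance
    missing_rate: float = 0.05
    effects: tuple[EffectSpec, ...] = ()
    effect_margin: int = 300  # CpG-free flank around planted regions
    repeats: tuple[RepeatFamilySpec, ...] = ()
    repeat_bias: dict[str, float] = field(default_factory=dict)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, n in self.groups.items():
            if grp not in GROUP_ATTRS:
                raise ValueError(f"unknown group {grp!r}")
            if n < 2:
                raise ValueError(f"group {grp}: replicate count must be >= 2")
        names = [c[0] for c in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for fam, mult in self.repeat_bias.items():
            if mult < 0:
                raise ValueError(f"repeat bias for {fam} must be >= 0")

    @property
    def genome(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def autosomes(self) -> list[str]:
        return [c for c, _ in self.chroms if c not in ("chrX", "chrY")]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "chroms" in d:
            d["chroms"] = tuple((str(c), int(l)) for c, l in d["chroms"])
        if "effects" in d:
            d["effects"] = tuple(
                e if isinstance(e, EffectSpec) else EffectSpec(**e)
                for e in d["effects"]
            )
        if "repeats" in d:
            d["repeats"] = tuple(
                r if isinstance(r, RepeatFamilySpec) else RepeatFamilySpec(**r)
                for r in d["repeats"]
            )
        if "expression" in d and not isinstance(d["expression"], ExpressionConfig):
            d["expression"] = ExpressionConfig(**d["expression"])
        return cls(**d)


@dataclass
class PlantedRegion:
    interval: GenomicInterval
    effect_class: str
    delta: float
    sign: int


@dataclass
class TruthSet:
    """Ground truth emitted by the simulator, for recovery testing."""

    planted_regions: list[PlantedRegion]
    deg_truth: pd.DataFrame  # gene_id, comparison, log2fc, effect_class
    repeat_bias: dict[str, float]
    clip_warnings: int = 0

    def regions_of(self, effect_class: str) -> list[PlantedRegion]:
        return [r for r in self.planted_regions if r.effect_class == effect_class]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.interval.chrom, r.interval.start, r.interval.end,
                 r.effect_class, r.delta, r.sign)
                for r in self.planted_regions
            ],
            columns=["chrom", "start", "end", "effect_class", "delta", "sign"],
        )


@dataclass
class Cohort:
    samples: list[MethylomeSample]
    truth: TruthSet
    tracks: dict[str, object]
    deg_tables: dict[str, list[DEGRecord]]
    genome: dict[str, int]
    config: SimulationConfig

    def samples_of(self, group: str) -> list[MethylomeSample]:
        return [s for s in self.samples if s.group == group]


#: default comparisons (baseline first, per the study's convention)
DEFAULT_COMPARISONS = (
    ("XX.F_vs_XY.M", "XX.F", "XY.M"),
    ("XY.F_vs_XY.M", "XY.F", "XY.M"),
    ("XX.F_vs_XY.F", "XX.F", "XY.F"),
    ("XXPaf.F_vs_XO.F", "XXPaf.F", "XO.F"),
)


def _place_regions(
    rng: np.random.Generator,
    spec: EffectSpec,
    allowed_chroms: Sequence[str],
    genome: dict[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int,
) -> list[PlantedRegion]:
    lengths = np.array([genome[c] for c in allowed_chroms], dtype=float)
    placed = []
    for _ in range(spec.n_regions):
        for _attempt in range(10_000):
            chrom = allowed_chroms[rng.choice(len(allowed_chroms), p=lengths / lengths.sum())]
            start = int(rng.integers(margin, genome[chrom] - spec.width - margin))
            end = start + spec.width
            clash = any(
                start - margin < e and s < end + margin
                for s, e in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(PlantedRegion(
                    GenomicInterval(chrom, start, end, ".", spec.effect_class),
                    spec.effect_class, spec.delta, spec.sign,
                ))
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_regions} {spec.effect_class} regions; "
                "genome too small for the requested margin"
            )
    return placed


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    depth = rng.poisson(lam, size=size)
    zeros = depth == 0
    while zeros.any():
        depth[zeros] = rng.poisson(lam, size=int(zeros.sum()))
        zeros = depth == 0
    return depth


def _beta_binomial(
    rng: np.random.Generator, depth: np.ndarray, mu: np.ndarray, rho: float
) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(depth, mu)
    conc = (1.0 - rho) / rho
    p = rng.beta(np.maximum(mu * conc, 1e-9), np.maximum((1.0 - mu) * conc, 1e-9))
    return rng.binomial(depth, p)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full cohort; identical seeds give identical outputs."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome

    # 1. plant effect regions (non-overlapping across classes, with margin)
    occupied: dict[str, list[tuple[int, int]]] = {}
    planted: list[PlantedRegion] = []
    default_chroms = {
        "phenotype": tuple(config.autosomes),
        "x_dosage": ("chrX",) if "chrX" in genome else tuple(config.autosomes),
        "y_linked": tuple(config.autosomes),
    }
    for spec in config.effects:
        allowed = spec.chroms or default_chroms[spec.effect_class]
        allowed = [c for c in allowed if c in genome]
        if not allowed:
            raise ValueError(f"no usable chromosome for {spec.effect_class} effects")
        planted.extend(
            _place_regions(rng, spec, allowed, genome, occupied, config.effect_margin)
        )

    # 2. CpG islands, clear of planted regions
    islands: list[GenomicInterval] = []
    island_occupied = {c: list(v) for c, v in occupied.items()}
    chrom_names = [c for c, _ in config.chroms]
    lengths = np.array([genome[c] for c in chrom_names], dtype=float)
    for _ in range(config.n_islands):
        for _attempt in range(10_000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=lengths / lengths.sum())]
            if genome[chrom] <= config.island_width + 2 * config.effect_margin:
                continue
            start = int(rng.integers(0, genome[chrom] - config.island_width))
            end = start + config.island_width
            clash = any(
                start - config.effect_margin < e and s < end + config.effect_margin
                for s, e in island_occupied.get(chrom, [])
            )
            if not clash:
                island_occupied.setdefault(chrom, []).append((start, end))
                islands.append(GenomicInterval(chrom, start, end, ".", "CGI"))
                break
    islands.sort(key=lambda iv: (iv.chrom, iv.start))

    # 3. CpG positions (1-based) and per-site baseline methylation
    site_chrom: list[str] = []
    site_pos: list[np.ndarray] = []
    site_mu: list[np.ndarray] = []
    for chrom, length in config.chroms:
        pieces_pos = []
        pieces_mu = []
        # background CpGs, excluding islands and planted regions (+margin)
        n_bg = rng.poisson(config.cpg_per_kb * length / 1000.0)
        pos = rng.integers(1, length + 1, size=n_bg)
        exclude = np.zeros(len(pos), dtype=bool)
        for s, e in occupied.get(chrom, []):
            exclude |= (pos - 1 >= s - config.effect_margin) & (
                pos - 1 < e + config.effect_margin)
        for iv in islands:
            if iv.chrom == chrom:
                exclude |= (pos - 1 >= iv.start) & (pos - 1 < iv.end)
        pos = pos[~exclude]
        pieces_pos.append(pos)
        pieces_mu.append(np.full(len(pos), config.background_level))
        # island CpGs
        for iv in islands:
            if iv.chrom != chrom:
                continue
            n_isl = rng.poisson(config.island_cpg_per_kb * len(iv) / 1000.0)
            p = rng.integers(iv.start + 1, iv.end + 1, size=n_isl)
            pieces_pos.append(p)
            pieces_mu.append(np.full(len(p), config.island_level))
        # planted-region CpGs: evenly spread with jitter so the region span
        # is covered by observable sites
        for region in planted:
            if region.interval.chrom != chrom:
                continue
            spec_n = next(
                s.n_cpg for s in config.effects
                if s.effect_class == region.effect_class
            )
            width = len(region.interval)
            centers = region.interval.start + (
                width * (np.arange(spec_n) + 0.5) / spec_n
            )
            jitter = rng.integers(
                -max(1, width // (4 * spec_n)), max(1, width // (4 * spec_n)) + 1,
                size=spec_n,
            )
            p = np.clip(
                np.round(centers).astype(np.int64) + jitter,
                region.interval.start + 1, region.interval.end,
            )
            pieces_pos.append(p.astype(np.int64))
            pieces_mu.append(np.full(spec_n, config.background_level))
        pos_all = np.concatenate(pieces_pos)
        mu_all = np.concatenate(pieces_mu)
        order = np.argsort(pos_all, kind="stable")
        pos_all, mu_all = pos_all[order], mu_all[order]
        keep = np.ones(len(pos_all), dtype=bool)
        keep[1:] = np.diff(pos_all) > 0  # dedupe
        site_chrom.append(chrom)
        site_pos.append(pos_all[keep])
        site_mu.append(mu_all[keep])

    # 4. per-group mu with planted shifts
    clip_count = 0
    group_mu: dict[str, list[np.ndarray]] = {}
    for group in config.groups:
        per_chrom = []
        for ci, chrom in enumerate(site_chrom):
            mu = site_mu[ci].copy()
            for region in planted:
                if region.interval.chrom != chrom:
                    continue
                if not group_affected(region.effect_class, group):
                    continue
                inside = (site_pos[ci] - 1 >= region.interval.start) & (
                    site_pos[ci] - 1 < region.interval.end)
                mu[inside] += region.delta * region.sign
            low, high = 0.02, 0.98
            n_clip = int(((mu < low) | (mu > high)).sum())
            if n_clip:
                clip_count += n_clip
            per_chrom.append(np.clip(mu, low, high))
        group_mu[group] = per_chrom
    if clip_count:
        warnings.warn(
            f"{clip_count} planted site means clipped to [0.02, 0.98]",
            stacklevel=2,
        )

    # 5. draw counts per sample
    samples: list[MethylomeSample] = []
    for group in sorted(config.groups):
        rho = config.dispersion_rho
        if group == "XXPaf.F":
            rho *= config.paf_rho_multiplier
        has_y = bool(GROUP_ATTRS[group]["has_y"])
        for rep in range(config.groups[group]):
            frames = []
            for ci, chrom in enumerate(site_chrom):
                if chrom == "chrY" and not has_y:
                    continue
                pos = site_pos[ci]
                mu = group_mu[group][ci]
                depth = _truncated_poisson(rng, config.coverage_mean, len(pos))
                meth = _beta_binomial(rng, depth, mu, rho)
                keep = rng.random(len(pos)) >= config.missing_rate
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos[keep],
                    "meth": meth[keep], "total": depth[keep],
                }))
            df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=SITE_COLUMNS)
            df = df[SITE_COLUMNS].astype(
                {"pos": np.int64, "meth": np.int64, "total": np.int64})
            samples.append(MethylomeSample(f"{group}_{rep + 1}", group, df))

    # 6. genes: one coupled gene downstream of each phenotype region, plus
    # background genes placed clear of planted regions
    genes: list[GeneModel] = []
    coupled: list[tuple[GeneModel, PlantedRegion]] = []
    gene_i = 0
    for region in planted:
        if region.effect_class != "phenotype":
            continue
        gene_i += 1
        tss = region.interval.end + int(rng.integers(200, 2000))
        length = int(rng.integers(2000, 6000))
        end = min(tss + length, genome[region.interval.chrom])
        if end - tss < 500:
            continue
        g = GeneModel(
            gene_id=f"gene{gene_i:04d}", chrom=region.interval.chrom,
            strand="+", tss=tss, start=tss, end=end,
            exons=[GenomicInterval(region.interval.chrom, tss, end, "+",
                                   f"gene{gene_i:04d}")],
        )
        genes.append(g)
        coupled.append((g, region))
    for _ in range(config.expression.n_background_genes):
        gene_i += 1
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))]
        length = int(rng.integers(2000, 8000))
        if genome[chrom] <= length + 1:
            continue
        start = int(rng.integers(0, genome[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + length
        gid = f"gene{gene_i:04d}"
        genes.append(GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, tss=tss,
            start=start, end=start + length,
            exons=[GenomicInterval(chrom, start, start + length, strand, gid)],
        ))

    # 7. expression truth and per-comparison DEG tables
    truth_rows = []
    deg_tables: dict[str, list[DEGRecord]] = {}
    for comp_name, baseline, other in DEFAULT_COMPARISONS:
        if baseline not in config.groups or other not in config.groups:
            continue
        records = []
        coupled_here: dict[str, float] = {}
        for g, region in coupled:
            affected_b = group_affected(region.effect_class, baseline)
            affected_o = group_affected(region.effect_class, other)
            if affected_b == affected_o:
                continue
            if rng.random() >= config.expression.coupling_prob:
                continue
            meth_sign_other = region.sign if affected_o else -region.sign
            lfc_sign = -meth_sign_other  # inverse methylation-expression coupling
            lfc = lfc_sign * rng.normal(
                config.expression.lfc_mean, config.expression.lfc_sd)
            coupled_here[g.gene_id] = lfc
            truth_rows.append((g.gene_id, comp_name, lfc, region.effect_class))
        for g in genes:
            if g.gene_id in coupled_here:
                lfc = coupled_here[g.gene_id] + rng.normal(0, 0.1)
                padj = float(rng.uniform(0, 1e-4))
            else:
                lfc = float(rng.normal(0, config.expression.null_lfc_sd))
                padj = float(rng.uniform(0.05, 1.0))
            records.append(DEGRecord(g.gene_id, float(lfc), padj, g.chrom))
        deg_tables[comp_name] = records
    deg_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "comparison", "log2fc", "effect_class"])

    truth = TruthSet(planted, deg_truth, dict(config.repeat_bias), clip_count)
    tracks: dict[str, object] = {
        "cgi": islands,
        "genes": genes,
        "chromatin": _simulate_chromatin_track(rng, genome),
    }
    if config.repeats:
        tracks["repeats"] = simulate_repeat_track(config, truth)
    return Cohort(samples, truth, tracks, deg_tables, genome, config)


def _simulate_chromatin_track(
    rng: np.random.Generator, genome: dict[str, int], segment: int = 2000
) -> list[GenomicInterval]:
    states = DEFAULT_CHROMATIN_STATES
    out = []
    for chrom, length in genome.items():
        edges = np.arange(0, length, segment)
        labels = rng.choice(len(states), size=len(edges))
        for s, li in zip(edges, labels):
            out.append(GenomicInterval(chrom, int(s), int(min(s + segment, length)),
                                       ".", states[li]))
    return out


def simulate_repeat_track(config: SimulationConfig, truth: TruthSet) -> pd.DataFrame:
    """Place repeat elements; biased families overlap planted regions at
    ``multiplier`` times the uniform background rate.

    Deterministic given ``config.seed`` (uses an offset stream so it can be
    called independently of :func:`simulate_cohort`).
    """
    for fam, mult in truth.repeat_bias.items():
        if mult < 0:
            raise ValueError(f"repeat bias multiplier for {fam} must be >= 0")
    rng = np.random.default_rng((config.seed, 0xB5))
    genome = config.genome
    chrom_names = list(genome)
    lengths = np.array([genome[c] for c in chrom_names], dtype=float)
    total_len = lengths.sum()
    regions = [r.interval for r in truth.planted_regions]
    rows = []
    for spec in config.repeats:
        mult = truth.repeat_bias.get(spec.family, 1.0)
        # per-element probability of overlapping any planted region when uniform
        p_uniform = sum(
            (len(r) + spec.length - 1) / total_len for r in regions
        )
        q = max(0.0, (mult - 1.0) * p_uniform)
        q = min(q, 0.95)
        for i in range(spec.n_elements):
            target = regions and rng.random() < q
            if target:
                r = regions[int(rng.integers(len(regions)))]
                lo = max(0, r.start - spec.length + 1)
                hi = max(lo + 1, r.end - 1)
                start = int(rng.integers(lo, hi))
                chrom = r.chrom
            else:
                chrom = chrom_names[int(rng.choice(len(chrom_names),
                                                   p=lengths / total_len))]
                start = int(rng.integers(0, max(1, genome[chrom] - spec.length)))
            sub = spec.subfamilies[i % len(spec.subfamilies)]
            rows.append((chrom, start, min(start + spec.length, genome[chrom]),
                         spec.family, sub))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "subfamily"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort in the same plain-text formats core_io reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for sample in cohort.samples:
        p = outdir / f"{sample.sample_id}.cpg.tsv"
        write_cpg_report(sample, p)
        manifest[f"sample:{sample.sample_id}"] = str(p)
    with open(outdir / "chrom.sizes", "wt") as fh:
        for chrom, length in cohort.genome.items():
            fh.write(f"{chrom}\t{length}\n")
    manifest["genome"] = str(outdir / "chrom.sizes")
    cohort.truth.frame().to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    manifest["truth_regions"] = str(outdir / "truth_regions.tsv")
    cohort.truth.deg_truth.to_csv(outdir / "truth_deg.tsv", sep="\t", index=False)
    manifest["truth_deg"] = str(outdir / "truth_deg.tsv")
    write_bed(cohort.tracks["cgi"], outdir / "cgi.bed")
    manifest["cgi"] = str(outdir / "cgi.bed")
    write_bed(cohort.tracks["chromatin"], outdir / "chromatin.bed")
    manifest["chromatin"] = str(outdir / "chromatin.bed")
    write_gene_models_bed12(cohort.tracks["genes"], outdir / "genes.bed12")
    manifest["genes"] = str(outdir / "genes.bed12")
    if "repeats" in cohort.tracks:
        cohort.tracks["repeats"].to_csv(
            outdir / "repeats.bed", sep="\t", index=False, header=False)
        manifest["repeats"] = str(outdir / "repeats.bed")
    for comp, records in cohort.deg_tables.items():
        p = outdir / f"deg_{comp}.tsv"
        pd.DataFrame(
            [(r.gene_id, r.log2fc, r.padj, r.chrom) for r in records],
            columns=["gene_id", "log2fc", "padj", "chrom"],
        ).to_csv(p, sep="\t", index=False)
        manifest[f"deg:{comp}"] = str(p)
    return manifest
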