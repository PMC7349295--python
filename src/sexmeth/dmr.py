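"""Region-level differential methylation calling.

Two independent strategies and their union:

* ``call_dmr_scan`` builds candidate regions from runs of significant CpGs
  in the site-level test output and applies length / CpG-count / significant-
  fraction / difference constraints, then merges nearby same-direction
  regions (gap <= 100 bp, inclusive);
* ``call_dmr_tiles`` pools counts in fixed non-overlapping 300 bp tiles and
  applies a two-proportion chi-square with a per-tile overdispersion factor,
  Benjamini-Hochberg adjusted across tiles;
* ``union_dmr`` keeps all scan regions plus tiles overlapping none of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import MethylomeSample, filter_coverage
from .dmc import ComparisonDesign
from .intervals import GenomicInterval, IntervalIndex


@dataclass
class DMRRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_cpg: int
    mean_delta: float
    direction: str  # hyper/hypo of other vs baseline
    source: str  # scan | tile
    stat: float  # area statistic (scan) or q-value (tile)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, ".",
                               self.source)

    def __len__(self) -> int:
        return self.end - self.start


def dmr_frame(records: Sequence[DMRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_cpg, r.mean_delta, r.direction,
          r.source, r.stat) for r in records],
        columns=["chrom", "start", "end", "n_cpg", "mean_delta", "direction",
                 "source", "stat"],
    )


def _runs_of_seeds(
    pos: np.ndarray, seed_mask: np.ndarray, direction: np.ndarray, link_gap: int
):
    """Maximal runs of same-direction seed CpGs with gaps <= link_gap."""
    seed_idx = np.flatnonzero(seed_mask)
    runs = []
    current: list[int] = []
    for i in seed_idx:
        if not current:
            current = [i]
            continue
        prev = current[-1]
        if direction[i] == direction[prev] and pos[i] - pos[prev] <= link_gap:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    if current:
        runs.append(current)
    return runs


def call_dmr_scan(
    records: pd.DataFrame,
    p_threshold: float = 1e-5,
    delta_threshold: float = 0.20,
    min_len: int = 50,
    min_cpg: int = 3,
    merge_gap: int = 100,
    link_gap: int = 300,
    min_sig_frac: float = 0.5,
) -> list[DMRRecord]:
    """Scan-based region calling from per-CpG test records.

    ``records`` must hold every tested CpG (not only significant ones),
    sorted by (chrom, pos); unsorted input is an error.
    """
    needed = {"chrom", "pos", "delta", "p"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    key = records[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"], kind="mergesort")):
        raise ValueError("records must be sorted by (chrom, pos)")

    out: list[DMRRecord] = []
    for chrom, sub in records.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        delta = sub["delta"].to_numpy()
        p = sub["p"].to_numpy()
        seed = p < p_threshold
        direction = np.where(delta >= 0, 1, -1)
        candidates = []
        for run in _runs_of_seeds(pos, seed, direction, link_gap):
            first, last = run[0], run[-1]
            lo, hi = pos[first], pos[last]
            # all CpGs inside the span, including interior non-seeds
            in_span = slice(
                np.searchsorted(pos, lo, "left"),
                np.searchsorted(pos, hi, "right"),
            )
            n_cpg = in_span.stop - in_span.start
            length = hi - lo + 1
            sig_frac = len(run) / n_cpg
            mean_delta = float(delta[in_span].mean())
            if (length >= min_len and n_cpg >= min_cpg
                    and sig_frac >= min_sig_frac
                    and abs(mean_delta) > delta_threshold):
                candidates.append(DMRRecord(
                    chrom, int(lo - 1), int(hi), n_cpg, mean_delta,
                    "hyper" if direction[first] > 0 else "hypo",
                    "scan", float(np.abs(delta[in_span]).sum()),
                ))
        # merge surviving same-direction regions with gap <= merge_gap
        # (inclusive); a merge that would dilute |mean_delta| below the
        # threshold is not performed, so every output region satisfies all
        # four constraints
        merged: list[DMRRecord] = []
        for cand in candidates:
            if (merged and cand.direction == merged[-1].direction
                    and cand.start - merged[-1].end <= merge_gap):
                prev = merged[-1]
                lo_pos, hi_pos = prev.start + 1, cand.end
                in_span = slice(
                    np.searchsorted(pos, lo_pos, "left"),
                    np.searchsorted(pos, hi_pos, "right"),
                )
                mean_delta = float(delta[in_span].mean())
                if abs(mean_delta) > delta_threshold:
                    merged[-1] = DMRRecord(
                        chrom, prev.start, cand.end,
                        in_span.stop - in_span.start, mean_delta,
                        prev.direction, "scan",
                        float(np.abs(delta[in_span]).sum()),
                    )
                    continue
            merged.append(cand)
        out.extend(merged)
    return out


def _tile_chi2(m_b, n_b, m_o, n_o) -> float:
    """Pearson chi-square for pooled 2x2 counts (no continuity correction)."""
    table = np.array([[m_b, n_b - m_b], [m_o, n_o - m_o]], dtype=float)
    if table.sum() == 0:
        return 0.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _overdispersion_factor(
    rep_m: np.ndarray, rep_n: np.ndarray, groups: np.ndarray
) -> float:
    """Replicate-level Pearson heterogeneity factor, floored at 1."""
    x2 = 0.0
    df = 0
    for g in np.unique(groups):
        sel = (groups == g) & (rep_n > 0)
        if sel.sum() < 2:
            continue
        m, n = rep_m[sel], rep_n[sel]
        p_hat = m.sum() / n.sum()
        if p_hat <= 0 or p_hat >= 1:
            continue
        x2 += float((((m - n * p_hat) ** 2) / (n * p_hat * (1 - p_hat))).sum())
        df += int(sel.sum()) - 1
    if df == 0:
        return 1.0
    return max(1.0, x2 / df)


def call_dmr_tiles(
    samples: Sequence[MethylomeSample],
    design: ComparisonDesign,
    width: int = 300,
    min_depth: int = 10,
    max_depth: int = 500,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.20,
    min_cpg: int = 1,
) -> list[DMRRecord]:
    """Fixed-tile region calling with overdispersion-corrected chi-square."""
    if width <= 0:
        raise ValueError("tile width must be positive")
    members = [
        s for s in samples
        if s.group in (design.baseline_group, design.other_group)
    ]
    for g in (design.baseline_group, design.other_group):
        if not any(s.group == g for s in members):
            raise ValueError(f"no samples for group {g!r}")
    filtered = [filter_coverage(s, min_depth, max_depth) for s in members]

    rows = []
    all_chroms = sorted({c for s in filtered for c in s.sites["chrom"].unique()})
    for chrom in all_chroms:
        per_rep = []
        for s in filtered:
            sub = s.sites[s.sites["chrom"] == chrom]
            tile_id = (sub["pos"].to_numpy() - 1) // width
            per_rep.append((s.group, tile_id, sub["meth"].to_numpy(),
                            sub["total"].to_numpy(), sub["pos"].to_numpy()))
        tile_ids = np.unique(np.concatenate([t for _, t, _, _, _ in per_rep]))
        if len(tile_ids) == 0:
            continue
        n_rep = len(per_rep)
        rep_m = np.zeros((n_rep, len(tile_ids)))
        rep_n = np.zeros((n_rep, len(tile_ids)))
        cpg_pos: dict[int, set] = {}
        for ri, (_, tid, meth, total, pos) in enumerate(per_rep):
            idx = np.searchsorted(tile_ids, tid)
            np.add.at(rep_m[ri], idx, meth)
            np.add.at(rep_n[ri], idx, total)
            for t, pp in zip(idx, pos):
                cpg_pos.setdefault(int(t), set()).add(int(pp))
        groups = np.array([g for g, _, _, _, _ in per_rep])
        is_base = groups == design.baseline_group
        for ti, tile in enumerate(tile_ids):
            n_cpg = len(cpg_pos.get(ti, ()))
            if n_cpg < min_cpg:
                continue
            m_b, n_b = rep_m[is_base, ti].sum(), rep_n[is_base, ti].sum()
            m_o, n_o = rep_m[~is_base, ti].sum(), rep_n[~is_base, ti].sum()
            if n_b == 0 or n_o == 0:
                continue
            stat = _tile_chi2(m_b, n_b, m_o, n_o)
            c_hat = _overdispersion_factor(rep_m[:, ti], rep_n[:, ti], groups)
            p = float(stats.chi2.sf(stat / c_hat, df=1))
            delta = m_o / n_o - m_b / n_b
            rows.append((chrom, int(tile) * width, (int(tile) + 1) * width,
                         n_cpg, delta, p))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg",
                                     "delta", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    keep = (df["q"] < q_threshold) & (df["delta"].abs() > delta_threshold)
    return [
        DMRRecord(r.chrom, int(r.start), int(r.end), int(r.n_cpg),
                  float(r.delta), "hyper" if r.delta >= 0 else "hypo",
                  "tile", float(r.q))
        for r in df[keep].itertuples(index=False)
    ]


def union_dmr(
    scan: Sequence[DMRRecord], tiles: Sequence[DMRRecord]
) -> list[DMRRecord]:
    """All scan regions plus tiles overlapping no scan region by >= 1 bp."""
    out = list(scan)
    if not scan:
        return out + list(tiles)
    index = IntervalIndex([r.interval for r in scan])
    for t in tiles:
        if not index.overlaps_any(t.chrom, t.start, t.end):
            out.append(t)
    return out


def write_dmr_bed(records: Sequence[DMRRecord], path) -> None:
    """BED6+ output: name=source, score=round(1000*|mean_delta|)."""
    with open(path, "wt") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.start)):
            score = int(round(1000 * abs(r.mean_delta)))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.source}\t{score}\t.\t"
                f"{r.n_cpg}\t{r.mean_delta:.6g}\t{r.direction}\t{r.stat:.6g}\n"
            )


def read_dmr_bed(path) -> list[DMRRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(DMRRecord(f[0], int(f[1]), int(f[2]), int(f[6]),
                                 float(f[7]), f[8], f[3], float(f[9])))
    return out
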