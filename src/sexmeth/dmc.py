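"""Per-CpG differential methylation testing between two groups.

The estimator is a smoothed-proportion Wald test: counts are pooled per
group over a uniform window centered on each CpG (default 500 bp, i.e.
+/-250 bp), a method-of-moments beta-binomial overdispersion is estimated
from the replicate-level windowed proportions, and the two-group difference
of smoothed levels is tested against a normal null.

For group g with R_g replicates the variance of the smoothed level is

    v_g = mu_g (1 - mu_g) (1 + (n_eff - 1) phi_g) / (n_eff * R_g)

with n_eff the pooled windowed total divided by the replicate count (the
per-replicate effective coverage) and phi_g the overdispersion (intra-class
correlation), floored at zero: the numerator term is the beta-binomial
variance of one replicate's windowed proportion and dividing by R_g gives
the variance of the group estimate.  No
multiple-testing correction is applied at the CpG level; calling uses a
fixed p-value threshold plus a methylation-difference threshold, both
strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MethylomeSample

DMC_COLUMNS = ["chrom", "pos", "delta", "wald", "p", "direction",
               "mu_baseline", "mu_other"]


@dataclass(frozen=True)
class ComparisonDesign:
    """A baseline-vs-other group contrast."""

    name: str
    baseline_group: str
    other_group: str

    def __post_init__(self) -> None:
        if self.baseline_group == self.other_group:
            raise ValueError("baseline and other group must differ")

    def swapped(self) -> "ComparisonDesign":
        return ComparisonDesign(
            f"{self.other_group}_vs_{self.baseline_group}",
            self.other_group, self.baseline_group,
        )


DEFAULT_DESIGNS = {
    "XX.F_vs_XY.M": ComparisonDesign("XX.F_vs_XY.M", "XX.F", "XY.M"),
    "XY.F_vs_XY.M": ComparisonDesign("XY.F_vs_XY.M", "XY.F", "XY.M"),
    "XX.F_vs_XY.F": ComparisonDesign("XX.F_vs_XY.F", "XX.F", "XY.F"),
    "XXPaf.F_vs_XO.F": ComparisonDesign("XXPaf.F_vs_XO.F", "XXPaf.F", "XO.F"),
}


@dataclass
class SmoothedSite:
    """Windowed group summaries at one CpG."""

    chrom: str
    pos: int
    mu: dict[str, float]
    n_eff: dict[str, float]
    phi: dict[str, float]
    n_rep: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, m in self.mu.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"mu out of [0,1] for group {g}: {m}")
            if self.n_eff[g] <= 0:
                raise ValueError(f"non-positive effective coverage for {g}")


class SmoothedSites:
    """Column-oriented container of smoothed sites for two-group tests."""

    def __init__(self, frame: pd.DataFrame, groups: tuple[str, str],
                 n_dropped: int = 0):
        self.frame = frame
        self.groups = groups
        self.n_dropped = n_dropped

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, i: int) -> SmoothedSite:
        row = self.frame.iloc[i]
        g1, g2 = self.groups
        return SmoothedSite(
            chrom=row["chrom"], pos=int(row["pos"]),
            mu={g1: row[f"mu_{g1}"], g2: row[f"mu_{g2}"]},
            n_eff={g1: row[f"neff_{g1}"], g2: row[f"neff_{g2}"]},
            phi={g1: row[f"phi_{g1}"], g2: row[f"phi_{g2}"]},
            n_rep={g1: int(row[f"nrep_{g1}"]), g2: int(row[f"nrep_{g2}"])},
        )


def _windowed_group_stats(
    pos: np.ndarray,
    meth: np.ndarray,  # (replicates, sites)
    total: np.ndarray,
    half: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled windowed mu, effective coverage, MoM overdispersion, pooled total."""
    n_rep, n_sites = meth.shape
    left = np.searchsorted(pos, pos - half, side="left")
    right = np.searchsorted(pos, pos + half, side="right")
    cm = np.concatenate([np.zeros((n_rep, 1)), np.cumsum(meth, axis=1)], axis=1)
    ct = np.concatenate([np.zeros((n_rep, 1)), np.cumsum(total, axis=1)], axis=1)
    wm = cm[:, right] - cm[:, left]  # (replicates, sites)
    wt = ct[:, right] - ct[:, left]
    pooled_m = wm.sum(axis=0)
    pooled_t = wt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(pooled_t > 0, pooled_m / np.maximum(pooled_t, 1), np.nan)
        p_rep = np.where(wt > 0, wm / np.maximum(wt, 1), np.nan)
    n_valid = (wt > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev2 = np.where(wt > 0, (p_rep - mu[None, :]) ** 2, 0.0)
        var_p = dev2.sum(axis=0) / np.maximum(n_valid - 1, 1)
        var_p = np.where(n_valid >= 2, var_p, 0.0)
        mean_inv_n = np.where(wt > 0, 1.0 / np.maximum(wt, 1), 0.0).sum(axis=0) \
            / np.maximum(n_valid, 1)
        denom = mu * (1.0 - mu)
        rho = np.where(
            (denom > 0) & (mean_inv_n < 1),
            (var_p / np.maximum(denom, 1e-12) - mean_inv_n)
            / np.maximum(1.0 - mean_inv_n, 1e-12),
            0.0,
        )
    phi = np.clip(rho, 0.0, 1.0)
    n_eff = pooled_t / n_rep
    return mu, n_eff, phi, pooled_t


def smooth(
    samples: Sequence[MethylomeSample],
    design: ComparisonDesign,
    window_bp: int = 500,
) -> SmoothedSites:
    """Windowed pooling of counts per group over the union of CpG positions.

    Sites with zero pooled windowed total in either group are dropped and
    counted in ``SmoothedSites.n_dropped``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp // 2
    by_group = {
        design.baseline_group: [s for s in samples
                                if s.group == design.baseline_group],
        design.other_group: [s for s in samples if s.group == design.other_group],
    }
    for g, members in by_group.items():
        if not members:
            raise ValueError(f"no samples for group {g!r}")

    all_sites = pd.concat(
        [s.sites[["chrom", "pos"]] for members in by_group.values()
         for s in members],
        ignore_index=True,
    ).drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")

    frames = []
    n_dropped = 0
    for chrom, sub in all_sites.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        cols: dict[str, np.ndarray] = {"chrom": chrom, "pos": pos}
        valid = np.ones(len(pos), dtype=bool)
        for group, members in by_group.items():
            meth = np.zeros((len(members), len(pos)))
            total = np.zeros((len(members), len(pos)))
            for ri, s in enumerate(members):
                ssub = s.sites[s.sites["chrom"] == chrom]
                idx = np.searchsorted(pos, ssub["pos"].to_numpy())
                meth[ri, idx] = ssub["meth"].to_numpy()
                total[ri, idx] = ssub["total"].to_numpy()
            mu, n_eff, phi, pooled_t = _windowed_group_stats(pos, meth, total, half)
            cols[f"mu_{group}"] = mu
            cols[f"neff_{group}"] = n_eff
            cols[f"phi_{group}"] = phi
            cols[f"nrep_{group}"] = np.full(len(pos), len(members))
            valid &= pooled_t > 0
        n_dropped += int((~valid).sum())
        frame = pd.DataFrame(cols)
        frames.append(frame[valid])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    # moderate the noisy per-window dispersion toward the genome-wide group
    # mean (prior df 2, site df R-1); stabilizes the normal-tail calibration
    # of the downstream Wald test with few replicates
    if len(out):
        for group, members in by_group.items():
            raw = out[f"phi_{group}"]
            d_site = max(len(members) - 1, 1)
            prior_df = 2.0
            out[f"phi_{group}"] = (
                (prior_df * raw.mean() + d_site * raw) / (prior_df + d_site)
            )
    return SmoothedSites(out, (design.baseline_group, design.other_group),
                         n_dropped)


def _wald_arrays(
    mu_b, mu_o, neff_b, neff_o, phi_b, phi_o, nrep_b=1.0, nrep_o=1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    delta = mu_o - mu_b
    v_b = mu_b * (1 - mu_b) * (1 + (neff_b - 1) * phi_b) / (neff_b * nrep_b)
    v_o = mu_o * (1 - mu_o) * (1 + (neff_o - 1) * phi_o) / (neff_o * nrep_o)
    v = v_b + v_o
    floor = 1.0 / (4.0 * neff_b * nrep_b) + 1.0 / (4.0 * neff_o * nrep_o)
    v = np.where(v <= 0, floor, v)
    wald = delta / np.sqrt(v)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    return delta, wald, p


def wald_test(site: SmoothedSite, design: ComparisonDesign) -> dict:
    """Single-site Wald test; returns a DMC record dict."""
    b, o = design.baseline_group, design.other_group
    if b not in site.mu or o not in site.mu:
        raise ValueError("site lacks one of the design's groups")
    delta, wald, p = _wald_arrays(
        np.float64(site.mu[b]), np.float64(site.mu[o]),
        np.float64(site.n_eff[b]), np.float64(site.n_eff[o]),
        np.float64(site.phi[b]), np.float64(site.phi[o]),
        np.float64(site.n_rep.get(b, 1)), np.float64(site.n_rep.get(o, 1)),
    )
    return {
        "chrom": site.chrom, "pos": site.pos, "delta": float(delta),
        "wald": float(wald), "p": float(min(p, 1.0)),
        "direction": "hyper" if delta >= 0 else "hypo",
        "mu_baseline": site.mu[b], "mu_other": site.mu[o],
    }


def wald_test_all(smoothed: SmoothedSites, design: ComparisonDesign) -> pd.DataFrame:
    """Vectorized Wald tests over all smoothed sites.

    Returns a DataFrame with columns chrom, pos, delta, wald, p, direction,
    mu_baseline, mu_other, sorted by (chrom, pos).
    """
    b, o = design.baseline_group, design.other_group
    f = smoothed.frame
    if len(f) == 0:
        return pd.DataFrame(columns=DMC_COLUMNS)
    delta, wald, p = _wald_arrays(
        f[f"mu_{b}"].to_numpy(), f[f"mu_{o}"].to_numpy(),
        f[f"neff_{b}"].to_numpy(), f[f"neff_{o}"].to_numpy(),
        f[f"phi_{b}"].to_numpy(), f[f"phi_{o}"].to_numpy(),
        f[f"nrep_{b}"].to_numpy(), f[f"nrep_{o}"].to_numpy(),
    )
    out = pd.DataFrame({
        "chrom": f["chrom"].to_numpy(), "pos": f["pos"].to_numpy(),
        "delta": delta, "wald": wald, "p": np.minimum(p, 1.0),
        "direction": np.where(delta >= 0, "hyper", "hypo"),
        "mu_baseline": f[f"mu_{b}"].to_numpy(),
        "mu_other": f[f"mu_{o}"].to_numpy(),
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def call_dmc(
    records: pd.DataFrame,
    p_threshold: float = 1e-5,
    delta_threshold: float = 0.20,
) -> pd.DataFrame:
    """Strict thresholding: keep p < p_threshold and |delta| > delta_threshold."""
    keep = (records["p"] < p_threshold) & (records["delta"].abs() > delta_threshold)
    return records[keep].reset_index(drop=True)


def run_comparison(
    samples: Sequence[MethylomeSample],
    design: ComparisonDesign,
    window_bp: int = 500,
    p_threshold: float = 1e-5,
    delta_threshold: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Smooth, test, and call one comparison; returns (all tests, called)."""
    smoothed = smooth(samples, design, window_bp)
    tested = wald_test_all(smoothed, design)
    return tested, call_dmc(tested, p_threshold, delta_threshold)


def select_top_variable(
    samples: Sequence[MethylomeSample], n: int = 2500
) -> pd.DataFrame:
    """Top-n most variable CpGs across samples (complete cases only).

    Returns a matrix of raw methylation levels indexed by (chrom, pos) with
    one column per sample, ordered by decreasing across-sample variance.
    """
    levels = []
    for s in samples:
        lv = s.sites.set_index(["chrom", "pos"])
        levels.append((lv["meth"] / lv["total"]).rename(s.sample_id))
    mat = pd.concat(levels, axis=1, join="inner")
    if mat.empty:
        return mat
    variances = mat.var(axis=1, ddof=1)
    order = variances.sort_values(ascending=False, kind="mergesort").index
    return mat.loc[order[: min(n, len(order))]]
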