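"""Set algebra over comparisons: UpSet-style intersections and effect classes.

Sites are keyed by exact (chrom, pos); regions are reduced to merged loci
(connected components of the >=1 bp overlap graph across all comparisons)
before membership is computed.  Classification applies boolean rules over
comparison membership with an explicit precedence order; the defaults are

* ``x_dosage``: present in XX.F_vs_XY.M, XX.F_vs_XY.F and XXPaf.F_vs_XO.F;
* ``y_linked``: present in XX.F_vs_XY.M and XX.F_vs_XY.F but absent from
  XXPaf.F_vs_XO.F;
* ``phenotype``: present in XX.F_vs_XY.M and XY.F_vs_XY.M;

evaluated in that order (first match wins); anything else is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

from .dmc import ComparisonDesign
from .dmr import DMRRecord
from .intervals import GenomicInterval, IntervalIndex, merge_intervals

SEX_CHROMS = {"chrX", "chrY"}
UNCLASSIFIED = "unclassified"


@dataclass
class ComparisonResult:
    design: ComparisonDesign
    dmc: pd.DataFrame  # called sites: chrom, pos, (delta, direction, ...)
    dmr: list[DMRRecord] = field(default_factory=list)


@dataclass(frozen=True)
class ClassRule:
    """Membership rule: all of ``requires`` present, none of ``excludes``."""

    name: str
    requires: frozenset[str]
    excludes: frozenset[str] = frozenset()


DEFAULT_RULES = (
    ClassRule("x_dosage",
              frozenset({"XX.F_vs_XY.M", "XX.F_vs_XY.F", "XXPaf.F_vs_XO.F"})),
    ClassRule("y_linked",
              frozenset({"XX.F_vs_XY.M", "XX.F_vs_XY.F"}),
              frozenset({"XXPaf.F_vs_XO.F"})),
    ClassRule("phenotype",
              frozenset({"XX.F_vs_XY.M", "XY.F_vs_XY.M"})),
)


def _dmc_membership(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """One row per site in the union, with a boolean column per comparison."""
    frames = []
    for res in results:
        if len(res.dmc):
            f = res.dmc[["chrom", "pos"]].copy()
            f[res.design.name] = True
            frames.append(f.set_index(["chrom", "pos"]))
    names = [r.design.name for r in results]
    if not frames:
        return pd.DataFrame(columns=names)
    merged = pd.concat(frames, axis=1).notna()
    for name in names:
        if name not in merged.columns:
            merged[name] = False
    return merged[names].astype(bool)


def _region_loci(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Merged loci over all comparisons' regions, with overlap membership."""
    all_ivs = [r.interval for res in results for r in res.dmr]
    names = [r.design.name for r in results]
    if not all_ivs:
        return pd.DataFrame(columns=["chrom", "start", "end", *names])
    loci = merge_intervals(all_ivs)
    rows = []
    indexes = {
        res.design.name: IntervalIndex([r.interval for r in res.dmr])
        for res in results
    }
    for locus in loci:
        row = {"chrom": locus.chrom, "start": locus.start, "end": locus.end}
        for name in names:
            row[name] = bool(indexes[name].overlaps_any(
                locus.chrom, locus.start, locus.end))
        rows.append(row)
    return pd.DataFrame(rows)


def membership_table(
    results: Sequence[ComparisonResult], level: str
) -> pd.DataFrame:
    """Boolean membership of union elements (sites or loci) per comparison."""
    if level == "dmc":
        m = _dmc_membership(results)
        return m.reset_index() if len(m) else pd.DataFrame(
            columns=["chrom", "pos", *[r.design.name for r in results]])
    if level == "dmr":
        return _region_loci(results)
    raise ValueError(f"level must be 'dmc' or 'dmr', got {level!r}")


def intersect_sets(
    results: Sequence[ComparisonResult], level: str = "dmc"
) -> pd.DataFrame:
    """UpSet-style mutually exclusive subset counts.

    One row per non-empty subset of comparisons, with total, autosomal, and
    sex-chromosome tallies.  Each element is counted in exactly the subset
    of comparisons containing it; rows sum to the union size.
    """
    if len(results) < 2:
        raise ValueError("need at least two comparisons")
    names = [r.design.name for r in results]
    members = membership_table(results, level)
    rows = []
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            in_subset = pd.Series(True, index=members.index)
            for name in names:
                want = name in subset
                in_subset &= members[name] == want
            sel = members[in_subset]
            is_sex = sel["chrom"].isin(SEX_CHROMS) if len(sel) else pd.Series(
                dtype=bool)
            rows.append({
                "subset": "&".join(subset),
                "degree": k,
                "count": int(len(sel)),
                "autosomal": int((~is_sex).sum()) if len(sel) else 0,
                "sex_chromosome": int(is_sex.sum()) if len(sel) else 0,
            })
    return pd.DataFrame(rows)


def _validate_rules(
    rules: Sequence[ClassRule], known: set[str]
) -> None:
    for rule in rules:
        unknown = (rule.requires | rule.excludes) - known
        if unknown:
            raise ValueError(
                f"rule {rule.name!r} references unknown comparisons: "
                f"{sorted(unknown)}"
            )


def _apply_rules(
    members: pd.DataFrame, names: list[str], rules: Sequence[ClassRule]
) -> list[str]:
    classes = []
    for _, row in members.iterrows():
        present = {n for n in names if row[n]}
        assigned = UNCLASSIFIED
        for rule in rules:
            if rule.requires <= present and not (rule.excludes & present):
                assigned = rule.name
                break
        classes.append(assigned)
    return classes


def classify_dmc(
    results: Sequence[ComparisonResult],
    rules: Sequence[ClassRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Classify every site in the union of called sites.

    Returns chrom, pos, one boolean column per comparison, and ``class``;
    rule order is precedence (first satisfied rule wins).
    """
    names = [r.design.name for r in results]
    _validate_rules(rules, set(names))
    members = membership_table(results, "dmc")
    members = members.copy()
    members["class"] = _apply_rules(members, names, rules)
    return members


def classify_regions(
    results: Sequence[ComparisonResult],
    rules: Sequence[ClassRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Classify merged region loci by overlap membership, same rule engine."""
    names = [r.design.name for r in results]
    _validate_rules(rules, set(names))
    members = membership_table(results, "dmr").copy()
    members["class"] = _apply_rules(members, names, rules)
    return members


def per_chromosome_counts(records) -> pd.DataFrame:
    """Tally records by chromosome and direction.

    Accepts a DMC DataFrame (chrom/direction columns) or a list of
    :class:`DMRRecord`.  The counts partition the input exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [(r.chrom, r.direction) for r in records],
            columns=["chrom", "direction"],
        )
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "direction", "count"])
    out = (
        df.groupby(["chrom", "direction"]).size().rename("count").reset_index()
    )
    return out.sort_values(["chrom", "direction"]).reset_index(drop=True)
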