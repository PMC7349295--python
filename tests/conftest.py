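"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sexmeth.classify import ComparisonResult
from sexmeth.core_io import MethylomeSample
from sexmeth.dmc import DEFAULT_DESIGNS, run_comparison
from sexmeth.dmr import call_dmr_scan, call_dmr_tiles, union_dmr
from sexmeth.simulate import EffectSpec, SimulationConfig, simulate_cohort


def make_sample(rows, sample_id="s1", group="XX.F") -> MethylomeSample:
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df = df.astype({"pos": np.int64, "meth": np.int64, "total": np.int64})
    return MethylomeSample(sample_id, group, df)


def effect_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        chroms=(("chr1", 1_500_000), ("chrX", 1_000_000), ("chrY", 200_000)),
        effects=(
            EffectSpec("phenotype", 8),
            EffectSpec("x_dosage", 8),
            EffectSpec("y_linked", 6),
        ),
        dispersion_rho=0.01,
        seed=seed,
    )


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with planted effects in all three classes (seed 1)."""
    return simulate_cohort(effect_config(1))


@pytest.fixture(scope="session")
def effect_results(effect_cohort):
    """Full four-comparison DMC+DMR results on the effect cohort."""
    results = []
    for design in DEFAULT_DESIGNS.values():
        tested, called = run_comparison(effect_cohort.samples, design)
        union = union_dmr(
            call_dmr_scan(tested),
            call_dmr_tiles(effect_cohort.samples, design),
        )
        results.append(ComparisonResult(design, called, union))
    return results


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects (two autosomes only)."""
    return simulate_cohort(SimulationConfig(
        chroms=(("chr1", 1_000_000), ("chr2", 1_000_000)),
        n_islands=12, seed=5,
    ))


def reciprocal_overlap(a, b, frac=0.5) -> bool:
    """>= frac reciprocal overlap between two intervals on one chromosome."""
    if a.chrom != b.chrom:
        return False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov >= frac * (a.end - a.start) and ov >= frac * (b.end - b.start)
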