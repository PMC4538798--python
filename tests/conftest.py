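"""Shared fixtures: deterministic random variants and a small synthetic cohort."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ovatime.core import DEFAULT_LAYOUT, VariantCall
from ovatime.simulate import KataegisSpec, SimConfig, generate_cohort, generate_dataset


@pytest.fixture(scope="session")
def layout():
    return DEFAULT_LAYOUT


def make_random_variant(rng: np.random.Generator, **overrides) -> VariantCall:
    """A structurally valid variant with randomized filter-relevant fields."""
    depth = int(rng.integers(8, 120))
    alt = int(rng.integers(0, depth + 1))
    fwd = int(rng.integers(0, alt + 1))
    g_depth = int(rng.integers(5, 400))
    g_alt = int(rng.integers(0, min(g_depth, 6) + 1))
    fields = dict(
        chrom=f"chr{int(rng.integers(1, 4))}",
        position=int(rng.integers(1, 50_000_000)),
        ref="C",
        alt="T",
        tumor_depth=depth,
        tumor_alt=alt,
        germline_depth=g_depth,
        germline_alt=g_alt,
        somatic_score=float(rng.integers(0, 60)),
        bq_mutant=tuple(int(q) for q in rng.integers(5, 41, size=alt)),
        alt_forward=fwd,
        alt_reverse=alt - fwd,
        strand_bias=float(rng.integers(0, 80)),
        dbsnp_maf=round(float(rng.uniform(0, 0.05)), 4) if rng.random() < 0.3 else None,
        homolog_count=int(rng.integers(0, 6)),
        category="Intergenic",
        variant_class="SNV",
        context="ACG",
        sample_id="S1",
    )
    fields.update(overrides)
    return VariantCall(**fields).validate()


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic sample with deletions, a kataegis cluster and SVs."""
    cfg = dataclasses.replace(
        SimConfig(),
        seed=11,
        n_snvs=300,
        n_deletions=3,
        n_svs=10,
        sv_clustered_fraction=0.5,
        kataegis=KataegisSpec(count=1, size=10, spacing=200, chrom="chr2"),
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def cohort_15():
    """Fifteen samples under the default study conditions (for paired tests)."""
    return generate_cohort(n_samples=15, seed=7)
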