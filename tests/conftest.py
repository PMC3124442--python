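"""Shared fixtures: synthetic scenario bundles at the study scale used for
operating-characteristic checks, plus small designs for unit tests."""

import numpy as np
import pytest

import mbdchip as mb
from mbdchip.io_formats import ProbeDesign

# compact study: two 300 kb chromosomes, enough features for every stage
SMALL = dict(
    chrom_lengths={"chrA": 300_000, "chrB": 300_000},
    islands_per_chrom=40,
    genes_per_chrom=6,
    n_methylated_regions=60,
    n_differential=12,
)


@pytest.fixture(scope="session")
def basic_bundle():
    """Full-scale planted-region study: 2 x 1 Mb, ~57k probes, 200 regions."""
    return mb.make_scenario("basic", seed=42)


@pytest.fixture(scope="session")
def basic_result(basic_bundle):
    b = basic_bundle
    return mb.run_sample(b.design, b.intensity, "A", genome=b.genome, with_fdr=True)


@pytest.fixture(scope="session")
def island_bundle():
    return mb.make_scenario("island_enriched", seed=7)


@pytest.fixture(scope="session")
def island_result(island_bundle):
    b = island_bundle
    return mb.run_sample(b.design, b.intensity, "A", genome=b.genome)


@pytest.fixture(scope="session")
def biased_bundle():
    return mb.make_scenario("biased", seed=3)


@pytest.fixture(scope="session")
def biased_result(biased_bundle):
    b = biased_bundle
    return mb.run_sample(b.design, b.intensity, "A", genome=b.genome)


@pytest.fixture(scope="session")
def small_basic_bundle():
    return mb.make_scenario("basic", seed=5, **SMALL)


@pytest.fixture(scope="session")
def small_basic_result(small_basic_bundle):
    b = small_basic_bundle
    return mb.run_sample(b.design, b.intensity, "A", genome=b.genome, with_fdr=True)


@pytest.fixture(scope="session")
def diff_bundle():
    return mb.make_scenario("differential", seed=11, **SMALL)


def toy_design(n: int = 50, chrom: str = "chrT", spacing: int = 35,
               length: int = 25, gc: int = 12) -> ProbeDesign:
    """A uniform single-chromosome design for constructed-signal tests."""
    starts = np.arange(n, dtype=np.int64) * spacing
    return ProbeDesign(
        probe_id=np.array([f"{chrom}:{s:06d}" for s in starts], dtype=object),
        chrom=np.array([chrom] * n, dtype=object),
        start=starts,
        length=np.full(n, length, dtype=np.int64),
        gc_count=np.full(n, gc, dtype=np.int64),
    )
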