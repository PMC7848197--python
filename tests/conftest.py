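import numpy as np
import pytest

from haploxo.io_formats import AnnotationTrack, HaplotypeSequence
from haploxo.marker_genotyping import load_marker_definitions
from haploxo.synthetic_data import (
    SimulationConfig,
    plant_marker_scaffold,
    simulate_haplotype_pair,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_at(seq: str, pos: int, rng: np.random.Generator) -> str:
    alts = [c for c in BASES if c != seq[pos]]
    return seq[:pos] + alts[rng.integers(0, 3)] + seq[pos + 1 :]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pair():
    """A 50-kb pair: identical lineage on the left half, divergent right."""
    cfg = SimulationConfig(
        region_length=50_000, breakpoints=[25_000], seed=7,
        within_lineage_rate=0.0,
    )
    return simulate_haplotype_pair(cfg)


@pytest.fixture(scope="session")
def marker_defs():
    return load_marker_definitions()


@pytest.fixture
def marker_panel(marker_defs):
    """Factory: scaffolded haplotype + track for a given seed."""

    def build(seed: int):
        rng = np.random.default_rng(seed)
        L = 60_000
        hap = HaplotypeSequence("hap", random_seq(rng, L))
        track = AnnotationTrack("hap", [])
        positions = [
            int((i + 1) * L / (len(marker_defs) + 1))
            for i in range(len(marker_defs))
        ]
        return plant_marker_scaffold(hap, track, marker_defs, positions, rng), rng

    return build
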