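import numpy as np
import pytest

from covasm import AssemblyConfig, PruneConfig, random_genome, run_assembly
from covasm.sim_reads import SimConfig, simulate_reads, tiling_reads


@pytest.fixture
def small_genome():
    """A 2 kb repeat-free genome (unique canonical 20-mers)."""
    return random_genome(2000, seed=11, unique_kminus1=20)


@pytest.fixture
def tiled_reads(small_genome):
    """Error-free reads deterministically tiling the whole small genome."""
    return tiling_reads(small_genome, read_len=75, coverage=30)


def assemble(reads, k=21, prune=None, min_contig_len=None, workers=1):
    """One-call assembly used throughout the tests."""
    cfg = AssemblyConfig(k=k, prune=prune, min_contig_len=min_contig_len,
                         workers=workers)
    return run_assembly(cfg, reads=reads)


@pytest.fixture
def assemble_fn():
    return assemble
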