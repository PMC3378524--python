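"""Seeded random graph fixtures shared by the edge-selection tests."""

import numpy as np

from covasm import CoverageTable
from covasm.dbg import build_graph, merge_unitigs
from covasm.edge_select import assign_preferred


def random_junction_graph(seed, max_nodes=50, k=5):
    """A small merged graph with junctions and varied coverages, or None.

    A random sequence with a re-inserted segment guarantees repeats, and a
    mutated second copy contributes branch points; per-k-mer coverages are
    randomized so preferred-edge choices and arbitration are non-trivial.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(25, 55))
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, n))
    a = int(rng.integers(0, max(1, n - 12)))
    seq = seq + seq[a:a + 10]  # forced repeat
    alt = list(seq)
    for pos in rng.integers(0, len(alt), 3):
        alt[pos] = "ACGT"[int(rng.integers(0, 4))]
    words = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    words |= {"".join(alt[i:i + k]) for i in range(len(alt) - k + 1)}
    counts = {w: int(rng.integers(1, 30)) for w in words if "N" not in w}
    g = merge_unitigs(build_graph(CoverageTable.from_counts(counts, k)))
    if len(g.nodes) > max_nodes:
        return None
    assign_preferred(g)
    return g
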