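"""Contig emission by traversal of mutually preferred links.

A contig is a maximal path along links that are preferred *in both
directions*.  A node whose preferred link was never mutualized ends its
contig there.  Paths start from the lexicographically smallest unvisited
terminal node; pure cycles are broken at their smallest node.  Every node
lands in exactly one contig; contigs shorter than ``min_len`` are dropped
at the very end (the default keeps everything — length/identity filtering
belongs to evaluation).  Output sequences are canonical (the smaller of the
spelled string and its reverse complement) so runs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .dbg import LEFT, RIGHT, Graph, Link, Node
from .kmer_table import canonical_str, revcomp


@dataclass
class Contig:
    """An assembled sequence plus the node path that spelled it."""

    seq: str
    node_path: List[Tuple[int, int]]  # (node id, orientation; 1 = rc)
    coverage: float

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_nodes(self) -> int:
        return len(self.node_path)


def _mutual_link(g: Graph, node: Node, side: int) -> Optional[Link]:
    link = node.preferred[side]
    if link is None or link.nbr == node.id:
        return None
    back = g.nodes[link.nbr].preferred[link.nbr_side]
    if (back is not None and back.nbr == node.id
            and back.nbr_side == side and back.eword == link.eword):
        return link
    return None


def _walk(g: Graph, start: int, orient: int, visited: set
          ) -> List[Tuple[int, int]]:
    path = [(start, orient)]
    visited.add(start)
    while True:
        cid, o = path[-1]
        exit_side = RIGHT if o == 0 else LEFT
        link = _mutual_link(g, g.nodes[cid], exit_side)
        if link is None or link.nbr in visited:
            return path
        path.append((link.nbr, 0 if link.nbr_side == LEFT else 1))
        visited.add(link.nbr)


def _spell(g: Graph, path: List[Tuple[int, int]]) -> str:
    parts = []
    for i, (nid, o) in enumerate(path):
        s = g.nodes[nid].seq if o == 0 else revcomp(g.nodes[nid].seq)
        parts.append(s if i == 0 else s[g.k - 1:])
    return "".join(parts)


def emit_contigs(g: Graph, min_len: Optional[int] = None) -> List[Contig]:
    """Traverse mutual preferred links into contigs.

    ``min_len`` defaults to k (emit everything a k-mer graph can spell).
    """
    if min_len is None:
        min_len = g.k
    visited: set = set()
    contigs: List[Contig] = []

    def emit(path: List[Tuple[int, int]]) -> None:
        seq = canonical_str(_spell(g, path))
        cov_sum = sum(g.nodes[nid].coverage * g.nodes[nid].member_count
                      for nid, _ in path)
        members = sum(g.nodes[nid].member_count for nid, _ in path)
        contigs.append(Contig(seq, path, cov_sum / members))

    order = g.sorted_ids()
    # pass 1: terminal nodes (some side has no mutual preferred link)
    for nid in order:
        if nid in visited:
            continue
        nd = g.nodes[nid]
        if _mutual_link(g, nd, LEFT) is None:
            emit(_walk(g, nid, 0, visited))
        elif _mutual_link(g, nd, RIGHT) is None:
            emit(_walk(g, nid, 1, visited))
    # pass 2: whatever remains lies on cycles; break each at its smallest node
    for nid in order:
        if nid not in visited:
            emit(_walk(g, nid, 0, visited))

    return [c for c in contigs if c.length >= min_len]
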