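"""Bidirected de Bruijn graph construction and unitig merging.

Every node stores one canonical sequence (the lexicographically smaller of
the word and its reverse complement) and stands for both strands.  Links are
sided: a node has a LEFT and a RIGHT side, up to four links per side (one
per extending base), and each link records which side of the neighbor it
attaches to, so a traversal that enters a neighbor on its RIGHT side reads
that neighbor reverse-complemented.  Links come in reciprocal pairs; the
only single-record edge is a hairpin loop joining a node's side to itself.

Edges are discovered from k-mer co-presence: for each surviving k-mer all
eight one-base extensions (4 bases x 2 sides) are looked up in the table.
Odd k is required so that no k-mer equals its own reverse complement.

Unitig merging collapses every maximal chain of nodes joined through
boundaries where both facing sides carry exactly one (non-loop) link.  The
merged node spells the overlap-merge of its members, its coverage is the
mean member k-mer coverage, and external links of the chain ends re-attach
to the merged node.  The set of spelled sequences and adjacencies is
unchanged; merging is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .kmer_table import (BASES, CoverageTable, canonical_packed,
                         canonical_str, decode, revcomp, revcomp_packed)

LEFT, RIGHT = 0, 1

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class Link:
    """A sided edge record.

    ``base`` is the extending nucleotide expressed in the *owning* node's
    stored orientation; ``eword`` is the canonical packed (k+1)-word of the
    junction, shared by the two reciprocal records of one edge and used to
    pair them up.
    """

    nbr: int
    nbr_side: int
    base: str
    eword: int


class Node:
    __slots__ = ("id", "seq", "coverage", "member_count", "links", "preferred")

    def __init__(self, nid: int, seq: str, coverage: float,
                 member_count: int = 1):
        self.id = nid
        self.seq = seq
        self.coverage = coverage
        self.member_count = member_count
        self.links: Tuple[List[Link], List[Link]] = ([], [])
        self.preferred: List[Optional[Link]] = [None, None]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Node({self.id}, {self.seq!r}, cov={self.coverage:.1f}, "
                f"deg=({len(self.links[0])},{len(self.links[1])}))")


class Graph:
    """A set of nodes addressed by integer id."""

    def __init__(self, k: int):
        if k < 3 or k % 2 == 0:
            raise ValueError("graph k must be odd and >= 3 (palindrome-free)")
        self.k = k
        self.nodes: Dict[int, Node] = {}
        self._next_id = 0

    def add_node(self, seq: str, coverage: float, member_count: int = 1) -> Node:
        nd = Node(self._next_id, seq, coverage, member_count)
        self.nodes[nd.id] = nd
        self._next_id += 1
        return nd

    def link_records(self) -> int:
        return sum(len(nd.links[s]) for nd in self.nodes.values()
                   for s in (LEFT, RIGHT))

    def node_by_seq(self, word: str) -> Optional[Node]:
        target = canonical_str(word)
        for nd in self.nodes.values():
            if nd.seq == target:
                return nd
        return None

    def sorted_ids(self) -> List[int]:
        return sorted(self.nodes, key=lambda i: self.nodes[i].seq)


def reciprocal(g: Graph, uid: int, uside: int, link: Link) -> Link:
    """The matching record of ``link`` on the neighbor (itself for hairpins)."""
    v = g.nodes[link.nbr]
    for l2 in v.links[link.nbr_side]:
        if l2.nbr == uid and l2.nbr_side == uside and l2.eword == link.eword:
            return l2
    raise AssertionError(
        f"link {g.nodes[uid].seq} side {uside} -> {v.seq} has no reciprocal")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(table: CoverageTable) -> Graph:
    """One node per surviving canonical k-mer, linked on (k-1)-overlaps."""
    k = table.k
    g = Graph(k)
    keys = sorted(table.as_dict().items())
    index: Dict[int, int] = {}
    for key, count in keys:
        nd = g.add_node(decode(key, k), float(count), 1)
        index[key] = nd.id

    mask = (1 << (2 * k)) - 1
    hi = 2 * (k - 1)
    for key, _count in keys:
        nd = g.nodes[index[key]]
        for b in range(4):
            # right extension: suffix(k-1) + b
            nw = ((key << 2) & mask) | b
            rcw = revcomp_packed(nw, k)
            c = min(nw, rcw)
            if c in index:
                nbr_side = LEFT if nw <= rcw else RIGHT
                ew = canonical_packed((key << 2) | b, k + 1)
                nd.links[RIGHT].append(Link(index[c], nbr_side, BASES[b], ew))
            # left extension: b + prefix(k-1)
            nw = (b << hi) | (key >> 2)
            rcw = revcomp_packed(nw, k)
            c = min(nw, rcw)
            if c in index:
                nbr_side = RIGHT if nw <= rcw else LEFT
                ew = canonical_packed((b << (2 * k)) | key, k + 1)
                nd.links[LEFT].append(Link(index[c], nbr_side, BASES[b], ew))
    return g


def side_is_junction(g: Graph, node: Node, side: int) -> bool:
    """More than one link, or a loop back to the node itself."""
    ls = node.links[side]
    return len(ls) > 1 or any(l.nbr == node.id for l in ls)


def is_junction(g: Graph, node: Node) -> bool:
    """A node with multiple neighbors (or a loop) on either side."""
    return side_is_junction(g, node, LEFT) or side_is_junction(g, node, RIGHT)


# ---------------------------------------------------------------------------
# unitig merging
# ---------------------------------------------------------------------------

def _sole_link(node: Node, side: int) -> Optional[Link]:
    ls = node.links[side]
    if len(ls) == 1 and ls[0].nbr != node.id:
        return ls[0]
    return None


def _mergeable(g: Graph, node: Node, side: int) -> Optional[Link]:
    """The boundary link if both facing sides are junction-free."""
    link = _sole_link(node, side)
    if link is None:
        return None
    v = g.nodes[link.nbr]
    if _sole_link(v, link.nbr_side) is None:
        return None
    return link


def merge_unitigs(g: Graph) -> Graph:
    """Collapse maximal junction-free chains into single unitig nodes."""
    visited: set = set()
    chains: List[List[Tuple[int, int]]] = []  # [(node id, orient)], orient 1 = rc
    interior: set = set()  # id() of link records consumed inside a chain

    def consume(uid: int, uside: int, link: Link) -> None:
        interior.add(id(link))
        interior.add(id(reciprocal(g, uid, uside, link)))

    for nid in g.sorted_ids():
        if nid in visited:
            continue
        chain: List[Tuple[int, int]] = [(nid, 0)]
        visited.add(nid)
        while True:  # extend right in chain frame
            cid, o = chain[-1]
            side = RIGHT if o == 0 else LEFT
            link = _mergeable(g, g.nodes[cid], side)
            if link is None or link.nbr in visited:
                break  # boundary, or cycle closing link (left unconsumed)
            consume(cid, side, link)
            chain.append((link.nbr, 0 if link.nbr_side == LEFT else 1))
            visited.add(link.nbr)
        while True:  # extend left in chain frame
            cid, o = chain[0]
            side = LEFT if o == 0 else RIGHT
            link = _mergeable(g, g.nodes[cid], side)
            if link is None or link.nbr in visited:
                break
            consume(cid, side, link)
            chain.insert(0, (link.nbr, 0 if link.nbr_side == RIGHT else 1))
            visited.add(link.nbr)
        chains.append(chain)

    ng = Graph(g.k)
    # (old node id, old side) -> (new id, new side, complement base?)
    endmap: Dict[Tuple[int, int], Tuple[int, int, bool]] = {}
    for chain in chains:
        parts: List[str] = []
        cov_sum = 0.0
        members = 0
        for i, (cid, o) in enumerate(chain):
            nd = g.nodes[cid]
            s = nd.seq if o == 0 else revcomp(nd.seq)
            parts.append(s if i == 0 else s[g.k - 1:])
            cov_sum += nd.coverage * nd.member_count
            members += nd.member_count
        seq = "".join(parts)
        cseq = canonical_str(seq)
        flipped = cseq != seq
        new = ng.add_node(cseq, cov_sum / members, members)
        lid, lo = chain[0]
        rid, ro = chain[-1]
        endmap[(lid, LEFT if lo == 0 else RIGHT)] = (
            new.id, RIGHT if flipped else LEFT, (lo == 1) ^ flipped)
        endmap[(rid, RIGHT if ro == 0 else LEFT)] = (
            new.id, LEFT if flipped else RIGHT, (ro == 1) ^ flipped)

    for (oid, oside), (nid2, nside, compf) in endmap.items():
        for link in g.nodes[oid].links[oside]:
            if id(link) in interior:
                continue
            tgt = endmap.get((link.nbr, link.nbr_side))
            if tgt is None:  # pragma: no cover - structural invariant
                raise AssertionError("external link into a consumed chain side")
            base = _COMP[link.base] if compf else link.base
            ng.nodes[nid2].links[nside].append(
                Link(tgt[0], tgt[1], base, link.eword))
    for nd in ng.nodes.values():
        for side in (LEFT, RIGHT):
            nd.links[side].sort(key=lambda l: (l.base, l.eword, l.nbr, l.nbr_side))
    return ng


# ---------------------------------------------------------------------------
# GFA dump
# ---------------------------------------------------------------------------

def write_gfa(g: Graph, path: str) -> None:
    """Dump the graph as GFA v1 (S-lines with a depth tag, L-lines)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        name = {nid: f"n{nid}" for nid in g.nodes}
        for nid in g.sorted_ids():
            nd = g.nodes[nid]
            fh.write(f"S\t{name[nid]}\t{nd.seq}\tdp:f:{nd.coverage:.2f}\n")
        seen = set()
        ov = f"{g.k - 1}M"
        for nid in g.sorted_ids():
            nd = g.nodes[nid]
            for side in (LEFT, RIGHT):
                for link in nd.links[side]:
                    edge = (min(nid, link.nbr), max(nid, link.nbr), link.eword)
                    if edge in seen:
                        continue
                    seen.add(edge)
                    # orient so the edge is read leaving nd rightward
                    fo = "+" if side == RIGHT else "-"
                    to = "+" if link.nbr_side == LEFT else "-"
                    fh.write(f"L\t{name[nid]}\t{fo}\t{name[link.nbr]}\t{to}"
                             f"\t{ov}\n")
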