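"""Coverage-driven preferred-edge selection and conflict resolution.

The weight of an edge leaving a node toward neighbor M is

    w = coverage(M) + max coverage over M's links on its continuing side

(the side of M facing away from the querying node; the max term is 0 when M
has no continuing links).  The one-step look-ahead lets a strong path win
even when it passes through one low-coverage node.  Per node and side, the
highest-weight link becomes the *preferred* link; ties break on the smaller
extending base (A<C<G<T), then the smaller neighbor sequence.

Preferred links are then made mutually consistent.  When node JN1 prefers
JN2 but JN2 does not prefer JN1 back, coverage arbitrates: if JN1's
coverage is strictly higher, JN2 is enforced to point back at JN1;
otherwise (including ties) the JN1-JN2 edge is disconnected and JN1
re-selects among its remaining links.  To guarantee that arbitration
terminates, an enforcement only replaces JN2's current pointer when JN1
strictly beats the pointer's present target on (coverage, then sequence);
a contender that cannot beat the incumbent is disconnected instead, so
every enforcement strictly improves the slot it writes and every
disconnection removes an edge.  Nodes are scanned in ascending sequence
order, LEFT side before RIGHT, in passes until a pass changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .dbg import LEFT, RIGHT, Graph, Link, Node, reciprocal

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


def edge_weight(g: Graph, node: Node, side: int, link: Link) -> float:
    """Weight of one link: neighbor coverage plus best continuing coverage."""
    m = g.nodes[link.nbr]
    cont = 1 - link.nbr_side
    best = 0.0
    for l2 in m.links[cont]:
        cov = g.nodes[l2.nbr].coverage
        if cov > best:
            best = cov
    return m.coverage + best


def _select(g: Graph, node: Node, side: int) -> Optional[Link]:
    """Argmax-weight link on one side (loops to self are never preferred)."""
    best: Optional[Link] = None
    best_key: Optional[Tuple] = None
    for link in node.links[side]:
        if link.nbr == node.id:
            continue
        key = (-edge_weight(g, node, side, link), _BASE_ORDER[link.base],
               g.nodes[link.nbr].seq, link.eword)
        if best_key is None or key < best_key:
            best, best_key = link, key
    return best


def assign_preferred(g: Graph) -> Graph:
    """Designate the preferred link per node per side (in place)."""
    for nd in g.nodes.values():
        for side in (LEFT, RIGHT):
            nd.preferred[side] = _select(g, nd, side)
    return g


@dataclass
class ArbitrationEvent:
    """One conflict-resolution step, for logging and inspection."""

    action: str  # "enforce" or "disconnect"
    jn1: str
    jn2: str
    cov1: float
    cov2: float
    new_preferred: Optional[str] = None  # jn1's re-selected neighbor (disconnect)


def _is_mutual(g: Graph, node: Node, side: int) -> bool:
    link = node.preferred[side]
    if link is None:
        return True
    back = g.nodes[link.nbr].preferred[link.nbr_side]
    return (back is not None and back.nbr == node.id
            and back.nbr_side == side and back.eword == link.eword)


def _reselect_feeders(g: Graph, node: Node, removed_side: int) -> None:
    # the removed link fed the look-ahead max of every link arriving at the
    # node's other side; re-select those neighbors' preferred links
    for link in node.links[1 - removed_side]:
        nbr = g.nodes[link.nbr]
        nbr.preferred[link.nbr_side] = _select(g, nbr, link.nbr_side)


def _disconnect(g: Graph, u: Node, side: int, link: Link) -> None:
    rec = reciprocal(g, u.id, side, link)
    v = g.nodes[link.nbr]
    u.links[side].remove(link)
    if rec is not link:  # hairpin loops have a single record
        v.links[link.nbr_side].remove(rec)
    u.preferred[side] = _select(g, u, side)
    if v.preferred[link.nbr_side] is rec:
        v.preferred[link.nbr_side] = _select(g, v, link.nbr_side)
    _reselect_feeders(g, u, side)
    _reselect_feeders(g, v, link.nbr_side)


def resolve_conflicts(g: Graph,
                      events: Optional[List[ArbitrationEvent]] = None
                      ) -> Tuple[Graph, int]:
    """Drive preferred links to a mutually consistent fixpoint (in place).

    Returns the graph and the number of scan passes used.  Raises if the
    fixpoint is not reached within a link-count bound (which would indicate
    a broken arbitration rule, not a data problem).
    """
    initial_links = g.link_records()
    limit = max(initial_links, 1) + 1
    passes = 0
    changed = True
    while changed:
        passes += 1
        if passes > limit:
            raise RuntimeError("conflict resolution failed to reach a fixpoint")
        changed = False
        for nid in g.sorted_ids():
            for side in (LEFT, RIGHT):
                u = g.nodes[nid]
                link = u.preferred[side]
                if link is None or _is_mutual(g, u, side):
                    continue
                v = g.nodes[link.nbr]
                changed = True
                if u.coverage > v.coverage and _beats_incumbent(g, u, v, link):
                    v.preferred[link.nbr_side] = reciprocal(g, u.id, side, link)
                    if events is not None:
                        events.append(ArbitrationEvent(
                            "enforce", u.seq, v.seq, u.coverage, v.coverage))
                else:
                    _disconnect(g, u, side, link)
                    newp = u.preferred[side]
                    if events is not None:
                        events.append(ArbitrationEvent(
                            "disconnect", u.seq, v.seq, u.coverage, v.coverage,
                            g.nodes[newp.nbr].seq if newp else None))
    return g, passes


def _beats_incumbent(g: Graph, u: Node, v: Node, link: Link) -> bool:
    cur = v.preferred[link.nbr_side]
    if cur is None:
        return True
    w = g.nodes[cur.nbr]
    if u.coverage != w.coverage:
        return u.coverage > w.coverage
    return u.seq < w.seq


def count_non_mutual(g: Graph) -> int:
    """Scan for preferred links without a reciprocal preferred link."""
    return sum(1 for nd in g.nodes.values() for side in (LEFT, RIGHT)
               if not _is_mutual(g, nd, side))
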