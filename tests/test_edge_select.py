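import copy

import pytest

from covasm import CoverageTable, canonical_str
from covasm.dbg import LEFT, RIGHT, build_graph
from covasm.edge_select import (ArbitrationEvent, assign_preferred,
                                count_non_mutual, edge_weight,
                                resolve_conflicts)
from graphgen import random_junction_graph
from oracles import rc


def prepared(counts, k=5):
    g = build_graph(CoverageTable.from_counts(counts, k))
    assign_preferred(g)
    return g


def link_to(g, node, side, nbr_seq):
    target = canonical_str(nbr_seq)
    for link in node.links[side]:
        if g.nodes[link.nbr].seq == target:
            return link
    raise AssertionError(f"no link {node.seq} side {side} -> {nbr_seq}")


def pref_seq(g, node, side):
    link = node.preferred[side]
    return g.nodes[link.nbr].seq if link else None


# chain A(3) -> B(5) -> {C(2), D(7)} realized as 5-mers:
# AAACA -> AACAC -> {ACACA, ACACC}
CHAIN = {"AAACA": 3, "AACAC": 5, "ACACA": 2, "ACACC": 7}


def test_edge_weight_one_step_lookahead():
    g = prepared(CHAIN)
    a = g.node_by_seq("AAACA")
    w = edge_weight(g, a, RIGHT, link_to(g, a, RIGHT, "AACAC"))
    assert w == 5 + max(2, 7)


def test_edge_weight_dead_end_contributes_zero():
    g = prepared({"AAACA": 3, "AACAC": 5})
    a = g.node_by_seq("AAACA")
    assert edge_weight(g, a, RIGHT, link_to(g, a, RIGHT, "AACAC")) == 5


def test_weights_are_strand_invariant():
    flipped = {rc(w): c for w, c in CHAIN.items()}
    g1, g2 = prepared(CHAIN), prepared(flipped)

    def weight_map(g):
        return {(nd.seq, side, l.base): edge_weight(g, nd, side, l)
                for nd in g.nodes.values() for side in (LEFT, RIGHT)
                for l in nd.links[side]}

    assert weight_map(g1) == weight_map(g2)


def test_preferred_is_argmax_with_tie_breaks():
    g = prepared(CHAIN)
    a = g.node_by_seq("AAACA")
    assert pref_seq(g, a, RIGHT) == canonical_str("AACAC")  # sole link
    b = g.node_by_seq("AACAC")
    assert pref_seq(g, b, RIGHT) == canonical_str("ACACC")  # weight 7 > 2
    # equal weights: smaller extending base wins (A < C)
    g = prepared({"AAACA": 3, "AACAC": 5, "ACACA": 6, "ACACC": 6})
    b = g.node_by_seq("AACAC")
    assert b.preferred[RIGHT].base == "A"
    assert pref_seq(g, b, RIGHT) == canonical_str("ACACA")


# --- the junction-arbitration scenario ------------------------------------
# ATTGG prefers CATTG (left side); CATTG prefers ATTGC (right side).

def arbitrate(cov_attgg, cov_cattg, cov_attgc, cov_tattg, boost=None):
    counts = {"ATTGG": cov_attgg, "CATTG": cov_cattg,
              "ATTGC": cov_attgc, "TATTG": cov_tattg}
    if boost:
        counts["TTGCA"] = boost  # look-ahead feeder keeping ATTGC preferred
    g = prepared(counts)
    events = []
    g, passes = resolve_conflicts(g, events)
    return g, events, passes


def test_conflict_higher_neighbor_coverage_disconnects_and_reselects():
    g, events, _ = arbitrate(cov_attgg=4, cov_cattg=10, cov_attgc=8,
                             cov_tattg=5)
    ev = events[0]
    assert ev.action == "disconnect"
    assert (ev.jn1, ev.jn2) == ("ATTGG", canonical_str("CATTG"))
    assert ev.new_preferred == canonical_str("TATTG")
    hub = g.node_by_seq("ATTGG")
    assert all(g.nodes[l.nbr].seq != canonical_str("CATTG")
               for l in hub.links[LEFT])  # edge truly removed
    assert count_non_mutual(g) == 0


def test_conflict_higher_own_coverage_enforces_pointer():
    g, events, _ = arbitrate(cov_attgg=10, cov_cattg=6, cov_attgc=8,
                             cov_tattg=5, boost=20)
    enforce = [e for e in events if e.action == "enforce"]
    assert enforce and (enforce[0].jn1, enforce[0].jn2) == \
        ("ATTGG", canonical_str("CATTG"))
    cattg = g.node_by_seq("CATTG")
    side = next(s for s in (LEFT, RIGHT)
                if any(g.nodes[l.nbr].seq == "ATTGG" for l in cattg.links[s]))
    assert pref_seq(g, cattg, side) == "ATTGG"
    assert count_non_mutual(g) == 0


def test_mutual_graph_is_a_fixpoint():
    g = prepared({"AAACA": 3, "AACAC": 5, "ACACC": 7})
    before = copy.deepcopy([(nd.seq, pref_seq(g, nd, LEFT),
                             pref_seq(g, nd, RIGHT))
                            for nd in g.nodes.values()])
    links_before = g.link_records()
    g, passes = resolve_conflicts(g, [])
    assert passes == 1 and g.link_records() == links_before
    after = [(nd.seq, pref_seq(g, nd, LEFT), pref_seq(g, nd, RIGHT))
             for nd in g.nodes.values()]
    assert after == before


@pytest.mark.parametrize("seed", range(25))
def test_resolution_invariants_on_random_junction_graphs(seed):
    g = random_junction_graph(seed)
    if g is None:
        pytest.skip("sampled graph exceeded the size cap")
    links0 = g.link_records()
    covs0 = {nd.id: nd.coverage for nd in g.nodes.values()}
    twin = copy.deepcopy(g)

    events = []
    g, passes = resolve_conflicts(g, events)
    assert passes <= max(links0, 1) + 1
    assert count_non_mutual(g) == 0
    assert g.link_records() <= links0
    assert {nd.id: nd.coverage for nd in g.nodes.values()} == covs0

    twin_events = []
    twin, _ = resolve_conflicts(twin, twin_events)
    assert [(e.action, e.jn1, e.jn2) for e in events] == \
        [(e.action, e.jn1, e.jn2) for e in twin_events]
    assert {nd.seq: (g.nodes[nd.preferred[0].nbr].seq if nd.preferred[0]
                     else None) for nd in g.nodes.values()} == \
        {nd.seq: (twin.nodes[nd.preferred[0].nbr].seq if nd.preferred[0]
                  else None) for nd in twin.nodes.values()}
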