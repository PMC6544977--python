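"""SCC analysis, attractor classification, signatures, condition mining."""

import itertools
import random

import networkx as nx
import pytest

import hsmkit as hk
from hsmkit.attractors import (
    canonical_digraph_form,
    find_attractors,
    mine_conditions,
    progress_indicators,
    strongly_connected_components,
    sweep_orderings,
)
from hsmkit.charph import build_characteristic_graph
from hsmkit.orderings import OrderingConstraints


def closure_scc_oracle(g: nx.DiGraph):
    """u, v share an SCC iff u reaches v and v reaches u (transitive closure)."""
    reach = {u: set(nx.descendants(g, u)) | {u} for u in g.nodes}
    comps = []
    seen = set()
    for u in g.nodes:
        if u in seen:
            continue
        comp = {v for v in g.nodes if v in reach[u] and u in reach[v]}
        seen |= comp
        comps.append(frozenset(comp))
    return sorted(comps, key=min)


def test_scc_trivial_cases():
    g = nx.MultiDiGraph()
    g.add_node("a")
    assert strongly_connected_components(g) == [frozenset({"a"})]
    g = nx.MultiDiGraph([(0, 1), (1, 2), (2, 0)])
    assert strongly_connected_components(g) == [frozenset({0, 1, 2})]


@pytest.mark.parametrize("seed", range(25))
def test_scc_matches_transitive_closure_oracle(seed):
    rng = random.Random(seed)
    n = rng.randint(1, 8)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < 0.3:
                g.add_edge(u, v)
    assert strongly_connected_components(g) == closure_scc_oracle(g)


def test_progress_indicator_clauses(toy, toy_orderings):
    o = toy_orderings[5]  # b3.dis < b3.as < b2.dis < b2.as
    cg = build_characteristic_graph(toy, o)
    # all-free mode: s2 rising with b3 free must eventually bind (progress);
    # s1 falls with no bound site: it decays forever without a forced exit
    assert progress_indicators(toy, cg, [(0, 0, 0)]) == ["s2"]
    # s2 falling while b3 stays bound must eventually release it
    assert progress_indicators(toy, cg, [(0, 0, 1)]) == ["s2"]


def test_toy_third_ordering_has_two_attractors(toy, toy_orderings):
    cg = build_characteristic_graph(toy, toy_orderings[2])
    reports = find_attractors(toy, cg)
    attractors = [r for r in reports if r.is_attractor]
    assert len(attractors) == 2
    for a in attractors:
        assert a.progress_indicators == ()


def test_two_mode_cycle_is_single_cycle_attractor(toy, toy_orderings):
    cg = build_characteristic_graph(toy, toy_orderings[4])
    (a,) = [r for r in find_attractors(toy, cg) if r.is_attractor]
    assert a.structure == "single_cycle"
    assert len(a.modes) == 2


def test_signature_is_insertion_order_invariant():
    nodes = ["x", "y", "z"]
    edges = [("x", "y", "A"), ("y", "z", "A"), ("z", "x", "B")]
    lab = {"x": "p", "y": "p", "z": "q"}
    sig1 = canonical_digraph_form(nodes, edges, lab.__getitem__, lambda e: e[2])
    for perm in itertools.permutations(nodes):
        shuffled_edges = list(reversed(edges))
        sig2 = canonical_digraph_form(list(perm), shuffled_edges, lab.__getitem__, lambda e: e[2])
        assert sig2 == sig1


def test_isomorphic_relabelled_cycles_share_a_signature():
    # same direction-labelled 2-cycle over different "sites"
    sig_a = canonical_digraph_form([0, 1], [(0, 1, "P"), (1, 0, "P")], {0: "u", 1: "d"}.__getitem__, lambda e: e[2])
    sig_b = canonical_digraph_form(["m", "n"], [("m", "n", "P"), ("n", "m", "P")], {"m": "u", "n": "d"}.__getitem__, lambda e: e[2])
    assert sig_a == sig_b


def test_auto_regulatory_attractors_of_last_orderings_agree(toy, toy_orderings):
    sigs = []
    for idx in (4, 5):
        cg = build_characteristic_graph(toy, toy_orderings[idx])
        (a,) = [r for r in find_attractors(toy, cg) if r.is_attractor]
        sigs.append(a.signature)
    assert sigs[0] == sigs[1]


def test_toy_sweep_counts(toy):
    sweep = sweep_orderings(toy, [OrderingConstraints()], seeds="settled", with_graph_signature=True)
    assert len(sweep.rows) == 6
    assert len({r.graph_signature for r in sweep.rows}) == 4
    assert len(sweep.distinct_signatures()) == 3
    assert sweep.attractor_counts() == [1, 1, 2, 1, 1, 1]


def test_no_threshold_model_sweeps_trivially():
    m = hk.random_model(1, n_genes=1, n_sites=0)
    sweep = sweep_orderings(m, [OrderingConstraints()])
    assert len(sweep.rows) == 1


def test_attractors_never_contain_progress_indicators(toy, toy_orderings):
    for o in toy_orderings:
        cg = build_characteristic_graph(toy, o)
        for r in find_attractors(toy, cg):
            if r.is_attractor:
                assert progress_indicators(toy, cg, r.modes) == []


def test_hysteresis_excludes_uniform_direction_in_cycling_sccs(toy, toy_orderings):
    """An SCC with both rise and fall edges of one substance cannot have that
    substance uniformly rising (or falling) in all members."""
    for o in toy_orderings:
        cg = build_characteristic_graph(toy, o)
        sem = cg.semantics
        for r in find_attractors(toy, cg):
            dirs_by_sub = {}
            for _, _, g in r.internal_edges:
                dirs_by_sub.setdefault(g.substance, set()).add(g.direction)
            for sub, ds in dirs_by_sub.items():
                if ds == {"rise", "fall"}:
                    assert {sem.direction(m, sub) for m in r.modes} != {"up"}
                    assert {sem.direction(m, sub) for m in r.modes} != {"down"}


def test_mine_conditions_single_ordering_returns_its_relations(toy, toy_orderings):
    sweep = sweep_orderings(toy, [OrderingConstraints()])
    row = sweep.rows[5]
    single = hk.SweepReport(model_name="toy", rows=[row])
    # re-id the row so mine_conditions indexes it correctly
    single.rows[0].ordering_id = 0
    conds = mine_conditions(single)
    for per_sig in conds.values():
        r = row.ordering.rank_map("s2")
        for rel in per_sig["always"]:
            if rel.startswith("s2:"):
                a, b = rel.split(": ")[1].split(" < ")
                ka = [k for k in r if k.label == a][0]
                kb = [k for k in r if k.label == b][0]
                assert r[ka] < r[kb]
    sweep.rows[5].ordering_id = 5  # restore


def test_behaviour_class_reports_fates(toy, toy_orderings):
    cg = build_characteristic_graph(toy, toy_orderings[5])
    (a,) = [r for r in find_attractors(toy, cg) if r.is_attractor]
    # s2 keeps cycling below b2; s1 is never activated and decays
    assert a.behaviour == "s1=decays,s2=persists"
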