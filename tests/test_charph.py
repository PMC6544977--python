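"""Mode consistency, direction vectors, event generation, graph building."""

import itertools

from hypothesis import given, settings, strategies as st

import hsmkit as hk
from hsmkit.charph import DOWN, UP, ModelSemantics, build_characteristic_graph
from hsmkit.model import ControlFunction, Generator, HSMModel, Substance, ThresholdKey
from hsmkit.orderings import OrderingConstraints


def interval_oracle(model, ordering, mode):
    """Independent consistency check: place rank i at value i and search a
    rational concentration satisfying every site's constraint directly."""
    sem = ModelSemantics(model, ordering)
    for sub in model.substance_ids():
        keys = model.threshold_keys(sub)
        if not keys:
            continue
        rank = ordering.rank_map(sub)
        candidates = [i + 0.5 for i in range(-1, len(ordering.groups_for(sub)) + 1)]
        ok = False
        for c in candidates:
            good = True
            for i, site in enumerate(model.sites):
                if sub not in site.ligands:
                    continue
                if mode[i] == site.ligands.index(sub) + 1:
                    good &= c > rank[ThresholdKey(sub, site.id, "dissoc")]
                elif mode[i] == 0:
                    good &= c < rank[ThresholdKey(sub, site.id, "assoc")]
            if good:
                ok = True
                break
        if not ok:
            return False
    return True


def toy_ordering(toy, text):
    s1 = hk.enumerate_orderings(toy, OrderingConstraints(), "s1")[0]
    (o,) = [x for x in hk.enumerate_orderings(toy, OrderingConstraints(), "s2") if x.substance_string("s2") == text]
    return o.merge(s1)


def test_all_free_is_always_consistent(toy, toy_orderings):
    for o in toy_orderings:
        assert hk.is_consistent_mode(toy, o, (0, 0, 0))


def test_repressor_gap_mode_is_inconsistent(phage):
    """bOR2 held by repressor while bOR1 is free needs a concentration both
    above dis(bOR2) and below as(bOR1) — impossible in the cascade order."""
    free = hk.phage_constraint_set("free_interleave")
    per = {
        s: hk.enumerate_orderings(phage, free, s)[0]
        for s in phage.substance_ids()
        if phage.threshold_keys(s)
    }
    joint = per["Cro"]
    for s in ("repressor", "CII", "N", "Q"):
        joint = joint.merge(per[s])
    sem = ModelSemantics(phage, joint)
    pos = {s.id: i for i, s in enumerate(phage.sites)}
    rep_code = phage.sites[pos["bOR2"]].ligands.index("repressor") + 1
    mode = [0] * len(phage.sites)
    mode[pos["bOR2"]] = rep_code
    assert not sem.is_consistent(tuple(mode))
    assert not interval_oracle(phage, joint, tuple(mode))


def test_consistency_matches_interval_oracle_on_toy(toy, toy_orderings):
    for o in toy_orderings:
        for mode in itertools.product((0, 1), repeat=3):
            assert hk.is_consistent_mode(toy, o, mode) == interval_oracle(toy, o, mode)


def test_direction_vector_from_truth_tables(toy):
    # b1 FREE, b2 BOUND(s2), b3 FREE: s1 on (needs b2 bound), s2 on (b3 free)
    assert hk.direction_vector(toy, (0, 1, 0)) == (UP, UP)
    assert hk.direction_vector(toy, (0, 0, 1)) == (DOWN, DOWN)


def test_constant_off_tables_give_all_down():
    m = hk.random_model(3, n_genes=2, n_sites=2)
    off = tuple(
        ControlFunction(c.id, c.inputs, {k: 0 for k in c.table}) for c in m.control_functions
    )
    m_off = HSMModel(m.name, m.substances, m.sites, off, m.generators)
    assert set(hk.direction_vector(m_off, (0, 0))) == {DOWN}


def test_steady_sink_has_no_events(toy, toy_orderings):
    # all sites free in ordering 6: s2 off only when b3 bound; craft a sink:
    # all-off model instead — no bound sites, all genes off -> no events
    m = hk.random_model(3, n_genes=2, n_sites=2)
    off = tuple(ControlFunction(c.id, c.inputs, {k: 0 for k in c.table}) for c in m.control_functions)
    m_off = HSMModel(m.name, m.substances, m.sites, off, m.generators)
    o = None
    lists = [
        hk.enumerate_orderings(m_off, OrderingConstraints(), s)
        for s in m_off.substance_ids()
        if m_off.threshold_keys(s)
    ]
    o = hk.joint_orderings(lists)[0] if lists else None
    sink = (0,) * len(m_off.sites)
    assert hk.enabled_events(m_off, o, sink) == []


def test_rising_substance_crosses_minimal_association_first(toy):
    o = toy_ordering(toy, "b2.dis < b3.dis < b3.as < b2.as")
    events = hk.enabled_events(toy, o, (0, 0, 0))
    # only s2 is rising; among free sites b2, b3 the lower association is b3
    assert len(events) == 1
    guard, target = events[0]
    assert guard.substance == "s2" and guard.direction == "rise"
    assert [k.label for k in guard.atoms] == ["b3.as"]
    assert target == (0, 0, 1)


def test_tied_thresholds_fire_as_one_compound_event(phage):
    equal = hk.phage_constraint_set("or2_ol2_equal")
    per = {
        s: hk.enumerate_orderings(phage, equal, s)[0]
        for s in phage.substance_ids()
        if phage.threshold_keys(s)
    }
    joint = per["Cro"]
    for s in ("repressor", "CII", "N", "Q"):
        joint = joint.merge(per[s])
    sem = ModelSemantics(phage, joint)
    pos = {s.id: i for i, s in enumerate(phage.sites)}
    mode = [0] * len(phage.sites)
    cro = phage.sites[pos["bOR3"]].ligands.index("Cro") + 1
    mode[pos["bOR3"]] = cro
    mode[pos["bOL3"]] = cro
    mode = tuple(mode)
    assert sem.direction(mode, "Cro") == UP
    cro_events = [(g, t) for g, t in sem.enabled_events(mode) if g.substance == "Cro"]
    assert len(cro_events) == 1
    guard, target = cro_events[0]
    assert sorted(k.label for k in guard.atoms) == ["bOL2.as", "bOR2.as"]
    assert target[pos["bOR2"]] == cro and target[pos["bOL2"]] == cro


def test_siteless_model_has_one_node_no_edges():
    always_on = ControlFunction("f", (), {(): 1})
    m = HSMModel(
        name="free-running",
        substances=(Substance("s"),),
        sites=(),
        control_functions=(always_on,),
        generators=(Generator("g", "s", "f"),),
    )
    o = hk.ThresholdOrdering.from_mapping({})
    cg = build_characteristic_graph(m, o)
    assert cg.n_nodes == 1 and cg.n_edges == 0


def test_toy_graphs_have_fewer_than_ten_nodes(toy, toy_orderings):
    for o in toy_orderings:
        assert build_characteristic_graph(toy, o).n_nodes < 10


def test_first_two_table_orderings_give_isomorphic_graphs(toy, toy_orderings):
    gs = [
        hk.graph_signature(build_characteristic_graph(toy, o, seeds="settled"))
        for o in toy_orderings
    ]
    assert gs[0] == gs[1]
    assert gs[4] == gs[5]
    assert len(set(gs)) == 4


def test_rebuilding_is_deterministic(toy, toy_orderings):
    o = toy_orderings[2]
    a = build_characteristic_graph(toy, o)
    b = build_characteristic_graph(toy, o)
    assert list(a.graph.nodes(data=True)) == list(b.graph.nodes(data=True))
    assert list(a.graph.edges(data="label")) == list(b.graph.edges(data="label"))


def test_settled_nodes_are_a_subset_of_consistent_nodes(toy, toy_orderings):
    for o in toy_orderings:
        full = set(build_characteristic_graph(toy, o).graph.nodes)
        settled = set(build_characteristic_graph(toy, o, seeds="settled").graph.nodes)
        assert settled <= full


def _joint_ordering(model):
    lists = [
        hk.enumerate_orderings(model, OrderingConstraints(), s)
        for s in model.substance_ids()
        if model.threshold_keys(s)
    ]
    return hk.joint_orderings(lists)[0] if lists else hk.ThresholdOrdering.from_mapping({})


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_graph_invariants_on_random_models(seed):
    """Every node consistent; every edge switches exactly the guarded sites
    in the guarded direction (hysteresis: rebinding requires release)."""
    m = hk.random_model(seed, n_genes=2 + seed % 2, n_sites=2 + seed % 3)
    o = _joint_ordering(m)
    cg = build_characteristic_graph(m, o)
    sem = cg.semantics
    bound_limit = 1
    for s in m.sites:
        bound_limit *= len(s.ligands) + 1
    assert cg.n_nodes <= bound_limit
    pos = {s.id: i for i, s in enumerate(m.sites)}
    for node in cg.graph.nodes:
        assert sem.is_consistent(node)
    for u, v, d in cg.graph.edges(data=True):
        g = d["guard"]
        for k in g.atoms:
            i = pos[k.site]
            code = m.sites[i].ligands.index(g.substance) + 1
            if g.direction == "rise":
                assert u[i] == 0 and v[i] == code
            else:
                # the freed site may be re-claimed at once by the other ligand
                assert u[i] == code and v[i] != code
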