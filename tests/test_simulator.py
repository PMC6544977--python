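"""Numeric event-driven simulation and its conformance to the graph."""

import random

import pytest

import hsmkit as hk
from hsmkit.charph import DOWN, STEADY, UP, build_characteristic_graph
from hsmkit.model import (
    BindingSite,
    ControlFunction,
    Generator,
    HSMModel,
    Substance,
    ThresholdKey,
)
from hsmkit.orderings import OrderingConstraints
from hsmkit.simulate import (
    NumericParameters,
    conforms,
    induced_ordering,
    params_from_ordering,
    settle_initial_mode,
    simulate,
)


def one_gene_model():
    """One always-on gene whose product binds a single site."""
    site = BindingSite("b", ("s",))
    return HSMModel(
        name="one-gene",
        substances=(Substance("s"),),
        sites=(site,),
        control_functions=(ControlFunction("f", (), {(): 1}),),
        generators=(Generator("g", "s", "f"),),
    )


def toy_joint(toy, idx):
    s1 = hk.enumerate_orderings(toy, OrderingConstraints(), "s1")[0]
    s2 = hk.enumerate_orderings(toy, OrderingConstraints(), "s2")[idx]
    return s2.merge(s1)


def test_settle_zero_concentrations_leaves_sites_free(toy, toy_orderings):
    params = params_from_ordering(toy, toy_orderings[0])
    assert settle_initial_mode(toy, params, {"s1": 0, "s2": 0}) == (0, 0, 0)


def test_settle_binds_sites_at_or_above_association(phage):
    free = hk.phage_constraint_set("free_interleave")
    per = [
        hk.enumerate_orderings(phage, free, s)[0]
        for s in phage.substance_ids()
        if phage.threshold_keys(s)
    ]
    joint = per[0]
    for o in per[1:]:
        joint = joint.merge(o)
    params = params_from_ordering(phage, joint)
    pos = {s.id: i for i, s in enumerate(phage.sites)}
    rep_code = phage.sites[pos["bOR1"]].ligands.index("repressor") + 1
    c = params.thresholds[ThresholdKey("repressor", "bOR2", "assoc")]  # exactly at bOR2.as
    mode = settle_initial_mode(phage, params, {"repressor": c})
    assert mode[pos["bOR1"]] == rep_code
    assert mode[pos["bOR2"]] == rep_code  # >= binds (boundary convention)
    assert mode[pos["bOR3"]] == 0


def test_first_crossing_time_is_threshold_over_rate():
    m = one_gene_model()
    params = NumericParameters(
        thresholds={
            ThresholdKey("s", "b", "dissoc"): 1.0,
            ThresholdKey("s", "b", "assoc"): 3.0,
        },
        rates={"g": (2.0, 1.0)},
    )
    run = simulate(m, params, {"s": 0.0})
    assert run.times[1] == pytest.approx(3.0 / 2.0)
    assert run.events[0][1] == (ThresholdKey("s", "b", "assoc"),)
    assert run.terminated == "steady"  # bound site, gene still on: no crossings left


def test_all_genes_off_is_a_single_mode_run(toy, toy_orderings):
    m = toy
    off = tuple(ControlFunction(c.id, c.inputs, {k: 0 for k in c.table}) for c in m.control_functions)
    m_off = HSMModel(m.name, m.substances, m.sites, off, m.generators)
    params = params_from_ordering(m_off, toy_orderings[0])
    run = simulate(m_off, params, {"s1": 0, "s2": 0})
    assert len(run.modes) == 1 and run.events == []


def test_trajectories_are_continuous_and_monotone_per_mode(toy, toy_orderings):
    params = params_from_ordering(toy, toy_orderings[2], rng=random.Random(5))
    run = simulate(toy, params, {"s1": 2.0, "s2": 0.5}, max_events=30)
    sem_dirs = [hk.direction_vector(toy, m) for m in run.modes]
    for si, sub in enumerate(toy.substance_ids()):
        pts = run.trajectories[sub]
        assert [t for t, _ in pts] == sorted(run.times)
        for i in range(len(pts) - 1):
            (t0, c0), (t1, c1) = pts[i], pts[i + 1]
            d = sem_dirs[i][si]
            if d == UP:
                assert c1 >= c0
            else:
                assert c1 <= c0
            assert c0 >= 0 and c1 >= 0


def test_bind_and_release_alternate_per_site(toy, toy_orderings):
    params = params_from_ordering(toy, toy_orderings[3], rng=random.Random(7))
    run = simulate(toy, params, {}, max_events=40)
    per_site = {}
    for _, crossings in run.events:
        for k in crossings:
            per_site.setdefault((k.substance, k.site), []).append(k.kind)
    for kinds in per_site.values():
        for a, b in zip(kinds, kinds[1:]):
            assert a != b


@pytest.mark.parametrize("trial", range(25))
def test_random_toy_runs_conform_to_their_graphs(toy, toy_orderings, trial):
    rng = random.Random(trial)
    o = toy_orderings[trial % 6]
    params = params_from_ordering(toy, o, rng=rng)
    init = {s: rng.uniform(0, 5) for s in toy.substance_ids()}
    run = simulate(toy, params, init, max_events=40)
    cg = build_characteristic_graph(toy, o)
    assert conforms(run, cg)
    assert induced_ordering(toy, params) == o


def test_doctored_run_does_not_conform(toy, toy_orderings):
    o = toy_orderings[2]
    params = params_from_ordering(toy, o)
    run = simulate(toy, params, {}, max_events=10)
    assert len(run.modes) >= 3
    run.modes.pop(1)
    run.events.pop(0)
    cg = build_characteristic_graph(toy, o)
    assert not conforms(run, cg)


def test_ordering_mismatch_is_an_error(toy, toy_orderings):
    params = params_from_ordering(toy, toy_orderings[0])
    run = simulate(toy, params, {})
    cg = build_characteristic_graph(toy, toy_orderings[2])
    with pytest.raises(ValueError):
        conforms(run, cg)


def test_bad_rates_are_rejected(toy, toy_orderings):
    params = params_from_ordering(toy, toy_orderings[0])
    params.rates["s1"] = (0.0, 1.0)
    with pytest.raises(ValueError):
        simulate(toy, params, {})


def test_anti_phase_alternation_in_the_coupling_regime(toy):
    """In the ordering where s2's b2-pair nests inside the b3-pair, the limit
    cycle couples the genes in anti-phase: the observational sequence cycles
    (down,up) -> (up,up) -> (up,down) -> (down,down), so the s1-active,
    s2-inactive label and its converse alternate."""
    o = toy_joint(toy, 3)  # b3.dis < b2.dis < b2.as < b3.as
    params = NumericParameters(
        thresholds={
            ThresholdKey("s1", "b1", "dissoc"): 50.0,
            ThresholdKey("s1", "b1", "assoc"): 100.0,  # s1 never reaches b1
            ThresholdKey("s2", "b3", "dissoc"): 1.0,
            ThresholdKey("s2", "b2", "dissoc"): 2.0,
            ThresholdKey("s2", "b2", "assoc"): 3.0,
            ThresholdKey("s2", "b3", "assoc"): 4.0,
        },
        rates={"s1": (1.0, 1.0), "s2": (1.0, 1.0)},
    )
    run = simulate(toy, params, {"s1": 0, "s2": 0}, max_events=30)
    obs = run.observational_sequence()
    anti = [v for v in obs[-12:] if v in ((UP, DOWN), (DOWN, UP))]
    assert len(anti) >= 4
    for a, b in zip(anti, anti[1:]):
        assert a != b  # strict alternation of the two anti-phase labels


def test_observational_sequence_marks_zero_floor_as_steady():
    m = one_gene_model()
    off = HSMModel(
        m.name,
        m.substances,
        m.sites,
        (ControlFunction("f", (), {(): 0}),),
        m.generators,
    )
    params = NumericParameters(
        thresholds={
            ThresholdKey("s", "b", "dissoc"): 1.0,
            ThresholdKey("s", "b", "assoc"): 2.0,
        },
        rates={"g": (1.0, 1.0)},
    )
    run = simulate(off, params, {"s": 0.0})
    assert run.observational_sequence() == [(STEADY,)]
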