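"""Built-in models: a two-gene toy network, a phage λ switch model, the
phage operator-threshold constraint sets, and a random-model generator for
property tests.

All builders are pure: the same call (same seed) returns an identical model.

Phage λ background.  The lysis–lysogeny decision is implemented by the λ
switch: operator cascades O_R1–3 and O_L1–3, each site bindable by both Cro
and repressor with opposite affinity orders.  Repressor affinity descends
along bOR1→bOR2→bOR3 (association thresholds ascend); Cro's order is the
reverse.  The model has ten binding sites, six control functions
(P_R, P_RN, P_ME, P_L, P_int, P_Q) and eleven genes (cI, cro, cII, O, P, Q,
int, N, cIII, xis, struc); operons are modelled as several generators
sharing one control function (cro/cII/O/P all driven by P_R).

The control truth tables below are a reconstruction from the switch's known
wiring, validated against the sweep statistics the analysis reproduces
(exactly two attractors per ordering; lysis cycling Cro across bOR2,
lysogeny cycling repressor across bOR2):

* P_R  on iff bOR1 and bOR2 are free (Cro's negative auto-regulation at
  bOR2, lysogenic shut-down when repressor holds bOR1);
* P_RN on iff bN is bound by N and bOR1, bOR2 are free (the N-dependent
  read-through producing Q);
* P_ME on iff bOR3 is free and bOR2 is either not held by repressor or
  overridden by CII on bCII-1 (occupancy of bOR3 — Cro at low
  concentration, or repressor's own negative feedback at high — silences
  cI outright; with bOR3 free, repressor on bOR2 represses unless CII
  triggers establishment; repressor's own oscillation runs across bOR2);
* P_L  on iff bOL1 and bOL2 are free;
* P_int on iff bCII-2 is bound by CII (CII's bCII-2 threshold lies below
  bCII-1's);
* P_Q  on iff bQ is bound by Q.

Site-state combinations unreachable under the shipped constraints (e.g.
repressor on bOL3) take the table value of the nearest reachable case —
the predicates above are total, so every row is defined.
"""

from __future__ import annotations

import itertools
import random
from typing import Callable, Sequence

from .model import (
    FREE,
    BindingSite,
    ControlFunction,
    Generator,
    HSMModel,
    Substance,
    ThresholdKey,
    bound_state,
)
from .orderings import OrderingConstraints, SubstanceConstraints

__all__ = [
    "toy_two_gene_model",
    "phage_lambda_model",
    "phage_constraint_set",
    "random_model",
    "table_from_predicate",
]


def table_from_predicate(
    sites: Sequence[BindingSite], inputs: Sequence[str], on: Callable[[dict[str, str]], bool]
) -> dict[tuple[str, ...], int]:
    """Total truth table over the cross product of the input sites' states."""
    by_id = {s.id: s for s in sites}
    domains = [by_id[i].states() for i in inputs]
    table = {}
    for states in itertools.product(*domains):
        env = dict(zip(inputs, states))
        table[states] = 1 if on(env) else 0
    return table


def toy_two_gene_model() -> HSMModel:
    """Two-gene network: s1 represses itself (via b1); s2 represses itself
    (via b3) and activates s1 (via b2)."""
    sites = (
        BindingSite("b1", ("s1",)),
        BindingSite("b2", ("s2",)),
        BindingSite("b3", ("s2",)),
    )
    f1 = ControlFunction(
        "f1",
        ("b1", "b2"),
        table_from_predicate(sites, ("b1", "b2"), lambda e: e["b1"] == FREE and e["b2"] == bound_state("s2")),
    )
    f2 = ControlFunction("f2", ("b3",), table_from_predicate(sites, ("b3",), lambda e: e["b3"] == FREE))
    return HSMModel(
        name="toy-two-gene",
        substances=(Substance("s1"), Substance("s2")),
        sites=sites,
        control_functions=(f1, f2),
        generators=(Generator("s1", "s1", "f1"), Generator("s2", "s2", "f2")),
    )


_OPERATORS = ("bOR1", "bOR2", "bOR3", "bOL1", "bOL2", "bOL3")


def phage_lambda_model() -> HSMModel:
    substances = tuple(
        Substance(s)
        for s in ("repressor", "Cro", "CII", "N", "Q", "cIII", "xis", "int", "O", "P", "struc")
    )
    sites = tuple(BindingSite(s, ("Cro", "repressor")) for s in _OPERATORS) + (
        BindingSite("bQ", ("Q",)),
        BindingSite("bN", ("N",)),
        BindingSite("bCII-1", ("CII",)),
        BindingSite("bCII-2", ("CII",)),
    )
    cro, rep, cii = bound_state("Cro"), bound_state("repressor"), bound_state("CII")

    p_r = ControlFunction(
        "P_R",
        ("bOR1", "bOR2"),
        table_from_predicate(sites, ("bOR1", "bOR2"), lambda e: e["bOR1"] == FREE and e["bOR2"] == FREE),
    )
    p_rn = ControlFunction(
        "P_RN",
        ("bN", "bOR1", "bOR2"),
        table_from_predicate(
            sites,
            ("bN", "bOR1", "bOR2"),
            lambda e: e["bN"] == bound_state("N") and e["bOR1"] == FREE and e["bOR2"] == FREE,
        ),
    )
    p_me = ControlFunction(
        "P_ME",
        ("bOR2", "bOR3", "bCII-1"),
        table_from_predicate(
            sites,
            ("bOR2", "bOR3", "bCII-1"),
            lambda e: e["bOR3"] == FREE and (e["bOR2"] != rep or e["bCII-1"] == cii),
        ),
    )
    p_l = ControlFunction(
        "P_L",
        ("bOL1", "bOL2"),
        table_from_predicate(sites, ("bOL1", "bOL2"), lambda e: e["bOL1"] == FREE and e["bOL2"] == FREE),
    )
    p_int = ControlFunction(
        "P_int", ("bCII-2",), table_from_predicate(sites, ("bCII-2",), lambda e: e["bCII-2"] == cii)
    )
    p_q = ControlFunction(
        "P_Q", ("bQ",), table_from_predicate(sites, ("bQ",), lambda e: e["bQ"] == bound_state("Q"))
    )

    generators = (
        Generator("cI", "repressor", "P_ME"),
        Generator("cro", "Cro", "P_R"),
        Generator("cII", "CII", "P_R"),
        Generator("O", "O", "P_R"),
        Generator("P", "P", "P_R"),
        Generator("Q", "Q", "P_RN"),
        Generator("N", "N", "P_L"),
        Generator("cIII", "cIII", "P_L"),
        Generator("xis", "xis", "P_L"),
        Generator("int", "int", "P_int"),
        Generator("struc", "struc", "P_Q"),
    )
    return HSMModel(
        name="phage-lambda",
        substances=substances,
        sites=sites,
        control_functions=(p_r, p_rn, p_me, p_l, p_int, p_q),
        generators=generators,
    )


def _k(sub: str, site: str, kind: str) -> ThresholdKey:
    return ThresholdKey(sub, site, kind)


def _cascade_constraints(sub: str, ascending: Sequence[str]) -> tuple[list, list]:
    """Per-site adjacency blocks plus block-order chains along a cascade."""
    adjacency = [(_k(sub, s, "dissoc"), _k(sub, s, "assoc")) for s in ascending]
    chains = [
        [_k(sub, a, "assoc"), _k(sub, b, "dissoc")] for a, b in zip(ascending, ascending[1:])
    ]
    return adjacency, chains


def _interleaved(sub: str, first: Sequence[str], second: Sequence[str]) -> list[ThresholdKey]:
    """Fully cascade-aligned ordering with the middle sites' pairs
    interleaved: first[0] block, second[0] block, then
    first[1].dis second[1].dis first[1].as second[1].as, then the top
    blocks."""
    seq: list[ThresholdKey] = []
    for f, s in ((first[0], second[0]),):
        seq += [_k(sub, f, "dissoc"), _k(sub, f, "assoc"), _k(sub, s, "dissoc"), _k(sub, s, "assoc")]
    seq += [
        _k(sub, first[1], "dissoc"),
        _k(sub, second[1], "dissoc"),
        _k(sub, first[1], "assoc"),
        _k(sub, second[1], "assoc"),
    ]
    for f, s in ((first[2], second[2]),):
        seq += [_k(sub, f, "dissoc"), _k(sub, f, "assoc"), _k(sub, s, "dissoc"), _k(sub, s, "assoc")]
    return seq


#: ascending threshold order along each operator cascade
_CASCADES = {
    "Cro": (("bOR3", "bOR2", "bOR1"), ("bOL3", "bOL2", "bOL1")),
    "repressor": (("bOR1", "bOR2", "bOR3"), ("bOL1", "bOL2", "bOL3")),
}


def phage_constraint_set(variant: str) -> OrderingConstraints:
    """Ordering constraints for the phage λ threshold sweep.

    ``"free_interleave"``: per-site closeness (adjacency) everywhere, the
    two cascade chains per protein, plus two explicitly admitted orderings
    per protein in which the bOR2 and bOL2 threshold pairs interleave —
    22 orderings per protein, 484 joint.

    ``"or2_ol2_equal"``: the bOR2 and bOL2 thresholds are tied for both
    proteins — 4 per protein, 16 joint.
    """
    if variant not in ("free_interleave", "or2_ol2_equal"):
        raise ValueError(f"unknown variant {variant!r}")
    per: dict[str, SubstanceConstraints] = {}
    for sub, (or_casc, ol_casc) in _CASCADES.items():
        adj_or, ch_or = _cascade_constraints(sub, or_casc)
        adj_ol, ch_ol = _cascade_constraints(sub, ol_casc)
        sc = SubstanceConstraints(sub, chains=ch_or + ch_ol, adjacency_blocks=adj_or + adj_ol)
        if variant == "free_interleave":
            sc.permitted_interleavings = [
                _interleaved(sub, or_casc, ol_casc),
                _interleaved(sub, ol_casc, or_casc),
            ]
        else:
            sc.equalities = [
                frozenset({_k(sub, "bOR2", "dissoc"), _k(sub, "bOL2", "dissoc")}),
                frozenset({_k(sub, "bOR2", "assoc"), _k(sub, "bOL2", "assoc")}),
            ]
        per[sub] = sc
    # CII: the bCII-1 binding concentration exceeds bCII-2's; unique ordering
    per["CII"] = SubstanceConstraints(
        "CII",
        chains=[[_k("CII", "bCII-2", "assoc"), _k("CII", "bCII-1", "dissoc")]],
        adjacency_blocks=[
            (_k("CII", "bCII-2", "dissoc"), _k("CII", "bCII-2", "assoc")),
            (_k("CII", "bCII-1", "dissoc"), _k("CII", "bCII-1", "assoc")),
        ],
    )
    return OrderingConstraints(per_substance=per)


def random_model(seed: int, n_genes: int, n_sites: int, max_ligands: int = 2) -> HSMModel:
    """Random valid model for property tests; reproducible per seed."""
    if n_genes < 1 or n_sites < 0:
        raise ValueError("need n_genes >= 1 and n_sites >= 0")
    rng = random.Random(seed)
    subs = tuple(Substance(f"s{i}") for i in range(n_genes))
    sub_ids = [s.id for s in subs]
    sites = []
    for j in range(n_sites):
        k = rng.randint(1, min(max_ligands, n_genes))
        sites.append(BindingSite(f"r{j}", tuple(rng.sample(sub_ids, k))))
    sites = tuple(sites)
    cfs = []
    gens = []
    for i, sub in enumerate(sub_ids):
        n_inputs = rng.randint(0, min(3, n_sites)) if n_sites else 0
        inputs = tuple(sorted(rng.sample([s.id for s in sites], n_inputs)))
        by_id = {s.id: s for s in sites}
        table = {
            states: rng.randint(0, 1)
            for states in itertools.product(*(by_id[x].states() for x in inputs))
        }
        cfs.append(ControlFunction(f"f{i}", inputs, table))
        gens.append(Generator(f"g{i}", sub, f"f{i}"))
    return HSMModel(
        name=f"random-{seed}",
        substances=subs,
        sites=sites,
        control_functions=tuple(cfs),
        generators=tuple(gens),
    )
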