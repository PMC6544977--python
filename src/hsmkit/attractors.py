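"""Attractor detection, classification across threshold orderings, and
mining of ordering conditions.

An attractor is a set of modes in which the system can remain forever.  The
search works on strongly connected components (SCCs) of the characteristic
graph: an SCC is disqualified when it contains a *progress indicator* — a
substance that rises in every member mode while an association threshold
remains uncrossed (some bindable site stays free), or falls in every member
mode while a site it occupies stays bound.  Either way the substance is
guaranteed to cross a threshold eventually, forcing an exit.  SCCs without
progress indicators, having an internal edge (or being steady sinks), are
reported as attractors; finality (no outgoing edge) is reported separately,
since a candidate may still be exited for particular rate choices.

Attractors are compared across orderings at three granularities:

* the *signature* — canonical form of the subgraph with nodes relabelled by
  direction vectors only and edges by the guard's substance (binding-site
  identities dropped): equality means isomorphic internal dynamics;
* the *behaviour class* — the long-run fate of every substance (decaying to
  zero vs persisting, i.e. cycling or accumulating): this is the coarse
  biological type of the stable behaviour.  Signatures that differ only in
  fine cycle structure (e.g. when tied thresholds make two sites toggle as
  one) share a behaviour class;
* the *fingerprint* — behaviour class plus the set of (site, ligand) pairs
  ever bound inside the attractor: variants of one behaviour that occupy
  different sites get different fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .charph import CharacteristicGraph, Mode, build_characteristic_graph
from .model import HSMModel
from .orderings import OrderingConstraints, ThresholdOrdering, enumerate_orderings, joint_orderings

__all__ = [
    "SCCReport",
    "SweepReport",
    "OrderingResult",
    "strongly_connected_components",
    "progress_indicators",
    "find_attractors",
    "attractor_signature",
    "attractor_fingerprint",
    "behaviour_class",
    "graph_signature",
    "sweep_orderings",
    "mine_conditions",
    "canonical_digraph_form",
]


# ---------------------------------------------------------------------------
# canonical form of a labelled digraph (individualization–refinement)


def _refine(n: int, colors: list[int], out_adj, in_adj) -> list[int]:
    while True:
        sigs = []
        for v in range(n):
            sigs.append(
                (
                    colors[v],
                    tuple(sorted((el, colors[u]) for u, el in out_adj[v])),
                    tuple(sorted((el, colors[u]) for u, el in in_adj[v])),
                )
            )
        remap = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [remap[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def canonical_digraph_form(
    nodes: Sequence, edges: Iterable[tuple], node_label, edge_label
) -> str:
    """Canonical encoding of a node/edge-labelled digraph, invariant under
    relabelling of nodes.  ``node_label(v)`` / ``edge_label(e)`` must return
    strings; *edges* are (u, v) or (u, v, data) tuples.

    Uses colour refinement with individualization and takes the minimal
    encoding over the branch tree — exact for the small graphs (attractor
    SCCs, toy-model graphs) this package handles.
    """
    order = list(nodes)
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    nlab = [str(node_label(v)) for v in order]
    eset = set()
    for e in edges:
        u, v = e[0], e[1]
        eset.add((index[u], index[v], str(edge_label(e))))
    out_adj = [[] for _ in range(n)]
    in_adj = [[] for _ in range(n)]
    for u, v, el in eset:
        out_adj[u].append((v, el))
        in_adj[v].append((u, el))
    lab_ids = {l: i for i, l in enumerate(sorted(set(nlab)))}
    init = [lab_ids[l] for l in nlab]

    best: list[str | None] = [None]

    def encode(colors: list[int]) -> str:
        perm = sorted(range(n), key=lambda v: colors[v])
        pos = {v: i for i, v in enumerate(perm)}
        node_part = "|".join(nlab[v] for v in perm)
        edge_part = ";".join(
            f"{pos[u]}>{pos[v]}:{el}" for u, v, el in sorted(eset, key=lambda t: (pos[t[0]], pos[t[1]], t[2]))
        )
        return node_part + "#" + edge_part

    def rec(colors: list[int]):
        colors = _refine(n, colors, out_adj, in_adj)
        cells: dict[int, list[int]] = {}
        for v, c in enumerate(colors):
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            enc = encode(colors)
            if best[0] is None or enc < best[0]:
                best[0] = enc
            return
        fresh = n + 1
        for v in target:
            c2 = list(colors)
            c2[v] = fresh
            rec(c2)

    rec(init)
    return best[0] or "#"


# ---------------------------------------------------------------------------
# SCC analysis


def _as_nx(graph) -> nx.MultiDiGraph:
    return graph.graph if isinstance(graph, CharacteristicGraph) else graph


def strongly_connected_components(graph) -> list[frozenset]:
    """Exact SCC partition (networkx/Tarjan-class algorithm), components in
    deterministic order (sorted by their minimal node)."""
    g = _as_nx(graph)
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def progress_indicators(model: HSMModel, cg: CharacteristicGraph, scc: Iterable[Mode]) -> list[str]:
    """Substances guaranteed to leave *scc*: uniformly rising with a free
    bindable site in every member mode, or uniformly falling with an
    occupied site in every member mode."""
    sem = cg.semantics
    members = list(scc)
    out = []
    for sub in sem.substances:
        thr = sem._thr[sub]
        if not thr:
            continue
        dirs = {sem.direction(m, sub) for m in members}
        if dirs == {"up"}:
            if all(any(m[pos] == 0 for pos, _, _, _ in thr) for m in members):
                out.append(sub)
        elif dirs == {"down"}:
            if all(any(m[pos] == code for pos, code, _, _ in thr) for m in members):
                out.append(sub)
    return out


@dataclass(frozen=True)
class SCCReport:
    """One strongly connected component with its stability classification."""

    scc_id: int
    modes: tuple[Mode, ...]
    internal_edges: tuple[tuple[Mode, Mode, object], ...]
    progress_indicators: tuple[str, ...]
    is_final: bool
    is_attractor: bool
    structure: str  # steady_node | single_cycle | branched
    guard_substances: tuple[str, ...]
    fingerprint: str | None = None
    signature: str | None = None
    behaviour: str | None = None


def _structure(modes, internal_edges, has_outgoing) -> str:
    if len(modes) == 1 and not internal_edges and not has_outgoing:
        return "steady_node"
    succ: dict[Mode, set[Mode]] = {m: set() for m in modes}
    for u, v, _ in internal_edges:
        succ[u].add(v)
    if internal_edges and all(len(s) == 1 for s in succ.values()):
        return "single_cycle"
    return "branched"


def find_attractors(model: HSMModel, cg: CharacteristicGraph, with_ids: bool = True) -> list[SCCReport]:
    """Annotate every SCC of *cg*; ``is_attractor`` marks components with no
    progress indicator that either contain an internal edge or are steady
    sinks.  Reports are ordered deterministically (by minimal member mode);
    fingerprints/signatures are attached to attractors."""
    g = cg.graph
    comps = strongly_connected_components(cg)
    comp_of: dict[Mode, int] = {}
    for i, c in enumerate(comps):
        for m in c:
            comp_of[m] = i
    internal: dict[int, list] = {i: [] for i in range(len(comps))}
    leaves: set[int] = set()
    for u, v, d in g.edges(data=True):
        cu, cv = comp_of[u], comp_of[v]
        if cu == cv:
            internal[cu].append((u, v, d["guard"]))
        else:
            leaves.add(cu)
    reports = []
    for i, c in enumerate(comps):
        modes = tuple(sorted(c))
        edges = tuple(sorted(internal[i], key=lambda e: (e[0], e[1], e[2].text)))
        pis = tuple(progress_indicators(model, cg, modes))
        is_final = i not in leaves
        steady_sink = len(modes) == 1 and not edges and i not in leaves
        is_attr = not pis and (bool(edges) or steady_sink)
        structure = _structure(modes, edges, i in leaves)
        guards = tuple(sorted({e[2].substance for e in edges}))
        fp = sig = beh = None
        if is_attr:
            beh = behaviour_class(cg, modes)
            fp = attractor_fingerprint(cg, modes, edges)
            sig = attractor_signature(cg, modes, edges)
        reports.append(
            SCCReport(
                scc_id=i,
                modes=modes,
                internal_edges=edges,
                progress_indicators=pis,
                is_final=is_final,
                is_attractor=is_attr,
                structure=structure,
                guard_substances=guards,
                fingerprint=fp,
                signature=sig,
                behaviour=beh,
            )
        )
    return reports


def attractor_signature(cg: CharacteristicGraph, modes, internal_edges) -> str:
    """Canonical form with nodes labelled by direction vectors only and
    edges by guard substance: site identities are dropped, so variants that
    differ only in which sites are occupied collapse together."""
    sem = cg.semantics
    return canonical_digraph_form(
        modes,
        internal_edges,
        node_label=lambda m: sem.direction_label(m),
        edge_label=lambda e: e[2].substance,
    )


def behaviour_class(cg: CharacteristicGraph, modes) -> str:
    """Long-run fate of every substance inside the attractor: ``decays``
    when its direction is down in every member mode (no site stays bound —
    the progress-indicator check already excludes that — so it degrades to
    zero), ``persists`` when it keeps being produced (steadily or
    cyclically), ``constant`` for generator-less inputs.  This is the coarse
    type of the stable behaviour; variants of one type share it."""
    sem = cg.semantics
    fates = []
    for sub in sem.substances:
        dirs = {sem.direction(m, sub) for m in modes}
        if dirs == {"down"}:
            fates.append(f"{sub}=decays")
        elif dirs == {"steady"}:
            fates.append(f"{sub}=constant")
        else:
            fates.append(f"{sub}=persists")
    return ",".join(fates)


def attractor_fingerprint(cg: CharacteristicGraph, modes, internal_edges) -> str:
    """Behaviour class plus the (site, ligand) pairs ever bound within the
    attractor — distinguishes variants of one behaviour that differ in
    binding-site occupancy (tied sites toggling jointly or in sequence over
    the same pairs count as the same variant)."""
    sem = cg.semantics
    bound = set()
    for m in modes:
        for pos, code in enumerate(m):
            if code:
                bound.add(f"{sem.site_ids[pos]}:{sem.ligands[pos][code - 1]}")
    return behaviour_class(cg, modes) + "|bound=" + ";".join(sorted(bound))


def graph_signature(cg: CharacteristicGraph) -> str:
    """Canonical form of the whole characteristic graph with direction-vector
    node labels and (substance, rise/fall) edge labels — equal for graphs
    with identical structure up to threshold renaming."""
    sem = cg.semantics
    nodes = sorted(cg.graph.nodes)
    edges = [(u, v, d["guard"]) for u, v, d in cg.graph.edges(data=True)]
    return canonical_digraph_form(
        nodes,
        edges,
        node_label=lambda m: sem.direction_label(m),
        edge_label=lambda e: f"{e[2].substance}.{e[2].direction}",
    )


# ---------------------------------------------------------------------------
# sweeps across orderings


@dataclass
class OrderingResult:
    ordering_id: int
    ordering: ThresholdOrdering
    attractors: list[SCCReport]
    n_sccs: int
    graph_nodes: int
    graph_signature: str | None = None


@dataclass
class SweepReport:
    """Per-ordering attractor reports plus cross-ordering aggregates."""

    model_name: str
    rows: list[OrderingResult]

    def attractor_counts(self) -> list[int]:
        return [len(r.attractors) for r in self.rows]

    def distinct_fingerprints(self) -> set[str]:
        return {a.fingerprint for r in self.rows for a in r.attractors}

    def distinct_signatures(self) -> set[str]:
        return {a.signature for r in self.rows for a in r.attractors}

    def distinct_behaviours(self) -> set[str]:
        return {a.behaviour for r in self.rows for a in r.attractors}

    def behaviour_orderings(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for r in self.rows:
            for a in r.attractors:
                out.setdefault(a.behaviour, set()).add(r.ordering_id)
        return out

    def signature_orderings(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for r in self.rows:
            for a in r.attractors:
                out.setdefault(a.signature, set()).add(r.ordering_id)
        return out

    def signature_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(sorted(self.distinct_signatures()))}

    def fingerprint_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(sorted(self.distinct_fingerprints()))}

    def behaviour_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(sorted(self.distinct_behaviours()))}

    def to_frame(self) -> pd.DataFrame:
        sig_ix, fp_ix = self.signature_index(), self.fingerprint_index()
        beh_ix = self.behaviour_index()
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "ordering_id": r.ordering_id,
                    "ordering": r.ordering.id,
                    "n_attractors": len(r.attractors),
                    "fingerprint_ids": ",".join(str(fp_ix[a.fingerprint]) for a in r.attractors),
                    "signature_ids": ",".join(str(sig_ix[a.signature]) for a in r.attractors),
                    "behaviours": ",".join(str(beh_ix[a.behaviour]) for a in r.attractors),
                }
            )
        return pd.DataFrame.from_records(recs)


def _enumerate_joint(model: HSMModel, constraints: OrderingConstraints) -> list[ThresholdOrdering]:
    lists = []
    for sub in model.substance_ids():
        if model.threshold_keys(sub):
            lists.append(enumerate_orderings(model, constraints, sub))
    return joint_orderings(lists)


def sweep_orderings(
    model: HSMModel,
    constraint_variants: Sequence[OrderingConstraints],
    seeds="all_consistent",
    with_graph_signature: bool = False,
) -> SweepReport:
    """Build a characteristic graph for every joint ordering admitted by any
    of the *constraint_variants* (concatenated, duplicate-free) and collect
    the attractor reports of each."""
    orderings: list[ThresholdOrdering] = []
    seen = set()
    for cons in constraint_variants:
        for o in _enumerate_joint(model, cons):
            if o not in seen:
                seen.add(o)
                orderings.append(o)
    rows = []
    for i, ordering in enumerate(orderings):
        try:
            cg = build_characteristic_graph(model, ordering, seeds=seeds)
            reports = find_attractors(model, cg)
        except Exception as e:  # pragma: no cover - surfaced with context
            raise RuntimeError(f"sweep failed for ordering {i} ({ordering.id})") from e
        rows.append(
            OrderingResult(
                ordering_id=i,
                ordering=ordering,
                attractors=[r for r in reports if r.is_attractor],
                n_sccs=len(reports),
                graph_nodes=cg.n_nodes,
                graph_signature=graph_signature(cg) if with_graph_signature else None,
            )
        )
    return SweepReport(model_name=model.name, rows=rows)


# ---------------------------------------------------------------------------
# condition mining


def _relations(ordering: ThresholdOrdering) -> set[str]:
    rels = set()
    for sub in ordering.substances:
        rank = ordering.rank_map(sub)
        keys = sorted(rank)
        for a in keys:
            for b in keys:
                if a != b and rank[a] < rank[b]:
                    rels.add(f"{sub}: {a.label} < {b.label}")
    return rels


def _relation_universe(ordering: ThresholdOrdering) -> set[str]:
    rels = set()
    for sub in ordering.substances:
        keys = sorted(ordering.rank_map(sub))
        for a in keys:
            for b in keys:
                if a != b:
                    rels.add(f"{sub}: {a.label} < {b.label}")
    return rels


def mine_conditions(sweep: SweepReport) -> dict[str, dict[str, list[str]]]:
    """Threshold-order relations shared by the orderings producing each
    behaviour.

    For each attractor signature the result lists the pairwise rank
    relations (``"sub: a.label < b.label"``) that hold in **every** ordering
    yielding that signature (``"always"`` — necessary within the sweep) and
    those holding in **none** (``"never"``).  Sufficiency of a relation for
    a behaviour can then be checked against the sweep rows.
    """
    if not sweep.rows:
        return {}
    universe = _relation_universe(sweep.rows[0].ordering)
    rel_cache: dict[int, set[str]] = {}
    out: dict[str, dict[str, list[str]]] = {}
    for sig, ordering_ids in sorted(sweep.signature_orderings().items()):
        if not ordering_ids:
            continue
        always: set[str] | None = None
        union: set[str] = set()
        for oid in sorted(ordering_ids):
            rels = rel_cache.get(oid)
            if rels is None:
                rels = rel_cache[oid] = _relations(sweep.rows[oid].ordering)
            always = set(rels) if always is None else (always & rels)
            union |= rels
        out[sig] = {"always": sorted(always or ()), "never": sorted(universe - union)}
    return out
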