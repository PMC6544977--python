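"""Mode semantics and characteristic-graph construction.

A *mode* records the state of every binding site (FREE or bound by one of
its ligands).  Under a fixed threshold ordering a mode constrains each
substance's concentration to an interval: above the dissociation threshold
of every site it occupies, below the association threshold of every free
site it could occupy.  A mode is *consistent* when all those intervals are
non-empty.

Within a mode each gene's expression is fixed by its control function, so
each substance monotonically rises (gene on) or falls (gene off).  The only
events are threshold crossings: a rising substance binds the free site with
the lowest uncrossed association rank; a falling substance releases the
bound site with the highest dissociation rank.  Tied thresholds fire as one
compound event.  The *characteristic graph* collects all consistent modes
and all guarded transitions between them — a safe over-approximation of
every numeric run of the model, for any rates and initial concentrations
compatible with the ordering.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx

from .model import FREE, HSMModel, ThresholdKey
from .orderings import ThresholdOrdering

__all__ = [
    "Mode",
    "Guard",
    "CharacteristicGraph",
    "ModelSemantics",
    "is_consistent_mode",
    "direction_vector",
    "enabled_events",
    "build_characteristic_graph",
    "iter_consistent_modes",
    "UP",
    "DOWN",
    "STEADY",
]

UP, DOWN, STEADY = "up", "down", "steady"
ARROWS = {UP: "↑", DOWN: "↓", STEADY: "→"}

#: A mode is a tuple of state codes aligned with the model's site order:
#: 0 = FREE, k = bound by ligands[k-1].
Mode = tuple[int, ...]


@dataclass(frozen=True)
class Guard:
    """Transition guard: the threshold crossing(s) that trigger an event.

    ``direction`` is ``"rise"`` (concentration reaches association
    thresholds; sites bind) or ``"fall"`` (drops to dissociation thresholds;
    sites release).  ``atoms`` lists the crossed keys — more than one when
    thresholds are tied.
    """

    substance: str
    direction: Literal["rise", "fall"]
    atoms: tuple[ThresholdKey, ...]

    @property
    def text(self) -> str:
        op = "≥" if self.direction == "rise" else "≤"
        return " & ".join(f"{self.substance} {op} {k.label}" for k in self.atoms)


class InconsistentModeError(ValueError):
    """A mode leaves some substance with an empty concentration interval."""


class ModelSemantics:
    """Cached per-model/per-ordering machinery for fast mode arithmetic."""

    def __init__(self, model: HSMModel, ordering: ThresholdOrdering | None = None):
        self.model = model
        self.ordering = ordering
        self.site_ids = [s.id for s in model.sites]
        self.site_index = {s: i for i, s in enumerate(self.site_ids)}
        self.ligands = [model.sites[i].ligands for i in range(len(model.sites))]
        self.substances = model.substance_ids()
        # generator/control lookup: substance -> (cf input indices, int-coded table) or None
        self._expr: dict[str, tuple[tuple[int, ...], dict[tuple[int, ...], int]] | None] = {}
        for sub in self.substances:
            gen = model.generator_for(sub)
            if gen is None:
                self._expr[sub] = None
                continue
            cf = model.control(gen.control)
            idx = tuple(self.site_index[i] for i in cf.inputs)
            coded: dict[tuple[int, ...], int] = {}
            for states, level in cf.table.items():
                codes = []
                for site_id, st in zip(cf.inputs, states):
                    site = model.site(site_id)
                    codes.append(0 if st == FREE else site.ligands.index(st.split(":", 1)[1]) + 1)
                coded[tuple(codes)] = level
            self._expr[sub] = (idx, coded)
        # (substance -> [(site_pos, ligand_code, dis_rank, as_rank)])
        self._thr: dict[str, list[tuple[int, int, int, int]]] = {}
        if ordering is not None:
            for sub in self.substances:
                entries = []
                keys = model.threshold_keys(sub)
                if keys:
                    rank = ordering.rank_map(sub)
                    for i, site in enumerate(model.sites):
                        if sub in site.ligands:
                            code = site.ligands.index(sub) + 1
                            entries.append(
                                (
                                    i,
                                    code,
                                    rank[ThresholdKey(sub, site.id, "dissoc")],
                                    rank[ThresholdKey(sub, site.id, "assoc")],
                                )
                            )
                self._thr[sub] = entries

    # -- derived vectors -------------------------------------------------
    def expression(self, mode: Mode, substance: str) -> int | None:
        entry = self._expr[substance]
        if entry is None:
            return None
        idx, coded = entry
        return coded[tuple(mode[i] for i in idx)]

    def direction(self, mode: Mode, substance: str) -> str:
        level = self.expression(mode, substance)
        if level is None:
            return STEADY
        return UP if level > 0 else DOWN

    def direction_vector(self, mode: Mode) -> tuple[str, ...]:
        return tuple(self.direction(mode, s) for s in self.substances)

    def direction_label(self, mode: Mode) -> str:
        return "".join(ARROWS[d] for d in self.direction_vector(mode))

    def mode_label(self, mode: Mode) -> str:
        parts = []
        for i, code in enumerate(mode):
            st = FREE if code == 0 else self.ligands[i][code - 1]
            parts.append(f"{self.site_ids[i]}:{st}")
        return ",".join(parts)

    # -- consistency -----------------------------------------------------
    def bounds(self, mode: Mode, substance: str) -> tuple[int, int]:
        """(max dissoc rank over bound sites, min assoc rank over free sites);
        vacuous sides are +/- a large sentinel."""
        lo, hi = -(10**9), 10**9
        for pos, code, dis_r, as_r in self._thr[substance]:
            st = mode[pos]
            if st == code:
                if dis_r > lo:
                    lo = dis_r
            elif st == 0:
                if as_r < hi:
                    hi = as_r
        return lo, hi

    def is_consistent(self, mode: Mode) -> bool:
        for sub in self.substances:
            lo, hi = self.bounds(mode, sub)
            if lo >= hi:
                return False
        return True

    def inconsistent_substances(self, mode: Mode) -> list[str]:
        return [s for s in self.substances if self.bounds(mode, s)[0] >= self.bounds(mode, s)[1]]

    # -- events ----------------------------------------------------------
    def _closure(self, mode: Mode) -> list[Mode]:
        """Consistent completions of *mode*: when a release leaves a free
        site whose association threshold is already below some substance's
        implied concentration, that substance binds it immediately.  If a
        site is claimed by several substances at once, branch."""
        if self.is_consistent(mode):
            return [mode]
        # offending (site position -> candidate ligand codes)
        claims: dict[int, list[tuple[str, int]]] = {}
        for sub in self.substances:
            lo, hi = self.bounds(mode, sub)
            if lo < hi:
                continue
            for pos, code, dis_r, as_r in self._thr[sub]:
                if mode[pos] == 0 and as_r <= lo:
                    claims.setdefault(pos, []).append((sub, code))
        if not claims:
            return []  # inconsistent but not fixable by binding
        out: list[Mode] = []
        positions = sorted(claims)
        for choice in itertools.product(*(claims[p] for p in positions)):
            new = list(mode)
            for p, (_, code) in zip(positions, choice):
                new[p] = code
            for m in self._closure(tuple(new)):
                if m not in out:
                    out.append(m)
        return out

    def enabled_events(self, mode: Mode) -> list[tuple[Guard, Mode]]:
        if not self.is_consistent(mode):
            raise InconsistentModeError(
                f"mode {self.mode_label(mode)} inconsistent for {self.inconsistent_substances(mode)}"
            )
        events: list[tuple[Guard, Mode]] = []
        for sub in self.substances:
            d = self.direction(mode, sub)
            thr = self._thr[sub]
            if d == UP:
                free = [(as_r, pos, code) for pos, code, _, as_r in thr if mode[pos] == 0]
                if not free:
                    continue
                best = min(r for r, _, _ in free)
                tied = [(pos, code) for r, pos, code in free if r == best]
                new = list(mode)
                for pos, code in tied:
                    new[pos] = code
                atoms = tuple(
                    sorted(ThresholdKey(sub, self.site_ids[pos], "assoc") for pos, _ in tied)
                )
                guard = Guard(sub, "rise", atoms)
                for target in self._closure(tuple(new)):
                    events.append((guard, target))
            elif d == DOWN:
                bound = [(dis_r, pos) for pos, code, dis_r, _ in thr if mode[pos] == code]
                if not bound:
                    continue
                best = max(r for r, _ in bound)
                tied = [pos for r, pos in bound if r == best]
                new = list(mode)
                for pos in tied:
                    new[pos] = 0
                atoms = tuple(sorted(ThresholdKey(sub, self.site_ids[pos], "dissoc") for pos in tied))
                guard = Guard(sub, "fall", atoms)
                for target in self._closure(tuple(new)):
                    events.append((guard, target))
        return events

    def settled_modes(self) -> list[Mode]:
        """Modes arising by settling some concentration vector: per
        substance, sites bind in ascending association-rank order, so the
        bound set is a rank-prefix; a site claimed by several ligands goes
        to the first declared one.  These are the possible initial modes of
        numeric runs."""
        regions: list[list[frozenset[int]]] = []  # per substance: possible bound-site sets
        for sub in self.substances:
            thr = self._thr[sub]
            if not thr:
                regions.append([frozenset()])
                continue
            cuts = sorted({as_r for _, _, _, as_r in thr})
            opts = [frozenset()]
            for c in cuts:
                opts.append(frozenset(pos for pos, _, _, as_r in thr if as_r <= c))
            regions.append(sorted(set(opts), key=sorted))
        out = set()
        for combo in itertools.product(*regions):
            mode = [0] * len(self.site_ids)
            for pos in range(len(self.site_ids)):
                for k, lig in enumerate(self.ligands[pos]):
                    si = self.substances.index(lig)
                    if pos in combo[si]:
                        mode[pos] = k + 1
                        break
            m = tuple(mode)
            if self.is_consistent(m):
                out.add(m)
        return sorted(out)

    # -- mode enumeration -------------------------------------------------
    def iter_consistent_modes(self) -> Iterable[Mode]:
        """Depth-first enumeration of all consistent modes with incremental
        pruning (an interval once empty cannot be refilled by later sites)."""
        n_sites = len(self.site_ids)
        # per-substance constraints indexed by site position
        per_pos: list[list[tuple[str, int, int, int]]] = [[] for _ in range(n_sites)]
        for sub in self.substances:
            for pos, code, dis_r, as_r in self._thr[sub]:
                per_pos[pos].append((sub, code, dis_r, as_r))
        lo = {s: -(10**9) for s in self.substances}
        hi = {s: 10**9 for s in self.substances}
        mode = [0] * n_sites

        def rec(pos: int):
            if pos == n_sites:
                yield tuple(mode)
                return
            n_states = len(self.ligands[pos]) + 1
            for code in range(n_states):
                updates: list[tuple[str, str, int]] = []
                ok = True
                for sub, lig_code, dis_r, as_r in per_pos[pos]:
                    if code == lig_code:
                        if dis_r > lo[sub]:
                            updates.append((sub, "lo", lo[sub]))
                            lo[sub] = dis_r
                    elif code == 0:
                        if as_r < hi[sub]:
                            updates.append((sub, "hi", hi[sub]))
                            hi[sub] = as_r
                    if lo[sub] >= hi[sub]:
                        ok = False
                if ok:
                    mode[pos] = code
                    yield from rec(pos + 1)
                for sub, which, old in reversed(updates):
                    if which == "lo":
                        lo[sub] = old
                    else:
                        hi[sub] = old
            mode[pos] = 0

        yield from rec(0)


# ---------------------------------------------------------------------------
# module-level wrappers (one-shot; build a ModelSemantics for repeated use)


def is_consistent_mode(model: HSMModel, ordering: ThresholdOrdering, mode: Mode) -> bool:
    return ModelSemantics(model, ordering).is_consistent(mode)


def direction_vector(model: HSMModel, mode: Mode) -> tuple[str, ...]:
    """Per-substance direction (``"up"``/``"down"``/``"steady"``), in the
    model's substance order.  ``steady`` only for substances without a
    generator."""
    return ModelSemantics(model).direction_vector(mode)


def enabled_events(
    model: HSMModel, ordering: ThresholdOrdering, mode: Mode
) -> list[tuple[Guard, Mode]]:
    return ModelSemantics(model, ordering).enabled_events(mode)


def iter_consistent_modes(model: HSMModel, ordering: ThresholdOrdering) -> Iterable[Mode]:
    return ModelSemantics(model, ordering).iter_consistent_modes()


@dataclass
class CharacteristicGraph:
    """All modes and guarded transitions admissible under one ordering.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose nodes are mode
    tuples; node attributes carry the site-state and direction labels, edge
    attribute ``guard`` the :class:`Guard`.
    """

    model: HSMModel
    ordering: ThresholdOrdering
    graph: nx.MultiDiGraph
    semantics: ModelSemantics = field(repr=False, default=None)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[Mode, Mode, Guard]]:
        return [(u, v, d["guard"]) for u, v, d in self.graph.edges(data=True)]


def _model_hash(model: HSMModel) -> str:
    from .model import model_to_dict
    import json

    return hashlib.sha256(json.dumps(model_to_dict(model), sort_keys=True).encode()).hexdigest()[:16]


def build_characteristic_graph(
    model: HSMModel,
    ordering: ThresholdOrdering,
    seeds: Literal["all_consistent", "settled"] | Sequence[Mode] = "all_consistent",
) -> CharacteristicGraph:
    """Build the characteristic graph for *model* under *ordering*.

    With the default ``seeds="all_consistent"`` every consistent mode is a
    node (the full feasible-state graph); ``seeds="settled"`` restricts to
    modes reachable from some settled initial state (the graph realisable
    by numeric runs); an explicit seed list yields the closure of those
    modes.  Construction is deterministic: nodes and edges are added in
    canonical mode order.
    """
    sem = ModelSemantics(model, ordering)
    if seeds == "all_consistent":
        nodes = sorted(sem.iter_consistent_modes())
    elif seeds == "settled":
        nodes = sem.settled_modes()
    else:
        nodes = sorted(set(seeds))
        for m in nodes:
            if not sem.is_consistent(m):
                raise InconsistentModeError(
                    f"seed mode {sem.mode_label(m)} inconsistent for {sem.inconsistent_substances(m)}"
                )
    g = nx.MultiDiGraph()
    queue = list(nodes)
    seen = set(nodes)
    for m in queue:
        g.add_node(m, label=sem.mode_label(m), directions=sem.direction_label(m))
    i = 0
    while i < len(queue):
        m = queue[i]
        i += 1
        for guard, target in sem.enabled_events(m):
            if target not in seen:
                seen.add(target)
                queue.append(target)
                g.add_node(target, label=sem.mode_label(target), directions=sem.direction_label(target))
            g.add_edge(m, target, guard=guard, label=guard.text)
    meta = {"model": model.name, "model_hash": _model_hash(model), "ordering_id": ordering.id}
    return CharacteristicGraph(model=model, ordering=ordering, graph=g, semantics=sem, metadata=meta)
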