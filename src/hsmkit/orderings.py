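"""Enumeration of threshold orderings compatible with partial constraints.

For each substance the association/dissociation thresholds of its binding
sites form a total preorder (ties allowed, represented as rank-groups).  When
affinities are only partially known, every linear ordering consistent with
the declared constraints is enumerated; the analysis downstream is then run
once per ordering.

Constraint vocabulary (per substance):

* ``chains`` — lists of threshold keys that must appear in strictly
  increasing rank order;
* ``adjacency_blocks`` — pairs (a, b) that must be consecutive, a
  immediately before b (used for "dissociation immediately before
  association of the same site" closeness assumptions);
* ``equalities`` — sets of keys forced to share a rank (tied thresholds);
* ``permitted_interleavings`` — explicit complete orderings that are admitted
  in addition to the constrained enumeration; they must satisfy the chains
  but are exempt from adjacency (used to admit a handful of orderings in
  which two sites' threshold pairs interleave).

``dissoc < assoc`` for every (substance, site) pair is an implicit, always-on
chain.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import HSMModel, ThresholdKey

__all__ = [
    "ThresholdOrdering",
    "SubstanceConstraints",
    "OrderingConstraints",
    "ConstraintError",
    "enumerate_orderings",
    "joint_orderings",
    "check_ordering",
    "phage_constraint_set",
    "read_constraints",
    "write_constraints",
]

log = logging.getLogger(__name__)

RankGroup = tuple[ThresholdKey, ...]


class ConstraintError(ValueError):
    """Unsatisfiable or ill-formed ordering constraints."""


@dataclass(frozen=True)
class ThresholdOrdering:
    """A total preorder over threshold keys, per substance.

    ``groups`` maps substance id -> ordered tuple of rank-groups; each
    rank-group is a sorted tuple of keys (singleton unless tied).  A joint
    ordering simply carries several substances.
    """

    groups: tuple[tuple[str, tuple[RankGroup, ...]], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[Sequence[ThresholdKey]]]) -> "ThresholdOrdering":
        items = []
        for sub in sorted(mapping):
            items.append((sub, tuple(tuple(sorted(g)) for g in mapping[sub])))
        return cls(groups=tuple(items))

    @property
    def substances(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.groups)

    def groups_for(self, substance: str) -> tuple[RankGroup, ...]:
        for s, gs in self.groups:
            if s == substance:
                return gs
        raise KeyError(substance)

    def rank(self, key: ThresholdKey) -> int:
        for i, group in enumerate(self.groups_for(key.substance)):
            if key in group:
                return i
        raise KeyError(key.qualified)

    def rank_map(self, substance: str) -> dict[ThresholdKey, int]:
        return {k: i for i, g in enumerate(self.groups_for(substance)) for k in g}

    def substance_string(self, substance: str) -> str:
        return " < ".join(" = ".join(k.label for k in g) for g in self.groups_for(substance))

    @property
    def id(self) -> str:
        """Canonical textual identity of the (joint) ordering."""
        return "; ".join(f"{s}: {self.substance_string(s)}" for s in self.substances)

    def merge(self, other: "ThresholdOrdering") -> "ThresholdOrdering":
        overlap = set(self.substances) & set(other.substances)
        if overlap:
            raise ValueError(f"orderings overlap on substances {sorted(overlap)}")
        return ThresholdOrdering.from_mapping(dict(self.groups) | dict(other.groups))

    def _sort_key(self):
        return tuple((s, tuple(tuple(k.label for k in g) for g in gs)) for s, gs in self.groups)


@dataclass
class SubstanceConstraints:
    substance: str
    chains: list[list[ThresholdKey]] = field(default_factory=list)
    adjacency_blocks: list[tuple[ThresholdKey, ThresholdKey]] = field(default_factory=list)
    equalities: list[frozenset[ThresholdKey]] = field(default_factory=list)
    permitted_interleavings: list[list[ThresholdKey]] = field(default_factory=list)


@dataclass
class OrderingConstraints:
    """Per-substance constraint sets; substances absent here are constrained
    only by the implicit per-site dissoc < assoc chains."""

    per_substance: dict[str, SubstanceConstraints] = field(default_factory=dict)

    def for_substance(self, substance: str) -> SubstanceConstraints:
        return self.per_substance.get(substance, SubstanceConstraints(substance))


# ---------------------------------------------------------------------------
# enumeration


def _implicit_chains(model: HSMModel, substance: str) -> list[list[ThresholdKey]]:
    chains = []
    keys = model.threshold_keys(substance)
    for site in {k.site for k in keys}:
        chains.append(
            [ThresholdKey(substance, site, "dissoc"), ThresholdKey(substance, site, "assoc")]
        )
    return chains


def _union_find_groups(keys: Sequence[ThresholdKey], equalities: Iterable[frozenset[ThresholdKey]]):
    parent = {k: k for k in keys}

    def find(x):
        while parent[x] is not x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for eq in equalities:
        eq = sorted(eq)
        for a, b in zip(eq, eq[1:]):
            ra, rb = find(a), find(b)
            if ra is not rb:
                parent[ra] = rb
    groups: dict[ThresholdKey, list[ThresholdKey]] = {}
    for k in keys:
        groups.setdefault(find(k), []).append(k)
    return {k: tuple(sorted(v)) for v in groups.values() for k in v}


def enumerate_orderings(
    model: HSMModel, constraints: OrderingConstraints, substance: str
) -> list[ThresholdOrdering]:
    """All total preorders of *substance*'s threshold keys satisfying the
    constraints, exhaustive and duplicate-free, in lexicographic order.

    Unsatisfiable constraints yield an empty list (a warning is logged);
    references to unknown keys raise :class:`ConstraintError`.
    """
    keys = model.threshold_keys(substance)
    if substance not in model.substance_ids():
        raise ConstraintError(f"unknown substance {substance!r}")
    keyset = set(keys)
    sc = constraints.for_substance(substance)
    for chain in sc.chains:
        for k in chain:
            if k not in keyset:
                raise ConstraintError(f"chain references unknown key {k.qualified}")
    for a, b in sc.adjacency_blocks:
        if a not in keyset or b not in keyset:
            raise ConstraintError(f"adjacency references unknown key {(a, b)}")
    for eq in sc.equalities:
        for k in eq:
            if k not in keyset:
                raise ConstraintError(f"equality references unknown key {k.qualified}")

    chains = _implicit_chains(model, substance) + [list(c) for c in sc.chains]

    # rank-groups from equalities
    group_of = _union_find_groups(keys, sc.equalities)
    # a group may not contain both thresholds of one site (dissoc < assoc is strict)
    for g in set(group_of.values()):
        sites = [(k.site, k.kind) for k in g]
        if len({s for s, _ in sites}) < len(g):
            log.warning("unsatisfiable: equality ties dissoc and assoc of one site (%s)", g)
            return _with_interleavings([], sc, chains, keys, substance)

    # units: maximal runs of groups forced consecutive by adjacency blocks
    units: list[list[RankGroup]] = []
    unit_of: dict[RankGroup, int] = {}
    for g in sorted(set(group_of.values())):
        unit_of[g] = len(units)
        units.append([g])

    def unit_index(g: RankGroup) -> int:
        return unit_of[g]

    ok = True
    for a, b in sc.adjacency_blocks:
        ga, gb = group_of[a], group_of[b]
        if ga == gb:
            ok = False
            break
        ua, ub = unit_index(ga), unit_index(gb)
        if ua == ub:
            seq = units[ua]
            ia, ib = seq.index(ga), seq.index(gb)
            if ib != ia + 1:
                ok = False
                break
            continue
        if units[ua][-1] is not ga and units[ua][-1] != ga:
            ok = False
            break
        if units[ub][0] != gb:
            ok = False
            break
        merged = units[ua] + units[ub]
        units[ua] = merged
        for g in units[ub]:
            unit_of[g] = ua
        units[ub] = []
    if not ok:
        log.warning("unsatisfiable adjacency constraints for %s", substance)
        return _with_interleavings([], sc, chains, keys, substance)

    live = [u for u in units if u]
    index_of = {id(u): i for i, u in enumerate(live)}
    unit_ids = {g: index_of[id(u)] for u in live for g in u}

    # precedence edges between units from chains
    n = len(live)
    succ: list[set[int]] = [set() for _ in range(n)]
    pred_count = [0] * n
    pos_in_unit = {g: (unit_ids[g], i) for u in live for i, g in enumerate(u)}
    edges = set()
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            ga, gb = group_of[a], group_of[b]
            (ua, ia), (ub, ib) = pos_in_unit[ga], pos_in_unit[gb]
            if ua == ub:
                if ia >= ib:
                    log.warning("unsatisfiable chain %s for %s", [k.label for k in chain], substance)
                    return _with_interleavings([], sc, chains, keys, substance)
                continue
            if (ua, ub) not in edges:
                edges.add((ua, ub))
                succ[ua].add(ub)
                pred_count[ub] += 1

    # lexicographic backtracking over topological orders of units
    unit_key = [tuple(tuple(k.label for k in g) for g in u) for u in live]
    order = sorted(range(n), key=lambda i: unit_key[i])
    results: list[ThresholdOrdering] = []
    placed: list[int] = []
    remaining_pred = pred_count[:]

    def backtrack():
        if len(placed) == n:
            flat = [g for i in placed for g in live[i]]
            results.append(ThresholdOrdering.from_mapping({substance: flat}))
            return
        for i in order:
            if remaining_pred[i] == 0 and i not in placed:
                placed.append(i)
                for j in succ[i]:
                    remaining_pred[j] -= 1
                backtrack()
                for j in succ[i]:
                    remaining_pred[j] += 1
                placed.pop()

    backtrack()
    return _with_interleavings(results, sc, chains, keys, substance)


def _with_interleavings(results, sc: SubstanceConstraints, chains, keys, substance):
    """Append the explicitly permitted interleaved orderings (adjacency-exempt)."""
    out = list(results)
    for seq in sc.permitted_interleavings:
        if sorted(seq) != sorted(keys):
            raise ConstraintError(
                f"permitted interleaving for {substance} must list every threshold key exactly once"
            )
        rank = {k: i for i, k in enumerate(seq)}
        if any(rank[a] >= rank[b] for chain in chains for a, b in zip(chain, chain[1:])):
            raise ConstraintError(f"permitted interleaving for {substance} violates a chain constraint")
        out.append(ThresholdOrdering.from_mapping({substance: [[k] for k in seq]}))
    seen = set()
    unique = []
    for o in out:
        if o not in seen:
            seen.add(o)
            unique.append(o)
    return sorted(unique, key=lambda o: o._sort_key())


def check_ordering(
    model: HSMModel, constraints: OrderingConstraints, ordering: ThresholdOrdering, substance: str
) -> bool:
    """Independent checker: does *ordering* satisfy all constraints for
    *substance*?  (Permitted interleavings are checked against chains only.)"""
    keys = model.threshold_keys(substance)
    rank = ordering.rank_map(substance)
    if set(rank) != set(keys):
        return False
    sc = constraints.for_substance(substance)
    chains = _implicit_chains(model, substance) + [list(c) for c in sc.chains]
    chains_ok = all(rank[a] < rank[b] for chain in chains for a, b in zip(chain, chain[1:]))
    if not chains_ok:
        return False
    for eq in sc.equalities:
        eq = list(eq)
        if any(rank[k] != rank[eq[0]] for k in eq):
            return False
    flat = [k for g in ordering.groups_for(substance) for k in sorted(g)]
    for seq in sc.permitted_interleavings:
        if flat == list(seq):
            return True  # adjacency-exempt
    for a, b in sc.adjacency_blocks:
        if rank[b] != rank[a] + 1:
            return False
        # nothing strictly between: rank-adjacency suffices in a preorder
    return True


def joint_orderings(per_substance_lists: Sequence[Sequence[ThresholdOrdering]]) -> list[ThresholdOrdering]:
    """Cartesian combination of per-substance ordering lists, in product order.

    An empty input list yields an empty product (with a logged diagnostic);
    no input lists at all (a model without thresholds) yield the single
    empty ordering.
    """
    if not per_substance_lists:
        return [ThresholdOrdering.from_mapping({})]
    for lst in per_substance_lists:
        if not lst:
            log.warning("joint_orderings: an input list is empty; product is empty")
            return []
    out = []
    for combo in itertools.product(*per_substance_lists):
        joint = combo[0]
        for o in combo[1:]:
            joint = joint.merge(o)
        out.append(joint)
    return out


def phage_constraint_set(variant: str) -> OrderingConstraints:
    """Constraint sets for the phage λ operator-threshold sweep; see
    :func:`hsmkit.fixtures.phage_constraint_set`."""
    from .fixtures import phage_constraint_set as _builder

    return _builder(variant)


# ---------------------------------------------------------------------------
# constraint file IO


def _key_to_json(k: ThresholdKey) -> str:
    return k.qualified


def _key_from_json(s: str) -> ThresholdKey:
    sub, _, label = s.partition(":")
    return ThresholdKey.from_label(sub, label)


def write_constraints(constraints: OrderingConstraints, path: str | Path) -> None:
    data = {
        sub: {
            "chains": [[_key_to_json(k) for k in c] for c in sc.chains],
            "adjacency_blocks": [[_key_to_json(a), _key_to_json(b)] for a, b in sc.adjacency_blocks],
            "equalities": [sorted(_key_to_json(k) for k in eq) for eq in sc.equalities],
            "permitted_interleavings": [[_key_to_json(k) for k in seq] for seq in sc.permitted_interleavings],
        }
        for sub, sc in sorted(constraints.per_substance.items())
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_constraints(path: str | Path) -> OrderingConstraints:
    data = json.loads(Path(path).read_text())
    per = {}
    for sub, sc in data.items():
        per[sub] = SubstanceConstraints(
            substance=sub,
            chains=[[_key_from_json(k) for k in c] for c in sc.get("chains", [])],
            adjacency_blocks=[
                (_key_from_json(a), _key_from_json(b)) for a, b in sc.get("adjacency_blocks", [])
            ],
            equalities=[frozenset(_key_from_json(k) for k in eq) for eq in sc.get("equalities", [])],
            permitted_interleavings=[
                [_key_from_json(k) for k in seq] for seq in sc.get("permitted_interleavings", [])
            ],
        )
    return OrderingConstraints(per_substance=per)
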