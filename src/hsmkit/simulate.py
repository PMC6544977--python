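"""Event-driven numeric simulation of HSM models.

Kinetics are piecewise linear: while a gene is expressed its product grows
at a constant rate, otherwise it decays at a constant rate, floored at
zero.  Binding is hysteretic: a site binds when the ligand concentration
reaches the association threshold on the way up (inclusive) and releases
when it falls to the dissociation threshold (inclusive).  Event times are
exact for linear dynamics — the next event is the earliest pending
threshold crossing; crossings at equal times fire as one compound event.

The simulator exists chiefly to validate the characteristic graph: every
run's mode sequence must be a walk in the graph built for the ordering the
numeric thresholds induce (:func:`conforms`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .charph import DOWN, STEADY, UP, CharacteristicGraph, Mode, ModelSemantics
from .model import HSMModel, ThresholdKey
from .orderings import ThresholdOrdering

__all__ = [
    "NumericParameters",
    "Run",
    "settle_initial_mode",
    "simulate",
    "conforms",
    "induced_ordering",
    "params_from_ordering",
]

_TIME_TOL = 1e-9


@dataclass
class NumericParameters:
    """Threshold values per (substance, site) pair and per-gene rates.

    ``thresholds`` maps :class:`ThresholdKey` to a positive value with
    dissociation < association for each pair; ``rates`` maps a generator id
    to ``(growth, degradation)``, both positive (concentration per unit
    time)."""

    thresholds: dict[ThresholdKey, float]
    rates: dict[str, tuple[float, float]]

    def validate(self, model: HSMModel) -> None:
        for sub in model.substance_ids():
            for key in model.threshold_keys(sub):
                if key not in self.thresholds:
                    raise ValueError(f"missing threshold value for {key.qualified}")
            for site in model.sites:
                if sub in site.ligands:
                    d = self.thresholds[ThresholdKey(sub, site.id, "dissoc")]
                    a = self.thresholds[ThresholdKey(sub, site.id, "assoc")]
                    if not (0 < d < a):
                        raise ValueError(f"{sub}/{site.id}: need 0 < dissoc ({d}) < assoc ({a})")
        for g in model.generators:
            gr, dr = self.rates.get(g.id, (None, None))
            if gr is None or not (gr > 0 and dr > 0):
                raise ValueError(f"generator {g.id}: growth and degradation rates must be positive")


def induced_ordering(model: HSMModel, params: NumericParameters) -> ThresholdOrdering:
    """Total preorder of each substance's thresholds induced by the numeric
    values (equal values share a rank)."""
    mapping = {}
    for sub in model.substance_ids():
        keys = model.threshold_keys(sub)
        if not keys:
            continue
        by_value: dict[float, list[ThresholdKey]] = {}
        for k in keys:
            by_value.setdefault(params.thresholds[k], []).append(k)
        mapping[sub] = [sorted(by_value[v]) for v in sorted(by_value)]
    return ThresholdOrdering.from_mapping(mapping)


def params_from_ordering(
    model: HSMModel, ordering: ThresholdOrdering, rng=None, base: float = 1.0
) -> NumericParameters:
    """Numeric parameters realising *ordering*: rank ``i`` maps to value
    ``base * (i + 1)`` (ties equal), optionally jittered (order-preserving)
    and with random rates when *rng* (a :class:`random.Random`) is given."""
    thresholds: dict[ThresholdKey, float] = {}
    for sub in ordering.substances:
        groups = ordering.groups_for(sub)
        values = []
        prev = 0.0
        for i in range(len(groups)):
            lo, hi = prev + 0.1 * base, base * (i + 1)
            v = rng.uniform(lo, max(hi, lo + 0.1 * base)) if rng else base * (i + 1)
            v = max(v, prev + 1e-3 * base)
            values.append(v)
            prev = v
        for i, group in enumerate(groups):
            for k in group:
                thresholds[k] = values[i]
    rates = {}
    for g in model.generators:
        if rng:
            rates[g.id] = (rng.uniform(0.3, 3.0), rng.uniform(0.3, 3.0))
        else:
            rates[g.id] = (1.0, 0.7)
    return NumericParameters(thresholds=thresholds, rates=rates)


@dataclass
class Run:
    """A concrete trajectory: mode sequence, switch times, and piecewise
    linear concentration profiles."""

    model: HSMModel
    params: NumericParameters
    initial: dict[str, float]
    modes: list[Mode]
    times: list[float]  # entry time of each mode, times[0] == 0
    events: list[tuple[float, tuple[ThresholdKey, ...]]]  # crossings between modes
    trajectories: dict[str, list[tuple[float, float]]]  # (t, concentration) breakpoints
    terminated: str = "steady"  # steady | horizon | max_events

    def observational_sequence(self) -> list[tuple[str, ...]]:
        """Per-mode direction vectors; a substance sitting at zero with its
        gene off (or pinned at a cap) reads as steady."""
        sem = ModelSemantics(self.model)
        out = []
        for i, m in enumerate(self.modes):
            vec = []
            for sub in sem.substances:
                d = sem.direction(m, sub)
                entry = self.trajectories[sub][i][1]
                if d == DOWN and entry <= 0.0:
                    d = STEADY
                vec.append(d)
            out.append(tuple(vec))
        return out


def settle_initial_mode(
    model: HSMModel, params: NumericParameters, concentrations: Mapping[str, float]
) -> Mode:
    """Initial site states compatible with the given concentrations: a site
    is FREE iff every ligand sits below its association threshold; otherwise
    it is bound by the first declared ligand at or above it (≥ binds)."""
    mode = []
    for site in model.sites:
        code = 0
        for i, lig in enumerate(site.ligands):
            v = params.thresholds[ThresholdKey(lig, site.id, "assoc")]
            if concentrations.get(lig, 0.0) >= v:
                code = i + 1
                break
        mode.append(code)
    return tuple(mode)


def _directions(sem: ModelSemantics, model: HSMModel, params: NumericParameters, mode: Mode):
    """Per-substance signed rate in this mode (+growth / -degradation / 0)."""
    rates = {}
    for sub in sem.substances:
        gen = model.generator_for(sub)
        if gen is None:
            rates[sub] = 0.0
            continue
        g, d = params.rates[gen.id]
        rates[sub] = g if sem.direction(mode, sub) == UP else -d
    return rates


def _bind_closure(model: HSMModel, params: NumericParameters, mode: list[int], conc: dict[str, float]) -> None:
    """Bind any free site whose ligand already sits at/above its association
    threshold (zero-duration completion after a release); first declared
    ligand wins when several qualify."""
    changed = True
    while changed:
        changed = False
        for pos, site in enumerate(model.sites):
            if mode[pos] != 0:
                continue
            for i, lig in enumerate(site.ligands):
                if conc[lig] >= params.thresholds[ThresholdKey(lig, site.id, "assoc")]:
                    mode[pos] = i + 1
                    changed = True
                    break


def simulate(
    model: HSMModel,
    params: NumericParameters,
    init: Mapping[str, float],
    horizon: float | None = None,
    max_events: int = 200,
) -> Run:
    """Exact event-driven simulation from the given initial concentrations.

    Terminates at the horizon, after ``max_events`` mode switches, or in a
    steady state (no pending crossings).  Deterministic given (params, init).
    """
    params.validate(model)
    sem = ModelSemantics(model)
    conc = {s: float(init.get(s, 0.0)) for s in sem.substances}
    if any(v < 0 for v in conc.values()):
        raise ValueError("initial concentrations must be non-negative")
    mode = settle_initial_mode(model, params, conc)
    t = 0.0
    modes = [mode]
    times = [0.0]
    events: list[tuple[float, tuple[ThresholdKey, ...]]] = []
    traj = {s: [(0.0, conc[s])] for s in sem.substances}
    terminated = "steady"

    while True:
        if len(events) >= max_events:
            terminated = "max_events"
            break
        rates = _directions(sem, model, params, mode)
        # pending crossings: (dt, key)
        pending: list[tuple[float, ThresholdKey]] = []
        for pos, site in enumerate(model.sites):
            if mode[pos] == 0:
                for i, lig in enumerate(site.ligands):
                    r = rates[lig]
                    if r > 0:
                        v = params.thresholds[ThresholdKey(lig, site.id, "assoc")]
                        if v >= conc[lig]:
                            pending.append(((v - conc[lig]) / r, ThresholdKey(lig, site.id, "assoc")))
            else:
                lig = site.ligands[mode[pos] - 1]
                r = rates[lig]
                if r < 0:
                    v = params.thresholds[ThresholdKey(lig, site.id, "dissoc")]
                    if v <= conc[lig]:
                        pending.append(((conc[lig] - v) / (-r), ThresholdKey(lig, site.id, "dissoc")))
        if not pending:
            break
        dt = min(p for p, _ in pending)
        if horizon is not None and t + dt > horizon:
            terminated = "horizon"
            dt = horizon - t
            t = horizon
            for s in sem.substances:
                conc[s] = max(0.0, conc[s] + rates[s] * dt)
                traj[s].append((t, conc[s]))
            break
        crossings = tuple(sorted(k for p, k in pending if p <= dt + _TIME_TOL * max(1.0, dt)))
        t += dt
        for s in sem.substances:
            conc[s] = max(0.0, conc[s] + rates[s] * dt)
        # snap crossed thresholds exactly
        for k in crossings:
            conc[k.substance] = params.thresholds[k]
        new_mode = list(mode)
        pos_of = {s.id: i for i, s in enumerate(model.sites)}
        for k in crossings:
            pos = pos_of[k.site]
            site = model.sites[pos]
            if k.kind == "assoc":
                new_mode[pos] = site.ligands.index(k.substance) + 1
            else:
                new_mode[pos] = 0
        _bind_closure(model, params, new_mode, conc)
        mode = tuple(new_mode)
        events.append((t, crossings))
        modes.append(mode)
        times.append(t)
        for s in sem.substances:
            traj[s].append((t, conc[s]))

    return Run(
        model=model,
        params=params,
        initial=dict(conc if not times else {s: traj[s][0][1] for s in sem.substances}),
        modes=modes,
        times=times,
        events=events,
        trajectories=traj,
        terminated=terminated,
    )


def conforms(run: Run, cg: CharacteristicGraph) -> bool:
    """True iff the run's mode sequence is a walk in *cg* whose edges carry
    the guards of the crossings that occurred.

    Raises ``ValueError`` when the graph was built for a different ordering
    than the one the run's parameters induce.
    """
    run_ord = induced_ordering(run.model, run.params)
    if run_ord != cg.ordering:
        raise ValueError("graph ordering does not match the ordering induced by the run's parameters")
    g = cg.graph

    def edge_matches(u: Mode, v: Mode, atoms: frozenset[ThresholdKey]) -> bool:
        if not g.has_edge(u, v):
            return False
        for d in g[u][v].values():
            if frozenset(d["guard"].atoms) == atoms:
                return True
        return False

    pos_of = {s.id: i for i, s in enumerate(run.model.sites)}
    for (m1, m2), (_, crossings) in zip(zip(run.modes, run.modes[1:]), run.events):
        by_sub: dict[str, list[ThresholdKey]] = {}
        for k in crossings:
            by_sub.setdefault(k.substance, []).append(k)
        subs = sorted(by_sub)
        if len(subs) == 1:
            if not edge_matches(m1, m2, frozenset(crossings)):
                return False
            continue
        # coincidental multi-substance event: admit any sequential decomposition
        import itertools

        ok = False
        for perm in itertools.permutations(subs):
            cur = m1
            good = True
            for sub in perm:
                # the intermediate mode: apply this substance's crossings, then
                # find the matching edge target among graph successors
                atoms = frozenset(by_sub[sub])
                nxt = None
                for _, v, d in g.out_edges(cur, data=True):
                    if frozenset(d["guard"].atoms) == atoms:
                        # target must agree with m2 on already-processed sites
                        nxt = v
                        break
                if nxt is None:
                    good = False
                    break
                cur = nxt
            if good and cur == m2:
                ok = True
                break
        if not ok:
            return False
    return True
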