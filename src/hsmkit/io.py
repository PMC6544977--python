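"""Serialization of characteristic graphs and analysis reports.

Graphs export to DOT, GraphML and JSON; DOT files use only a small subset
of the language (node/edge statements with quoted attributes) and can be
re-imported with :func:`import_dot` for round-trip checks.  Sweep reports
export to CSV (one row per ordering) and JSON; mined conditions to JSON.
"""

from __future__ import annotations

import json
import re
from typing import Any

import networkx as nx

from .attractors import SweepReport
from .charph import CharacteristicGraph

__all__ = [
    "export_graph",
    "import_dot",
    "graph_to_labelled_nx",
    "export_sweep",
    "export_conditions",
]

GRAPH_FORMATS = ("dot", "graphml", "json")


def graph_to_labelled_nx(cg: CharacteristicGraph) -> nx.MultiDiGraph:
    """String-keyed copy of the graph (node id = site-state label) with
    plain-string attributes, suitable for any serializer."""
    g = nx.MultiDiGraph(**{k: str(v) for k, v in cg.metadata.items()})
    for n, d in cg.graph.nodes(data=True):
        g.add_node(d["label"], directions=d["directions"])
    for u, v, d in cg.graph.edges(data=True):
        g.add_edge(
            cg.graph.nodes[u]["label"],
            cg.graph.nodes[v]["label"],
            label=d["label"],
            substance=d["guard"].substance,
            direction=d["guard"].direction,
        )
    return g


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_graph(cg: CharacteristicGraph, fmt: str) -> str:
    """Render the graph in ``dot``, ``graphml`` or ``json``."""
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unsupported graph format {fmt!r} (choose from {GRAPH_FORMATS})")
    g = graph_to_labelled_nx(cg)
    if fmt == "dot":
        lines = ["digraph characteristic {"]
        for n, d in sorted(g.nodes(data=True)):
            lines.append(f"  {_dot_quote(n)} [directions={_dot_quote(d['directions'])}];")
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1], e[2]["label"])):
            lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)} [label={_dot_quote(d['label'])}];")
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        import io as _io

        buf = _io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    data = {
        "metadata": cg.metadata,
        "nodes": [{"id": n, "directions": d["directions"]} for n, d in sorted(g.nodes(data=True))],
        "edges": [
            {"source": u, "target": v, "guard": d["label"], "substance": d["substance"], "direction": d["direction"]}
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1], e[2]["label"]))
        ],
    }
    return json.dumps(data, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


_NODE_RE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*\[directions="((?:[^"\\]|\\.)*)"\]\s*;\s*$')
_EDGE_RE = re.compile(
    r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*\[label="((?:[^"\\]|\\.)*)"\]\s*;\s*$'
)


def _unesc(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def import_dot(text: str) -> nx.MultiDiGraph:
    """Parse DOT text produced by :func:`export_graph` back into a labelled
    multidigraph (the emitted subset only, not general DOT)."""
    g = nx.MultiDiGraph()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("digraph", "}")):
            continue
        m = _NODE_RE.match(line)
        if m:
            g.add_node(_unesc(m.group(1)), directions=_unesc(m.group(2)))
            continue
        m = _EDGE_RE.match(line)
        if m:
            g.add_edge(_unesc(m.group(1)), _unesc(m.group(2)), label=_unesc(m.group(3)))
            continue
        raise ValueError(f"unparseable DOT line: {line!r}")
    return g


def export_sweep(sweep: SweepReport, fmt: str) -> str:
    """Sweep report as ``csv`` (one row per ordering) or ``json`` (rows plus
    aggregate counts and the signature/fingerprint indices)."""
    if fmt == "csv":
        return sweep.to_frame().to_csv(index=False)
    if fmt == "json":
        sig_ix, fp_ix = sweep.signature_index(), sweep.fingerprint_index()
        beh_ix = sweep.behaviour_index()
        data: dict[str, Any] = {
            "model": sweep.model_name,
            "n_orderings": len(sweep.rows),
            "n_distinct_signatures": len(sig_ix),
            "n_distinct_fingerprints": len(fp_ix),
            "n_distinct_behaviours": len(beh_ix),
            "behaviours": {str(i): b for b, i in beh_ix.items()},
            "rows": [
                {
                    "ordering_id": r.ordering_id,
                    "ordering": r.ordering.id,
                    "n_attractors": len(r.attractors),
                    "attractors": [
                        {
                            "n_modes": len(a.modes),
                            "structure": a.structure,
                            "is_final": a.is_final,
                            "guard_substances": list(a.guard_substances),
                            "signature_id": sig_ix[a.signature],
                            "fingerprint_id": fp_ix[a.fingerprint],
                            "behaviour_id": beh_ix[a.behaviour],
                        }
                        for a in r.attractors
                    ],
                }
                for r in sweep.rows
            ],
        }
        return json.dumps(data, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    raise ValueError(f"unsupported report format {fmt!r}")


def export_conditions(conditions: dict, sweep: SweepReport | None = None) -> str:
    """Mined ordering conditions as JSON, keyed by signature id when the
    sweep is supplied (signature canonical strings are long)."""
    if sweep is not None:
        sig_ix = sweep.signature_index()
        data = {str(sig_ix[s]): v for s, v in conditions.items()}
    else:
        data = conditions
    return json.dumps(data, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
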