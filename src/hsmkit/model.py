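"""Domain types for hybrid-system models (HSM) of gene regulatory networks.

An HSM couples continuous protein concentrations with discrete binding-site
states.  Four building blocks define a model:

* **substances** — molecules whose concentrations evolve continuously;
* **binding sites** — discrete-state elements, FREE or BOUND by one of their
  declared ligands; each (ligand, site) pair owns an association and a
  dissociation threshold, with dissociation < association (hysteresis);
* **control functions** — total discrete maps from input site-state tuples to
  a gene expression level (0 = off, >0 = on);
* **substance generators** — genes: each produces one substance at a level
  given by its control function, with monotone growth/degradation.

This module holds the static model description, its validation, and a JSON
on-disk format with canonical (round-trip stable) serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Substance",
    "BindingSite",
    "ThresholdKey",
    "ControlFunction",
    "Generator",
    "HSMModel",
    "Diagnostic",
    "ModelFormatError",
    "FREE",
    "bound_state",
    "validate_model",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
]

#: Site-state encoding used in control tables and serialized files.
FREE = "FREE"


def bound_state(substance: str) -> str:
    """Encoded site state for a site occupied by *substance*."""
    return f"BOUND:{substance}"


class ModelFormatError(ValueError):
    """Raised when a model file does not conform to the JSON schema.

    The message names the JSON path of the offending element.
    """


@dataclass(frozen=True, order=True)
class ThresholdKey:
    """Identifies one concentration threshold: (substance, site, kind).

    kind is ``"assoc"`` (binding on the way up) or ``"dissoc"`` (release on
    the way down).  Rendered textually as e.g. ``bOR2.as`` / ``bOR2.dis``,
    scoped to a substance.
    """

    substance: str
    site: str
    kind: str  # "assoc" | "dissoc"

    def __post_init__(self) -> None:
        if self.kind not in ("assoc", "dissoc"):
            raise ValueError(f"threshold kind must be assoc/dissoc, got {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.site}.{'as' if self.kind == 'assoc' else 'dis'}"

    @property
    def qualified(self) -> str:
        return f"{self.substance}:{self.label}"

    @classmethod
    def from_label(cls, substance: str, label: str) -> "ThresholdKey":
        site, _, suffix = label.rpartition(".")
        kind = {"as": "assoc", "dis": "dissoc"}.get(suffix)
        if not site or kind is None:
            raise ValueError(f"bad threshold label {label!r} (want '<site>.as' or '<site>.dis')")
        return cls(substance, site, kind)


@dataclass(frozen=True)
class Substance:
    id: str
    role: str = "protein"


@dataclass(frozen=True)
class BindingSite:
    """A binding site with an ordered tuple of ligand substance ids.

    A site has ``len(ligands) + 1`` states: FREE plus BOUND(x) per ligand.
    """

    id: str
    ligands: tuple[str, ...]

    def states(self) -> tuple[str, ...]:
        return (FREE,) + tuple(bound_state(s) for s in self.ligands)


@dataclass(frozen=True)
class ControlFunction:
    """Discrete control function: input site-state tuples -> expression level."""

    id: str
    inputs: tuple[str, ...]
    table: Mapping[tuple[str, ...], int]

    def level(self, states: tuple[str, ...]) -> int:
        return self.table[states]


@dataclass(frozen=True)
class Generator:
    """A gene: produces ``product`` at the level of control function ``control``.

    Numeric rates are only used by the simulator; growth is the concentration
    gain per unit time while expressed, degradation the loss while silent.
    """

    id: str
    product: str
    control: str
    growth_rate: float | None = None
    degradation_rate: float | None = None


@dataclass(frozen=True)
class HSMModel:
    name: str
    substances: tuple[Substance, ...]
    sites: tuple[BindingSite, ...]
    control_functions: tuple[ControlFunction, ...]
    generators: tuple[Generator, ...]
    version: str = "1"

    # -- lookups ---------------------------------------------------------
    def substance_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.substances)

    def site(self, site_id: str) -> BindingSite:
        return self._site_map[site_id]

    def control(self, cf_id: str) -> ControlFunction:
        return self._cf_map[cf_id]

    @property
    def _site_map(self) -> dict[str, BindingSite]:
        return {s.id: s for s in self.sites}

    @property
    def _cf_map(self) -> dict[str, ControlFunction]:
        return {c.id: c for c in self.control_functions}

    def generator_for(self, substance: str) -> Generator | None:
        for g in self.generators:
            if g.product == substance:
                return g
        return None

    def threshold_keys(self, substance: str) -> tuple[ThresholdKey, ...]:
        """All threshold keys of *substance*, dissoc before assoc per site,
        sites in declared order."""
        keys: list[ThresholdKey] = []
        for s in self.sites:
            if substance in s.ligands:
                keys.append(ThresholdKey(substance, s.id, "dissoc"))
                keys.append(ThresholdKey(substance, s.id, "assoc"))
        return tuple(keys)

    def ligand_pairs(self) -> tuple[ThresholdKey, ...]:
        out = []
        for s in self.sites:
            for lig in s.ligands:
                out.append((lig, s.id))
        return tuple(out)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``code`` is machine-readable."""

    code: str
    path: str
    message: str


def _dup(ids: Iterable[str]) -> set[str]:
    seen, dups = set(), set()
    for i in ids:
        (dups if i in seen else seen).add(i)
    return dups


def validate_model(model: HSMModel) -> list[Diagnostic]:
    """Structural validation.  Returns an empty list iff the model is
    well-formed; otherwise one diagnostic per violation (never raises)."""
    diags: list[Diagnostic] = []
    sub_ids = {s.id for s in model.substances}
    site_ids = {s.id for s in model.sites}
    cf_ids = {c.id for c in model.control_functions}

    for kind, ids in (
        ("substances", [s.id for s in model.substances]),
        ("sites", [s.id for s in model.sites]),
        ("control_functions", [c.id for c in model.control_functions]),
        ("generators", [g.id for g in model.generators]),
    ):
        for d in sorted(_dup(ids)):
            diags.append(Diagnostic("DUPLICATE_ID", f"$.{kind}", f"duplicate id {d!r}"))

    for s in model.sites:
        if not 1 <= len(s.ligands) <= 2:
            diags.append(
                Diagnostic("BAD_LIGAND_COUNT", f"$.sites.{s.id}", f"site has {len(s.ligands)} ligands (want 1 or 2)")
            )
        for lig in s.ligands:
            if lig not in sub_ids:
                diags.append(Diagnostic("UNKNOWN_SUBSTANCE", f"$.sites.{s.id}", f"unknown ligand {lig!r}"))

    for c in model.control_functions:
        for inp in c.inputs:
            if inp not in site_ids:
                diags.append(Diagnostic("UNKNOWN_SITE", f"$.control_functions.{c.id}", f"unknown input site {inp!r}"))
        known_inputs = [i for i in c.inputs if i in site_ids]
        if len(known_inputs) == len(c.inputs):
            import itertools

            expected = set(itertools.product(*(model.site(i).states() for i in c.inputs)))
            got = set(c.table.keys())
            if got != expected:
                missing = expected - got
                extra = got - expected
                if missing:
                    diags.append(
                        Diagnostic(
                            "TABLE_NOT_TOTAL",
                            f"$.control_functions.{c.id}.table",
                            f"{len(missing)} input state tuples lack a level (e.g. {sorted(missing)[0]})",
                        )
                    )
                if extra:
                    diags.append(
                        Diagnostic(
                            "TABLE_BAD_STATE",
                            f"$.control_functions.{c.id}.table",
                            f"{len(extra)} rows use undeclared states (e.g. {sorted(extra)[0]})",
                        )
                    )
        for states, level in c.table.items():
            if not (isinstance(level, int) and level >= 0):
                diags.append(
                    Diagnostic(
                        "BAD_LEVEL",
                        f"$.control_functions.{c.id}.table",
                        f"level for {states} must be a non-negative integer, got {level!r}",
                    )
                )

    products: dict[str, list[str]] = {}
    for g in model.generators:
        if g.product not in sub_ids:
            diags.append(Diagnostic("UNKNOWN_SUBSTANCE", f"$.generators.{g.id}", f"unknown product {g.product!r}"))
        else:
            products.setdefault(g.product, []).append(g.id)
        if g.control not in cf_ids:
            diags.append(Diagnostic("UNKNOWN_CONTROL", f"$.generators.{g.id}", f"unknown control function {g.control!r}"))
        for attr in ("growth_rate", "degradation_rate"):
            v = getattr(g, attr)
            if v is not None and not v > 0:
                diags.append(Diagnostic("BAD_RATE", f"$.generators.{g.id}.{attr}", f"{attr} must be positive, got {v!r}"))

    for sub in sorted(sub_ids):
        n = len(products.get(sub, []))
        if n == 0:
            diags.append(Diagnostic("NO_GENERATOR", f"$.substances.{sub}", f"substance {sub!r} has no generator"))
        elif n > 1:
            diags.append(
                Diagnostic(
                    "MULTIPLE_GENERATORS", f"$.substances.{sub}", f"substance {sub!r} produced by {products[sub]}"
                )
            )
    return diags


# ---------------------------------------------------------------------------
# JSON serialization (canonical: sorted keys, table rows in state order)


def model_to_dict(model: HSMModel) -> dict:
    return {
        "name": model.name,
        "version": model.version,
        "substances": [{"id": s.id, "role": s.role} for s in model.substances],
        "sites": [{"id": s.id, "ligands": list(s.ligands)} for s in model.sites],
        "control_functions": [
            {
                "id": c.id,
                "inputs": list(c.inputs),
                "table": [
                    {"states": list(states), "level": level}
                    for states, level in sorted(c.table.items())
                ],
            }
            for c in model.control_functions
        ],
        "generators": [
            {
                "id": g.id,
                "product": g.product,
                "control": g.control,
                "growth_rate": g.growth_rate,
                "degradation_rate": g.degradation_rate,
            }
            for g in model.generators
        ],
    }


def _require(obj: dict, key: str, path: str):
    if not isinstance(obj, dict):
        raise ModelFormatError(f"{path}: expected an object")
    if key not in obj:
        raise ModelFormatError(f"{path}.{key}: required field missing")
    return obj[key]


def model_from_dict(data: dict) -> HSMModel:
    subs = tuple(
        Substance(id=_require(s, "id", f"$.substances[{i}]"), role=s.get("role", "protein"))
        for i, s in enumerate(_require(data, "substances", "$"))
    )
    sites = tuple(
        BindingSite(
            id=_require(s, "id", f"$.sites[{i}]"),
            ligands=tuple(_require(s, "ligands", f"$.sites[{i}]")),
        )
        for i, s in enumerate(_require(data, "sites", "$"))
    )
    cfs = []
    for i, c in enumerate(_require(data, "control_functions", "$")):
        path = f"$.control_functions[{i}]"
        rows = _require(c, "table", path)
        table: dict[tuple[str, ...], int] = {}
        for j, row in enumerate(rows):
            states = tuple(_require(row, "states", f"{path}.table[{j}]"))
            level = _require(row, "level", f"{path}.table[{j}]")
            if not isinstance(level, int):
                raise ModelFormatError(f"{path}.table[{j}].level: expected integer")
            table[states] = level
        cfs.append(ControlFunction(id=_require(c, "id", path), inputs=tuple(_require(c, "inputs", path)), table=table))
    gens = tuple(
        Generator(
            id=_require(g, "id", f"$.generators[{i}]"),
            product=_require(g, "product", f"$.generators[{i}]"),
            control=_require(g, "control", f"$.generators[{i}]"),
            growth_rate=g.get("growth_rate"),
            degradation_rate=g.get("degradation_rate"),
        )
        for i, g in enumerate(_require(data, "generators", "$"))
    )
    return HSMModel(
        name=_require(data, "name", "$"),
        version=str(data.get("version", "1")),
        substances=subs,
        sites=sites,
        control_functions=tuple(cfs),
        generators=gens,
    )


def write_model(model: HSMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n")


def read_model(path: str | Path) -> HSMModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"$: not valid JSON ({e})") from e
    return model_from_dict(data)
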