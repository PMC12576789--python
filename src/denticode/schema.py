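"""Versioned denticle character schemas.

A schema is an ordered collection of morphological character traits
("characters" in the paleontological sense).  Each trait enumerates a
small set of discrete states and carries a symmetric state-distance
matrix over its *codable* (non-zero) states plus a weight used in the
disparity calculation.  State 0 is a sentinel everywhere it exists: it
means either that the specimen is too broken/obscured to code the trait
or that the trait is inapplicable (a nested character whose controlling
character rules it out).  Zero states never enter a distance
computation; they are excluded pair-by-pair downstream.

Schemas are versioned.  New states bump the version by 0.1, new traits
by 1.0, and every historical version remains loadable by name so that
previously coded datasets stay analyzable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NOT_COMPARABLE",
    "DESCRIPTOR_SCALE",
    "TraitDef",
    "NestingRule",
    "Schema",
    "SchemaError",
    "build_matrix_from_descriptors",
    "load_schema",
    "write_schema_file",
    "validate_schema",
    "trait_distance",
    "bundled_versions",
]


class _NotComparable:
    """Sentinel for a state pair involving a 0 (broken / inapplicable).

    Distinct from a numeric 0 so that missingness can never masquerade
    as similarity.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_COMPARABLE"

    def __bool__(self) -> bool:
        return False


NOT_COMPARABLE = _NotComparable()

#: Verbal disparity descriptors -> numeric rank.  The source descriptions
#: are verbal orderings; any strictly monotone mapping preserves them.
DESCRIPTOR_SCALE: dict[str, float] = {
    "identical": 0.0,
    "similar": 1.0,
    "more similar": 1.0,
    "somewhat different": 1.0,
    "different": 2.0,
    "equally different": 2.0,
    "significantly different": 3.0,
    "very different": 3.0,
    "maximal": 4.0,
}

VALID_WEIGHTS = (0.5, 1.0, 2.0)
ZERO_MEANINGS = ("broken", "not-applicable", "absent-nested")


class SchemaError(ValueError):
    """Raised for unknown versions or malformed schema files."""


@dataclass(frozen=True)
class TraitDef:
    """One morphological character.

    Parameters
    ----------
    trait_id
        Short label, letter group plus index, e.g. ``"F1"``.
    group
        Single letter A-O.
    name
        Human-readable label.
    weight
        Disparity weight, one of 0.5, 1 or 2.  The first character
        describing a feature carries full weight; nested characters that
        elaborate on it are down-weighted to 0.5.
    states
        Ordered ``(index, label)`` pairs.  Indices are consecutive
        integers starting at 0 (if the trait has a zero state) or 1.
    zero_meaning
        Interpretation of state 0 (``"broken"``, ``"not-applicable"`` or
        ``"absent-nested"``), or ``None`` when the trait has no zero
        state.
    dist
        Symmetric non-negative matrix over the non-zero states, zero on
        the diagonal, ordered by state index.
    """

    trait_id: str
    group: str
    name: str
    weight: float
    states: tuple[tuple[int, str], ...]
    zero_meaning: str | None
    dist: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist", np.asarray(self.dist, dtype=float))

    @property
    def has_zero_state(self) -> bool:
        return self.states[0][0] == 0

    @property
    def state_indices(self) -> tuple[int, ...]:
        return tuple(idx for idx, _ in self.states)

    @property
    def nonzero_states(self) -> tuple[int, ...]:
        return tuple(idx for idx, _ in self.states if idx != 0)

    @property
    def max_distance(self) -> float:
        return float(self.dist.max()) if self.dist.size else 0.0

    def distance(self, a: int, b: int):
        """Distance between two states; NOT_COMPARABLE if either is 0."""
        if a not in self.state_indices or b not in self.state_indices:
            raise KeyError(
                f"trait {self.trait_id}: state out of range ({a!r}, {b!r})"
            )
        if a == 0 or b == 0:
            return NOT_COMPARABLE
        off = 1 if self.has_zero_state else self.state_indices[0]
        return float(self.dist[a - off, b - off])

    def state_label(self, idx: int) -> str:
        for i, label in self.states:
            if i == idx:
                return label
        raise KeyError(f"trait {self.trait_id}: no state {idx}")


@dataclass(frozen=True)
class NestingRule:
    """When ``controller`` takes a state in ``when_states``, every trait
    in ``require`` must hold its required value (usually 0, meaning the
    dependent character is inapplicable)."""

    controller: str
    when_states: tuple[int, ...]
    require: tuple[tuple[str, int], ...]

    @property
    def dependents(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.require)


@dataclass
class Schema:
    """A versioned, ordered collection of trait definitions."""

    version: str
    traits: tuple[TraitDef, ...]
    nesting_rules: tuple[NestingRule, ...] = ()
    historical: bool = False
    note: str = ""
    _by_id: dict[str, TraitDef] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {t.trait_id: t for t in self.traits}

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self._by_id

    def __len__(self) -> int:
        return len(self.traits)

    @property
    def trait_ids(self) -> tuple[str, ...]:
        return tuple(t.trait_id for t in self.traits)

    def trait(self, trait_id: str) -> TraitDef:
        try:
            return self._by_id[trait_id]
        except KeyError:
            raise KeyError(f"unknown trait {trait_id!r} in {self.version}") from None

    def drop_traits(self, drop: Iterable[str]) -> "Schema":
        """Schema copy with the given traits removed and nesting rules
        pruned (rules lose dropped dependents; rules whose controller is
        dropped disappear)."""
        dropset = set(drop)
        unknown = dropset - set(self.trait_ids)
        if unknown:
            raise KeyError(f"unknown traits: {sorted(unknown)}")
        kept = tuple(t for t in self.traits if t.trait_id not in dropset)
        if not kept:
            raise ValueError("cannot drop every trait")
        rules = []
        for r in self.nesting_rules:
            if r.controller in dropset:
                continue
            req = tuple((t, v) for t, v in r.require if t not in dropset)
            if req:
                rules.append(NestingRule(r.controller, r.when_states, req))
        return Schema(
            version=self.version,
            traits=kept,
            nesting_rules=tuple(rules),
            historical=self.historical,
            note=self.note,
        )

    def equals(self, other: "Schema") -> bool:
        """Field-by-field equality (used for round-trip checks)."""
        if (self.version, self.historical) != (other.version, other.historical):
            return False
        if self.nesting_rules != other.nesting_rules:
            return False
        if len(self.traits) != len(other.traits):
            return False
        for a, b in zip(self.traits, other.traits):
            if (a.trait_id, a.group, a.name, a.weight, a.states, a.zero_meaning) != (
                b.trait_id,
                b.group,
                b.name,
                b.weight,
                b.states,
                b.zero_meaning,
            ):
                return False
            if not np.array_equal(a.dist, b.dist):
                return False
        return True


def build_matrix_from_descriptors(
    trait_id: str,
    states: Sequence[int],
    pairwise: Mapping[tuple[int, int], str | float],
) -> np.ndarray:
    """Build a symmetric state-distance matrix from verbal descriptors.

    ``states`` are the non-zero state indices in order.  ``pairwise``
    maps unordered state pairs to either a descriptor from
    :data:`DESCRIPTOR_SCALE` or a numeric value (ordinal traits use unit
    or fractional steps directly).  Every unordered pair of distinct
    states must be covered.
    """
    states = list(states)
    n = len(states)
    pos = {s: i for i, s in enumerate(states)}
    mat = np.zeros((n, n), dtype=float)
    seen: set[frozenset] = set()
    for (a, b), desc in pairwise.items():
        if a not in pos or b not in pos:
            raise SchemaError(f"trait {trait_id}: unknown state in pair ({a},{b})")
        if a == b:
            raise SchemaError(f"trait {trait_id}: self-pair ({a},{a}) not allowed")
        if isinstance(desc, str):
            try:
                val = DESCRIPTOR_SCALE[desc]
            except KeyError:
                raise SchemaError(
                    f"trait {trait_id}: unknown descriptor {desc!r} for ({a},{b})"
                ) from None
        else:
            val = float(desc)
        if val < 0:
            raise SchemaError(f"trait {trait_id}: negative distance for ({a},{b})")
        mat[pos[a], pos[b]] = val
        mat[pos[b], pos[a]] = val
        seen.add(frozenset((a, b)))
    missing = [
        (states[i], states[j])
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((states[i], states[j])) not in seen
    ]
    if missing:
        raise SchemaError(f"trait {trait_id}: missing pairs {missing}")
    return mat


# ---------------------------------------------------------------------------
# Validation

_TRAIT_ID_RE = re.compile(r"^[A-O][0-9]+$")


def validate_schema(schema: Schema) -> list[dict]:
    """Check every structural invariant; returns a list of issues.

    Each issue is ``{"trait_id": ..., "rule": ..., "message": ...}``.
    An empty list means the schema is internally consistent.  Historical
    stub schemas (no traits) are exempt from the trait-level checks.
    """
    issues: list[dict] = []

    def add(trait_id: str, rule: str, message: str) -> None:
        issues.append({"trait_id": trait_id, "rule": rule, "message": message})

    seen_ids: set[str] = set()
    for t in schema.traits:
        if t.trait_id in seen_ids:
            add(t.trait_id, "unique-id", "duplicate trait id")
        seen_ids.add(t.trait_id)
        if not _TRAIT_ID_RE.match(t.trait_id):
            add(t.trait_id, "id-format", "trait id must be letter A-O plus number")
        if t.group != t.trait_id[0]:
            add(t.trait_id, "group", f"group {t.group!r} does not match id")
        if t.weight not in VALID_WEIGHTS:
            add(t.trait_id, "weight-domain", f"weight {t.weight} not in {VALID_WEIGHTS}")
        idxs = t.state_indices
        if idxs[0] not in (0, 1) or list(idxs) != list(
            range(idxs[0], idxs[0] + len(idxs))
        ):
            add(t.trait_id, "state-indices", "states must be consecutive from 0 or 1")
        if t.has_zero_state and t.zero_meaning not in ZERO_MEANINGS:
            add(t.trait_id, "zero-meaning", f"invalid zero meaning {t.zero_meaning!r}")
        if not t.has_zero_state and t.zero_meaning is not None:
            add(t.trait_id, "zero-meaning", "zero meaning set but no zero state")
        nz = len(t.nonzero_states)
        if t.dist.shape != (nz, nz):
            add(t.trait_id, "dist-shape", f"dist is {t.dist.shape}, expected {(nz, nz)}")
            continue
        if nz and np.any(np.diag(t.dist) != 0):
            add(t.trait_id, "diagonal", "dist diagonal must be zero")
        if not np.array_equal(t.dist, t.dist.T):
            add(t.trait_id, "symmetry", "dist must be symmetric")
        if np.any(t.dist < 0):
            add(t.trait_id, "nonnegative", "dist must be nonnegative")

    for r in schema.nesting_rules:
        if r.controller not in schema:
            add(r.controller, "nesting-controller", "controller trait missing")
            continue
        ctrl = schema.trait(r.controller)
        for s in r.when_states:
            if s not in ctrl.state_indices:
                add(r.controller, "nesting-state", f"controller has no state {s}")
        for dep, val in r.require:
            if dep not in schema:
                add(dep, "nesting-dependent", f"dependent trait {dep} missing")
                continue
            dep_t = schema.trait(dep)
            if val == 0 and not dep_t.has_zero_state:
                add(dep, "nesting-zero", "dependent required 0 but has no zero state")
            elif val != 0 and val not in dep_t.state_indices:
                add(dep, "nesting-value", f"dependent has no state {val}")

    return issues


# ---------------------------------------------------------------------------
# Serialization

def _trait_to_dict(t: TraitDef) -> dict:
    return {
        "trait_id": t.trait_id,
        "group": t.group,
        "name": t.name,
        "weight": t.weight,
        "states": [{"index": i, "label": lbl} for i, lbl in t.states],
        "zero_meaning": t.zero_meaning,
        "dist": t.dist.tolist(),
    }


def _trait_from_dict(d: Mapping) -> TraitDef:
    try:
        return TraitDef(
            trait_id=d["trait_id"],
            group=d["group"],
            name=d["name"],
            weight=float(d["weight"]),
            states=tuple((int(s["index"]), str(s["label"])) for s in d["states"]),
            zero_meaning=d.get("zero_meaning"),
            dist=np.asarray(d["dist"], dtype=float),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(
            f"malformed trait entry {d.get('trait_id', '<missing id>')!r}: {exc}"
        ) from exc


def schema_to_dict(schema: Schema) -> dict:
    return {
        "version": schema.version,
        "historical": schema.historical,
        "note": schema.note,
        "traits": [_trait_to_dict(t) for t in schema.traits],
        "nesting_rules": [
            {
                "controller": r.controller,
                "when_states": list(r.when_states),
                "require": {t: v for t, v in r.require},
            }
            for r in schema.nesting_rules
        ],
    }


def schema_from_dict(d: Mapping) -> Schema:
    try:
        version = d["version"]
        traits = tuple(_trait_from_dict(t) for t in d.get("traits", []))
        rules = tuple(
            NestingRule(
                controller=r["controller"],
                when_states=tuple(int(s) for s in r["when_states"]),
                require=tuple(sorted((t, int(v)) for t, v in r["require"].items())),
            )
            for r in d.get("nesting_rules", [])
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema file: {exc}") from exc
    schema = Schema(
        version=version,
        traits=traits,
        nesting_rules=rules,
        historical=bool(d.get("historical", False)),
        note=d.get("note", ""),
    )
    if not schema.historical:
        issues = validate_schema(schema)
        if issues:
            first = issues[0]
            raise SchemaError(
                f"schema {version} failed validation: trait {first['trait_id']} "
                f"({first['rule']}): {first['message']}; {len(issues)} issue(s) total"
            )
    return schema


def write_schema_file(schema: Schema, path: str | Path) -> None:
    """Write a schema to JSON (or YAML if the suffix is .yaml/.yml)."""
    path = Path(path)
    doc = schema_to_dict(schema)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(
            json.dumps(doc, indent=1, sort_keys=False), encoding="utf-8"
        )


def bundled_versions() -> list[str]:
    """Names of the schema versions shipped with the package."""
    out = []
    for entry in resources.files("denticode.data").iterdir():
        m = re.match(r"(denticles_v[\d.]+)\.json$", entry.name)
        if m:
            out.append(m.group(1))
    return sorted(out)


def load_schema(version_or_path: str | Path) -> Schema:
    """Load a bundled schema by version name or a schema file by path.

    Bundled names look like ``"denticles_v0.5"``.  Files may be JSON or
    YAML in the same structure that :func:`write_schema_file` emits.
    """
    name = str(version_or_path)
    candidate = resources.files("denticode.data").joinpath(f"{name}.json")
    if re.match(r"^denticles_v[\d.]+$", name):
        if not candidate.is_file():
            raise SchemaError(
                f"unknown schema version {name!r}; bundled: {bundled_versions()}"
            )
        return schema_from_dict(json.loads(candidate.read_text(encoding="utf-8")))
    path = Path(version_or_path)
    if not path.exists():
        raise SchemaError(f"no such schema version or file: {name!r}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return schema_from_dict(yaml.safe_load(text))
    return schema_from_dict(json.loads(text))


def trait_distance(schema: Schema, trait_id: str, a: int, b: int):
    """Distance between two states of a trait.

    Returns :data:`NOT_COMPARABLE` when either state is the 0 sentinel.
    Raises ``KeyError`` for unknown traits or out-of-range states.
    """
    if trait_id not in schema:
        raise KeyError(f"unknown trait {trait_id!r}")
    return schema.trait(trait_id).distance(a, b)
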