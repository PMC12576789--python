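"""Reading, writing, and validating specimen coding sheets.

A coding sheet is delimited text (comma or tab), one row per denticle
specimen: a ``specimen_id`` column, one integer column per schema trait,
and any number of free metadata columns (taxon, body position, source,
image type, ...).  Trait columns may appear in any order in the file;
the canonical write order is schema order.

Missing trait cells are errors rather than an implicit 0: silently
imputing "broken" would bias disparity downward.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema import Schema

__all__ = [
    "DenticleCode",
    "ValidationIssue",
    "CodingSheetError",
    "read_coding_sheet",
    "write_coding_sheet",
    "validate_code",
    "validate_codes",
    "write_validation_report",
]

ID_COLUMN = "specimen_id"
VALIDATION_RULES = ("range", "nesting", "ordering-B2C2")


class CodingSheetError(ValueError):
    """Raised for structurally unusable coding sheets."""


@dataclass(frozen=True)
class DenticleCode:
    """One specimen's coded character-state vector plus metadata."""

    specimen_id: str
    states: dict[str, int]
    meta: dict[str, str] = field(default_factory=dict)

    def state(self, trait_id: str) -> int:
        return self.states[trait_id]

    def with_states(self, new_states: dict[str, int]) -> "DenticleCode":
        merged = dict(self.states)
        merged.update(new_states)
        return DenticleCode(self.specimen_id, merged, dict(self.meta))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DenticleCode):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.states == other.states
            and self.meta == other.meta
        )

    def __hash__(self) -> int:
        return hash((self.specimen_id, tuple(sorted(self.states.items()))))


@dataclass(frozen=True)
class ValidationIssue:
    """One rule violation on one specimen/trait."""

    specimen_id: str
    trait_id: str
    rule: str
    message: str

    def __post_init__(self) -> None:
        if self.rule not in VALIDATION_RULES:
            raise ValueError(f"unknown validation rule {self.rule!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "specimen_id": self.specimen_id,
                "trait_id": self.trait_id,
                "rule": self.rule,
                "message": self.message,
            }
        )


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def read_coding_sheet(path: str | Path, schema: Schema) -> list[DenticleCode]:
    """Parse a coding sheet into one :class:`DenticleCode` per data row.

    The header must contain ``specimen_id`` and every trait column of the
    schema; extra columns become metadata.  Blank or non-integer trait
    cells and missing trait columns raise :class:`CodingSheetError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    if ID_COLUMN not in df.columns:
        raise CodingSheetError(f"{path.name}: missing required column {ID_COLUMN!r}")
    missing = [t for t in schema.trait_ids if t not in df.columns]
    if missing:
        raise CodingSheetError(
            f"{path.name}: missing trait column(s): {', '.join(missing)}"
        )
    meta_cols = [c for c in df.columns if c != ID_COLUMN and c not in schema.trait_ids]
    codes: list[DenticleCode] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        states: dict[str, int] = {}
        for t in schema.trait_ids:
            cell = rec[t].strip()
            if cell == "":
                raise CodingSheetError(
                    f"{path.name} line {row_no}: blank cell for trait {t} "
                    f"(missing data must be coded explicitly, not left empty)"
                )
            try:
                states[t] = int(cell)
            except ValueError:
                raise CodingSheetError(
                    f"{path.name} line {row_no}: trait {t} value {cell!r} "
                    "is not an integer"
                ) from None
        codes.append(
            DenticleCode(
                specimen_id=str(rec[ID_COLUMN]),
                states=states,
                meta={c: rec[c] for c in meta_cols},
            )
        )
    return codes


def write_coding_sheet(
    codes: Sequence[DenticleCode], path: str | Path, schema: Schema
) -> None:
    """Write codes as CSV (RFC-4180 quoting); trait columns in schema order."""
    path = Path(path)
    meta_cols: list[str] = []
    for c in codes:
        for k in c.meta:
            if k not in meta_cols:
                meta_cols.append(k)
    header = [ID_COLUMN, *schema.trait_ids, *meta_cols]
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for c in codes:
            w.writerow(
                [c.specimen_id]
                + [c.states[t] for t in schema.trait_ids]
                + [c.meta.get(k, "") for k in meta_cols]
            )


def validate_code(code: DenticleCode, schema: Schema) -> list[ValidationIssue]:
    """Range, nesting, and edge-texture ordering checks for one specimen.

    Issues come back in deterministic order (sorted by trait id, range
    issues before nesting ones per trait).
    """
    issues: list[ValidationIssue] = []
    missing = [t for t in schema.trait_ids if t not in code.states]
    if missing:
        raise CodingSheetError(
            f"specimen {code.specimen_id}: missing trait(s) {', '.join(missing)}"
        )
    out_of_range: set[str] = set()
    for t in schema.traits:
        v = code.states[t.trait_id]
        if v not in t.state_indices:
            out_of_range.add(t.trait_id)
            issues.append(
                ValidationIssue(
                    code.specimen_id,
                    t.trait_id,
                    "range",
                    f"state {v} outside {t.state_indices[0]}.."
                    f"{t.state_indices[-1]}",
                )
            )
    for r in schema.nesting_rules:
        if r.controller in out_of_range:
            continue
        ctrl_state = code.states[r.controller]
        if ctrl_state not in r.when_states:
            continue
        for dep, required in r.require:
            if dep in out_of_range:
                continue
            if code.states[dep] != required:
                issues.append(
                    ValidationIssue(
                        code.specimen_id,
                        dep,
                        "nesting",
                        f"{r.controller}={ctrl_state} requires {dep}={required}, "
                        f"found {code.states[dep]}",
                    )
                )
    # The B2/C2 low-before-high convention only governs denticles that
    # lack directionality on both edges (B1=4 and C1=4).
    if all(t in schema for t in ("B1", "C1", "B2", "C2")):
        if (
            code.states["B1"] == 4
            and code.states["C1"] == 4
            and code.states["B2"] != 0
            and code.states["C2"] != 0
            and code.states["B2"] > code.states["C2"]
        ):
            issues.append(
                ValidationIssue(
                    code.specimen_id,
                    "B2",
                    "ordering-B2C2",
                    f"B2={code.states['B2']} must not exceed C2="
                    f"{code.states['C2']} when directionality is absent",
                )
            )
    order = {"range": 0, "nesting": 1, "ordering-B2C2": 2}
    issues.sort(key=lambda i: (i.trait_id, order[i.rule]))
    return issues


def validate_codes(
    codes: Iterable[DenticleCode], schema: Schema
) -> list[ValidationIssue]:
    """Validate many specimens; issues concatenated in input order."""
    out: list[ValidationIssue] = []
    for c in codes:
        out.extend(validate_code(c, schema))
    return out


def write_validation_report(
    issues: Sequence[ValidationIssue], path: str | Path
) -> None:
    """JSON-lines report, one issue per line."""
    Path(path).write_text(
        "".join(i.to_json() + "\n" for i in issues), encoding="utf-8"
    )
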