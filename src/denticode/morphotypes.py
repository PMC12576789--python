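"""Morphotype identification and the named catalog.

A morphotype is a unique combination of character states.  Specimens
whose codes differ in at most one or two coded traits are, in practice,
the same type observed with ordinary specimen-to-specimen noise, so the
partition can optionally merge near-duplicates: with ``merge_tolerance``
k > 0, specimens are single-linkage clustered on the number of
comparable traits (both non-zero) at which they disagree, at threshold
k.  Tolerance 0 means exact state-vector equality, zeros included.

Gross types (the 18 visually defined groupings) are labels only; they
are determined independently of the disparity calculation and no
classifier is provided for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .disparity import UNDEFINED, pair_disparity
from .io import DenticleCode, read_coding_sheet, write_coding_sheet
from .schema import Schema

__all__ = [
    "Morphotype",
    "assign_morphotypes",
    "match_to_catalog",
    "hamming_comparable",
    "read_catalog",
    "write_catalog",
    "count_catalog_types",
    "gross_type_vocabulary",
]

MORPHOTYPE_COLUMN = "morphotype_name"
GROSS_TYPE_COLUMN = "gross_type"


@dataclass
class Morphotype:
    """A cluster of specimens sharing (nearly) one state combination."""

    name: str
    canonical: dict[str, int]
    members: tuple[str, ...]
    gross_type: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def canonical_code(self) -> DenticleCode:
        return DenticleCode(self.name, dict(self.canonical), dict(self.meta))


def hamming_comparable(a: DenticleCode, b: DenticleCode, schema: Schema) -> int:
    """Number of traits at which two codes are comparable and disagree.

    Traits where either specimen holds the 0 sentinel are excluded from
    the count — a broken character is unknown, not different.
    """
    return sum(
        1
        for t in schema.trait_ids
        if a.states[t] != 0 and b.states[t] != 0 and a.states[t] != b.states[t]
    )


def _state_vector(code: DenticleCode, schema: Schema) -> tuple[int, ...]:
    return tuple(code.states[t] for t in schema.trait_ids)


def assign_morphotypes(
    codes: Sequence[DenticleCode],
    schema: Schema,
    merge_tolerance: int = 0,
    weighted_threshold: float | None = None,
) -> list[Morphotype]:
    """Partition specimens into morphotypes.

    With ``merge_tolerance=0`` the groups are exact equality classes of
    the full state vector (zeros equal only zeros).  With tolerance k in
    {1, 2} the groups are single-linkage components at comparable-trait
    Hamming distance <= k.  ``weighted_threshold``, if given, replaces
    the Hamming criterion with normalized pair disparity <= threshold.

    The result is deterministic for a given input: morphotypes are
    ordered (and named MT001, MT002, ...) by their lexicographically
    smallest canonical state vector; the canonical code of a group is
    its most frequent member vector, ties broken lexicographically.
    """
    if merge_tolerance not in (0, 1, 2):
        raise ValueError("merge_tolerance must be 0, 1 or 2")
    n = len(codes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    if merge_tolerance == 0 and weighted_threshold is None:
        seen: dict[tuple[int, ...], int] = {}
        for i, c in enumerate(codes):
            v = _state_vector(c, schema)
            if v in seen:
                union(seen[v], i)
            else:
                seen[v] = i
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if weighted_threshold is not None:
                    d = pair_disparity(codes[i], codes[j], schema)
                    close = d is not UNDEFINED and d <= weighted_threshold
                else:
                    close = (
                        hamming_comparable(codes[i], codes[j], schema)
                        <= merge_tolerance
                    )
                if close:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    morphs: list[Morphotype] = []
    for members in groups.values():
        vectors = [_state_vector(codes[i], schema) for i in members]
        freq: dict[tuple[int, ...], int] = {}
        for v in vectors:
            freq[v] = freq.get(v, 0) + 1
        best = max(freq.items(), key=lambda kv: (kv[1], tuple(-x for x in kv[0])))
        canonical_vec = best[0]
        morphs.append(
            Morphotype(
                name="",
                canonical=dict(zip(schema.trait_ids, canonical_vec)),
                members=tuple(codes[i].specimen_id for i in sorted(members)),
            )
        )
    morphs.sort(key=lambda m: _state_vector(m.canonical_code(), schema))
    width = max(3, len(str(len(morphs))))
    for k, m in enumerate(morphs, start=1):
        m.name = f"MT{k:0{width}d}"
    return morphs


def match_to_catalog(
    code: DenticleCode,
    catalog: Sequence[Morphotype],
    schema: Schema,
) -> list[tuple[str, object]]:
    """Rank catalog morphotypes by disparity to a query specimen.

    Returns ``(name, disparity)`` pairs sorted ascending; pairs with no
    shared codable traits come last with :data:`UNDEFINED` as the value.
    The ranking is invariant to catalog order (ties broken by name).
    """
    if not catalog:
        raise ValueError("catalog is empty")
    scored = []
    for m in catalog:
        d = pair_disparity(code, m.canonical_code(), schema)
        scored.append((m.name, d))
    defined = sorted(
        ((n, d) for n, d in scored if d is not UNDEFINED), key=lambda x: (x[1], x[0])
    )
    undefined = sorted(((n, d) for n, d in scored if d is UNDEFINED))
    return defined + undefined


# ---------------------------------------------------------------------------
# Catalog files: coding-sheet format plus morphotype_name / gross_type columns.

def read_catalog(path: str | Path, schema: Schema) -> list[Morphotype]:
    codes = read_coding_sheet(path, schema)
    catalog = []
    for c in codes:
        name = c.meta.get(MORPHOTYPE_COLUMN) or c.specimen_id
        catalog.append(
            Morphotype(
                name=name,
                canonical=dict(c.states),
                members=(c.specimen_id,),
                gross_type=c.meta.get(GROSS_TYPE_COLUMN) or None,
                meta={
                    k: v
                    for k, v in c.meta.items()
                    if k not in (MORPHOTYPE_COLUMN, GROSS_TYPE_COLUMN)
                },
            )
        )
    return catalog


def write_catalog(
    catalog: Sequence[Morphotype], path: str | Path, schema: Schema
) -> None:
    codes = []
    for m in catalog:
        meta = dict(m.meta)
        meta[MORPHOTYPE_COLUMN] = m.name
        meta[GROSS_TYPE_COLUMN] = m.gross_type or ""
        codes.append(DenticleCode(m.name, dict(m.canonical), meta))
    write_coding_sheet(codes, path, schema)


def count_catalog_types(
    catalog: Sequence[Morphotype],
    schema: Schema,
    catch_all_names: Sequence[str] = ("generic linear", "generic geometric"),
) -> dict[str, int]:
    """Unique state combinations in a catalog, split into named types and
    catch-alls (matched case-insensitively against ``catch_all_names``)."""
    catch = {n.lower() for n in catch_all_names}
    named_vecs = set()
    catch_vecs = set()
    for m in catalog:
        vec = tuple(m.canonical[t] for t in schema.trait_ids)
        if m.name.lower() in catch or (m.gross_type or "").lower() in catch:
            catch_vecs.add(vec)
        else:
            named_vecs.add(vec)
    return {
        "named": len(named_vecs),
        "catch_all": len(catch_vecs),
        "total": len(named_vecs | catch_vecs),
    }


def gross_type_vocabulary() -> list[str]:
    """The 18 controlled gross-type labels shipped with the package."""
    text = resources.files("denticode.data").joinpath("gross_types.txt").read_text(
        encoding="utf-8"
    )
    return [line.strip() for line in text.splitlines() if line.strip()]
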