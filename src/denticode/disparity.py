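"""Pairwise weighted disparity between coded denticles.

Disparity between two specimens is computed only over the traits both
were actually coded for — the overlap of their codable (non-zero)
character sets.  Over that shared set S the raw disparity is

    raw(a, b) = sum_{t in S} w_t * d_t(a_t, b_t)

and the normalized disparity divides by the maximum attainable weighted
distance over the same shared set,

    D(a, b) = raw(a, b) / sum_{t in S} w_t * max(d_t),

so a heavily broken fossil pair is commensurable with a complete modern
pair.  When S is empty (or carries no distance range) the pair is
UNDEFINED — flagged, never silently zero.  A global-denominator mode
(dividing every pair by the full-schema maximum) is kept for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import DenticleCode
from .schema import Schema

__all__ = [
    "UNDEFINED",
    "DisparityMatrix",
    "pair_disparity",
    "pairwise_matrix",
    "trait_contributions",
    "character_jackknife",
]


class _Undefined:
    """Sentinel for a pair with no shared codable traits."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()

Normalization = Literal["pair", "global", "raw"]


@dataclass
class DisparityMatrix:
    """Symmetric disparity matrix with per-pair overlap bookkeeping.

    ``D[i, j]`` is NaN exactly where ``defined[i, j]`` is False (no
    shared codable traits); ``shared_weight`` holds the summed trait
    weights of each pair's comparable set and ``comparable_count`` the
    number of comparable traits.
    """

    ids: tuple[str, ...]
    D: np.ndarray
    shared_weight: np.ndarray
    comparable_count: np.ndarray
    normalization: str = "pair"

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.D)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if np.isnan(self.D[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def submatrix(self, keep_ids: Sequence[str]) -> "DisparityMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        sel = np.ix_(idx, idx)
        return DisparityMatrix(
            ids=tuple(keep_ids),
            D=self.D[sel].copy(),
            shared_weight=self.shared_weight[sel].copy(),
            comparable_count=self.comparable_count[sel].copy(),
            normalization=self.normalization,
        )

    def to_csv(self, path: str | Path, companion_shared_weight: bool = True) -> None:
        """Square CSV with id header; optional *_shared_weight.csv companion."""
        path = Path(path)
        pd.DataFrame(self.D, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, index_label="specimen_id", float_format="%.10g"
        )
        if companion_shared_weight:
            side = path.with_name(path.stem + "_shared_weight" + path.suffix)
            pd.DataFrame(
                self.shared_weight, index=list(self.ids), columns=list(self.ids)
            ).to_csv(side, index_label="specimen_id", float_format="%.10g")

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP-style lower-triangle distance file (undefined pairs
        written as -1, which PHYLIP consumers must prune)."""
        lines = [f"{self.n}"]
        for i, sid in enumerate(self.ids):
            vals = [
                "-1" if np.isnan(self.D[i, j]) else f"{self.D[i, j]:.6f}"
                for j in range(i)
            ]
            lines.append("  ".join([f"{sid[:10]:<10}"] + vals).rstrip())
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _pair_terms(a: DenticleCode, b: DenticleCode, schema: Schema):
    """Shared codable traits with their weighted distances and maxima."""
    for t in schema.traits:
        sa, sb = a.states[t.trait_id], b.states[t.trait_id]
        if sa == 0 or sb == 0:
            continue
        yield t, t.distance(sa, sb), t.max_distance


def pair_disparity(
    a: DenticleCode,
    b: DenticleCode,
    schema: Schema,
    normalized: bool = True,
):
    """Disparity between two specimens, or :data:`UNDEFINED`.

    With ``normalized=True`` the value lies in [0, 1]; otherwise the raw
    weighted sum is returned.  UNDEFINED is returned when the two codes
    share no codable trait, or when the shared traits admit no distance
    at all (zero denominator).
    """
    raw = 0.0
    denom = 0.0
    any_shared = False
    for t, d, dmax in _pair_terms(a, b, schema):
        any_shared = True
        raw += t.weight * d
        denom += t.weight * dmax
    if not any_shared:
        return UNDEFINED
    if not normalized:
        return raw
    if denom == 0.0:
        return UNDEFINED
    return raw / denom


def trait_contributions(
    a: DenticleCode, b: DenticleCode, schema: Schema
) -> dict[str, dict]:
    """Per-trait decomposition of the raw disparity between two codes.

    Returns ``{trait_id: {"weight", "distance", "weighted"}}`` for the
    shared codable traits (their ``weighted`` values sum to the raw
    disparity) plus ``{"comparable": False}`` entries for traits one or
    both specimens could not be coded for.
    """
    out: dict[str, dict] = {}
    for t in schema.traits:
        sa, sb = a.states[t.trait_id], b.states[t.trait_id]
        if sa == 0 or sb == 0:
            out[t.trait_id] = {"comparable": False}
            continue
        d = t.distance(sa, sb)
        out[t.trait_id] = {
            "comparable": True,
            "weight": t.weight,
            "distance": d,
            "weighted": t.weight * d,
        }
    return out


def pairwise_matrix(
    codes: Sequence[DenticleCode],
    schema: Schema,
    normalization: Normalization = "pair",
) -> DisparityMatrix:
    """All-pairs disparity over a specimen collection.

    ``normalization="pair"`` (default) uses the per-pair maximum over the
    shared traits; ``"global"`` divides every raw value by the
    full-schema maximum ``sum_t w_t max(d_t)``; ``"raw"`` skips
    normalization.
    """
    ids = [c.specimen_id for c in codes]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate specimen ids: {dupes}")
    if len(codes) < 2:
        raise ValueError("need at least two codes")
    n = len(codes)
    # Vectorized evaluation: per trait, gather states, mask zeros, look
    # up distances for all pairs at once.
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    denom = np.zeros((n, n))
    global_denom = sum(t.weight * t.max_distance for t in schema.traits)
    for t in schema.traits:
        states = np.array([c.states[t.trait_id] for c in codes])
        nz = states != 0
        mask = np.outer(nz, nz)
        off = 1 if t.has_zero_state else t.state_indices[0]
        si = np.where(nz, states - off, 0)
        dists = t.dist[np.ix_(si, si)]
        D += np.where(mask, t.weight * dists, 0.0)
        shared += np.where(mask, t.weight, 0.0)
        denom += np.where(mask, t.weight * t.max_distance, 0.0)
        counts += mask
    np.fill_diagonal(counts, [len([1 for t in schema.traits if c.states[t.trait_id] != 0]) for c in codes])
    if normalization == "pair":
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(denom > 0, D / np.where(denom > 0, denom, 1.0), np.nan)
    elif normalization == "global":
        D = np.where(counts > 0, D / global_denom, np.nan)
    elif normalization == "raw":
        D = np.where(counts > 0, D, np.nan)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown normalization {normalization!r}")
    np.fill_diagonal(D, 0.0)
    return DisparityMatrix(
        ids=tuple(ids),
        D=D,
        shared_weight=shared,
        comparable_count=counts,
        normalization=normalization,
    )


def character_jackknife(
    codes: Sequence[DenticleCode],
    schema: Schema,
    drop: str | Sequence[str],
    normalization: Normalization = "pair",
) -> DisparityMatrix:
    """Sensitivity analysis: recompute disparity with characters removed.

    ``drop`` is a trait id ("F1"), a group letter ("O": every trait in
    that group), or a sequence of either.  Equivalent to
    :func:`pairwise_matrix` on a schema copy with those traits removed
    and their nesting rules pruned.
    """
    items = [drop] if isinstance(drop, str) else list(drop)
    trait_ids: list[str] = []
    for item in items:
        if item in schema:
            trait_ids.append(item)
        elif len(item) == 1 and any(t.group == item for t in schema.traits):
            trait_ids.extend(t.trait_id for t in schema.traits if t.group == item)
        else:
            raise KeyError(f"no trait or group named {item!r}")
    reduced = schema.drop_traits(trait_ids)
    return pairwise_matrix(codes, reduced, normalization=normalization)
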