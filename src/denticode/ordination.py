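"""Non-metric multidimensional scaling of a disparity matrix.

The character code yields categorical dissimilarities, so the
morphospace is built with NMDS: find a k-dimensional configuration
whose inter-point distances best preserve the *rank order* of the
disparities, judged by Kruskal's stress-1,

    stress1 = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where d_ij are configuration distances and dhat_ij the monotone
(isotonic) regression of d on the disparities.  Ties in the disparities
are handled weakly (Kruskal's primary approach): tied dissimilarities
are free to take different fitted values.

Minimization is delegated to scikit-learn's SMACOF non-metric MDS; the
best of ``n_restarts`` random starts is kept and stress-1 is recomputed
here from the final configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .disparity import DisparityMatrix
from .io import DenticleCode

__all__ = ["Ordination", "nmds", "kruskal_stress", "overlay_grouping"]


@dataclass
class Ordination:
    """A k-dimensional NMDS configuration with its final stress."""

    ids: tuple[str, ...]
    coords: np.ndarray
    k: int
    stress: float
    seed: int
    n_restarts: int
    converged: bool

    def to_csv(self, path: str | Path) -> None:
        header = "# stress1=%.6f k=%d seed=%d\n" % (self.stress, self.k, self.seed)
        cols = ",".join(f"dim{i + 1}" for i in range(self.k))
        lines = [header, f"specimen_id,{cols}\n"]
        for sid, row in zip(self.ids, self.coords):
            lines.append(sid + "," + ",".join(f"{v:.8f}" for v in row) + "\n")
        Path(path).write_text("".join(lines), encoding="utf-8")


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration against a dissimilarity matrix.

    Isotonic regression (weak ties) of configuration distances on the
    dissimilarities supplies the fitted monotone targets.
    """
    iu = np.triu_indices(D.shape[0], k=1)
    delta = D[iu]
    d = pdist(coords)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat_sorted = iso.fit_transform(delta[order], d[order])
    dhat = np.empty_like(d)
    dhat[order] = dhat_sorted
    denom = float(np.sum(d**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def nmds(
    D: DisparityMatrix | np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    eps: float = 1e-6,
    ids: Sequence[str] | None = None,
) -> Ordination:
    """Ordinate a disparity matrix in k dimensions.

    Runs ``n_restarts`` independent random initializations (seeded from
    ``seed``) and keeps the configuration with the lowest stress-1.
    Raises ``ValueError`` if the matrix has undefined pairs (remove the
    offending specimens first) or if ``k >= n``.
    """
    if isinstance(D, DisparityMatrix):
        undef = D.undefined_pairs
        if undef:
            shown = ", ".join(f"{a}~{b}" for a, b in undef[:5])
            raise ValueError(
                f"disparity matrix has {len(undef)} undefined pair(s) "
                f"({shown}{'...' if len(undef) > 5 else ''}); drop those "
                "specimens before ordination"
            )
        mat = D.D
        ids = D.ids
    else:
        mat = np.asarray(D, dtype=float)
        if np.isnan(mat).any():
            raise ValueError("dissimilarity matrix contains NaN")
        ids = tuple(ids) if ids is not None else tuple(
            f"s{i}" for i in range(mat.shape[0])
        )
    n = mat.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} specimens, got {n}")

    rng = np.random.default_rng(seed)
    best_coords = None
    best_stress = np.inf
    converged = False
    for _ in range(n_restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=sub,
            normalized_stress=True,
        )
        coords = model.fit_transform(mat)
        s = kruskal_stress(mat, coords)
        if s < best_stress - 1e-12:
            best_stress = s
            best_coords = coords
            converged = model.n_iter_ < max_iter
    best_coords = best_coords - best_coords.mean(axis=0)  # center at origin
    return Ordination(
        ids=tuple(ids),
        coords=best_coords,
        k=k,
        stress=float(best_stress),
        seed=seed,
        n_restarts=n_restarts,
        converged=bool(converged),
    )


def overlay_grouping(
    ordination: Ordination,
    codes: Sequence[DenticleCode],
    trait_id: str,
) -> dict:
    """Summarize how a trait's states cluster in ordination space.

    For every state of ``trait_id`` present among the specimens, returns
    the centroid of its members and their mean distance to it (spread).
    Also reports a between/within ratio — mean distance between state
    centroids over mean within-state spread — as a grouping-strength
    statistic; it is None (flagged) when only one state is present or
    all spreads are zero.
    """
    by_id = {c.specimen_id: c for c in codes}
    missing = [s for s in ordination.ids if s not in by_id]
    if missing:
        raise KeyError(f"codes missing for specimens: {missing[:5]}")
    states: dict[int, list[int]] = {}
    for i, sid in enumerate(ordination.ids):
        st = by_id[sid].states[trait_id]
        states.setdefault(st, []).append(i)
    groups = {}
    for st, idx in sorted(states.items()):
        pts = ordination.coords[idx]
        centroid = pts.mean(axis=0)
        spread = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
        groups[st] = {"centroid": centroid, "spread": spread, "n": len(idx)}
    ratio = None
    if len(groups) > 1:
        cents = np.array([g["centroid"] for g in groups.values()])
        between = float(np.mean(pdist(cents)))
        within = float(np.mean([g["spread"] for g in groups.values()]))
        ratio = between / within if within > 0 else None
    return {"trait_id": trait_id, "groups": groups, "between_within_ratio": ratio}
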