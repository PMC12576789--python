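"""Qualitative orderings implied by the trait disparity descriptions.

The shipped distance matrices are an ordinal reconstruction of verbal
descriptions; the numeric values are a convention, but the *orderings*
those descriptions state are contractual.  This module lists them as
checkable relations so the bundled matrices (or a user-supplied
replacement) can be audited: each entry asserts
``d(trait, pair_a)  op  factor * d(trait, pair_b)``.

Examples of what is encoded: a geometric ridge system is closer to a
meandering one than to a smooth crown; radial symmetry is farther from
asymmetry than one plane is from two; cusp counts and texture-coverage
bins step ordinally.
"""

from __future__ import annotations

from .schema import Schema

__all__ = ["ORDERING_ASSERTIONS", "check_orderings"]

# (trait_id, pair_a, op, pair_b, factor)
ORDERING_ASSERTIONS: list[tuple[str, tuple[int, int], str, tuple[int, int], float]] = [
    # A1: spines far from everything; cruciform/circular far from unlike shapes
    ("A1", (1, 5), ">", (5, 9), 1.0),
    ("A1", (2, 3), ">", (5, 9), 1.0),
    ("A1", (2, 4), ">", (4, 8), 1.0),
    # A2: lobed near rounded; pointed near stretched
    ("A2", (1, 5), "<", (1, 2), 1.0),
    ("A2", (3, 4), "<", (1, 3), 1.0),
    # B1/C1: no-directionality far; the rest step equally
    ("B1", (4, 1), ">", (1, 2), 1.0),
    ("B1", (1, 2), "==", (2, 3), 1.0),
    ("C1", (4, 2), ">", (2, 3), 1.0),
    # B2/C2: smooth far from textured edges, vertex in between
    ("B2", (1, 2), ">", (1, 4), 1.0),
    ("B2", (1, 3), ">", (3, 4), 1.0),
    ("C2", (1, 2), ">", (1, 4), 1.0),
    # D1: radial symmetry farthest from asymmetric; one vs two planes close
    ("D1", (1, 4), ">", (2, 3), 1.0),
    ("D1", (1, 4), ">", (1, 2), 1.0),
    ("D1", (2, 4), ">", (2, 3), 1.0),
    # E1: cusp counts step ordinally; one cusp apart from multi-cusped
    ("E1", (3, 5), "==", (3, 4), 2.0),
    ("E1", (2, 3), ">", (3, 4), 1.0),
    ("E1", (1, 2), ">", (3, 4), 1.0),
    # E2/E3: ridge association contrasts; irregular cusps stand out
    ("E2", (1, 2), ">", (1, 3), 1.0),
    ("E3", (1, 4), ">", (1, 2), 1.0),
    # E4: cusp-length bins in unit steps
    ("E4", (1, 3), "==", (1, 2), 2.0),
    # F1: geometric/meandering/branching cohere; spine+linear pair up;
    # smooth is maximally unlike everything
    ("F1", (3, 4), "<", (3, 1), 1.0),
    ("F1", (3, 4), "<", (3, 5), 1.0),
    ("F1", (3, 6), "<", (3, 5), 1.0),
    ("F1", (2, 5), "<", (2, 3), 1.0),
    ("F1", (1, 2), ">", (2, 5), 1.0),
    # G1: proportionate steps, compressed at the many-ridged end
    ("G1", (2, 4), "==", (2, 3), 2.0),
    ("G1", (6, 7), "<", (5, 6), 1.0),
    ("G1", (1, 2), ">", (2, 3), 1.0),
    # G2: two..five equally dissimilar; one ridge and none stand apart
    ("G2", (3, 4), "==", (4, 6), 1.0),
    ("G2", (2, 3), ">", (3, 4), 1.0),
    ("G2", (1, 2), ">", (3, 4), 1.0),
    # G3: one vs two outgrowths closer than none vs one
    ("G3", (2, 3), "<", (1, 2), 1.0),
    # H1: parallel/converging/diverging cohere; intersecting+radial pair up
    ("H1", (1, 2), "<", (1, 4), 1.0),
    ("H1", (5, 6), "<", (5, 1), 1.0),
    # I1: no-central-ridge near one-ridge, far from true central ridges
    ("I1", (1, 2), "<", (1, 3), 1.0),
    ("I1", (3, 4), "<", (1, 4), 1.0),
    # I2: straight nearer curved than meandering
    ("I2", (1, 2), "<", (1, 3), 1.0),
    # I3/J2: troughs and irregular widths farthest from parallel ridges
    ("I3", (1, 5), ">", (1, 2), 1.0),
    ("I3", (2, 4), "<", (1, 5), 1.0),
    ("J2", (1, 5), ">", (1, 2), 1.0),
    # J1: curved forms cohere; meandering/combination stand out together
    ("J1", (2, 3), "<", (1, 2), 1.0),
    ("J1", (4, 5), "<", (1, 4), 1.0),
    # K1: polygonal central shapes cohere; mound/multiple/no-shape far
    ("K1", (2, 6), "<", (2, 8), 1.0),
    ("K1", (1, 2), ">", (2, 3), 1.0),
    ("K1", (10, 4), ">", (4, 9), 1.0),
    # K2: central-shape symmetry mirrors D1
    ("K2", (1, 4), ">", (2, 3), 1.0),
    ("K2", (2, 4), "<", (1, 4), 1.0),
    # L1: ridgeless crowns far; combination lengths the outlier among ridged
    ("L1", (1, 2), ">", (2, 5), 1.0),
    ("L1", (2, 5), ">", (2, 3), 1.0),
    # L2: undefined vs fully defined is the extreme; partial near central-only
    ("L2", (1, 3), ">", (1, 2), 1.0),
    ("L2", (2, 4), "<", (2, 3), 1.0),
    # L3/L4
    ("L3", (1, 2), ">", (2, 3), 1.0),
    ("L4", (4, 1), ">", (1, 2), 1.0),
    # M1: depression counts linear; broken-multiple scores like two
    ("M1", (2, 4), "==", (2, 3), 2.0),
    ("M1", (7, 2), "==", (3, 2), 1.0),
    # M3: both-locations far from single locations
    ("M3", (3, 1), ">", (1, 2), 1.0),
    # N1: protrusions the outlier; surface textures cohere
    ("N1", (7, 3), ">", (3, 4), 1.0),
    ("N1", (4, 5), "<", (2, 4), 1.0),
    ("N1", (1, 2), ">", (2, 3), 1.0),
    # N2: whole-crown textures far from local patches
    ("N2", (1, 3), ">", (1, 2), 1.0),
    ("N2", (2, 4), ">", (3, 4), 1.0),
    # N3: coverage bins in unit steps
    ("N3", (1, 3), "==", (1, 2), 2.0),
    # O1: tree roots and crown-continuous bases the extremes
    ("O1", (10, 1), ">", (1, 2), 1.0),
    ("O1", (12, 1), ">", (10, 1), 1.0),
    ("O1", (10, 1), ">", (11, 1), 1.0),
    # O2/O4/O5/O7: the "none"/no-directionality states stand apart
    ("O2", (4, 1), ">", (1, 2), 1.0),
    ("O4", (1, 2), ">", (2, 3), 1.0),
    ("O5", (1, 2), ">", (2, 3), 1.0),
    ("O7", (4, 1), ">", (1, 2), 1.0),
    # O8: the crown-to-root angle sweeps semi-continuously
    ("O8", (1, 4), "==", (1, 2), 3.0),
    ("O8", (1, 2), "<", (1, 3), 1.0),
]


def check_orderings(
    schema: Schema,
    assertions=ORDERING_ASSERTIONS,
) -> list[str]:
    """Evaluate the ordering assertions against a schema's matrices.

    Returns human-readable descriptions of the violated assertions
    (empty list = all hold).
    """
    failures = []
    for trait_id, pa, op, pb, factor in assertions:
        t = schema.trait(trait_id)
        da = t.distance(*pa)
        db = factor * t.distance(*pb)
        ok = {"<": da < db, ">": da > db, "==": da == db}[op]
        if not ok:
            failures.append(
                f"{trait_id}: d{pa}={da} not {op} {factor}*d{pb}={db}"
            )
    return failures
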