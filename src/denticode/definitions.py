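"""Curated definition of the denticles_v0.5 character schema.

The 46 traits below follow the published character code for dermal
denticles: states, weights, and an ordinal reconstruction of each
trait's state-distance matrix from its verbal disparity description.
The verbal descriptions give orderings, not numbers; they are mapped
onto the descriptor scale (identical=0 .. maximal=4), with ordinal
traits expanded to unit (or, where the description compresses the top
bins, fractional) steps.  The bundled ``denticles_v0.5.json`` is frozen
output of :func:`build_v05`; regenerating it (scripts/build_schema_data.py)
must be a no-op.

Matrix-construction vocabulary used in the pair tables:

* a plain number is an ordinal step distance;
* a string is looked up in :data:`denticode.schema.DESCRIPTOR_SCALE`.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

from .schema import (
    NestingRule,
    Schema,
    TraitDef,
    build_matrix_from_descriptors,
)

__all__ = ["build_v05", "build_historical_stub", "V05_TRAIT_TABLE", "V05_NESTING_RULES"]


def _pairs(states: Sequence[int], default, overrides: Mapping | None = None) -> dict:
    """All unordered state pairs at ``default``, with overrides applied."""
    table = {(a, b): default for a, b in combinations(states, 2)}
    for (a, b), v in (overrides or {}).items():
        key = (a, b) if (a, b) in table else (b, a)
        table[key] = v
    return table


def _block(table: dict, group_a: Sequence[int], group_b: Sequence[int], value) -> None:
    """Set every cross pair between two state groups."""
    for a in group_a:
        for b in group_b:
            if a == b:
                continue
            key = (a, b) if (a, b) in table else (b, a)
            table[key] = value


def _ordinal(states: Sequence[int], positions: Mapping[int, float] | None = None) -> dict:
    """Unit-step ordinal distances, optionally with custom positions."""
    pos = positions or {s: float(s) for s in states}
    return {(a, b): abs(pos[a] - pos[b]) for a, b in combinations(states, 2)}


# --------------------------------------------------------------------------
# Per-trait tables.  Each entry: (group, name, weight, states, zero_meaning,
# pairwise descriptor map over non-zero states).

def _a1():
    s = list(range(1, 10))
    t = _pairs(s, "equally different")
    # spines erupt semi-vertically: maximally unlike every flat-lying shape
    _block(t, [1], s[1:], "maximal")
    # cruciform (angular, with depressions/mounds) vs rounder shapes
    _block(t, [2], [3, 4, 8], "very different")
    # circular crowns lack an anterior/posterior: far from angular shapes
    _block(t, [3], [2, 5, 9], "very different")
    return t


def _a2():
    s = list(range(1, 7))
    t = _pairs(s, "different")
    t[(1, 5)] = "more similar"   # lobed shares the rounded spade's round edges
    t[(3, 4)] = "more similar"   # pointed and stretched both end in a point
    return t


def _b1():
    t = _pairs([1, 2, 3], 1.0)   # straight/rounded/pointed differ one step
    _block(t, [4], [1, 2, 3], "very different")  # no directionality at all
    return t


def _b2():
    return {
        (1, 2): "significantly different",  # smooth vs scalloped
        (1, 3): "significantly different",  # smooth vs pointed
        (1, 4): "different",                # vertex sits between
        (2, 3): "different",
        (2, 4): "different",
        (3, 4): "different",
    }


def _b3():
    return {(1, 2): "equally different"}


def _d1():
    return {
        (1, 2): "significantly different",  # asymmetric vs one plane
        (1, 3): "significantly different",
        (1, 4): "maximal",                  # asymmetric vs radial
        (2, 3): "similar",                  # one vs two planes
        (2, 4): "significantly different",
        (3, 4): "significantly different",
    }


def _e1():
    s = list(range(1, 12))
    t = _ordinal(s)                      # cusp counts step by one bin
    for x in range(3, 12):               # one cusp stands apart from multi
        t[(2, x)] = abs(x - 2) + 1
    _block(t, [1], s[1:], "significantly different")  # no cusps at all
    return t


def _e2():
    return {
        (1, 2): "different",       # unassociated vs ridge-associated cusps
        (1, 3): "somewhat different",
        (2, 3): "somewhat different",
    }


def _e3():
    t = _pairs([1, 2, 3], "somewhat different")
    _block(t, [4], [1, 2, 3], "very different")  # irregular cusps
    return t


def _e4():
    return _ordinal([1, 2, 3])  # relative cusp-length bins, one-step increments


def _f1():
    s = list(range(1, 7))
    t = _pairs(s, "very different")
    _block(t, [3, 4, 6], [3, 4, 6], "more similar")  # geometric/meandering/branching
    t[(2, 5)] = "equally different"                  # linear vs spine
    _block(t, [1], s[1:], "maximal")                 # smooth: the only no-ridge system
    return t


def _g1():
    # states 2..6 are 1..5 segments, one step apart; the six-ten and
    # eleven-plus bins sit at compressed half-step positions because
    # many-ridged types routinely vary by a few segments.
    pos = {2: 1.0, 3: 2.0, 4: 3.0, 5: 4.0, 6: 5.0, 7: 5.5, 8: 6.5}
    t = _ordinal(list(pos), pos)
    _block(t, [1], list(pos), "very different")  # no ridge segments
    return t


def _g2():
    t = _pairs(list(range(1, 8)), "different")
    _block(t, [3, 4, 5, 6], [3, 4, 5, 6], "somewhat different")  # two..five ridges
    _block(t, [1], list(range(2, 8)), "very different")          # no ridges
    return t


def _g3():
    return {
        (1, 2): "equally different",  # no outgrowths vs one
        (1, 3): "equally different",
        (2, 3): "somewhat different",
    }


def _h1():
    s = list(range(1, 9))
    t = _pairs(s, "equally different")
    _block(t, [1, 2, 3], [1, 2, 3], "more similar")  # parallel/converge/diverge
    _block(t, [5, 6], [1, 2, 3, 4, 7, 8], "very different")
    t[(5, 6)] = "more similar"                       # intersecting vs apex-radial
    return t


def _i1():
    return {
        (1, 2): "more similar",           # no central ridge vs only one ridge
        (1, 3): "very different",
        (1, 4): "very different",
        (2, 3): "more similar",           # a lone ridge is usually central
        (2, 4): "more similar",
        (3, 4): "different",              # distinct vs same-as-others
    }


def _i2():
    return {
        (1, 2): "more similar",       # straight vs curved
        (1, 3): "equally different",  # vs meandering
        (2, 3): "equally different",
    }


def _i3():
    s = list(range(1, 7))
    t = _pairs(s, "different")
    _block(t, [2, 3, 4], [2, 3, 4], "somewhat different")  # triangular/diamond family
    t[(1, 5)] = "very different"   # parallel vs trough
    t[(1, 6)] = "very different"   # parallel vs irregular
    return t


def _j1():
    t = _pairs(list(range(1, 6)), "equally different")
    t[(2, 3)] = "more similar"                        # the two curved forms
    _block(t, [4, 5], [1, 2, 3], "very different")    # meandering / combination
    t[(4, 5)] = "more similar"
    return t


def _j2():
    s = list(range(1, 7))
    t = _pairs(s, "different")
    _block(t, [2, 3, 4], [2, 3, 4], "somewhat different")
    t[(1, 5)] = "very different"
    t[(1, 6)] = "very different"
    t[(5, 6)] = "somewhat different"  # troughs and irregular, alike in kind
    return t


def _k1():
    s = list(range(1, 12))
    polygons = [2, 3, 4, 5, 6, 7, 9]  # enclosed geometric shapes with a dimple
    t = _pairs(s, "different")
    _block(t, polygons, polygons, "somewhat different")
    _block(t, [1], s[1:], "very different")        # ridges but no central shape
    _block(t, [8], polygons, "very different")     # mound: no dimple, no polygon
    _block(t, [10], polygons + [8], "very different")  # multiple central shapes
    t[(8, 10)] = "very different"
    return t


def _k2():
    return {
        (1, 2): "significantly different",  # no symmetry vs one plane
        (1, 3): "significantly different",
        (1, 4): "maximal",                  # no symmetry vs radial
        (2, 3): "similar",
        (2, 4): "different",
        (3, 4): "different",
    }


def _l1():
    t = _pairs(list(range(1, 6)), "somewhat different")
    _block(t, [1], [2, 3, 4, 5], "very different")  # no ridges
    _block(t, [5], [2, 3, 4], "different")          # combination lengths
    return t


def _l2():
    return {
        (1, 2): "very different",   # undefined vs partly defined
        (1, 3): "maximal",          # undefined vs fully defined
        (1, 4): "very different",
        (2, 3): "different",
        (2, 4): "somewhat different",  # partial and central-only, alike
        (3, 4): "different",
    }


def _l3():
    return {
        (1, 2): "very different",  # one ridge vs multiple
        (1, 3): "very different",
        (2, 3): "equally different",  # equal vs variable heights
    }


def _l4():
    t = _pairs([1, 2, 3, 4, 5], "equally different")
    _block(t, [4], [1, 2, 3, 5], "very different")  # variable profiles
    return t


def _m1():
    s = list(range(1, 8))
    t = _ordinal(list(range(2, 7)))              # 1..5+ depressions, unit steps
    # state 7 (multiple, exact count unreadable) scores exactly like state 3
    t[(3, 7)] = 0.0
    for x in [2, 4, 5, 6]:
        t[(x, 7)] = t[(min(x, 3), max(x, 3))]
    _block(t, [1], s[1:], "very different")      # no depressions
    return t


def _m2():
    return _pairs([1, 2, 3], "equally different")


def _m3():
    return {
        (1, 2): "more similar",      # central vs edge
        (1, 3): "very different",    # vs both
        (2, 3): "very different",
    }


def _m4():
    return _pairs(list(range(1, 8)), "equally different")


def _n1():
    s = list(range(1, 8))
    t = _pairs(s, "equally different")
    _block(t, [1], s[1:], "very different")          # no ridges
    _block(t, [2], [3, 4, 5, 6], "different")        # plain ridges vs featured
    _block(t, [7], [2, 3, 4, 5, 6], "very different")  # vertical protrusions
    _block(t, [3], [4, 5, 6], "more similar")        # micro-reliefs near textures
    _block(t, [4, 5, 6], [4, 5, 6], "more similar")  # the surface textures
    return t


def _n2():
    s = list(range(1, 8))
    t = _pairs(s, "equally different")
    t[(1, 3)] = "very different"                     # ridges-only vs crown-except-ridges
    _block(t, [2], [4, 5, 6, 7], "very different")   # whole crown vs local patches
    return t


def _n3():
    return _ordinal([1, 2, 3])  # coverage bins, one-step increments


def _o1():
    s = list(range(1, 13))
    plain = list(range(1, 10))
    t = _pairs(plain, "similar")                    # ordinary base outlines
    _block(t, [11], plain, "different")             # mirrors the crown
    _block(t, [10], plain + [11], "very different")  # tree roots
    _block(t, [12], s[:-1], "maximal")              # base continuous with crown
    t[(10, 11)] = "very different"
    return t


def _o2():
    t = _pairs([1, 2, 3], "equally different")
    _block(t, [4], [1, 2, 3], "very different")  # no directionality
    return t


def _o3():
    return _pairs([1, 2, 3], "equally different")


def _o4():
    t = _pairs(list(range(1, 8)), "equally different")
    _block(t, [1], list(range(2, 8)), "very different")  # grooveless base
    return t


def _o5():
    t = _pairs(list(range(1, 6)), "equally different")
    _block(t, [1], [2, 3, 4, 5], "very different")  # no root opening
    return t


def _o6():
    return _pairs([1, 2, 3], "equally different")


def _o7():
    t = _pairs([1, 2, 3, 4], "equally different")
    _block(t, [4], [1, 2, 3], "very different")  # no peduncle
    return t


def _o8():
    return _ordinal([1, 2, 3, 4])  # perpendicular-obtuse-parallel-acute sweep


def _o9():
    return _pairs([1, 2, 3], "equally different")


def _o10():
    return {(1, 2): "equally different"}


BROKEN = "broken"
NA = "not-applicable"
NESTED = "absent-nested"

#: trait_id -> (name, weight, states, zero_meaning, pair-table factory)
V05_TRAIT_TABLE: dict[str, tuple] = {
    "A1": (
        "Overall shape of crown",
        2.0,
        {1: "Spine", 2: "Cruciform", 3: "Circular/Oval", 4: "Spade",
         5: "Diamond/Rectangle", 6: "Elongated Asymmetrical", 7: "Irregular",
         8: "Fan-like", 9: "Triangular/Arrow-like"},
        None,
        _a1,
    ),
    "A2": (
        "Spade subtype",
        0.5,
        {0: "Not a spade", 1: "Rounded spade", 2: "Squared spade",
         3: "Pointed spade", 4: "Stretched spade", 5: "Lobed spade",
         6: "Irregular spade"},
        NESTED,
        _a2,
    ),
    "B1": (
        "Anterior/base shape",
        1.0,
        {0: "Too broken to code", 1: "Straight", 2: "Rounded",
         3: "Pointed (vertex)", 4: "Lacks directionality"},
        BROKEN,
        _b1,
    ),
    "B2": (
        "Anterior marginal macro texture",
        1.0,
        {0: "Too broken to code", 1: "Smooth", 2: "Scalloped",
         3: "Pointed", 4: "Anterior is a vertex"},
        BROKEN,
        _b2,
    ),
    "B3": (
        "Anterior marginal micro texture",
        1.0,
        {1: "Smooth", 2: "Distinct serrated"},
        None,
        _b3,
    ),
    "C1": (
        "Posterior shape",
        1.0,
        {0: "Too broken to code", 1: "Straight", 2: "Rounded",
         3: "Pointed (vertex)", 4: "Lacks directionality"},
        BROKEN,
        _b1,
    ),
    "C2": (
        "Posterior marginal macro texture",
        1.0,
        {0: "Too broken to code", 1: "Smooth", 2: "Scalloped",
         3: "Pointed", 4: "Posterior is a vertex"},
        BROKEN,
        _b2,
    ),
    "C3": (
        "Posterior marginal micro texture",
        1.0,
        {1: "Smooth", 2: "Distinct serrated"},
        None,
        _b3,
    ),
    "D1": (
        "Planes of symmetry",
        1.0,
        {1: "None/asymmetrical", 2: "One", 3: "Two", 4: "Three+/radial"},
        None,
        _d1,
    ),
    "E1": (
        "Number of cusps",
        1.0,
        {i: lbl for i, lbl in enumerate(
            ["No cusps", "One cusp", "Two cusps", "Three cusps", "Four cusps",
             "Five cusps", "Six cusps", "Seven cusps", "Eight cusps",
             "Nine cusps", "Ten or more cusps"], start=1)},
        None,
        _e1,
    ),
    "E2": (
        "Cusp-ridge association",
        0.5,
        {0: "No cusps", 1: "Cusps not associated with ridges",
         2: "Cusps associated with ridges", 3: "Some cusps associated"},
        NESTED,
        _e2,
    ),
    "E3": (
        "Cusps similarity",
        0.5,
        {0: "No cusps/only one cusp", 1: "Similar cusps",
         2: "Central cusp distinct", 3: "Opposite similar, adjacent distinct",
         4: "Irregular"},
        NESTED,
        _e3,
    ),
    "E4": (
        "Relative maximum cusp length",
        0.5,
        {0: "No cusps", 1: "Cusp < 1/4 crown", 2: "1/4 to 1/2 crown",
         3: "Cusp > 1/2 crown"},
        NESTED,
        _e4,
    ),
    "F1": (
        "Ridge system",
        2.0,
        {1: "Smooth", 2: "Linear", 3: "Geometric", 4: "Meandering",
         5: "Spine", 6: "Branching"},
        None,
        _f1,
    ),
    "G1": (
        "Number of ridge segments",
        1.0,
        {1: "None", 2: "One", 3: "Two", 4: "Three", 5: "Four", 6: "Five",
         7: "Six-ten", 8: "Eleven or more"},
        None,
        _g1,
    ),
    "G2": (
        "Number of independent ridges",
        1.0,
        {1: "None", 2: "One", 3: "Two", 4: "Three", 5: "Four", 6: "Five",
         7: "Six or more"},
        None,
        _g2,
    ),
    "G3": (
        "Ridge outgrowths",
        1.0,
        {0: "No ridges or broken", 1: "No ridge outgrowths",
         2: "One ridge outgrowth", 3: "Two ridge outgrowths"},
        NA,
        _g3,
    ),
    "H1": (
        "Ridge orientation",
        0.5,
        {0: "Only one ridge/no ridges", 1: "Parallel",
         2: "Converges from anterior", 3: "Diverges from anterior",
         4: "Diverges then converges", 5: "Ridges intersect/branch",
         6: "Apex radial", 7: "Irregular/no pattern",
         8: "Multiple orientations"},
        NESTED,
        _h1,
    ),
    "I1": (
        "Central ridge or trough disparity",
        0.5,
        {0: "No ridges", 1: "No central ridge", 2: "Only one ridge",
         3: "Same as other ridges", 4: "Distinct from other ridges"},
        NESTED,
        _i1,
    ),
    "I2": (
        "Central ridge directionality",
        0.5,
        {0: "No central ridge", 1: "Straight", 2: "Curved", 3: "Meandering"},
        NESTED,
        _i2,
    ),
    "I3": (
        "Central ridge width",
        0.5,
        {0: "No central ridge", 1: "Parallel",
         2: "Triangular widening from anterior",
         3: "Triangular thinning from anterior", 4: "Diamond-like",
         5: "Creates a central trough", 6: "Irregular"},
        NESTED,
        _i3,
    ),
    "J1": (
        "Non-central ridge directionality",
        0.5,
        {0: "None/only central ridge", 1: "Straight", 2: "Concave curved",
         3: "Convex curved", 4: "Meandering", 5: "Combination"},
        NESTED,
        _j1,
    ),
    "J2": (
        "Non-central ridge width",
        0.5,
        {0: "None/only central ridge", 1: "Parallel",
         2: "Triangular widening from anterior",
         3: "Triangular thinning from anterior", 4: "Diamond-like",
         5: "Creates troughs", 6: "Irregular/combination"},
        NESTED,
        _j2,
    ),
    "K1": (
        "Central ridge system shape",
        1.0,
        {0: "No ridges", 1: "Ridges but no central shape", 2: "Circular/oval",
         3: "Triangular", 4: "Quadrilateral", 5: "Pentagonal", 6: "Hexagon",
         7: "Heptagon", 8: "Mound", 9: "Octagon", 10: "Multiple",
         11: "Irregular"},
        NESTED,
        _k1,
    ),
    "K2": (
        "Central ridge system shape planes of symmetry",
        0.5,
        {0: "No central shape", 1: "No symmetry", 2: "One", 3: "Two",
         4: "Radial"},
        NESTED,
        _k2,
    ),
    "L1": (
        "Ridge length",
        0.5,
        {1: "No ridges", 2: "Ridge length = lateral length",
         3: "Ridge ends/begins mid crown", 4: "Ridge begins and ends mid crown",
         5: "Combination of lengths"},
        None,
        _l1,
    ),
    "L2": (
        "Ridge definition",
        0.5,
        {0: "No ridges", 1: "Not clearly defined", 2: "Partly defined",
         3: "Clearly defined", 4: "Only central ridge defined"},
        BROKEN,
        _l2,
    ),
    "L3": (
        "Relative ridge heights",
        0.5,
        {0: "No ridges", 1: "Only one ridge", 2: "Equal heights",
         3: "Variable heights"},
        BROKEN,
        _l3,
    ),
    "L4": (
        "Ridge/trough angularity",
        0.5,
        {0: "No ridges", 1: "Rounded", 2: "Triangular", 3: "Funnel shaped",
         4: "Variable/other", 5: "Rectangular"},
        BROKEN,
        _l4,
    ),
    "M1": (
        "Number of depressions",
        1.0,
        {1: "None", 2: "One", 3: "Two", 4: "Three", 5: "Four",
         6: "Five or more", 7: "Multiple (>2), broken"},
        None,
        _m1,
    ),
    "M2": (
        "Depression type",
        0.5,
        {0: "No depression", 1: "Thumbprint", 2: "Open tunnel", 3: "Dimples"},
        BROKEN,
        _m2,
    ),
    "M3": (
        "Location of depression",
        0.5,
        {0: "No depression", 1: "Central", 2: "Close to edge",
         3: "Both central and edge"},
        BROKEN,
        _m3,
    ),
    "M4": (
        "Shape of dimple",
        0.5,
        {0: "None", 1: "Circle", 2: "Elongated", 3: "Teardrop",
         4: "Square/quadrilateral", 5: "Pentagon", 6: "Irregular",
         7: "Multiple with different shapes"},
        BROKEN,
        _m4,
    ),
    "N1": (
        "Secondary ridge features",
        1.0,
        {1: "No ridges", 2: "No secondary features", 3: "Micro-reliefs",
         4: "Honeycomb texture", 5: "Wavy texture", 6: "Honeycomb/wavy combo",
         7: "Vertical protrusions"},
        None,
        _n1,
    ),
    "N2": (
        "Surface texture location",
        0.5,
        {0: "None", 1: "Ridges only", 2: "Crown and ridges",
         3: "Crown except ridges", 4: "Anterior only", 5: "Middle only",
         6: "Posterior only", 7: "Edges only"},
        BROKEN,
        _n2,
    ),
    "N3": (
        "Surface texture coverage",
        0.5,
        {0: "None", 1: "Less than 30%", 2: "30% to 70%", 3: "More than 70%"},
        BROKEN,
        _n3,
    ),
    "O1": (
        "Overall base shape",
        1.0,
        {0: "Base not preserved/observable", 1: "Kite shaped",
         2: "Kite/cruciform, extended vertices",
         3: "Kite/cruciform missing 1/4", 4: "Rhombus", 5: "Rounded rhombus",
         6: "Stretched rhombus", 7: "Trapezoid/rhombus hybrid",
         8: "Oval/oval-like", 9: "Circular", 10: "Tree roots",
         11: "Mirrors crown shape", 12: "Base continuous with crown"},
        BROKEN,
        _o1,
    ),
    "O2": (
        "Base width/length",
        1.0,
        {0: "Base not preserved/observable", 1: "Equal width and length",
         2: "Wider than long", 3: "Longer than wide",
         4: "Unequal, no directionality"},
        BROKEN,
        _o2,
    ),
    "O3": (
        "Crown to base ratio",
        1.0,
        {0: "Base not preserved/observable", 1: "Equal areas",
         2: "Crown larger", 3: "Base larger"},
        BROKEN,
        _o3,
    ),
    "O4": (
        "Number of grooves",
        1.0,
        {0: "Base not preserved/observable", 1: "No grooves", 2: "One",
         3: "Two", 4: "Three", 5: "Four", 6: "Five", 7: "Six plus"},
        BROKEN,
        _o4,
    ),
    "O5": (
        "Root foramen opening shape",
        1.0,
        {0: "Base not preserved/observable", 1: "No root opening",
         2: "Rhombus", 3: "Ellipse", 4: "Arc", 5: "Mirrors base shape"},
        BROKEN,
        _o5,
    ),
    "O6": (
        "Root foramen location",
        1.0,
        {0: "Base not preserved/no opening", 1: "Center", 2: "Anterior",
         3: "Posterior"},
        BROKEN,
        _o6,
    ),
    "O7": (
        "Peduncle height to width",
        1.0,
        {0: "Base not preserved/observable", 1: "Equal width and height",
         2: "Wider than high", 3: "Higher than wide", 4: "No peduncle"},
        BROKEN,
        _o7,
    ),
    "O8": (
        "Crown to root angle",
        1.0,
        {0: "Base not preserved/observable", 1: "Perpendicular", 2: "Obtuse",
         3: "Parallel", 4: "Acute"},
        BROKEN,
        _o8,
    ),
    "O9": (
        "Base to crown connection location",
        1.0,
        {0: "Base not preserved/observable", 1: "Anterior of crown",
         2: "Center of crown", 3: "Posterior of crown"},
        BROKEN,
        _o9,
    ),
    "O10": (
        "Mound",
        1.0,
        {0: "Base not preserved/observable", 1: "Not mounded", 2: "Mounded"},
        BROKEN,
        _o10,
    ),
}

#: (controller, states that trigger, {dependent: required value}).
#: The required value is 0 (inapplicable) except where the dependent has
#: no zero state and instead owns an explicit "none" state.
V05_NESTING_RULES: list[tuple[str, tuple[int, ...], dict[str, int]]] = [
    # A spade subtype only exists for spade-shaped crowns
    ("A1", (1, 2, 3, 5, 6, 7, 8, 9), {"A2": 0}),
    # Cusp elaborations require cusps
    ("E1", (1,), {"E2": 0, "E3": 0, "E4": 0}),
    ("E1", (2,), {"E3": 0}),  # similarity needs more than one cusp
    # A smooth crown has no ridges, hence no ridge characters at all
    ("F1", (1,), {
        "G1": 1, "G2": 1, "G3": 0, "H1": 0,
        "I1": 0, "I2": 0, "I3": 0, "J1": 0, "J2": 0,
        "K1": 0, "K2": 0,
        "L1": 1, "L2": 0, "L3": 0, "L4": 0,
        "N1": 1, "N2": 0, "N3": 0,
    }),
    # Central-ridge details require a central ridge
    ("I1", (0, 1), {"I2": 0, "I3": 0}),
    # Central-shape symmetry requires a central ridge system shape
    ("K1", (0, 1), {"K2": 0}),
    # Depression details require depressions; dimple shape requires dimples
    ("M1", (1,), {"M2": 0, "M3": 0, "M4": 0}),
    ("M2", (0, 1, 2), {"M4": 0}),
    # Surface-texture location/coverage require a surface texture (N1 4-6)
    ("N1", (1, 2, 3, 7), {"N2": 0, "N3": 0}),
    # Foramen location requires a root opening
    ("O5", (0, 1), {"O6": 0}),
]


def build_v05() -> Schema:
    """Construct the denticles_v0.5 schema from the curated tables."""
    traits = []
    for trait_id, (name, weight, states, zero_meaning, factory) in V05_TRAIT_TABLE.items():
        nonzero = [s for s in states if s != 0]
        dist = build_matrix_from_descriptors(trait_id, nonzero, factory())
        traits.append(
            TraitDef(
                trait_id=trait_id,
                group=trait_id[0],
                name=name,
                weight=weight,
                states=tuple(sorted(states.items())),
                zero_meaning=zero_meaning,
                dist=dist,
            )
        )
    rules = tuple(
        NestingRule(c, tuple(ws), tuple(sorted(req.items())))
        for c, ws, req in V05_NESTING_RULES
    )
    return Schema(version="denticles_v0.5", traits=tuple(traits), nesting_rules=rules)


def build_historical_stub(version: str) -> Schema:
    """Structure-only placeholder for a pre-0.5 schema version."""
    return Schema(
        version=version,
        traits=(),
        nesting_rules=(),
        historical=True,
        note="historical, matrices unavailable",
    )
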