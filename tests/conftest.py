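"""Shared fixtures: the bundled schema, a hand-checkable toy schema,
random mini-schemas, and an independent brute-force disparity oracle."""

from __future__ import annotations

import numpy as np
import pytest

from denticode.io import DenticleCode
from denticode.schema import Schema, TraitDef, load_schema


@pytest.fixture(scope="session")
def v05() -> Schema:
    return load_schema("denticles_v0.5")


@pytest.fixture(scope="session")
def toy_schema() -> Schema:
    """Three traits (weights 2, 1, 0.5) with hand-set matrices."""
    return Schema(
        version="toy_v1",
        traits=(
            TraitDef(
                trait_id="A1",
                group="A",
                name="shape",
                weight=2.0,
                states=((1, "one"), (2, "two"), (3, "three")),
                zero_meaning=None,
                dist=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
            ),
            TraitDef(
                trait_id="B1",
                group="B",
                name="edge",
                weight=1.0,
                states=((0, "broken"), (1, "smooth"), (2, "serrated")),
                zero_meaning="broken",
                dist=np.array([[0, 3], [3, 0]], dtype=float),
            ),
            TraitDef(
                trait_id="C1",
                group="C",
                name="texture",
                weight=0.5,
                states=((0, "n/a"), (1, "flat"), (2, "wavy"), (3, "ridged")),
                zero_meaning="not-applicable",
                dist=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
            ),
        ),
        nesting_rules=(),
    )


def build_zero_capable_schema() -> Schema:
    """Every trait zero-capable, so fully uncodable specimens exist."""
    def trait(tid, n_states):
        nz = n_states - 1
        d = np.abs(np.subtract.outer(np.arange(nz), np.arange(nz))).astype(float)
        return TraitDef(
            trait_id=tid,
            group=tid[0],
            name=tid,
            weight=1.0,
            states=tuple((i, f"s{i}") for i in range(n_states)),
            zero_meaning="broken",
            dist=d,
        )

    return Schema(
        version="zc_v1",
        traits=(trait("A1", 4), trait("B1", 3), trait("C1", 5)),
        nesting_rules=(),
    )


@pytest.fixture(scope="session")
def zero_capable_schema() -> Schema:
    return build_zero_capable_schema()


def make_random_schema(rng: np.random.Generator) -> Schema:
    """A random mini-schema: <=6 traits, <=5 states each, no nesting."""
    letters = list("ABCDEFGHIJKLMNO")
    n_traits = int(rng.integers(1, 7))
    traits = []
    for i in range(n_traits):
        tid = f"{letters[i]}1"
        has_zero = bool(rng.integers(0, 2))
        n_nonzero = int(rng.integers(2, 6))
        start = 0 if has_zero else 1
        states = tuple(
            (idx, f"s{idx}") for idx in range(start, start + n_nonzero + (1 if has_zero else 0))
        )
        nz = n_nonzero
        m = np.triu(rng.integers(0, 5, size=(nz, nz)).astype(float), k=1)
        dist = m + m.T
        weight = float(rng.choice([0.5, 1.0, 2.0]))
        traits.append(
            TraitDef(
                trait_id=tid,
                group=tid[0],
                name=tid,
                weight=weight,
                states=states,
                zero_meaning="broken" if has_zero else None,
                dist=dist,
            )
        )
    return Schema(version="rand", traits=tuple(traits))


def make_random_code(
    schema: Schema, rng: np.random.Generator, specimen_id: str, zero_prob: float = 0.25
) -> DenticleCode:
    states = {}
    for t in schema.traits:
        if t.has_zero_state and rng.random() < zero_prob:
            states[t.trait_id] = 0
        else:
            nz = t.nonzero_states
            states[t.trait_id] = int(nz[rng.integers(0, len(nz))])
    return DenticleCode(specimen_id, states)


def oracle_pair(a: DenticleCode, b: DenticleCode, schema: Schema):
    """Independent naive reference for pairwise disparity.

    Plain double loop over traits with explicit matrix indexing; returns
    (raw, denominator, n_comparable) and leaves normalization and the
    undefined decision to the caller.
    """
    raw = 0.0
    denom = 0.0
    count = 0
    for t in schema.traits:
        sa = a.states[t.trait_id]
        sb = b.states[t.trait_id]
        if sa == 0 or sb == 0:
            continue
        first_nonzero = min(t.nonzero_states)
        d = float(t.dist[sa - first_nonzero][sb - first_nonzero])
        raw += t.weight * d
        denom += t.weight * float(np.max(t.dist))
        count += 1
    return raw, denom, count
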