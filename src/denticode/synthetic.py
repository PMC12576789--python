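"""Synthetic denticle codes: valid random specimens, morphotype
clusters, and taphonomically degraded ("broken") copies.

Every generated code satisfies the schema's range and nesting rules by
construction: traits are drawn in schema order (controllers always
precede their dependents in the shipped schemas), and whenever a drawn
controller state triggers a nesting rule the dependent values are forced
rather than sampled.  States are sampled uniformly over the non-zero
states unless a rule forces a value; the character code gives no state
frequencies, so uniform is the neutral choice.

"Fossil mode" zeroes every base (O-group) trait, mirroring the fact
that the subcutaneous base is almost never preserved in sediment-hosted
material.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import DenticleCode, validate_code
from .schema import Schema

__all__ = [
    "GeneratorConfig",
    "generate_code",
    "make_cluster_dataset",
    "degrade_code",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design for a synthetic cluster dataset.

    mutation_rate is the per-trait probability that a cluster member
    deviates from its centroid; breakage_fraction the per-trait
    probability that a zero-capable trait of a degraded specimen is
    zeroed; base_loss forces all O-group traits to 0 (fossil mode).
    """

    seed: int = 0
    n_morphotypes: int = 5
    specimens_per_type: int = 10
    mutation_rate: float = 0.05
    breakage_fraction: float = 0.0
    base_loss: bool = False
    min_centroid_separation: int = 5

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "breakage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _forced_values(schema: Schema, states: dict[str, int]) -> dict[str, int]:
    """Dependent values required by the controller states drawn so far."""
    forced: dict[str, int] = {}
    for r in schema.nesting_rules:
        ctrl = states.get(r.controller)
        if ctrl is None:
            ctrl = forced.get(r.controller)
        if ctrl is not None and ctrl in r.when_states:
            forced.update(dict(r.require))
    return forced


def _fix_b2c2(schema: Schema, states: dict[str, int]) -> None:
    """Enforce the low-before-high edge-texture convention where it
    applies (no directionality on either edge)."""
    needed = all(t in schema for t in ("B1", "C1", "B2", "C2"))
    if (
        needed
        and states.get("B1") == 4
        and states.get("C1") == 4
        and states.get("B2", 0) != 0
        and states.get("C2", 0) != 0
        and states["B2"] > states["C2"]
    ):
        states["B2"], states["C2"] = states["C2"], states["B2"]


def _sample_states(
    schema: Schema,
    rng: np.random.Generator,
    base_loss: bool = False,
) -> dict[str, int]:
    states: dict[str, int] = {}
    for t in schema.traits:
        forced = _forced_values(schema, states)
        if base_loss and t.group == "O" and t.has_zero_state:
            states[t.trait_id] = 0
        elif t.trait_id in forced:
            states[t.trait_id] = forced[t.trait_id]
        else:
            choices = t.nonzero_states
            states[t.trait_id] = int(choices[rng.integers(0, len(choices))])
    _fix_b2c2(schema, states)
    return states


def _repair(
    schema: Schema,
    states: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Restore nesting validity after point mutations.

    Walks traits in schema order; a dependent whose controller now rules
    it out is forced, and a dependent left at a stale forced value whose
    controller no longer applies is resampled from the codable states.
    """
    fixed: dict[str, int] = {}
    for t in schema.traits:
        forced = _forced_values(schema, fixed)
        v = states[t.trait_id]
        if t.trait_id in forced:
            fixed[t.trait_id] = forced[t.trait_id]
        elif v == 0 and t.has_zero_state:
            # a zero no rule forces: resample a codable state so clean
            # cluster members stay fully coded (breakage is applied
            # separately by degrade_code)
            choices = t.nonzero_states
            fixed[t.trait_id] = int(choices[rng.integers(0, len(choices))])
        else:
            fixed[t.trait_id] = v
    _fix_b2c2(schema, fixed)
    return fixed


def generate_code(
    schema: Schema,
    seed: int | np.random.Generator,
    specimen_id: str = "synthetic",
    base_loss: bool = False,
) -> DenticleCode:
    """One valid random specimen code (deterministic given the seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = DenticleCode(specimen_id, _sample_states(schema, rng, base_loss))
    assert not validate_code(code, schema), "generator produced an invalid code"
    return code


def _mutate(
    schema: Schema,
    centroid: dict[str, int],
    rate: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Per-trait point mutations at ``rate``, then nesting repair."""
    states = dict(centroid)
    for t in schema.traits:
        if rng.random() >= rate:
            continue
        current = states[t.trait_id]
        alternatives = [s for s in t.nonzero_states if s != current]
        if alternatives:
            states[t.trait_id] = int(alternatives[rng.integers(0, len(alternatives))])
    return _repair(schema, states, rng)


def make_cluster_dataset(
    schema: Schema,
    cfg: GeneratorConfig,
) -> tuple[list[DenticleCode], list[int]]:
    """Morphotype clusters: distinct centroids plus mutated members.

    Returns ``(codes, labels)`` where ``labels[i]`` is the index of the
    centroid specimen ``codes[i]`` was generated from.  Centroids are
    redrawn until every pair disagrees on at least
    ``cfg.min_centroid_separation`` comparable traits; if
    ``cfg.breakage_fraction`` > 0 it is applied (via
    :func:`degrade_code`) to every second specimen.
    """
    from .morphotypes import hamming_comparable  # local: avoids cycle

    rng = np.random.default_rng(cfg.seed)
    centroids: list[DenticleCode] = []
    attempts = 0
    while len(centroids) < cfg.n_morphotypes:
        attempts += 1
        if attempts > 200 * cfg.n_morphotypes:
            raise ValueError(
                f"cannot place {cfg.n_morphotypes} centroids at separation "
                f">= {cfg.min_centroid_separation} in this schema"
            )
        cand = generate_code(
            schema, rng, f"centroid{len(centroids)}", base_loss=cfg.base_loss
        )
        if all(
            hamming_comparable(cand, c, schema) >= cfg.min_centroid_separation
            for c in centroids
        ):
            centroids.append(cand)

    codes: list[DenticleCode] = []
    labels: list[int] = []
    for k, cen in enumerate(centroids):
        for m in range(cfg.specimens_per_type):
            states = _mutate(schema, cen.states, cfg.mutation_rate, rng)
            if cfg.base_loss:
                for t in schema.traits:
                    if t.group == "O" and t.has_zero_state:
                        states[t.trait_id] = 0
                states = dict(states)
            code = DenticleCode(f"T{k:02d}S{m:02d}", states, {"true_morphotype": str(k)})
            issues = validate_code(code, schema)
            assert not issues, f"cluster generator produced invalid code: {issues[0]}"
            codes.append(code)
            labels.append(k)

    if cfg.breakage_fraction > 0:
        for i in range(0, len(codes), 2):
            codes[i] = degrade_code(
                codes[i], schema, cfg.breakage_fraction, rng
            )
    return codes, labels


def degrade_code(
    code: DenticleCode,
    schema: Schema,
    breakage_fraction: float,
    seed: int | np.random.Generator,
) -> DenticleCode:
    """Simulate taphonomic damage by zeroing zero-capable traits.

    Each trait with a 0 sentinel is independently zeroed with
    probability ``breakage_fraction``; nesting consistency is maintained
    (zeroing a controller drags its dependents to their required
    values), so the result always validates.
    """
    if not 0.0 <= breakage_fraction <= 1.0:
        raise ValueError("breakage_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = dict(code.states)
    for t in schema.traits:
        if t.has_zero_state and rng.random() < breakage_fraction:
            states[t.trait_id] = 0
    # cascade forced values triggered by the new zeros
    fixed: dict[str, int] = {}
    for t in schema.traits:
        forced = _forced_values(schema, fixed)
        if t.trait_id in forced:
            fixed[t.trait_id] = forced[t.trait_id]
        else:
            fixed[t.trait_id] = states[t.trait_id]
    _fix_b2c2(schema, fixed)
    degraded = DenticleCode(code.specimen_id, fixed, dict(code.meta))
    issues = validate_code(degraded, schema)
    assert not issues, f"degrade produced invalid code: {issues[0]}"
    return degraded


def write_dataset(
    codes: Sequence[DenticleCode],
    labels: Sequence[int],
    sheet_path,
    labels_path,
    schema: Schema,
) -> None:
    """Standard coding-sheet CSV plus a (specimen_id, true_morphotype) CSV."""
    from .io import write_coding_sheet

    write_coding_sheet(codes, sheet_path, schema)
    lines = ["specimen_id,true_morphotype\n"]
    for c, lab in zip(codes, labels):
        lines.append(f"{c.specimen_id},{lab}\n")
    from pathlib import Path

    Path(labels_path).write_text("".join(lines), encoding="utf-8")
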