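"""Disparity engine vs an independent brute-force oracle, plus the
missing-data (shared-overlap) semantics."""

from __future__ import annotations

import numpy as np
import pytest

from denticode.disparity import (
    UNDEFINED,
    character_jackknife,
    pair_disparity,
    pairwise_matrix,
    trait_contributions,
)
from denticode.io import DenticleCode
from denticode.synthetic import GeneratorConfig, degrade_code, generate_code, make_cluster_dataset

from conftest import (
    build_zero_capable_schema,
    make_random_code,
    make_random_schema,
    oracle_pair,
)

from hypothesis import given, settings
from hypothesis import strategies as st

_ZC = build_zero_capable_schema()


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    sa=st.tuples(st.integers(0, 3), st.integers(0, 2), st.integers(0, 4)),
    sb=st.tuples(st.integers(0, 3), st.integers(0, 2), st.integers(0, 4)),
)
def test_pair_disparity_symmetric_bounded_and_undefined_iff_no_overlap(sa, sb):
    """For arbitrary state vectors: symmetry, [0,1] bounds, zero identity,
    and UNDEFINED exactly when the codable overlap is empty."""
    tids = ("A1", "B1", "C1")
    a = DenticleCode("a", dict(zip(tids, sa)))
    b = DenticleCode("b", dict(zip(tids, sb)))
    dab = pair_disparity(a, b, _ZC)
    dba = pair_disparity(b, a, _ZC)
    overlap = any(x != 0 and y != 0 for x, y in zip(sa, sb))
    if not overlap:
        assert dab is UNDEFINED and dba is UNDEFINED
    else:
        assert dab == dba
        assert 0.0 <= dab <= 1.0
        if sa == sb:
            assert dab == 0.0


class TestPairDisparity:
    def test_self_disparity_zero(self, v05):
        for seed in range(5):
            c = generate_code(v05, seed)
            assert pair_disparity(c, c, v05) == 0.0

    def test_disjoint_codable_sets_are_undefined(self, zero_capable_schema):
        a = DenticleCode("a", {"A1": 1, "B1": 0, "C1": 0})
        b = DenticleCode("b", {"A1": 0, "B1": 2, "C1": 1})
        assert pair_disparity(a, b, zero_capable_schema) is UNDEFINED

    def test_hand_computed_toy_value(self, toy_schema):
        a = DenticleCode("a", {"A1": 1, "B1": 1, "C1": 2})
        b = DenticleCode("b", {"A1": 2, "B1": 2, "C1": 0})
        # shared traits: A1 (w=2, d(1,2)=1 -> 2), B1 (w=1, d(1,2)=3 -> 3);
        # C1 excluded. raw = 5; denominator = 2*2 + 1*3 = 7.
        assert pair_disparity(a, b, toy_schema, normalized=False) == 5.0
        assert pair_disparity(a, b, toy_schema) == pytest.approx(5.0 / 7.0)

    def test_normalized_upper_bound_attained(self, toy_schema):
        a = DenticleCode("a", {"A1": 1, "B1": 1, "C1": 1})
        b = DenticleCode("b", {"A1": 3, "B1": 2, "C1": 3})
        assert pair_disparity(a, b, toy_schema) == 1.0

    def test_degraded_twin_has_zero_disparity(self, v05):
        for seed in (0, 1, 2):
            c = generate_code(v05, seed)
            broken = degrade_code(c, v05, 0.5, seed + 100)
            d = pair_disparity(c, broken, v05)
            if d is not UNDEFINED:
                assert d == 0.0


class TestOracleEquivalence:
    def test_engine_matches_naive_loop_on_random_schemas(self):
        """Random mini-schemas and codes: exact agreement with the oracle."""
        rng = np.random.default_rng(20240901)
        for trial in range(60):
            schema = make_random_schema(rng)
            codes = [
                make_random_code(schema, rng, f"s{i}") for i in range(int(rng.integers(2, 8)))
            ]
            dm = pairwise_matrix(codes, schema)
            for i in range(len(codes)):
                for j in range(len(codes)):
                    raw, denom, count = oracle_pair(codes[i], codes[j], schema)
                    if i == j:
                        assert dm.D[i, j] == 0.0
                        continue
                    assert dm.comparable_count[i, j] == count
                    if count == 0 or denom == 0.0:
                        assert np.isnan(dm.D[i, j])
                    else:
                        assert dm.D[i, j] == pytest.approx(raw / denom, abs=1e-12)
                        assert 0.0 <= dm.D[i, j] <= 1.0 + 1e-12

    def test_v05_matrix_matches_oracle_on_synthetic_codes(self, v05):
        codes = [generate_code(v05, s, f"sp{s}") for s in range(20)]
        dm = pairwise_matrix(codes, v05)
        assert np.array_equal(dm.D, dm.D.T)
        for i in range(20):
            for j in range(i + 1, 20):
                raw, denom, count = oracle_pair(codes[i], codes[j], v05)
                assert dm.D[i, j] == pytest.approx(raw / denom, abs=1e-12)
                assert dm.shared_weight[i, j] == pytest.approx(
                    sum(
                        t.weight
                        for t in v05.traits
                        if codes[i].states[t.trait_id] != 0
                        and codes[j].states[t.trait_id] != 0
                    )
                )


class TestMatrixSemantics:
    def test_identical_codes_give_all_zero(self, v05):
        c = generate_code(v05, 4)
        codes = [DenticleCode(f"s{i}", dict(c.states)) for i in range(4)]
        dm = pairwise_matrix(codes, v05)
        assert np.all(dm.D == 0.0)

    def test_duplicate_ids_rejected(self, v05):
        c = generate_code(v05, 4)
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_matrix([c, c], v05)

    def test_zeroing_traits_changes_overlap_never_value_validity(self, v05):
        """Missing data shrinks the shared set but never yields NaN except
        for truly empty overlap, and never a negative or >1 value."""
        rng = np.random.default_rng(5)
        codes = [generate_code(v05, s, f"s{s}") for s in range(6)]
        degraded = [
            DenticleCode(f"b{i}", degrade_code(c, v05, 0.6, rng).states)
            for i, c in enumerate(codes)
        ]
        dm = pairwise_matrix(codes + degraded, v05)
        defined = dm.D[~np.isnan(dm.D)]
        assert np.all(defined >= 0.0) and np.all(defined <= 1.0 + 1e-12)
        undef = np.isnan(dm.D)
        assert np.array_equal(undef, dm.comparable_count == 0)

    def test_global_vs_pair_normalization(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(4)]
        per_pair = pairwise_matrix(codes, v05, normalization="pair")
        glob = pairwise_matrix(codes, v05, normalization="global")
        raw = pairwise_matrix(codes, v05, normalization="raw")
        full_denom = sum(t.weight * t.max_distance for t in v05.traits)
        assert np.allclose(glob.D, raw.D / full_denom)
        # complete codes: both normalizations coincide
        assert np.allclose(per_pair.D, glob.D) or np.any(
            per_pair.shared_weight < per_pair.shared_weight.max()
        )

    def test_exports_round_trip(self, v05, tmp_path):
        import pandas as pd

        codes = [generate_code(v05, s, f"s{s}") for s in range(5)]
        dm = pairwise_matrix(codes, v05)
        p = tmp_path / "disp.csv"
        dm.to_csv(p)
        back = pd.read_csv(p, index_col=0)
        assert np.allclose(back.values, dm.D)
        side = pd.read_csv(tmp_path / "disp_shared_weight.csv", index_col=0)
        assert np.allclose(side.values, dm.shared_weight)
        phy = tmp_path / "disp.phy"
        dm.to_phylip(phy)
        lines = phy.read_text().splitlines()
        assert lines[0] == "5"
        assert len(lines) == 6


class TestContributions:
    def test_identical_codes_all_zero_distance(self, v05):
        c = generate_code(v05, 9)
        contrib = trait_contributions(c, c, v05)
        for rec in contrib.values():
            if rec["comparable"]:
                assert rec["distance"] == 0.0

    def test_single_trait_difference_owns_the_whole_raw(self, v05):
        c = generate_code(v05, 21)
        c = c.with_states({"F1": 2})
        d = c.with_states({"F1": 3})
        contrib = trait_contributions(c, d, v05)
        raw = pair_disparity(c, d, v05, normalized=False)
        assert contrib["F1"]["weighted"] == pytest.approx(raw)
        others = [
            r["weighted"] for t, r in contrib.items() if t != "F1" and r["comparable"]
        ]
        assert sum(others) == 0.0

    def test_shares_sum_to_raw_on_toy(self, toy_schema):
        a = DenticleCode("a", {"A1": 1, "B1": 1, "C1": 2})
        b = DenticleCode("b", {"A1": 2, "B1": 2, "C1": 0})
        contrib = trait_contributions(a, b, toy_schema)
        assert contrib["C1"] == {"comparable": False}
        total = sum(r["weighted"] for r in contrib.values() if r["comparable"])
        assert total == pair_disparity(a, b, toy_schema, normalized=False)


class TestJackknife:
    def test_dropping_an_agreed_trait_leaves_d_unchanged_after_renormalization(
        self, toy_schema
    ):
        a = DenticleCode("a", {"A1": 1, "B1": 1, "C1": 1})
        b = DenticleCode("b", {"A1": 2, "B1": 1, "C1": 3})
        full = pairwise_matrix([a, b], toy_schema)
        # B1 agrees: removing it subtracts equal amounts from raw and from
        # the attainable denominator only if its distance is 0, so D shifts
        # by the denominator change; verify against direct recomputation
        dropped = character_jackknife([a, b], toy_schema, "B1")
        direct = pairwise_matrix([a, b], toy_schema.drop_traits(["B1"]))
        assert np.allclose(dropped.D, direct.D, equal_nan=True)
        raw_full = pair_disparity(a, b, toy_schema, normalized=False)
        raw_drop = 2.0 * 1.0 + 0.5 * 2.0  # A1 and C1 terms only
        assert raw_full == raw_drop + 0.0  # agreed trait contributed nothing
        assert dropped.D[0, 1] == pytest.approx(raw_drop / (2 * 2 + 0.5 * 2))

    def test_dropping_group_o_on_fossil_codes_is_exact_noop(self, v05):
        cfg = GeneratorConfig(seed=3, n_morphotypes=3, specimens_per_type=3,
                              base_loss=True)
        codes, _ = make_cluster_dataset(v05, cfg)
        full = pairwise_matrix(codes, v05)
        jack = character_jackknife(codes, v05, "O")
        assert np.array_equal(full.D, jack.D)

    def test_dropping_the_only_differing_trait_zeroes_d(self, v05):
        c = generate_code(v05, 21).with_states({"F1": 2})
        d = c.with_states({"F1": 3})
        d = DenticleCode("other", d.states)
        jack = character_jackknife([c, d], v05, "F1")
        assert jack.D[0, 1] == 0.0

    def test_unknown_drop_target_raises(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(2)]
        with pytest.raises(KeyError):
            character_jackknife(codes, v05, "Q")


def test_within_morphotype_disparity_below_between_even_when_broken(v05):
    """Grouping signal survives heavy breakage: mean within-cluster
    disparity stays below mean between-cluster disparity after zeroing
    ~40% of zero-capable traits in half the specimens."""
    cfg = GeneratorConfig(seed=11, n_morphotypes=5, specimens_per_type=10,
                          mutation_rate=0.05, breakage_fraction=0.4)
    codes, labels = make_cluster_dataset(v05, cfg)
    dm = pairwise_matrix(codes, v05)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(codes), dtype=bool)
    within = np.nanmean(dm.D[same & off])
    between = np.nanmean(dm.D[~same])
    assert within < between
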