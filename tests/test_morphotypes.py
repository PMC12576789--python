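"""Morphotype assignment, catalog matching, and catalog bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from denticode.disparity import UNDEFINED
from denticode.io import DenticleCode
from denticode.morphotypes import (
    assign_morphotypes,
    count_catalog_types,
    gross_type_vocabulary,
    hamming_comparable,
    match_to_catalog,
    read_catalog,
    write_catalog,
    Morphotype,
)
from denticode.synthetic import degrade_code, generate_code


class TestAssign:
    def test_identical_codes_form_one_morphotype(self, v05):
        c = generate_code(v05, 8)
        codes = [DenticleCode("a", dict(c.states)), DenticleCode("b", dict(c.states))]
        morphs = assign_morphotypes(codes, v05, merge_tolerance=0)
        assert len(morphs) == 1
        assert morphs[0].members == ("a", "b")
        assert morphs[0].canonical == c.states

    def test_three_trait_difference_splits_at_tolerance_two(self, v05):
        a = generate_code(v05, 15).with_states({"F1": 2})
        b = a.with_states({"D1": 1 if a.states["D1"] != 1 else 2,
                           "B3": 3 - a.states["B3"],
                           "C3": 3 - a.states["C3"]})
        b = DenticleCode("b", b.states)
        assert hamming_comparable(a, b, v05) == 3
        assert len(assign_morphotypes([a, b], v05, merge_tolerance=2)) == 2
        assert len(assign_morphotypes([a, b], v05, merge_tolerance=0)) == 2

    def test_two_trait_difference_merges_at_tolerance_two(self, v05):
        a = generate_code(v05, 15).with_states({"F1": 2})
        b = a.with_states({"B3": 3 - a.states["B3"], "C3": 3 - a.states["C3"]})
        b = DenticleCode("b", b.states)
        assert len(assign_morphotypes([a, b], v05, merge_tolerance=2)) == 1
        assert len(assign_morphotypes([a, b], v05, merge_tolerance=1)) == 2

    def test_tolerance_zero_is_an_equivalence_relation(self, v05):
        """Exact grouping is reflexive, symmetric, transitive: every member
        pair within a morphotype has identical full state vectors."""
        rng = np.random.default_rng(2)
        base = [generate_code(v05, s, f"s{s}") for s in range(6)]
        codes = []
        for i, c in enumerate(base):
            for rep in range(int(rng.integers(1, 4))):
                codes.append(DenticleCode(f"s{i}r{rep}", dict(c.states)))
        morphs = assign_morphotypes(codes, v05, merge_tolerance=0)
        by_id = {c.specimen_id: c for c in codes}
        seen = set()
        for m in morphs:
            vectors = {tuple(sorted(by_id[s].states.items())) for s in m.members}
            assert len(vectors) == 1
            seen.update(m.members)
        assert seen == {c.specimen_id for c in codes}  # a true partition

    def test_zeros_equal_only_zeros_at_tolerance_zero(self, v05):
        c = generate_code(v05, 30)
        broken = degrade_code(c, v05, 1.0, 0)
        assert broken.states != c.states
        morphs = assign_morphotypes([c, broken], v05, merge_tolerance=0)
        assert len(morphs) == 2

    def test_deterministic_naming_and_order(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(5)]
        m1 = assign_morphotypes(codes, v05, merge_tolerance=0)
        m2 = assign_morphotypes(list(reversed(codes)), v05, merge_tolerance=0)
        assert [m.canonical for m in m1] == [m.canonical for m in m2]
        assert [m.name for m in m1] == [f"MT{i:03d}" for i in range(1, 6)]


class TestCatalogMatch:
    def test_catalog_code_matches_itself_first(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(4)]
        catalog = assign_morphotypes(codes, v05)
        query = DenticleCode("q", dict(catalog[2].canonical))
        ranked = match_to_catalog(query, catalog, v05)
        assert ranked[0] == (catalog[2].name, 0.0)

    def test_degraded_copy_recovers_its_parent(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(6)]
        catalog = assign_morphotypes(codes, v05)
        rng = np.random.default_rng(77)
        for m in catalog:
            query = degrade_code(m.canonical_code(), v05, 0.3, rng)
            ranked = match_to_catalog(query, catalog, v05)
            assert ranked[0][0] == m.name
            assert ranked[0][1] == 0.0

    def test_fully_uncodable_query_is_all_undefined(self, zero_capable_schema):
        catalog = [
            Morphotype("m1", {"A1": 1, "B1": 1, "C1": 2}, ("m1",)),
            Morphotype("m2", {"A1": 2, "B1": 2, "C1": 4}, ("m2",)),
        ]
        query = DenticleCode("q", {"A1": 0, "B1": 0, "C1": 0})
        ranked = match_to_catalog(query, catalog, zero_capable_schema)
        assert all(d is UNDEFINED for _, d in ranked)

    def test_ranking_invariant_to_catalog_order(self, v05):
        codes = [generate_code(v05, s, f"s{s}") for s in range(5)]
        catalog = assign_morphotypes(codes, v05)
        query = generate_code(v05, 99, "q")
        r1 = match_to_catalog(query, catalog, v05)
        r2 = match_to_catalog(query, list(reversed(catalog)), v05)
        assert r1 == r2

    def test_empty_catalog_rejected(self, v05):
        with pytest.raises(ValueError):
            match_to_catalog(generate_code(v05, 1), [], v05)


class TestCatalogFiles:
    def test_catalog_round_trip_with_gross_types(self, v05, tmp_path):
        codes = [generate_code(v05, s, f"s{s}") for s in range(3)]
        catalog = assign_morphotypes(codes, v05)
        vocab = gross_type_vocabulary()
        for m, g in zip(catalog, vocab):
            m.gross_type = g
        p = tmp_path / "catalog.csv"
        write_catalog(catalog, p, v05)
        back = read_catalog(p, v05)
        assert [m.name for m in back] == [m.name for m in catalog]
        assert [m.gross_type for m in back] == [m.gross_type for m in catalog]
        assert [m.canonical for m in back] == [m.canonical for m in catalog]

    def test_counting_distinguishes_catch_alls(self, v05, tmp_path):
        """A synthetic catalog with two catch-all entries: the counter
        reports named and catch-all unique codes separately."""
        codes = [generate_code(v05, s, f"s{s}") for s in range(8)]
        catalog = assign_morphotypes(codes, v05)
        catalog[0].name = "generic linear"
        catalog[1].name = "generic geometric"
        counts = count_catalog_types(catalog, v05)
        assert counts == {"named": 6, "catch_all": 2, "total": 8}

    def test_gross_type_vocabulary_has_18_labels(self):
        vocab = gross_type_vocabulary()
        assert len(vocab) == 18
        assert "Tridents" in vocab and "Other Meandering" in vocab
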