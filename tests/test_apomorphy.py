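"""Character-matrix construction and apomorphy-call rules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lvr.apomorphy import (
    ApomorphyCall,
    CharacterMatrix,
    build_character_matrix,
    detect_autapomorphies,
    detect_synapomorphies,
)
from lvr.datasets import load_lvr_l_subregion_matrix, load_lvr_length_matrix

from .oracles import synapomorphy_oracle


def _matrix(cells: dict[str, dict[str, set[int]]], outgroup: str) -> CharacterMatrix:
    groups = tuple(cells)
    characters = tuple(next(iter(cells.values())))
    values = {
        (g, c): frozenset(cells[g][c]) for g in groups for c in characters
    }
    return CharacterMatrix(groups, outgroup, characters, values)


def _random_matrix(rng) -> CharacterMatrix:
    n_groups = int(rng.integers(3, 6))
    n_chars = int(rng.integers(1, 5))
    groups = [f"g{i}" for i in range(n_groups)]
    cells = {
        g: {
            f"c{j}": set(
                rng.integers(0, 5, size=int(rng.integers(1, 3))).tolist()
            )
            for j in range(n_chars)
        }
        for g in groups
    }
    return _matrix(cells, "g0")


class TestCharacterMatrix:
    def test_invariants(self):
        with pytest.raises(ValueError, match="outgroup"):
            _matrix({"a": {"c": {1}}, "b": {"c": {2}}}, "z")
        with pytest.raises(ValueError, match="empty"):
            CharacterMatrix(("a", "b"), "a", ("c",), {("a", "c"): frozenset({1})})

    def test_build_from_table_singletons(self):
        table = pd.DataFrame(
            {
                "sequence_id": ["s1", "s2"],
                "taxon_group": ["out", "in1"],
                "X": [6, 3],
            }
        )
        m = build_character_matrix(table, "out")
        assert m.cell("out", "X") == frozenset({6})
        assert m.cell("in1", "X") == frozenset({3})

    def test_build_range_cell_rendered(self):
        table = pd.DataFrame(
            {
                "sequence_id": ["s1", "s2", "s3"],
                "taxon_group": ["out", "aca", "aca"],
                "X": [6, 3, 4],
            }
        )
        m = build_character_matrix(table, "out")
        assert m.cell("aca", "X") == frozenset({3, 4})
        assert m.to_frame().loc["aca", "X"] == "3-4"

    def test_tsv_round_trip(self, tmp_path):
        m = load_lvr_length_matrix()
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = CharacterMatrix.from_tsv(p)
        assert back.groups == m.groups
        assert back.outgroup == m.outgroup
        assert back.values == m.values


class TestAutapomorphies:
    def test_published_subregion_matrix_counts(self):
        calls = detect_autapomorphies(load_lvr_l_subregion_matrix())
        per_group: dict[str, list[str]] = {}
        for c in calls:
            (g,) = c.bearer
            per_group.setdefault(g, []).append(c.character)
        assert sorted(per_group["Cantacaderinae"]) == ["LB", "LC", "LD", "LE"]
        assert per_group["Acalyptaini"] == ["LB"]
        assert per_group["Litadeini"] == ["LB"]
        assert "Outgroup" not in per_group

    def test_published_lvr_matrix_x_character(self):
        calls = detect_autapomorphies(load_lvr_length_matrix())
        x_calls = [c for c in calls if c.character == "X"]
        assert len(x_calls) == 1
        assert x_calls[0].bearer == frozenset({"Acalyptaini"})
        assert x_calls[0].shared_value == frozenset({3, 4})

    def test_identical_cells_no_calls(self):
        m = _matrix(
            {g: {"c1": {5}, "c2": {7}} for g in ("out", "a", "b")}, "out"
        )
        assert detect_autapomorphies(m) == []

    def test_range_cells_use_set_disjointness(self):
        m = _matrix(
            {"out": {"x": {6}}, "a": {"x": {3, 4}}, "b": {"x": {4, 5}}}, "out"
        )
        assert detect_autapomorphies(m) == []  # {3,4} meets {4,5}

    def test_duplicate_group_destroys_autapomorphy(self):
        base = {"out": {"x": {6}}, "a": {"x": {3}}, "b": {"x": {5}}}
        assert len(detect_autapomorphies(_matrix(base, "out"))) == 2
        base["a2"] = {"x": {3}}
        calls = detect_autapomorphies(_matrix(base, "out"))
        assert {min(c.bearer) for c in calls} == {"b"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            m = _random_matrix(rng)
            perm = list(rng.permutation(m.groups))
            perm_m = CharacterMatrix(
                tuple(perm), m.outgroup, m.characters, dict(m.values)
            )
            a = {(c.character, frozenset(c.bearer)) for c in detect_autapomorphies(m)}
            b = {
                (c.character, frozenset(c.bearer))
                for c in detect_autapomorphies(perm_m)
            }
            assert a == b


class TestSynapomorphies:
    def test_published_subregion_matrix_calls(self):
        calls = detect_synapomorphies(load_lvr_l_subregion_matrix())
        by_char = {c.character: c for c in calls}
        tribes = frozenset({"Acalyptaini", "Litadeini", "Tingini"})
        assert by_char["LA"].bearer == tribes
        assert by_char["LA"].shared_value == frozenset({19})
        assert by_char["LC"].bearer == tribes
        assert by_char["LC"].shared_value == frozenset({8})
        assert by_char["LD"].bearer == tribes
        assert by_char["LD"].shared_value == frozenset({10})
        assert by_char["LE"].bearer == frozenset({"Acalyptaini", "Litadeini"})
        assert by_char["LE"].shared_value == frozenset({16})
        assert set(by_char) == {"LA", "LC", "LD", "LE"}

    def test_shared_with_outgroup_not_called(self):
        m = _matrix(
            {"out": {"c": {5}}, "a": {"c": {5}}, "b": {"c": {5}}}, "out"
        )
        assert detect_synapomorphies(m) == []

    def test_range_cells_warn_and_cannot_bear(self):
        m = _matrix(
            {"out": {"c": {1}}, "a": {"c": {5, 6}}, "b": {"c": {5}}, "d": {"c": {5}}},
            "out",
        )
        with pytest.warns(UserWarning, match="range-valued"):
            calls = detect_synapomorphies(m)
        # value 5 occurs in the excluded range cell of 'a', so no call
        assert calls == []

    def test_clade_restriction(self):
        m = _matrix(
            {"out": {"c": {1}}, "a": {"c": {5}}, "b": {"c": {5}}, "d": {"c": {2}}},
            "out",
        )
        allowed = [frozenset({"a", "d"})]
        assert detect_synapomorphies(m, clades=allowed) == []
        allowed = [frozenset({"a", "b"})]
        (call,) = detect_synapomorphies(m, clades=allowed)
        assert call.bearer == frozenset({"a", "b"})

    def test_matches_exhaustive_subset_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            m = _random_matrix(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                calls = detect_synapomorphies(m)
            expect = synapomorphy_oracle(m)
            got = {
                c.character: (set(c.bearer), next(iter(c.shared_value)))
                for c in calls
            }
            assert got == {ch: (set(s), v) for ch, (s, v) in expect.items()}

    def test_never_both_call_types_for_same_group(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            m = _random_matrix(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                autos = detect_autapomorphies(m)
                syns = detect_synapomorphies(m)
            auto_pairs = {(c.character, next(iter(c.bearer))) for c in autos}
            syn_pairs = {(c.character, g) for c in syns for g in c.bearer}
            assert not auto_pairs & syn_pairs


class TestApomorphyCall:
    def test_call_invariants(self):
        with pytest.raises(ValueError):
            ApomorphyCall("c", frozenset({"a", "b"}), "autapomorphy", frozenset({1}))
        with pytest.raises(ValueError):
            ApomorphyCall("c", frozenset({"a"}), "synapomorphy", frozenset({1}))
        with pytest.raises(ValueError):
            ApomorphyCall("c", frozenset({"a"}), "plesiomorphy", frozenset({1}))
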