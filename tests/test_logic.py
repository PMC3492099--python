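"""Cube algebra and two-level minimization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    oracle_cube_minterms,
    oracle_min_cover_size,
    oracle_primes,
    random_truth_function,
)
from sitelogic.logic import (
    Cover,
    Cube,
    ExactLimitError,
    HeuristicLimitError,
    TruthFunction,
    covers_equivalent,
    cube_covers,
    espresso_minimize,
    merge_adjacent,
    prime_implicants,
    qm_minimize,
)


class TestCubeCovers:
    @pytest.mark.parametrize(
        "cube,pattern,expected",
        [
            ("-0-0", "0000", True),
            ("-0-0", "0001", False),
            ("----", "1010", True),
            ("1-1-", [1, 0, 1, 1], True),
            ("1-1-", [0, 0, 1, 1], False),
        ],
    )
    def test_fixed_literal_agreement(self, cube, pattern, expected):
        assert cube_covers(Cube(cube), pattern) is expected

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            cube_covers(Cube("01"), "011")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            Cube("01x")


class TestMergeAdjacent:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("111", "011", "-11"),  # ĀBC + ABC = BC
            ("111", "100", None),  # two differing fixed positions
            ("-11", "-01", "--1"),
            ("0-0", "0-1", "0--"),
            ("0-0", "001", None),  # don't-care patterns disagree
        ],
    )
    def test_single_position_merges(self, a, b, expected):
        got = merge_adjacent(Cube(a), Cube(b))
        assert (got.literals if got else None) == expected

    @given(
        st.integers(1, 5).flatmap(
            lambda n: st.tuples(
                st.text("01-", min_size=n, max_size=n),
                st.text("01-", min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_merge_covers_exactly_the_union(self, pair):
        a, b = pair
        merged = merge_adjacent(Cube(a), Cube(b))
        if merged is not None:
            assert set(oracle_cube_minterms(merged.literals)) == set(
                oracle_cube_minterms(a)
            ) | set(oracle_cube_minterms(b))


class TestPrimeImplicants:
    def test_worked_table_primes(self, table_function):
        primes = {c.literals for c in prime_implicants(table_function)}
        assert {"-0-0", "--1-"} <= primes

    def test_tautology_collapses_to_all_dash(self):
        f = TruthFunction(3, frozenset(range(8)), frozenset())
        assert [c.literals for c in prime_implicants(f)] == ["---"]

    def test_empty_on_set_yields_no_primes(self):
        f = TruthFunction(3, frozenset(), frozenset({0, 1}))
        assert prime_implicants(f) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        f = random_truth_function(rng, 5)
        if not f.on_set:
            pytest.skip("degenerate draw")
        got = {c.literals for c in prime_implicants(f)}
        assert got == oracle_primes(f)


class TestQmMinimize:
    def test_worked_table_reduces_to_two_rules(self, table_function):
        cover = qm_minimize(table_function)
        assert sorted(c.literals for c in cover) == ["--1-", "-0-0"]

    def test_absorption_axiom_single_cube(self):
        f = TruthFunction(
            3, frozenset({3, 7}), frozenset(set(range(8)) - {3, 7})
        )
        assert [c.literals for c in qm_minimize(f)] == ["-11"]

    def test_single_minterm_no_dontcares(self):
        f = TruthFunction(3, frozenset({5}), frozenset(set(range(8)) - {5}))
        assert [c.literals for c in qm_minimize(f)] == ["101"]

    def test_empty_on_set(self):
        f = TruthFunction(3, frozenset(), frozenset({1}))
        assert len(qm_minimize(f)) == 0

    def test_width_limit_refused(self):
        f = TruthFunction(17, frozenset({0}), frozenset({1}))
        with pytest.raises(ExactLimitError, match="espresso"):
            qm_minimize(f)

    def test_deterministic_output(self):
        rng = np.random.default_rng(3)
        f = random_truth_function(rng, 6)
        a = [c.literals for c in qm_minimize(f)]
        b = [c.literals for c in qm_minimize(f)]
        assert a == b


class TestEspressoMinimize:
    def test_worked_table_two_cube_equivalent(self, table_function):
        cover = espresso_minimize(table_function)
        assert len(cover) == 2
        assert covers_equivalent(cover, table_function)

    def test_fixed_point_on_minimal_input(self):
        f = TruthFunction(
            3, frozenset({3, 7}), frozenset(set(range(8)) - {3, 7})
        )
        assert len(espresso_minimize(f)) == 1

    def test_width_limit_refused(self):
        f = TruthFunction(23, frozenset({0}), frozenset({1}))
        with pytest.raises(HeuristicLimitError):
            espresso_minimize(f)

    @pytest.mark.parametrize("seed", range(15))
    def test_never_beats_exact_minimizer(self, seed):
        rng = np.random.default_rng(100 + seed)
        f = random_truth_function(rng, 8)
        if not f.on_set:
            pytest.skip("degenerate draw")
        e = espresso_minimize(f)
        q = qm_minimize(f)
        assert covers_equivalent(e, f)
        assert len(e) >= len(q)

    def test_deterministic_output(self):
        rng = np.random.default_rng(7)
        f = random_truth_function(rng, 7)
        a = [c.literals for c in espresso_minimize(f)]
        b = [c.literals for c in espresso_minimize(f)]
        assert a == b


class TestCoverSoundnessCompleteness:
    """A produced cover must hit every on-set and no off-set minterm."""

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("minimize", [qm_minimize, espresso_minimize])
    def test_exhaustive_on_off_check(self, seed, minimize):
        rng = np.random.default_rng(200 + seed)
        f = random_truth_function(rng, 6)
        cover = minimize(f)
        for m in f.on_set:
            assert cover.covers_minterm(m)
        for m in f.off_set:
            assert not cover.covers_minterm(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_cover_size(self, seed):
        """Re-minimizing the function a minimal cover realizes keeps size."""
        rng = np.random.default_rng(300 + seed)
        f = random_truth_function(rng, 6)
        if not f.on_set:
            pytest.skip("degenerate draw")
        cover = qm_minimize(f)
        realized = cover.minterms()
        f2 = TruthFunction(
            f.n_vars, realized, frozenset(range(64)) - realized
        )
        assert len(qm_minimize(f2)) == len(cover)


class TestCoversEquivalent:
    def test_worked_table_cover_is_equivalent(self, table_function):
        cover = Cover((Cube("-0-0"), Cube("--1-")), 4)
        assert covers_equivalent(cover, table_function)

    def test_empty_cover_vs_nonempty_on_set(self, table_function):
        assert not covers_equivalent(Cover((), 4), table_function)

    def test_off_set_violation_detected(self, table_function):
        cover = Cover((Cube("----"),), 4)
        assert not covers_equivalent(cover, table_function)

    def test_width_mismatch_rejected(self, table_function):
        with pytest.raises(ValueError):
            covers_equivalent(Cover((), 5), table_function)


class TestTruthFunction:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            TruthFunction(2, frozenset({1}), frozenset({1}))

    def test_from_patterns_builds_on_off(self):
        f = TruthFunction.from_patterns(
            [[0, 0], [1, 1]], [1, 0], n_vars=2
        )
        assert f.on_set == {0} and f.off_set == {3}
        assert f.dont_cares() == {1, 2}

    def test_from_patterns_rejects_contradictions(self):
        with pytest.raises(ValueError, match="contradictory"):
            TruthFunction.from_patterns([[1, 1], [1, 1]], [1, 0], n_vars=2)
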