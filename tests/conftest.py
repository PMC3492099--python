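"""Shared fixtures and independent brute-force oracles.

The oracles enumerate cubes and covers directly (all 3^n product terms,
iterative-deepening exact cover) without touching the package's minimizer
internals, so they can vouch for prime-implicant sets and minimum cover
sizes on small functions.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from sitelogic.encoding import EncodedDataset
from sitelogic.logic import TruthFunction


# --- the worked 4-variable function (inputs A,B,C,D; rows 1..16 = 0..15) ----
TABLE_ON = frozenset({0, 2, 3, 8, 10, 11})
TABLE_DC = frozenset({6, 7, 14, 15})
TABLE_OFF = frozenset(range(16)) - TABLE_ON - TABLE_DC


@pytest.fixture
def table_function() -> TruthFunction:
    return TruthFunction(n_vars=4, on_set=TABLE_ON, off_set=TABLE_OFF)


@pytest.fixture
def table_positive_dataset() -> EncodedDataset:
    """The six positive rows of the worked table as a labeled bit matrix."""
    rows = [format(m, "04b") for m in sorted(TABLE_ON)]
    return EncodedDataset(
        patterns=np.array([[int(c) for c in r] for r in rows]),
        labels=np.ones(len(rows), dtype=int),
        meanings=[],
        provenance=[f"pattern_{m + 1}" for m in sorted(TABLE_ON)],
    )


def random_truth_function(
    rng: np.random.Generator, n: int, p_on: float = 0.35, p_off: float = 0.35
) -> TruthFunction:
    r = rng.random(1 << n)
    on = frozenset(np.where(r < p_on)[0].tolist())
    off = frozenset(np.where((r >= p_on) & (r < p_on + p_off))[0].tolist())
    return TruthFunction(n, on, off)


# --- independent oracles -----------------------------------------------------


def oracle_cube_minterms(lits: str) -> list[int]:
    """Minterms covered by a cube string, by direct enumeration."""
    out = [0]
    for ch in lits:
        if ch == "-":
            out = [2 * m for m in out] + [2 * m + 1 for m in out]
        else:
            out = [2 * m + int(ch) for m in out]
    return sorted(out)


def oracle_primes(f: TruthFunction) -> set[str]:
    """All prime implicants by enumerating every cube over {0,1,-}."""
    care = f.on_set | f.dont_cares()
    valid = set()
    for lits in product("01-", repeat=f.n_vars):
        s = "".join(lits)
        ms = oracle_cube_minterms(s)
        if all(m in care for m in ms) and any(m in f.on_set for m in ms):
            valid.add(s)

    def contains(a: str, b: str) -> bool:
        return all(ca == "-" or ca == cb for ca, cb in zip(a, b))

    return {
        s
        for s in valid
        if not any(o != s and contains(o, s) for o in valid)
    }


def oracle_min_cover_size(f: TruthFunction) -> int:
    """Exact minimum cover cardinality by iterative-deepening search."""
    primes = sorted(oracle_primes(f))
    cover_sets = [frozenset(oracle_cube_minterms(p)) & f.on_set for p in primes]
    on = frozenset(f.on_set)

    def reachable(uncovered: frozenset, depth: int) -> bool:
        if not uncovered:
            return True
        if depth == 0:
            return False
        m = min(uncovered)
        for cs in cover_sets:
            if m in cs and reachable(uncovered - cs, depth - 1):
                return True
        return False

    for k in range(1, len(primes) + 1):
        if reachable(on, k):
            return k
    raise AssertionError("on-set not coverable by its own primes")
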