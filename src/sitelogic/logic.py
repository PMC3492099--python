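"""Two-level logic minimization of partially specified boolean functions.

A boolean function over ``n`` variables is given as a partition of the
:math:`2^n` minterms into an on-set (output 1), an off-set (output 0) and a
don't-care set (output unspecified, written ``-``).  Minimization rewrites the
on-set as a small sum-of-products cover: a list of cubes (product terms over
``{0,1,-}``) that together contain every on-set minterm and avoid every
off-set minterm.  Don't-care minterms may be absorbed by cubes whenever that
shortens the cover.

Two minimizers are provided:

* :func:`qm_minimize` — exact Quine-McCluskey: enumerate all prime
  implicants, extract essential primes, and solve the remaining set-cover
  problem exactly by branch and bound.  Exponential in ``n``; guarded by
  ``exact_limit``.
* :func:`espresso_minimize` — a deterministic EXPAND / IRREDUNDANT / REDUCE
  iteration in the style of the ESPRESSO heuristic.  Returns a valid cover
  with no global-minimality guarantee, but scales to the widths used after
  feature selection (the classic espresso-family tools cap at 22 inputs,
  mirrored by ``heuristic_limit``).

Minterm index convention: the leftmost variable of a cube string is the most
significant bit, so cube ``"-0-0"`` over variables A,B,C,D fixes B=0, D=0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Cube",
    "TruthFunction",
    "Cover",
    "cube_covers",
    "merge_adjacent",
    "prime_implicants",
    "qm_minimize",
    "espresso_minimize",
    "covers_equivalent",
    "ExactLimitError",
    "HeuristicLimitError",
]

DEFAULT_EXACT_LIMIT = 16
DEFAULT_HEURISTIC_LIMIT = 22


class ExactLimitError(ValueError):
    """Exact minimization refused: too many variables; use the heuristic."""


class HeuristicLimitError(ValueError):
    """Heuristic minimization refused: width exceeds the supported limit."""


@dataclass(frozen=True, order=True)
class Cube:
    """A product term: one character in ``{0,1,-}`` per input variable.

    A cube covers a fully specified pattern iff every non-``-`` literal
    equals the corresponding bit.  ``"-"`` marks a variable as irrelevant.
    """

    literals: str

    def __post_init__(self) -> None:
        bad = set(self.literals) - {"0", "1", "-"}
        if bad:
            raise ValueError(f"invalid cube characters: {sorted(bad)!r}")

    @property
    def width(self) -> int:
        return len(self.literals)

    @property
    def n_fixed(self) -> int:
        return sum(c != "-" for c in self.literals)

    def value_mask(self) -> tuple[int, int]:
        """Return ``(value, dc_mask)`` ints; leftmost literal is the MSB."""
        value = 0
        mask = 0
        for ch in self.literals:
            value <<= 1
            mask <<= 1
            if ch == "1":
                value |= 1
            elif ch == "-":
                mask |= 1
        return value, mask

    @classmethod
    def from_value_mask(cls, value: int, mask: int, width: int) -> "Cube":
        chars = []
        for i in range(width - 1, -1, -1):
            bit = 1 << i
            if mask & bit:
                chars.append("-")
            else:
                chars.append("1" if value & bit else "0")
        return cls("".join(chars))

    def covers_minterm(self, minterm: int) -> bool:
        value, mask = self.value_mask()
        return (minterm | mask) == (value | mask)

    def minterms(self) -> list[int]:
        """All minterm indices this cube covers (2**k for k don't-cares)."""
        value, mask = self.value_mask()
        free = [i for i in range(self.width) if mask & (1 << i)]
        out = []
        for bits in range(1 << len(free)):
            m = value
            for j, pos in enumerate(free):
                if bits & (1 << j):
                    m |= 1 << pos
            out.append(m)
        return sorted(out)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.literals


@dataclass(frozen=True)
class TruthFunction:
    """On/off/don't-care partition of the minterms of ``n_vars`` inputs.

    ``dc_set=None`` means the don't-care set is implicitly the complement of
    ``on_set | off_set`` — the usual situation here, where only the training
    patterns have known outputs and the astronomically many unseen patterns
    are left unspecified.
    """

    n_vars: int
    on_set: frozenset[int] = frozenset()
    off_set: frozenset[int] = frozenset()
    dc_set: Optional[frozenset[int]] = None

    def __post_init__(self) -> None:
        if self.n_vars <= 0:
            raise ValueError("n_vars must be positive")
        object.__setattr__(self, "on_set", frozenset(self.on_set))
        object.__setattr__(self, "off_set", frozenset(self.off_set))
        if self.dc_set is not None:
            object.__setattr__(self, "dc_set", frozenset(self.dc_set))
        total = 1 << self.n_vars
        sets = [self.on_set, self.off_set] + (
            [self.dc_set] if self.dc_set is not None else []
        )
        for s in sets:
            if s and (min(s) < 0 or max(s) >= total):
                raise ValueError("minterm index out of range")
        if self.on_set & self.off_set:
            raise ValueError("on_set and off_set overlap")
        if self.dc_set is not None and (
            self.dc_set & self.on_set or self.dc_set & self.off_set
        ):
            raise ValueError("dc_set overlaps on_set/off_set")

    def dont_cares(self) -> frozenset[int]:
        """The explicit don't-care set (materializes the complement)."""
        if self.dc_set is not None:
            return self.dc_set
        total = 1 << self.n_vars
        return frozenset(range(total)) - self.on_set - self.off_set

    @classmethod
    def from_patterns(
        cls,
        patterns: Iterable[Sequence[int]],
        labels: Iterable[int],
        n_vars: int,
    ) -> "TruthFunction":
        """Build a function from labeled bit patterns; the rest is don't-care."""
        on: set[int] = set()
        off: set[int] = set()
        for bits, y in zip(patterns, labels):
            if len(bits) != n_vars:
                raise ValueError("pattern width != n_vars")
            idx = 0
            for b in bits:
                idx = (idx << 1) | int(b)
            (on if y else off).add(idx)
        clash = on & off
        if clash:
            raise ValueError(f"contradictory patterns at minterms {sorted(clash)}")
        return cls(n_vars=n_vars, on_set=frozenset(on), off_set=frozenset(off))


@dataclass(frozen=True)
class Cover:
    """A sum-of-products: the OR of its cubes realizes the on-set."""

    cubes: tuple[Cube, ...]
    n_vars: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cubes", tuple(self.cubes))
        for c in self.cubes:
            if c.width != self.n_vars:
                raise ValueError("cube width mismatch in cover")

    def __len__(self) -> int:
        return len(self.cubes)

    def __iter__(self):
        return iter(self.cubes)

    def covers_minterm(self, minterm: int) -> bool:
        return any(c.covers_minterm(minterm) for c in self.cubes)

    def minterms(self) -> frozenset[int]:
        out: set[int] = set()
        for c in self.cubes:
            out.update(c.minterms())
        return frozenset(out)


def cube_covers(cube: Cube, pattern: Sequence[int] | str) -> bool:
    """True iff ``pattern`` agrees with every fixed literal of ``cube``."""
    if len(pattern) != cube.width:
        raise ValueError(
            f"width mismatch: cube {cube.width}, pattern {len(pattern)}"
        )
    for lit, bit in zip(cube.literals, pattern):
        if lit == "-":
            continue
        if int(bit) != int(lit):
            return False
    return True


def merge_adjacent(a: Cube, b: Cube) -> Optional[Cube]:
    """Merge two cubes differing in exactly one fixed position.

    Implements the absorption ``X·A + X·Ā = X``: if the cubes agree on their
    don't-care positions and on all but one fixed literal, the differing
    literal becomes ``-``.  Returns ``None`` when no such merge exists.
    """
    if a.width != b.width:
        raise ValueError("width mismatch")
    av, am = a.value_mask()
    bv, bm = b.value_mask()
    if am != bm:
        return None
    diff = (av ^ bv) & ~am
    if diff == 0 or diff & (diff - 1):
        return None  # zero or more than one differing fixed bit
    return Cube.from_value_mask(av & ~diff, am | diff, a.width)


def _prime_implicants_vm(
    care: frozenset[int], n_vars: int
) -> list[tuple[int, int]]:
    """All maximal cubes inside the care set (on ∪ dc), as (value, mask).

    For widths up to 12 a dynamic program over all 3^n cubes is used: a
    cube is an implicant iff both halves of any split variable are, so
    implicant indicators propagate from minterms upward in one numpy pass
    per don't-care mask.  Wider functions fall back to classic
    Quine-McCluskey pairwise merging, which is preferable only when the
    care set is small.
    """
    if n_vars <= 12:
        return _prime_implicants_dp(care, n_vars)
    return _prime_implicants_merge(care)


def _prime_implicants_dp(care: frozenset[int], n_vars: int) -> list[tuple[int, int]]:
    total = 1 << n_vars
    idx = np.arange(total)
    impl: dict[int, np.ndarray] = {}
    base = np.zeros(total, dtype=bool)
    base[list(care)] = True
    impl[0] = base
    masks_by_pop: dict[int, list[int]] = {}
    for m in range(total):
        masks_by_pop.setdefault(bin(m).count("1"), []).append(m)
    for pop in range(1, n_vars + 1):
        for m in masks_by_pop[pop]:
            low = m & -m  # split on the lowest don't-care bit
            child = impl[m ^ low]
            arr = child & child[idx | low]
            arr[idx & m != 0] = False  # only canonical values (v & m == 0)
            impl[m] = arr
    primes: list[tuple[int, int]] = []
    for m in range(total):
        arr = impl[m]
        vs = np.where(arr)[0]
        for v in vs:
            v = int(v)
            # prime iff no single-variable widening is an implicant
            if any(
                impl[m | b][v & ~b]
                for b in (1 << i for i in range(n_vars))
                if not m & b
            ):
                continue
            primes.append((v, m))
    return sorted(primes)


def _prime_implicants_merge(care: frozenset[int]) -> list[tuple[int, int]]:
    current: set[tuple[int, int]] = {(m, 0) for m in care}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        # group by (mask, popcount of value) so only adjacent groups compare
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for vm in current:
            groups.setdefault((vm[1], bin(vm[0]).count("1")), []).append(vm)
        for (mask, ones), members in groups.items():
            partners = groups.get((mask, ones + 1), [])
            for v1, m1 in members:
                for v2, m2 in partners:
                    diff = v1 ^ v2
                    if diff & (diff - 1) == 0 and diff:
                        merged.add((v1 & ~diff, m1 | diff))
                        used.add((v1, m1))
                        used.add((v2, m2))
        primes.update(current - used)
        current = merged
    return sorted(primes)


def prime_implicants(f: TruthFunction) -> list[Cube]:
    """All prime implicants: maximal cubes avoiding the off-set.

    Single minterms are merged pairwise whenever they differ in one bit
    (``A + Ā = 1``), repeatedly, until no cube can be widened further.
    Don't-care minterms participate in merging but need not be covered.
    """
    if not f.on_set:
        return []
    care = f.on_set | f.dont_cares()
    vms = _prime_implicants_vm(frozenset(care), f.n_vars)
    # primes made entirely of don't-cares are useless for covering
    on_arr = np.array(sorted(f.on_set), dtype=np.int64)
    vms = [
        (v, m) for v, m in vms if bool(((on_arr | m) == (v | m)).any())
    ]
    cubes = [Cube.from_value_mask(v, m, f.n_vars) for v, m in vms]
    return sorted(cubes, key=lambda c: c.literals)


def _min_cover_branch_bound(
    primes: list[Cube], on_set: frozenset[int]
) -> list[Cube]:
    """Minimum-cardinality prime subset covering ``on_set``.

    The classical unate-covering reductions run first — essential primes
    (sole coverer of some minterm), row dominance (a minterm whose coverer
    set contains another minterm's is redundant) and column dominance (a
    prime whose remaining coverage is contained in another's can be
    dropped) — iterated to a fixed point with vectorized containment
    tests; the surviving cyclic core is solved by depth-first branch and
    bound with an independent-row lower bound.  Among equal-size covers
    the search prefers the lexicographically smallest cube list, so the
    output is deterministic.
    """
    import math

    on_list = sorted(on_set)
    on_arr = np.array(on_list, dtype=np.int64)
    n_on = len(on_arr)
    if not primes:
        raise ValueError("no primes to cover a nonempty on-set")
    # cov[c, r]: prime c covers on-minterm r
    cov = np.stack(
        [(on_arr | m) == (v | m) for v, m in (pr.value_mask() for pr in primes)]
    )
    lex_rank = np.argsort(
        np.argsort([pr.literals for pr in primes], kind="stable")
    )

    col_alive = np.ones(len(primes), dtype=bool)
    row_alive = np.ones(n_on, dtype=bool)
    chosen: list[int] = []

    changed = True
    while changed and row_alive.any():
        changed = False
        sub = cov[np.ix_(col_alive, row_alive)]
        cols = np.where(col_alive)[0]
        rows = np.where(row_alive)[0]
        # essential columns: sole coverer of some live row
        counts = sub.sum(axis=0)
        ess = np.unique(sub[:, counts == 1].argmax(axis=0))
        if len(ess):
            for c_local in ess:
                c = int(cols[c_local])
                chosen.append(c)
                row_alive &= ~cov[c]
                col_alive[c] = False
            changed = True
            continue
        B = sub.astype(np.int32)
        # row dominance: drop row a when coverers(a) ⊇ coverers(b), b ≠ a
        # (ties: keep the lowest row index)
        X = B.T @ (1 - B)  # X[b, a] = #coverers of b missing from a
        contain = X == 0  # contain[b, a]: coverers(b) ⊆ coverers(a)
        nr = len(rows)
        strict = contain & ~contain.T
        drop_rows = strict.any(axis=0)
        eq = contain & contain.T
        np.fill_diagonal(eq, False)
        eq_drop = eq & (np.arange(nr)[:, None] < np.arange(nr)[None, :])
        drop_rows |= eq_drop.any(axis=0)
        if drop_rows.any():
            row_alive[rows[drop_rows]] = False
            changed = True
            continue
        # column dominance: drop column c1 when its live coverage is
        # contained in another's (ties: keep the lexicographically
        # smaller cube)
        Y = B @ (1 - B).T  # Y[c1, c2] = #rows of c1 not covered by c2
        ccontain = Y == 0  # ccontain[c1, c2]: rows(c1) ⊆ rows(c2)
        nc = len(cols)
        cstrict = ccontain & ~ccontain.T
        drop_cols = cstrict.any(axis=1)
        ceq = ccontain & ccontain.T
        np.fill_diagonal(ceq, False)
        lr = lex_rank[cols]
        ceq_drop = ceq & (lr[:, None] > lr[None, :])
        drop_cols |= ceq_drop.any(axis=1)
        if drop_cols.any():
            col_alive[cols[drop_cols]] = False
            changed = True

    if not row_alive.any():
        return sorted((primes[i] for i in chosen), key=lambda c: c.literals)

    # cyclic core: branch and bound
    core_rows = [int(r) for r in np.where(row_alive)[0]]
    candidates = sorted(
        (int(c) for c in np.where(col_alive)[0] if cov[c][row_alive].any()),
        key=lambda c: (-int(cov[c][row_alive].sum()), primes[c].literals),
    )
    core_sets = {
        c: frozenset(r for r in core_rows if cov[c][r]) for c in candidates
    }
    row_cands = {
        r: [c for c in candidates if r in core_sets[c]] for r in core_rows
    }
    best: list[Optional[list[int]]] = [None]

    def lex_key(sel: list[int]) -> list[str]:
        return sorted(primes[i].literals for i in chosen + sel)

    def lower_bound(uncovered: frozenset[int]) -> int:
        # greedy independent rows: no two share a candidate column
        used_cols: set[int] = set()
        lb = 0
        for r in sorted(uncovered, key=lambda r: len(row_cands[r])):
            cs = row_cands[r]
            if not any(c in used_cols for c in cs):
                lb += 1
                used_cols.update(cs)
        return lb

    def search(uncovered: frozenset[int], selected: list[int]) -> None:
        if not uncovered:
            if (
                best[0] is None
                or len(selected) < len(best[0])
                or (
                    len(selected) == len(best[0])
                    and lex_key(selected) < lex_key(best[0])
                )
            ):
                best[0] = list(selected)
            return
        if best[0] is not None and len(selected) + 1 > len(best[0]):
            return
        if (
            best[0] is not None
            and len(selected) + lower_bound(uncovered) > len(best[0])
        ):
            return
        # branch on the hardest minterm (fewest coverers)
        r = min(uncovered, key=lambda row: (len(row_cands[row]), row))
        for c in row_cands[r]:
            if c not in selected:
                search(uncovered - core_sets[c], selected + [c])

    if len(candidates) > 18:
        # large cyclic core: exact binary set cover via HiGHS; the
        # lexicographic tie-break among equal-size optima applies only to
        # the branch-and-bound path below (small cores)
        from scipy.optimize import Bounds, LinearConstraint, milp

        A = np.stack(
            [[1.0 if r in core_sets[c] else 0.0 for c in candidates]
             for r in core_rows]
        )
        res = milp(
            c=np.ones(len(candidates)),
            constraints=LinearConstraint(A, lb=1),
            integrality=np.ones(len(candidates)),
            bounds=Bounds(0, 1),
        )
        if res.status != 0:  # pragma: no cover - HiGHS failure is fatal
            raise RuntimeError(f"set-cover ILP failed: {res.message}")
        best[0] = [c for c, x in zip(candidates, res.x) if x > 0.5]
    else:
        # greedy warm start bounds the search from the outset
        greedy: list[int] = []
        uncov = set(core_rows)
        while uncov:
            c = max(
                candidates,
                key=lambda c: (len(core_sets[c] & uncov), -lex_rank[c]),
            )
            if not core_sets[c] & uncov:
                break
            greedy.append(c)
            uncov -= core_sets[c]
        if not uncov:
            best[0] = greedy
        search(frozenset(core_rows), [])
    assert best[0] is not None
    return sorted((primes[i] for i in chosen + best[0]), key=lambda c: c.literals)


def qm_minimize(
    f: TruthFunction, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> Cover:
    """Exact two-level minimization (Quine-McCluskey + exact set cover).

    Returns a minimum-cardinality cover of the on-set; don't-care minterms
    may be covered when doing so widens a cube.  Refuses widths above
    ``exact_limit`` (memory and time double per added variable).
    """
    if f.n_vars > exact_limit:
        raise ExactLimitError(
            f"{f.n_vars} variables exceeds exact_limit={exact_limit}; "
            "use espresso_minimize"
        )
    if not f.on_set:
        return Cover((), f.n_vars)
    primes = prime_implicants(f)
    cubes = _min_cover_branch_bound(primes, f.on_set)
    return Cover(tuple(cubes), f.n_vars)


# --- ESPRESSO-style heuristic ------------------------------------------------


def _covers(on_arr: np.ndarray, v: int, m: int) -> np.ndarray:
    """Boolean mask of minterms in ``on_arr`` covered by cube ``(v, m)``."""
    return (on_arr | m) == (v | m)


def _cube_hits_offset(value: int, mask: int, off_arr: np.ndarray) -> bool:
    if len(off_arr) == 0:
        return False
    return bool(((off_arr | mask) == (value | mask)).any())


def _expand(
    cover: list[tuple[int, int]],
    on_arr: np.ndarray,
    off_arr: np.ndarray,
    n_vars: int,
    raise_preference: Optional[Sequence[float]] = None,
) -> list[tuple[int, int]]:
    """Widen each cube against the off-set until it is a prime implicant.

    Cubes are processed in descending order of covered on-set minterms
    (ties by original index); cubes already inside an earlier expanded
    cube are dropped.  Within a cube, literals are raised greedily with
    the classic covering heuristic: at each step raise the safe literal
    whose removal lets the cube swallow the most on-set minterms, breaking
    ties by how few off-set minterms the literal distinguishes, then by
    leftmost position.  Literals shared by many positive examples but
    irrelevant to the off-set get raised away; the literals that actually
    separate the on-set from the off-set survive.

    ``raise_preference`` optionally refines the tie-break: among raises
    with equal coverage gain, the variable with the smallest preference
    value is raised (shed) first.  Callers with an external
    variable-importance ranking (e.g. SVM-RFE) pass it here so
    uninformative literals are shed before informative ones.
    """
    full = (1 << n_vars) - 1
    order = sorted(
        range(len(cover)),
        key=lambda i: (-int(_covers(on_arr, *cover[i]).sum()), i),
    )
    expanded: list[tuple[int, int]] = []
    for i in order:
        v, m = cover[i]
        # skip cubes already inside an expanded cube
        if any(
            (m2 & m) == m and (v | m2) == (v2 | m2) for v2, m2 in expanded
        ):
            continue
        while True:
            best: Optional[tuple[tuple, int]] = None
            for bp in range(n_vars):
                bit = 1 << bp
                if m & bit:
                    continue
                nv, nm = v & ~bit, m | bit
                if _cube_hits_offset(nv, nm, off_arr):
                    continue
                covered = int(_covers(on_arr, nv, nm).sum())
                # off-set minterms this literal alone distinguishes
                if len(off_arr):
                    blocking = int(
                        (((off_arr ^ v) & (~m & full)) == bit).sum()
                    )
                else:
                    blocking = 0
                # bit position bp counts from the right; variable index
                # (left to right) is n_vars - 1 - bp
                pref = (
                    raise_preference[n_vars - 1 - bp]
                    if raise_preference is not None
                    else 0.0
                )
                key = (-covered, pref, blocking, -bp)
                if best is None or key < best[0]:
                    best = (key, bp)
            if best is None:
                break
            bit = 1 << best[1]
            v, m = v & ~bit, m | bit
        if raise_preference is not None:
            v, m = _exchange_literals(
                v, m, on_arr, off_arr, n_vars, raise_preference
            )
        expanded.append((v, m))
    return expanded


def _exchange_literals(
    v: int,
    m: int,
    on_arr: np.ndarray,
    off_arr: np.ndarray,
    n_vars: int,
    pref: Sequence[float],
) -> tuple[int, int]:
    """Swap low-preference guard literals for trusted variables.

    A fully expanded cube may retain a literal on a weakly trusted
    variable only because the greedy raising order locked it in as the
    last safeguard against the off-set.  When every on-set minterm the
    cube covers agrees on some raised, more-trusted variable, that
    variable can be fixed back and the weak literal raised instead —
    coverage never shrinks and the off-set stays avoided.  Repeats until
    no such exchange exists; deterministic.
    """

    def pref_of(bp: int) -> float:
        return pref[n_vars - 1 - bp]

    improved = True
    while improved:
        improved = False
        fixed = sorted(
            (bp for bp in range(n_vars) if not m & (1 << bp)),
            key=lambda bp: (pref_of(bp), -bp),
        )
        for lo in fixed:
            lo_bit = 1 << lo
            covered = on_arr[_covers(on_arr, v, m)]
            raised = sorted(
                (bp for bp in range(n_vars) if m & (1 << bp)),
                key=lambda bp: (-pref_of(bp), bp),
            )
            done = False
            for hi in raised:
                if pref_of(hi) <= pref_of(lo):
                    break
                hi_bit = 1 << hi
                bits = (covered & hi_bit) != 0
                if len(covered) == 0 or (bits.any() and not bits.all()):
                    continue
                b = 1 if len(covered) and bits.all() else 0
                nv = (v & ~lo_bit & ~hi_bit) | (hi_bit if b else 0)
                nm = (m | lo_bit) & ~hi_bit
                if not _cube_hits_offset(nv, nm, off_arr):
                    v, m = nv, nm
                    improved = True
                    done = True
                    break
            if done:
                break
    return v, m


def _coverage_matrix(
    cover: list[tuple[int, int]], on_arr: np.ndarray
) -> np.ndarray:
    if not cover:
        return np.zeros((0, len(on_arr)), dtype=bool)
    return np.stack([_covers(on_arr, v, m) for v, m in cover])


def _irredundant(
    cover: list[tuple[int, int]],
    on_arr: np.ndarray,
    n_vars: int = 0,
    raise_preference: Optional[Sequence[float]] = None,
) -> list[tuple[int, int]]:
    """Drop cubes whose on-set contribution is covered by the rest.

    Greedy: keep cubes in descending contribution order until the on-set is
    covered; deterministic tie-break by cube order.  When a variable
    preference is given, cube trust — the preference of the weakest
    variable a cube fixes — takes precedence over contribution: rules
    built entirely on trusted variables are kept first, and cubes leaning
    on weak variables survive only for minterms nothing cleaner covers.
    """
    C = _coverage_matrix(cover, on_arr)
    sizes = C.sum(axis=1)
    if raise_preference is None:
        order = sorted(range(len(cover)), key=lambda i: (-int(sizes[i]), i))
    else:
        def trust(i: int) -> float:
            v, m = cover[i]
            prefs = [
                raise_preference[n_vars - 1 - bp]
                for bp in range(n_vars)
                if not m & (1 << bp)
            ]
            return min(prefs) if prefs else float("inf")

        order = sorted(
            range(len(cover)), key=lambda i: (-trust(i), -int(sizes[i]), i)
        )
    kept: list[int] = []
    covered = np.zeros(len(on_arr), dtype=bool)
    for i in order:
        if (C[i] & ~covered).any():
            kept.append(i)
            covered |= C[i]
        if covered.all():
            break
    kept.sort()
    return [cover[i] for i in kept]


def _reduce(
    cover: list[tuple[int, int]], on_arr: np.ndarray, n_vars: int
) -> list[tuple[int, int]]:
    """Shrink each cube to the smallest cube holding its essential minterms.

    Cubes are processed sequentially against the *current* state of the
    cover, so every shrink preserves total on-set coverage: a minterm a
    cube gives up is, at that moment, covered by another cube.  Cubes
    whose entire contribution is covered elsewhere are dropped.
    """
    C = _coverage_matrix(cover, on_arr)
    counts = C.sum(axis=0)
    cur: list[Optional[tuple[int, int]]] = list(cover)
    for i in range(len(cur)):
        essential = on_arr[C[i] & (counts == 1)]
        if not len(essential):
            counts -= C[i]
            C[i] = False
            cur[i] = None
            continue
        base = int(essential[0])
        diff_union = 0
        for mt in essential[1:]:
            diff_union |= base ^ int(mt)
        new_m = diff_union  # free exactly the disagreeing bits
        new_v = base & ~new_m
        new_cov = _covers(on_arr, new_v, new_m)
        counts += new_cov.astype(counts.dtype) - C[i].astype(counts.dtype)
        C[i] = new_cov
        cur[i] = (new_v, new_m)
    return [vm for vm in cur if vm is not None]


def espresso_minimize(
    f: TruthFunction,
    max_iters: int = 10,
    heuristic_limit: int = DEFAULT_HEURISTIC_LIMIT,
    raise_preference: Optional[Sequence[float]] = None,
) -> Cover:
    """Heuristic two-level minimization (EXPAND / IRREDUNDANT / REDUCE).

    Starting from the on-set minterms as unit cubes, each pass greedily
    widens cubes against the off-set (EXPAND), drops cubes covered by the
    rest (IRREDUNDANT), and shrinks the survivors to their essential
    minterms (REDUCE) to give the next EXPAND different raising room.  Stops
    when cover size and literal count no longer improve or after
    ``max_iters`` passes.  All orderings are fixed, so the output is
    deterministic; global minimality is not guaranteed.

    ``raise_preference`` (one value per variable, left to right; smaller =
    shed first) biases which literals EXPAND raises on coverage-gain ties
    — see :func:`_expand`.
    """
    if f.n_vars > heuristic_limit:
        raise HeuristicLimitError(
            f"{f.n_vars} variables exceeds heuristic_limit={heuristic_limit}"
        )
    if not f.on_set:
        return Cover((), f.n_vars)
    on_arr = np.array(sorted(f.on_set), dtype=np.int64)
    off_arr = np.array(sorted(f.off_set), dtype=np.int64)
    cover = [(int(mt), 0) for mt in on_arr]

    def n_lits(c: list[tuple[int, int]]) -> int:
        return sum(f.n_vars - bin(m).count("1") for _, m in c)

    best: Optional[list[tuple[int, int]]] = None
    for _ in range(max_iters):
        cover = _expand(cover, on_arr, off_arr, f.n_vars, raise_preference)
        cover = _irredundant(cover, on_arr, f.n_vars, raise_preference)
        if best is not None and (len(cover), n_lits(cover)) >= (
            len(best), n_lits(best)
        ):
            break
        best = list(cover)
        cover = _reduce(cover, on_arr, f.n_vars)
    assert best is not None
    cubes = sorted(
        (Cube.from_value_mask(v, m, f.n_vars) for v, m in best),
        key=lambda c: c.literals,
    )
    return Cover(tuple(cubes), f.n_vars)


def covers_equivalent(c: Cover, f: TruthFunction, check_limit: int = 20) -> bool:
    """True iff ``c`` covers every on-set minterm and no off-set minterm.

    Exhaustive over the specified minterms (don't-cares are free either
    way); refuses absurd widths to keep the check honest and bounded.
    """
    if c.n_vars != f.n_vars:
        raise ValueError("width mismatch between cover and function")
    if f.n_vars > check_limit:
        raise ValueError(f"exhaustive check limited to {check_limit} variables")
    return all(c.covers_minterm(m) for m in f.on_set) and not any(
        c.covers_minterm(m) for m in f.off_set
    )
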