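"""Scoring minimized rules by training popularity and making predictions.

Logic minimization discards how many training examples each rule (cube)
condenses.  That count — the *score* of a rule — is restored here by
counting, with multiplicity, the positive training patterns each cube
covers.  A test pattern's score is then the sum of the scores of the rules
it satisfies; patterns satisfying no rule fall to the implicit 0-output
rule and score 0.  A tunable cutoff turns scores into labels, trading
sensitivity for positive predictive value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .encoding import EncodedDataset, VariableMeaning
from .logic import Cover, Cube, cube_covers

__all__ = [
    "ScoredRule",
    "ScoredRuleSet",
    "PredictionScore",
    "Cutoff",
    "score_rules",
    "score_pattern",
    "score_patterns",
    "score_threshold",
    "predict",
    "render_rules",
]


@dataclass(frozen=True)
class ScoredRule:
    cube: Cube
    score: int


@dataclass(frozen=True)
class ScoredRuleSet:
    """Minimized rules with training-popularity scores.

    Rules are kept sorted by descending score, ties by lexicographic cube,
    so "the most popular rule" is well defined.  Zero-score rules (cubes
    covering only don't-cares) are retained but observable via
    :attr:`zero_score_rules`.
    """

    rules: tuple[ScoredRule, ...]
    n_vars: int
    meanings: tuple[VariableMeaning, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.rules, key=lambda r: (-r.score, r.cube.literals))
        )
        object.__setattr__(self, "rules", ordered)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def zero_score_rules(self) -> tuple[ScoredRule, ...]:
        return tuple(r for r in self.rules if r.score == 0)

    @property
    def top_rule(self) -> ScoredRule:
        if not self.rules:
            raise ValueError("empty rule set")
        return self.rules[0]

    def cover(self) -> Cover:
        return Cover(tuple(r.cube for r in self.rules), self.n_vars)


@dataclass(frozen=True)
class PredictionScore:
    """Score of one test pattern: sum over the rules it satisfies."""

    pattern_id: Union[int, str]
    score: int
    n_rules_hit: int


@dataclass(frozen=True)
class Cutoff:
    """How scores become positive predictions.

    * ``all_rules`` — positive iff the pattern satisfies at least one rule
      (score ≥ 1): the raw minimized-rule classifier.
    * ``top_fraction`` — keep the fraction ``f`` of positive-scoring
      examples with the highest scores; boundary ties are all included.
    * ``min_score`` — positive iff score ≥ ``s``; e.g. the sum of the two
      top rule scores demands that both rules be satisfied.
    """

    mode: Literal["all_rules", "top_fraction", "min_score"] = "all_rules"
    fraction: Optional[float] = None
    min_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode == "top_fraction":
            if self.fraction is None or not (0 < self.fraction <= 1):
                raise ValueError("top_fraction requires fraction in (0, 1]")
        elif self.mode == "min_score":
            if self.min_score is None or self.min_score < 1:
                raise ValueError("min_score requires an integer >= 1")
        elif self.mode != "all_rules":
            raise ValueError(f"unknown cutoff mode {self.mode!r}")


def score_rules(cover: Cover, training: EncodedDataset) -> ScoredRuleSet:
    """Score each cube by the positive training patterns it covers.

    Counting respects multiplicity: a pattern that occurred four times
    before duplicate collapsing contributes four to every rule covering it.
    """
    if training.width != cover.n_vars:
        raise ValueError(
            f"width mismatch: cover {cover.n_vars}, dataset {training.width}"
        )
    pos = training.labels == 1
    pos_patterns = training.patterns[pos]
    pos_mult = training.multiplicity[pos]
    rules = []
    for cube in cover:
        s = sum(
            int(m)
            for row, m in zip(pos_patterns, pos_mult)
            if cube_covers(cube, row)
        )
        rules.append(ScoredRule(cube=cube, score=s))
    return ScoredRuleSet(
        rules=tuple(rules),
        n_vars=cover.n_vars,
        meanings=tuple(training.meanings),
    )


def score_pattern(
    pattern: Sequence[int], rs: ScoredRuleSet, pattern_id: Union[int, str] = 0
) -> PredictionScore:
    """Sum the scores of the rules ``pattern`` satisfies."""
    if len(pattern) != rs.n_vars:
        raise ValueError(
            f"width mismatch: pattern {len(pattern)}, rules {rs.n_vars}"
        )
    total = 0
    hits = 0
    for rule in rs:
        if cube_covers(rule.cube, pattern):
            total += rule.score
            hits += 1
    return PredictionScore(pattern_id=pattern_id, score=total, n_rules_hit=hits)


def score_patterns(
    patterns: np.ndarray,
    rs: ScoredRuleSet,
    ids: Optional[Sequence[Union[int, str]]] = None,
) -> list[PredictionScore]:
    """Vectorized scoring of a pattern matrix against the rule set."""
    patterns = np.asarray(patterns, dtype=np.uint8)
    if patterns.ndim == 1:
        patterns = patterns[None, :]
    n = len(patterns)
    if patterns.shape[1] != rs.n_vars:
        raise ValueError("width mismatch")
    if ids is None:
        ids = list(range(n))
    totals = np.zeros(n, dtype=np.int64)
    hits = np.zeros(n, dtype=np.int64)
    for rule in rs:
        fixed = np.array([c != "-" for c in rule.cube.literals])
        want = np.array([c == "1" for c in rule.cube.literals], dtype=np.uint8)
        if fixed.any():
            sat = (patterns[:, fixed] == want[fixed]).all(axis=1)
        else:
            sat = np.ones(n, dtype=bool)
        totals[sat] += rule.score
        hits[sat] += 1
    return [
        PredictionScore(pattern_id=i, score=int(s), n_rules_hit=int(h))
        for i, s, h in zip(ids, totals, hits)
    ]


def score_threshold(scores: Sequence[PredictionScore], cutoff: Cutoff) -> int:
    """The minimum score a pattern needs to be called positive."""
    if cutoff.mode == "all_rules":
        return 1
    if cutoff.mode == "min_score":
        assert cutoff.min_score is not None
        return int(cutoff.min_score)
    positive_scores = sorted(
        (s.score for s in scores if s.score > 0), reverse=True
    )
    if not positive_scores:
        return 1
    m = len(positive_scores)
    import math

    idx = max(0, math.ceil(cutoff.fraction * m) - 1)
    return positive_scores[idx]


def predict(
    scores: Sequence[PredictionScore], cutoff: Cutoff = Cutoff()
) -> np.ndarray:
    """Binary labels from scores under the given cutoff.

    ``top_fraction f`` keeps at least a fraction ``f`` of the
    positive-scoring examples (ties at the threshold all included);
    raising any cutoff can only remove positives, never add them.
    """
    thr = score_threshold(scores, cutoff)
    return np.array([1 if s.score >= thr else 0 for s in scores], dtype=int)


def render_rules(rs: ScoredRuleSet, site_name: str = "site") -> str:
    """Human-readable rule table.

    One line per rule: the cube, its score and the conjunction of
    conditions phrased through each variable's meaning ("Nucleotide 10 is
    T", "Amino Acid in Position −1 is not P", ...).  A trailing note states
    the implicit 0-output rule.
    """
    lines = []
    header = f"{'cube':<{max(6, rs.n_vars + 2)}}{'score':>7}  conditions"
    lines.append(header)
    for rule in rs:
        conds = []
        for j, lit in enumerate(rule.cube.literals):
            if lit == "-":
                continue
            if rs.meanings:
                conds.append(rs.meanings[j].render(int(lit)))
            else:
                verb = "=" if lit == "1" else "≠"
                conds.append(f"x{j + 1} {verb} 1")
        text = " and ".join(conds) if conds else "always"
        lines.append(
            f"{rule.cube.literals:<{max(6, rs.n_vars + 2)}}{rule.score:>7}  "
            f"If {text} then the sequence is a {site_name}."
        )
    lines.append(f"Everything else is not a {site_name}.")
    return "\n".join(lines)
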