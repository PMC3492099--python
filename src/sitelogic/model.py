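"""The rule-extraction classifier as a model/results pair.

:class:`SiteRuleModel` holds labeled sequence windows (14-nt DNA windows
for binding-site prediction, 11-residue S/T-centered windows for
O-glycosylation) plus the training configuration; :meth:`SiteRuleModel.fit`
runs the full pipeline —

    one-hot encode → SVM-RFE to the top-k variables → project →
    deduplicate / remove contradictions → partially specified truth
    function (unseen patterns are don't-cares) → two-level logic
    minimization (exact Quine-McCluskey when k is small, ESPRESSO-style
    heuristic otherwise) → score rules by training popularity

— and returns a :class:`SiteRuleResults` carrying the ranked variables,
the scored rules, training diagnostics and prediction methods
(:meth:`~SiteRuleResults.scan_sequence` for DNA,
:meth:`~SiteRuleResults.classify_st_windows` for proteins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import rules as rules_mod
from .encoding import (
    CleaningReport,
    EncodedDataset,
    UNKNOWN_RESIDUE,
    clean_dataset,
    dna_meanings,
    encode_dna,
    encode_protein,
    protein_meanings,
)
from .logic import (
    DEFAULT_EXACT_LIMIT,
    DEFAULT_HEURISTIC_LIMIT,
    TruthFunction,
    espresso_minimize,
    qm_minimize,
)
from .rules import Cutoff, PredictionScore, ScoredRuleSet, score_patterns
from .svm_rfe import FeatureRanking, project_dataset, rfe_rank

__all__ = ["SiteRuleModel", "SiteRuleResults", "SitePredictor", "encode_windows"]


def encode_windows(
    windows: Sequence[str], kind: Literal["tfbs", "glyco"]
) -> EncodedDataset:
    """One-hot encode a batch of equal-length windows with meanings."""
    if not windows:
        raise ValueError("no windows given")
    if kind == "tfbs":
        width = len(windows[0])
        vecs = [encode_dna(w) for w in windows]
        meanings = dna_meanings(width)
    elif kind == "glyco":
        vecs = [encode_protein(w) for w in windows]
        meanings = protein_meanings()
    else:
        raise ValueError(f"unknown kind {kind!r}")
    patterns = np.array([v.bits for v in vecs], dtype=np.uint8)
    return EncodedDataset(
        patterns=patterns,
        labels=np.zeros(len(windows), dtype=np.int8),
        meanings=meanings,
        provenance=[f"window_{i}" for i in range(len(windows))],
    )


class SiteRuleModel:
    """Interpretable site classifier trained by logic minimization.

    Parameters
    ----------
    windows : sequence of str
        Training windows; all the same length (14 nt typical for DNA
        binding sites, exactly 11 residues for protein S/T windows).
    labels : sequence of {0,1}
        1 for verified sites, 0 for non-sites.
    kind : {"tfbs", "glyco"}
        Selects the encoding (4 bits/nt vs 21 bits/residue) and the
        prediction surface (sliding-window DNA scan vs centered S/T
        windows).
    k : int
        Number of top variables kept by SVM-RFE before minimization.
        Defaults to 22 for DNA (the input cap of classic espresso-family
        minimizers) and 20 for protein windows.
    C, tol : float
        Soft-margin penalty and solver tolerance of the linear SVM.
    exact_limit : int
        Widest function minimized exactly; beyond it the heuristic runs.
    contradiction_policy : {"drop", "majority"}
        How projected patterns seen with both labels are resolved.
    cutoff : Cutoff
        Default score cutoff used by the Results prediction methods.
    """

    def __init__(
        self,
        windows: Sequence[str],
        labels: Sequence[int],
        kind: Literal["tfbs", "glyco"] = "tfbs",
        k: Optional[int] = None,
        C: float = 1.0,
        tol: float = 1e-6,
        exact_limit: int = DEFAULT_EXACT_LIMIT,
        heuristic_limit: int = DEFAULT_HEURISTIC_LIMIT,
        contradiction_policy: Literal["drop", "majority"] = "drop",
        cutoff: Cutoff = Cutoff(),
        rfe_step: int = 1,
    ) -> None:
        windows = [str(w).upper() for w in windows]
        labels = np.asarray(labels, dtype=np.int8)
        if len(windows) != len(labels):
            raise ValueError("windows and labels length mismatch")
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(set(len(w) for w in windows)) != 1:
            raise ValueError("all windows must share one length")
        self.kind = kind
        self.windows = windows
        self.window_length = len(windows[0])
        if kind == "glyco":
            centers = {w[5] for w in windows if w[5] != UNKNOWN_RESIDUE}
            if len(centers) > 1:
                raise ValueError(
                    "glyco windows must share a central residue (S or T); "
                    f"got {sorted(centers)}"
                )
            self.center = centers.pop() if centers else "T"
        else:
            self.center = None
        self.k = k if k is not None else (22 if kind == "tfbs" else 20)
        if self.k > heuristic_limit:
            raise ValueError(f"k={self.k} exceeds heuristic_limit={heuristic_limit}")
        self.C = C
        self.tol = tol
        self.exact_limit = exact_limit
        self.heuristic_limit = heuristic_limit
        self.contradiction_policy = contradiction_policy
        self.cutoff = cutoff
        self.rfe_step = rfe_step
        self.dataset = encode_windows(windows, kind)
        self.dataset.labels = labels

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        window_col: str = "window",
        label_col: str = "label",
        **kwargs,
    ) -> "SiteRuleModel":
        return cls(
            windows=df[window_col].tolist(),
            labels=df[label_col].to_numpy(),
            **kwargs,
        )

    @classmethod
    def from_encoded(cls, dataset: EncodedDataset, **kwargs) -> "SiteRuleModel":
        """Build a model directly from an already-binary pattern table.

        Bypasses sequence encoding: the dataset's columns are the
        variables fed to feature selection and minimization.  Prediction
        then happens on raw bit patterns rather than sequence windows.
        """
        obj = cls.__new__(cls)
        obj.kind = "encoded"
        obj.windows = None
        obj.window_length = dataset.width
        obj.center = None
        obj.k = kwargs.pop("k", None) or dataset.width
        obj.C = kwargs.pop("C", 1.0)
        obj.tol = kwargs.pop("tol", 1e-6)
        obj.exact_limit = kwargs.pop("exact_limit", DEFAULT_EXACT_LIMIT)
        obj.heuristic_limit = kwargs.pop(
            "heuristic_limit", DEFAULT_HEURISTIC_LIMIT
        )
        obj.contradiction_policy = kwargs.pop("contradiction_policy", "drop")
        obj.cutoff = kwargs.pop("cutoff", Cutoff())
        obj.rfe_step = kwargs.pop("rfe_step", 1)
        if kwargs:
            raise TypeError(f"unknown arguments: {sorted(kwargs)}")
        obj.dataset = dataset
        return obj

    def fit(self) -> "SiteRuleResults":
        """Run the full pipeline and return fitted results."""
        y = self.dataset.labels
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("training data must contain both classes")
        ranking = rfe_rank(
            self.dataset.patterns,
            y,
            k=self.k,
            C=self.C,
            tol=self.tol,
            step=self.rfe_step,
        )
        projected = project_dataset(self.dataset, ranking)
        cleaned, report = clean_dataset(projected, self.contradiction_policy)
        if cleaned.n == 0 or cleaned.labels.sum() == 0:
            raise ValueError(
                "no usable training patterns after contradiction removal"
            )
        f = TruthFunction.from_patterns(
            cleaned.patterns, cleaned.labels, n_vars=self.k
        )
        if self.k <= self.exact_limit:
            cover = qm_minimize(f, exact_limit=self.exact_limit)
            minimizer = "quine-mccluskey"
        else:
            # shed literals of weakly class-associated variables first:
            # preference = |two-proportion z| of each selected column
            X = projected.patterns.astype(float)
            pos = X[y == 1]
            neg = X[y == 0]
            pooled = X.mean(axis=0)
            se = np.sqrt(
                np.clip(pooled * (1 - pooled), 1e-12, None)
                * (1 / len(pos) + 1 / len(neg))
            )
            preference = list(np.abs((pos.mean(axis=0) - neg.mean(axis=0)) / se))
            cover = espresso_minimize(
                f,
                heuristic_limit=self.heuristic_limit,
                raise_preference=preference,
            )
            minimizer = "espresso"
        ruleset = rules_mod.score_rules(cover, cleaned)
        return SiteRuleResults(
            model=self,
            ranking=ranking,
            ruleset=ruleset,
            cleaned=cleaned,
            cleaning_report=report,
            truth_function=f,
            minimizer=minimizer,
        )


@dataclass
class SiteRuleResults:
    """Fitted rules, variable ranking and prediction methods."""

    model: SiteRuleModel
    ranking: FeatureRanking
    ruleset: ScoredRuleSet
    cleaned: EncodedDataset
    cleaning_report: CleaningReport
    truth_function: TruthFunction
    minimizer: str

    # --- diagnostics ---------------------------------------------------------

    @property
    def n_rules(self) -> int:
        return len(self.ruleset)

    @property
    def n_distinct_patterns(self) -> int:
        """Distinct projected training patterns after cleaning."""
        return self.cleaned.n

    def training_sensitivity(self) -> float:
        """Fraction of retained positive training patterns satisfying ≥1
        rule — 1.0 by construction of a complete cover."""
        pos = self.cleaned.patterns[self.cleaned.labels == 1]
        if len(pos) == 0:
            return float("nan")
        scores = score_patterns(pos, self.ruleset)
        return float(np.mean([s.n_rules_hit > 0 for s in scores]))

    def ranking_table(self) -> pd.DataFrame:
        """Selected variables in importance order (most informative first),
        with their 1-based indices and biological meanings."""
        order = list(self.ranking.order)
        # survivors appear last in elimination order; reverse → best first
        survivors = order[len(order) - len(self.ranking.selected):][::-1]
        rows = []
        meanings = self.model.dataset.meanings
        for rank, idx in enumerate(survivors, start=1):
            rows.append(
                {
                    "ranking": rank,
                    "variable": idx + 1,
                    "meaning": meanings[idx].description if meanings else "",
                }
            )
        return pd.DataFrame(rows)

    def rules_table(self) -> pd.DataFrame:
        rows = []
        for i, rule in enumerate(self.ruleset, start=1):
            rows.append(
                {
                    "rule": i,
                    "cube": rule.cube.literals,
                    "score": rule.score,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary: configuration, ranking, scored rules."""
        m = self.model
        if m.kind == "tfbs":
            site = "TFBS"
        elif m.kind == "glyco":
            site = f"O-glycosylated {m.center}"
        else:
            site = "site"
        lines = [
            "Logic-minimization rule model",
            "=" * 64,
            f"kind: {m.kind}   window: {m.window_length}   "
            f"encoded width: {m.dataset.width}",
            f"training windows: {len(m.windows)} "
            f"({int(m.dataset.labels.sum())} positive)",
            f"top variables (SVM-RFE): {m.k}   minimizer: {self.minimizer}",
            f"distinct patterns after cleaning: {self.n_distinct_patterns}   "
            f"contradictions removed: "
            f"{len(self.cleaning_report.removed_contradictions)}",
            f"rules: {self.n_rules}   "
            f"training sensitivity (all rules): "
            f"{100 * self.training_sensitivity():.1f}%",
            "",
            "Top variables:",
            self.ranking_table().to_string(index=False),
            "",
            "Rules (cube over selected variables, score = positive training "
            "patterns covered):",
            rules_mod.render_rules(self.ruleset, site_name=site),
        ]
        return "\n".join(lines)

    # --- prediction ----------------------------------------------------------

    @property
    def predictor(self) -> "SitePredictor":
        """Standalone predictor (serializable; what the CLI persists)."""
        return SitePredictor(
            kind=self.model.kind,
            window_length=self.model.window_length,
            center=self.model.center,
            selected=tuple(self.ranking.selected),
            ruleset=self.ruleset,
            cutoff=self.model.cutoff,
        )

    def score_windows(self, windows: Sequence[str]) -> list[PredictionScore]:
        return self.predictor.score_windows(windows)

    def predict_windows(
        self, windows: Sequence[str], cutoff: Optional[Cutoff] = None
    ) -> np.ndarray:
        return self.predictor.predict_windows(windows, cutoff)

    def scan_sequence(self, dna: str) -> list[PredictionScore]:
        return self.predictor.scan_sequence(dna)

    def predict_sites(
        self, dna: str, cutoff: Optional[Cutoff] = None
    ) -> list[int]:
        return self.predictor.predict_sites(dna, cutoff)

    def classify_st_windows(self, protein: str) -> pd.DataFrame:
        return self.predictor.classify_st_windows(protein)


@dataclass(frozen=True)
class SitePredictor:
    """A fitted rule classifier detached from its training data.

    Carries just what prediction needs: the encoding kind, window length,
    central residue (protein models), the selected variable columns
    (0-based, original encoding order), the scored rules over those
    columns, and the default cutoff.
    """

    kind: Literal["tfbs", "glyco"]
    window_length: int
    center: Optional[str]
    selected: tuple[int, ...]
    ruleset: ScoredRuleSet
    cutoff: Cutoff = Cutoff()

    def score_windows(self, windows: Sequence[str]) -> list[PredictionScore]:
        """Score raw sequence windows against the fitted rules."""
        ds = encode_windows([w.upper() for w in windows], self.kind)
        projected = ds.patterns[:, list(self.selected)]
        return score_patterns(projected, self.ruleset)

    def predict_windows(
        self, windows: Sequence[str], cutoff: Optional[Cutoff] = None
    ) -> np.ndarray:
        scores = self.score_windows(windows)
        return rules_mod.predict(scores, cutoff or self.cutoff)

    def scan_sequence(self, dna: str) -> list[PredictionScore]:
        """Slide the window over a DNA sequence; one score per 1-based
        start position 1..L−w+1, forward strand only."""
        if self.kind != "tfbs":
            raise ValueError("scan_sequence applies to DNA models")
        dna = dna.upper()
        w = self.window_length
        if len(dna) < w:
            raise ValueError("sequence shorter than the window")
        onehot = np.zeros((len(dna), 4), dtype=np.uint8)
        codes = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, ch in enumerate(dna):
            if ch not in codes:
                raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}")
            onehot[i, codes[ch]] = 1
        n_windows = len(dna) - w + 1
        cols = list(self.selected)
        X = np.empty((n_windows, len(cols)), dtype=np.uint8)
        starts = np.arange(n_windows)
        for j, c in enumerate(cols):
            slot, base = divmod(c, 4)
            X[:, j] = onehot[starts + slot, base]
        return score_patterns(X, self.ruleset, ids=list(range(1, n_windows + 1)))

    def predict_sites(
        self, dna: str, cutoff: Optional[Cutoff] = None
    ) -> list[int]:
        """1-based start positions predicted positive under the cutoff."""
        scores = self.scan_sequence(dna)
        labels = rules_mod.predict(scores, cutoff or self.cutoff)
        return [s.pattern_id for s, lab in zip(scores, labels) if lab == 1]

    def classify_st_windows(self, protein: str) -> pd.DataFrame:
        """Score every candidate residue of a protein sequence.

        Each residue equal to the model's central residue (S or T) yields
        an 11-residue window; windows truncated at the protein ends are
        padded with the UNKNOWN symbol.  Returns one row per candidate:
        1-based residue position, the window, score and rules hit.
        """
        if self.kind != "glyco":
            raise ValueError("classify_st_windows applies to protein models")
        protein = protein.upper()
        rows = []
        windows = []
        for i, ch in enumerate(protein):
            if ch != self.center:
                continue
            left = protein[max(0, i - 5) : i]
            right = protein[i + 1 : i + 6]
            window = (
                UNKNOWN_RESIDUE * (5 - len(left))
                + left
                + ch
                + right
                + UNKNOWN_RESIDUE * (5 - len(right))
            )
            windows.append(window)
            rows.append({"position": i + 1, "residue": ch, "window": window})
        if not rows:
            return pd.DataFrame(
                columns=["position", "residue", "window", "score", "n_rules_hit"]
            )
        scores = self.score_windows(windows)
        df = pd.DataFrame(rows)
        df["score"] = [s.score for s in scores]
        df["n_rules_hit"] = [s.n_rules_hit for s in scores]
        return df
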