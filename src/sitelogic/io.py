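"""File readers and writers: FASTA, labeled-window TSV, rankings,
predictions, and fitted-predictor persistence.

Sequence I/O goes through Biopython; tables through pandas.  Fitted
predictors serialize to a small JSON document (kind, window geometry,
selected variables, scored cubes, cutoff) so a trained model can be reused
by the command line without retraining.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dataclasses import asdict, dataclass

import yaml

from .encoding import variable_meaning
from .logic import Cube
from .model import SitePredictor
from .rules import Cutoff, PredictionScore, ScoredRule, ScoredRuleSet

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_labeled_windows",
    "write_labeled_windows",
    "write_ranking",
    "write_rule_table",
    "write_scan_predictions",
    "write_st_predictions",
    "save_predictor",
    "load_predictor",
]

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Reusable training configuration, serializable as YAML.

    All seeds are explicit so a run documented by its config file is
    reproducible exactly.
    """

    kind: str = "tfbs"
    k: int = 22
    C: float = 1.0
    exact_limit: int = 16
    heuristic_limit: int = 22
    contradiction_policy: str = "drop"
    cutoff_mode: str = "all_rules"
    cutoff_fraction: float | None = None
    cutoff_min_score: int | None = None
    rfe_step: int = 1
    train_fraction: float = 0.9
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.heuristic_limit:
            raise ValueError(
                f"k={self.k} exceeds heuristic_limit={self.heuristic_limit}"
            )
        if self.kind not in ("tfbs", "glyco"):
            raise ValueError(f"unknown kind {self.kind!r}")

    def cutoff(self) -> Cutoff:
        return Cutoff(
            mode=self.cutoff_mode,
            fraction=self.cutoff_fraction,
            min_score=self.cutoff_min_score,
        )

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Multi-record FASTA → list of (id, uppercased sequence)."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_labeled_windows(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Tab-separated ``sequence<TAB>label`` (no header) → windows, labels."""
    df = pd.read_csv(path, sep="\t", header=None, names=["window", "label"])
    return df["window"].astype(str).tolist(), df["label"].to_numpy(dtype=np.int8)


def write_labeled_windows(
    windows: Sequence[str], labels: Sequence[int], path: PathLike
) -> None:
    pd.DataFrame({"window": windows, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_ranking(
    ranking_table: pd.DataFrame, path: PathLike
) -> None:
    """Rank / variable-index / meaning TSV."""
    ranking_table.to_csv(path, sep="\t", index=False)


def write_rule_table(
    rs: ScoredRuleSet, path: PathLike, site_name: str = "site"
) -> None:
    """Cube, score and rendered conditions, one rule per line."""
    rows = []
    for i, rule in enumerate(rs, start=1):
        conds = []
        for j, lit in enumerate(rule.cube.literals):
            if lit == "-":
                continue
            if rs.meanings:
                conds.append(rs.meanings[j].render(int(lit)))
            else:
                conds.append(f"x{j + 1}={lit}")
        rows.append(
            {
                "rule": i,
                "cube": rule.cube.literals,
                "score": rule.score,
                "conditions": " and ".join(conds) if conds else "always",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scan_predictions(
    scores: Sequence[PredictionScore],
    seq_id: str,
    window_length: int,
    path: PathLike,
    positive_only: bool = True,
) -> None:
    """BED-like TSV of scan results: id, start, end (1-based inclusive),
    score, rules hit."""
    rows = [
        {
            "sequence": seq_id,
            "start": s.pattern_id,
            "end": int(s.pattern_id) + window_length - 1,
            "score": s.score,
            "rules_hit": s.n_rules_hit,
        }
        for s in scores
        if (s.score > 0 or not positive_only)
    ]
    pd.DataFrame(
        rows, columns=["sequence", "start", "end", "score", "rules_hit"]
    ).to_csv(path, sep="\t", index=False)


def write_st_predictions(
    df: pd.DataFrame, protein_id: str, path: PathLike
) -> None:
    out = df.copy()
    out.insert(0, "protein", protein_id)
    out.to_csv(path, sep="\t", index=False)


# --- predictor persistence ---------------------------------------------------


def save_predictor(predictor: SitePredictor, path: PathLike) -> None:
    doc = {
        "format": "sitelogic-predictor",
        "version": 1,
        "kind": predictor.kind,
        "window_length": predictor.window_length,
        "center": predictor.center,
        "selected": list(predictor.selected),
        "rules": [
            {"cube": r.cube.literals, "score": r.score}
            for r in predictor.ruleset
        ],
        "cutoff": {
            "mode": predictor.cutoff.mode,
            "fraction": predictor.cutoff.fraction,
            "min_score": predictor.cutoff.min_score,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_predictor(path: PathLike) -> SitePredictor:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "sitelogic-predictor":
        raise ValueError(f"{path} is not a sitelogic predictor file")
    kind = doc["kind"]
    meaning_kind = "dna" if kind == "tfbs" else "protein"
    selected = [int(i) for i in doc["selected"]]
    meanings = tuple(variable_meaning(i + 1, meaning_kind) for i in selected)
    ruleset = ScoredRuleSet(
        rules=tuple(
            ScoredRule(cube=Cube(r["cube"]), score=int(r["score"]))
            for r in doc["rules"]
        ),
        n_vars=len(selected),
        meanings=meanings,
    )
    c = doc.get("cutoff") or {}
    cutoff = Cutoff(
        mode=c.get("mode", "all_rules"),
        fraction=c.get("fraction"),
        min_score=c.get("min_score"),
    )
    return SitePredictor(
        kind=kind,
        window_length=int(doc["window_length"]),
        center=doc.get("center"),
        selected=tuple(selected),
        ruleset=ruleset,
        cutoff=cutoff,
    )
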