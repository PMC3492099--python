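"""One-hot binary encodings of sequence windows and continuous features.

DNA windows are encoded 4 bits per nucleotide (A→1000, C→0100, G→0010,
T→0001), so a 14-nt binding-site window becomes 56 binary variables.
Protein windows are encoded 21 bits per residue: the 20 standard amino
acids ranked by the alphabetical order of their *full* names
(Ala, Arg, Asn, Asp, Cys, Gln, Glu, Gly, His, Ile, Leu, Lys, Met, Phe,
Pro, Ser, Thr, Trp, Tyr, Val) plus an UNKNOWN category at rank 21 for
incomplete sequences, so an 11-residue window becomes 231 variables.

Every binary variable has a direct biological reading ("Nucleotide 7 is/is
not C"); this interpretability is the point of the one-hot scheme, and the
reason denser encodings are deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "UNKNOWN_RESIDUE",
    "BitVector",
    "VariableMeaning",
    "EncodedDataset",
    "CleaningReport",
    "encode_dna",
    "decode_dna",
    "encode_protein",
    "decode_protein",
    "variable_index",
    "variable_meaning",
    "dna_meanings",
    "protein_meanings",
    "binarize_continuous",
    "clean_dataset",
]

DNA_ALPHABET = "ACGT"

# one-letter codes ordered by full amino-acid name:
# Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
UNKNOWN_RESIDUE = "X"
_PROTEIN_RANKS = PROTEIN_ALPHABET + UNKNOWN_RESIDUE  # rank 21 = unknown

PROTEIN_WINDOW = 11  # residues -5..+5 around the central S/T
PROTEIN_BLOCK = 21


@dataclass(frozen=True)
class BitVector:
    """An ordered sequence of bits with a fixed width."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))

    @property
    def width(self) -> int:
        return len(self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)

    def __getitem__(self, i):
        return self.bits[i]

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)


@dataclass(frozen=True)
class VariableMeaning:
    """Human-readable meaning of one binary variable.

    ``index`` is 1-based; ``window_position`` is the 1-based nucleotide slot
    for DNA or the signed offset (−5..+5, 0 = central S/T) for protein.
    """

    index: int
    window_position: int
    symbol: str
    kind: Literal["dna", "protein"]

    @property
    def description(self) -> str:
        if self.kind == "dna":
            return f"Nucleotide {self.window_position} is/is not {self.symbol}"
        sym = "UNKNOWN" if self.symbol == UNKNOWN_RESIDUE else self.symbol
        return (
            f"Amino Acid in Position {self.window_position} is/is not {sym}"
        )

    def render(self, value: int) -> str:
        """Condition text for a fixed literal value (1 → is, 0 → is not)."""
        verb = "is" if value else "is not"
        if self.kind == "dna":
            return f"Nucleotide {self.window_position} {verb} {self.symbol}"
        sym = "UNKNOWN" if self.symbol == UNKNOWN_RESIDUE else self.symbol
        return f"Amino Acid in Position {self.window_position} {verb} {sym}"


@dataclass
class CleaningReport:
    """What :func:`clean_dataset` merged or removed."""

    merged_duplicates: list[tuple[str, int, int]] = field(default_factory=list)
    #: (pattern, label, multiplicity) groups collapsed to one instance
    removed_contradictions: list[tuple[str, dict[int, int]]] = field(
        default_factory=list
    )
    #: (pattern, {label: count}) groups dropped or tie-removed
    resolved_majority: list[tuple[str, int, dict[int, int]]] = field(
        default_factory=list
    )
    #: (pattern, winning label, {label: count}) under the majority policy
    empty_output: bool = False


@dataclass
class EncodedDataset:
    """A binary pattern matrix with labels, meanings and multiplicities.

    ``patterns`` is an ``(n, width)`` uint8 matrix; ``multiplicity[i]``
    counts how many raw examples collapsed into row ``i`` (1 before
    cleaning).  ``meanings`` carries the per-column biological reading.
    """

    patterns: np.ndarray
    labels: np.ndarray
    meanings: list[VariableMeaning]
    multiplicity: Optional[np.ndarray] = None
    provenance: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.ndim != 2:
            self.patterns = self.patterns.reshape(len(self.labels), -1)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.patterns):
            raise ValueError("labels and patterns length mismatch")
        if self.meanings and len(self.meanings) != self.width:
            raise ValueError("meanings length != pattern width")
        if self.multiplicity is None:
            self.multiplicity = np.ones(len(self.labels), dtype=np.int64)
        else:
            self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)
        if self.provenance is not None and len(self.provenance) != len(self.labels):
            raise ValueError("provenance length mismatch")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def width(self) -> int:
        return self.patterns.shape[1] if self.patterns.size else (
            len(self.meanings) if self.meanings else 0
        )

    def pattern_strings(self) -> list[str]:
        return ["".join(str(int(b)) for b in row) for row in self.patterns]


# --- sequence encodings ------------------------------------------------------


def encode_dna(seq: str) -> BitVector:
    """One-hot encode a DNA string, 4 bits per nucleotide (A,C,G,T order)."""
    bits: list[int] = []
    for pos, ch in enumerate(seq.upper(), start=1):
        try:
            rank = DNA_ALPHABET.index(ch)
        except ValueError:
            raise ValueError(
                f"non-ACGT character {ch!r} at position {pos}"
            ) from None
        block = [0, 0, 0, 0]
        block[rank] = 1
        bits.extend(block)
    return BitVector(tuple(bits))


def decode_dna(bv: BitVector | Sequence[int]) -> str:
    bits = list(bv)
    if len(bits) % 4:
        raise ValueError("bit width not a multiple of 4")
    out = []
    for i in range(0, len(bits), 4):
        block = bits[i : i + 4]
        if sum(block) != 1:
            raise ValueError(f"block {i // 4 + 1} is not one-hot")
        out.append(DNA_ALPHABET[block.index(1)])
    return "".join(out)


def encode_protein(window: str) -> BitVector:
    """One-hot encode an 11-residue window, 21 bits per residue.

    Residues are the 20 standard amino acids plus ``X`` for unknown
    (rank 21), used to pad windows truncated by protein ends.
    """
    window = window.upper()
    if len(window) != PROTEIN_WINDOW:
        raise ValueError(
            f"protein window must be {PROTEIN_WINDOW} residues, got {len(window)}"
        )
    bits: list[int] = []
    for pos, ch in enumerate(window, start=1):
        try:
            rank = _PROTEIN_RANKS.index(ch)
        except ValueError:
            raise ValueError(
                f"unrecognized residue {ch!r} at window slot {pos}"
            ) from None
        block = [0] * PROTEIN_BLOCK
        block[rank] = 1
        bits.extend(block)
    return BitVector(tuple(bits))


def decode_protein(bv: BitVector | Sequence[int]) -> str:
    bits = list(bv)
    if len(bits) % PROTEIN_BLOCK:
        raise ValueError("bit width not a multiple of 21")
    out = []
    for i in range(0, len(bits), PROTEIN_BLOCK):
        block = bits[i : i + PROTEIN_BLOCK]
        if sum(block) != 1:
            raise ValueError(f"block {i // PROTEIN_BLOCK + 1} is not one-hot")
        out.append(_PROTEIN_RANKS[block.index(1)])
    return "".join(out)


# --- variable meanings -------------------------------------------------------


def _protein_position(block: int) -> int:
    """Window slot 1..11 → signed offset −5..+5 (slot 6 = central S/T)."""
    return block - 6


def variable_index(
    window_position: int, symbol: str, kind: Literal["dna", "protein"]
) -> int:
    """1-based variable index of (window position, symbol) under the layout
    ``index = (block − 1) · alphabet_size + symbol_rank``."""
    symbol = symbol.upper()
    if kind == "dna":
        block = window_position
        rank = DNA_ALPHABET.index(symbol) + 1
        return (block - 1) * 4 + rank
    block = window_position + 6
    if not 1 <= block <= PROTEIN_WINDOW:
        raise ValueError(f"protein position {window_position} outside −5..+5")
    rank = _PROTEIN_RANKS.index(symbol) + 1
    return (block - 1) * PROTEIN_BLOCK + rank


def variable_meaning(
    index: int, kind: Literal["dna", "protein"]
) -> VariableMeaning:
    """Invert the encoding layout: variable index → (position, symbol)."""
    if kind == "dna":
        alphabet, size = DNA_ALPHABET, 4
    elif kind == "protein":
        alphabet, size = _PROTEIN_RANKS, PROTEIN_BLOCK
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if index < 1:
        raise ValueError("variable index is 1-based")
    block, rank = divmod(index - 1, size)
    block += 1
    if kind == "dna":
        pos = block
    else:
        if block > PROTEIN_WINDOW:
            raise ValueError(f"index {index} beyond the 231-bit protein layout")
        pos = _protein_position(block)
    return VariableMeaning(
        index=index, window_position=pos, symbol=alphabet[rank], kind=kind
    )


def dna_meanings(window: int = 14) -> list[VariableMeaning]:
    return [variable_meaning(i, "dna") for i in range(1, 4 * window + 1)]


def protein_meanings() -> list[VariableMeaning]:
    return [
        variable_meaning(i, "protein")
        for i in range(1, PROTEIN_BLOCK * PROTEIN_WINDOW + 1)
    ]


# --- continuous features -----------------------------------------------------


def binarize_continuous(
    values: np.ndarray,
    thresholds: Sequence[Sequence[float]],
    labels: Optional[Sequence[int]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> EncodedDataset:
    """Threshold continuous features into bits.

    One threshold ``t`` for a feature yields one bit (1 iff value > t);
    ``k ≥ 2`` strictly increasing thresholds yield ``k+1`` one-hot
    interval-membership bits (below the first, between consecutive
    thresholds, above the last).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, p = values.shape
    if len(thresholds) != p:
        raise ValueError("one threshold list per feature required")
    for ts in thresholds:
        if list(ts) != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError(f"thresholds must be strictly increasing: {ts}")
    cols: list[np.ndarray] = []
    meanings: list[VariableMeaning] = []
    names = feature_names or [f"F{j + 1}" for j in range(p)]
    for j, ts in enumerate(thresholds):
        x = values[:, j]
        if len(ts) == 1:
            cols.append((x > ts[0]).astype(np.uint8))
        else:
            # one-hot interval membership: (<t1), [t1,t2], ..., (>tk);
            # threshold values themselves land in a closed interior interval
            k = len(ts)
            tarr = np.asarray(ts, dtype=float)
            idx = np.minimum(np.searchsorted(tarr, x, side="right"), k - 1)
            idx[x < tarr[0]] = 0
            idx[x > tarr[-1]] = k
            for b in range(k + 1):
                cols.append((idx == b).astype(np.uint8))
    patterns = np.column_stack(cols) if cols else np.zeros((n, 0), np.uint8)
    y = np.zeros(n, dtype=np.int8) if labels is None else np.asarray(labels)
    return EncodedDataset(patterns=patterns, labels=y, meanings=[])


# --- contradiction / duplicate cleaning --------------------------------------


def clean_dataset(
    ds: EncodedDataset, policy: Literal["drop", "majority"] = "drop"
) -> tuple[EncodedDataset, CleaningReport]:
    """Collapse duplicate patterns and resolve label contradictions.

    Logic minimization requires a function: one output per input pattern.
    Duplicates collapse to a single row whose multiplicity is retained
    (rule scores need occurrence counts).  Pattern groups seen with both
    labels are removed outright (``drop``, the conservative default) or
    resolved to the majority label with ties removed (``majority``).
    """
    report = CleaningReport()
    groups: dict[str, dict[int, int]] = {}
    order: list[str] = []
    for row, y, mult in zip(ds.patterns, ds.labels, ds.multiplicity):
        key = "".join(str(int(b)) for b in row)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        groups[key][int(y)] = groups[key].get(int(y), 0) + int(mult)
    keep_rows: list[str] = []
    keep_labels: list[int] = []
    keep_mult: list[int] = []
    for key in order:
        counts = groups[key]
        if len(counts) == 1:
            (label, count), = counts.items()
            if count > 1:
                report.merged_duplicates.append((key, label, count))
            keep_rows.append(key)
            keep_labels.append(label)
            keep_mult.append(count)
            continue
        if policy == "drop":
            report.removed_contradictions.append((key, dict(counts)))
            continue
        c0, c1 = counts.get(0, 0), counts.get(1, 0)
        if c0 == c1:
            report.removed_contradictions.append((key, dict(counts)))
            continue
        winner = 1 if c1 > c0 else 0
        report.resolved_majority.append((key, winner, dict(counts)))
        keep_rows.append(key)
        keep_labels.append(winner)
        keep_mult.append(counts[winner])
    if keep_rows:
        patterns = np.array(
            [[int(c) for c in key] for key in keep_rows], dtype=np.uint8
        )
    else:
        patterns = np.zeros((0, ds.width), dtype=np.uint8)
        report.empty_output = True
    cleaned = EncodedDataset(
        patterns=patterns,
        labels=np.asarray(keep_labels, dtype=np.int8),
        meanings=list(ds.meanings),
        multiplicity=np.asarray(keep_mult, dtype=np.int64),
    )
    return cleaned, report
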