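"""Seeded synthetic datasets with the structure of the two case studies.

The original training data — 73 SOX9 binding sites from TRANSFAC and
the OGLYCBASE/Swiss-Prot serine/threonine windows — are not
redistributable, so this module generates stand-ins with the same
statistical shape:

* **TFBS**: 14-nt motif instances built from a consensus with a handful of
  fixed positions (default: positions 6–10, echoing the window region the
  minimized rules concentrate on) subject to a small per-position mutation
  rate, implanted without overlap into i.i.d. background DNA.
* **O-glycosylation**: 11-residue windows centered on S or T whose flanking
  residues follow positional enrichment weights (default: threonine and
  proline enriched at alternating offsets, the pattern the most popular
  extracted rules exhibit); negatives draw flanks uniformly.

Everything is driven by :class:`numpy.random.Generator` seeds and is fully
reproducible.  These generators emulate the *signal structure* of the real
data, not its phylogeny or composition biases; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoding import DNA_ALPHABET, PROTEIN_ALPHABET, UNKNOWN_RESIDUE

__all__ = [
    "MotifSpec",
    "GlycoSpec",
    "generate_background_dna",
    "sample_motif_instance",
    "implant_motifs",
    "generate_glyco_dataset",
]

_DEFAULT_FIXED = {6: "G", 7: "C", 8: "A", 9: "A", 10: "T"}


@dataclass(frozen=True)
class MotifSpec:
    """A consensus-core motif model for 14-nt binding-site windows.

    ``fixed_positions`` maps 1-based window slots to their consensus
    nucleotide; each fixed slot independently mutates to a uniformly chosen
    other base with probability ``mutation_rate``.  Non-fixed slots draw
    from ``background`` (A,C,G,T frequencies).
    """

    length: int = 14
    fixed_positions: dict[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_FIXED)
    )
    mutation_rate: float = 0.05
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0,1]")
        for pos, base in self.fixed_positions.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"fixed position {pos} outside 1..{self.length}")
            if base not in DNA_ALPHABET:
                raise ValueError(f"invalid consensus base {base!r}")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector")


@dataclass(frozen=True)
class GlycoSpec:
    """Positional residue-preference model for 11-residue S/T windows.

    ``preferences`` maps signed positions (−5..+5, excluding 0) to
    ``{residue: weight}`` enrichment multipliers applied on top of a
    uniform base for positive windows; unlisted residues keep weight 1.
    The central residue is fixed to ``center``.  The default preferences
    echo the threonine/proline periodicity of mucin-type acceptor sites
    (T favored at −4, −2, +2, +4; disfavored at +1, +3, +5), with the
    favored-position weight set so that roughly a third of positive
    windows carry the full periodic pattern — the prevalence the most
    popular extracted rule exhibits on real threonine acceptor data.
    """

    center: str = "T"
    preferences: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            -4: {"T": 60.0},
            -2: {"T": 60.0},
            1: {"T": 0.05, "P": 3.0},
            2: {"T": 60.0},
            3: {"T": 0.05, "P": 3.0},
            4: {"T": 60.0},
            5: {"T": 0.05},
        }
    )
    n_pos: int = 500
    n_neg: int = 500
    unknown_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.center not in ("S", "T"):
            raise ValueError("center must be 'S' or 'T'")
        if not 0 <= self.unknown_rate <= 1:
            raise ValueError("unknown_rate must be in [0,1]")
        for pos, table in self.preferences.items():
            if pos == 0 or not -5 <= pos <= 5:
                raise ValueError(f"preference position {pos} outside ±1..±5")
            for res, w in table.items():
                if res not in PROTEIN_ALPHABET:
                    raise ValueError(f"unknown residue {res!r}")
                if w <= 0:
                    raise ValueError("weights must be positive")


def generate_background_dna(
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Random DNA with i.i.d. base draws from ``composition`` (A,C,G,T)."""
    if length <= 0:
        raise ValueError("length must be positive")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or comp.min() < 0 or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("composition must be 4 nonnegative values summing to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=comp)
    bases = np.array(list(DNA_ALPHABET))
    return "".join(bases[idx])


def sample_motif_instance(spec: MotifSpec, rng: np.random.Generator) -> str:
    """One motif instance: consensus at fixed slots (mutated at the given
    rate), background draws elsewhere."""
    bases = np.array(list(DNA_ALPHABET))
    out = list(
        bases[rng.choice(4, size=spec.length, p=np.asarray(spec.background))]
    )
    for pos, base in spec.fixed_positions.items():
        if rng.random() < spec.mutation_rate:
            others = [b for b in DNA_ALPHABET if b != base]
            out[pos - 1] = others[rng.integers(len(others))]
        else:
            out[pos - 1] = base
    return "".join(out)


def implant_motifs(
    background: str,
    spec: MotifSpec,
    n_sites: int,
    min_gap: int = 10,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    instances: Optional[Sequence[str]] = None,
) -> tuple[str, list[int]]:
    """Write ``n_sites`` non-overlapping motif instances into a sequence.

    Returns the edited sequence and the sorted 1-based start positions.
    ``instances``, if given, supplies the site sequences verbatim (e.g.
    held-out training sites); otherwise they are sampled from ``spec``.
    Implant positions are drawn uniformly, rejecting placements closer
    than ``min_gap`` to an accepted one.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(background)
    if instances is not None and len(instances) != n_sites:
        raise ValueError("len(instances) != n_sites")
    if n_sites * (spec.length + min_gap) > L:
        raise ValueError("cannot pack that many sites into the background")
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_sites:
        attempts += 1
        if attempts > 10000 * max(1, n_sites):
            raise ValueError("implant packing failed; loosen min_gap")
        s = int(rng.integers(0, L - spec.length + 1))
        if all(abs(s - t) >= spec.length + min_gap for t in starts):
            starts.append(s)
    starts.sort()
    seq = list(background)
    for i, s in enumerate(starts):
        inst = (
            instances[i] if instances is not None else sample_motif_instance(spec, rng)
        )
        if len(inst) != spec.length:
            raise ValueError("instance length != motif length")
        seq[s : s + spec.length] = list(inst)
    return "".join(seq), [s + 1 for s in starts]  # 1-based starts


def _positive_window(spec: GlycoSpec, rng: np.random.Generator) -> str:
    out = []
    for pos in range(-5, 6):
        if pos == 0:
            out.append(spec.center)
            continue
        weights = np.ones(len(PROTEIN_ALPHABET))
        for res, w in spec.preferences.get(pos, {}).items():
            weights[PROTEIN_ALPHABET.index(res)] = w
        weights /= weights.sum()
        out.append(PROTEIN_ALPHABET[rng.choice(len(PROTEIN_ALPHABET), p=weights)])
    return "".join(out)


def _negative_window(spec: GlycoSpec, rng: np.random.Generator) -> str:
    flanks = [
        PROTEIN_ALPHABET[i]
        for i in rng.integers(0, len(PROTEIN_ALPHABET), size=10)
    ]
    return "".join(flanks[:5]) + spec.center + "".join(flanks[5:])


def generate_glyco_dataset(
    spec: GlycoSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], np.ndarray]:
    """Labeled 11-residue windows: positives follow the preference table,
    negatives draw flanks uniformly; both share the central residue.

    With ``unknown_rate > 0`` each flank residue is independently replaced
    by the UNKNOWN symbol, emulating windows truncated at protein ends.
    """
    if spec.n_pos <= 0 or spec.n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    windows: list[str] = []
    for _ in range(spec.n_pos):
        windows.append(_positive_window(spec, rng))
    for _ in range(spec.n_neg):
        windows.append(_negative_window(spec, rng))
    if spec.unknown_rate > 0:
        masked = []
        for w in windows:
            chars = list(w)
            for i in range(11):
                if i != 5 and rng.random() < spec.unknown_rate:
                    chars[i] = UNKNOWN_RESIDUE
            masked.append("".join(chars))
        windows = masked
    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg, dtype=np.int8)
    return windows, labels
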