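"""Berkeley PLA format: the function-table interchange of espresso-family
tools.

A PLA file declares the input/output widths (``.i``/``.o``), optional
variable labels (``.ilb``/``.ob``), the logical type (``.type``), then one
line per product term: the input part over ``{0,1,-}`` and the output part
over ``{0,1,-}``, ending with ``.e``.

``type fr`` (the canonical interchange here) lists the on-set (output 1)
and off-set (output 0) explicitly; every unlisted input pattern is a
don't-care.  This sidesteps materializing all :math:`2^n` rows — over four
million already at n=22 — while carrying exactly the partially specified
function the minimizer needs.  An explicit materialization path exists for
small n, guarded by a row-count cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .logic import Cover, Cube, TruthFunction

__all__ = [
    "PLADocument",
    "PLAParseError",
    "MaterializeError",
    "read_pla",
    "write_pla",
    "truth_function_to_pla",
    "pla_to_truth_function",
    "cover_to_pla",
    "pla_to_cover",
    "table_rows",
    "DEFAULT_MATERIALIZE_CAP",
]

DEFAULT_MATERIALIZE_CAP = 1 << 16


class PLAParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MaterializeError(ValueError):
    """Refused to write a complete truth table: too many rows."""


@dataclass
class PLADocument:
    n_inputs: int
    n_outputs: int = 1
    input_labels: Optional[list[str]] = None
    output_labels: Optional[list[str]] = None
    cubes: list[tuple[str, str]] = field(default_factory=list)
    type: str = "fr"

    def __post_init__(self) -> None:
        if self.input_labels is not None:
            if len(self.input_labels) != self.n_inputs:
                raise ValueError(".ilb label count != .i")
            if len(set(self.input_labels)) != self.n_inputs:
                raise ValueError("duplicate input labels")
        if self.output_labels is not None and (
            len(self.output_labels) != self.n_outputs
        ):
            raise ValueError(".ob label count != .o")
        for i, (ins, outs) in enumerate(self.cubes):
            if len(ins) != self.n_inputs:
                raise ValueError(f"cube {i + 1}: input width != .i")
            if len(outs) != self.n_outputs:
                raise ValueError(f"cube {i + 1}: output width != .o")
            if set(ins) - set("01-") or set(outs) - set("01-~"):
                raise ValueError(f"cube {i + 1}: invalid characters")


def read_pla(text: str) -> PLADocument:
    """Parse PLA text; unknown directives and width mismatches raise
    :class:`PLAParseError` with the offending line number."""
    n_inputs: Optional[int] = None
    n_outputs = 1
    ilb: Optional[list[str]] = None
    ob: Optional[list[str]] = None
    pla_type = "fr"
    declared_p: Optional[int] = None
    cubes: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("."):
            parts = line.split()
            directive = parts[0]
            if directive == ".i":
                n_inputs = int(parts[1])
            elif directive == ".o":
                n_outputs = int(parts[1])
            elif directive == ".ilb":
                ilb = parts[1:]
            elif directive == ".ob":
                ob = parts[1:]
            elif directive == ".type":
                pla_type = parts[1]
            elif directive == ".p":
                declared_p = int(parts[1])
            elif directive in (".e", ".end"):
                break
            else:
                raise PLAParseError(f"unknown directive {directive}", lineno)
            continue
        if n_inputs is None:
            raise PLAParseError("cube line before .i declaration", lineno)
        parts = line.split()
        if len(parts) == 1 and n_outputs == 0:
            ins, outs = parts[0], ""
        elif len(parts) >= 2:
            ins, outs = parts[0], "".join(parts[1:])
        else:
            raise PLAParseError("cube line missing output part", lineno)
        if len(ins) != n_inputs:
            raise PLAParseError(
                f"input part width {len(ins)} != .i {n_inputs}", lineno
            )
        if len(outs) != n_outputs:
            raise PLAParseError(
                f"output part width {len(outs)} != .o {n_outputs}", lineno
            )
        if set(ins) - set("01-"):
            raise PLAParseError("invalid input characters", lineno)
        cubes.append((ins, outs))
    if n_inputs is None:
        raise PLAParseError("missing .i declaration", 1)
    if declared_p is not None and declared_p != len(cubes):
        raise PLAParseError(
            f".p declares {declared_p} terms but {len(cubes)} found", 1
        )
    return PLADocument(
        n_inputs=n_inputs,
        n_outputs=n_outputs,
        input_labels=ilb,
        output_labels=ob,
        cubes=cubes,
        type=pla_type,
    )


def write_pla(doc: PLADocument) -> str:
    lines = [f".i {doc.n_inputs}", f".o {doc.n_outputs}"]
    if doc.input_labels:
        lines.append(".ilb " + " ".join(doc.input_labels))
    if doc.output_labels:
        lines.append(".ob " + " ".join(doc.output_labels))
    lines.append(f".type {doc.type}")
    lines.append(f".p {len(doc.cubes)}")
    for ins, outs in doc.cubes:
        lines.append(f"{ins} {outs}")
    lines.append(".e")
    return "\n".join(lines) + "\n"


def table_rows(n_inputs: int) -> int:
    """Rows of the complete function table over ``n_inputs`` variables."""
    if n_inputs < 0:
        raise ValueError("n_inputs must be nonnegative")
    return 1 << n_inputs


def truth_function_to_pla(
    f: TruthFunction,
    materialize: bool = False,
    materialize_cap: int = DEFAULT_MATERIALIZE_CAP,
    input_labels: Optional[Sequence[str]] = None,
) -> PLADocument:
    """Serialize a partially specified function.

    By default only the on-set and off-set minterms are written
    (``type fr``; the rest is don't-care by convention).  With
    ``materialize=True`` every minterm gets a row (``type fd``-style
    explicitness), refused when the table would exceed
    ``materialize_cap`` rows.
    """
    n = f.n_vars
    cubes: list[tuple[str, str]] = []

    def mt(m: int) -> str:
        return format(m, f"0{n}b")

    if materialize:
        rows = table_rows(n)
        if rows > materialize_cap:
            raise MaterializeError(
                f"complete table over {n} inputs has {rows:,} rows, "
                f"exceeding the cap of {materialize_cap:,}; "
                "write type-fr with implicit don't-cares instead"
            )
        for m in range(rows):
            out = "1" if m in f.on_set else ("0" if m in f.off_set else "-")
            cubes.append((mt(m), out))
    else:
        for m in sorted(f.on_set):
            cubes.append((mt(m), "1"))
        for m in sorted(f.off_set):
            cubes.append((mt(m), "0"))
    return PLADocument(
        n_inputs=n,
        n_outputs=1,
        input_labels=list(input_labels) if input_labels else None,
        cubes=cubes,
        type="fr",
    )


def pla_to_truth_function(doc: PLADocument, expand_limit: int = 20) -> TruthFunction:
    """Interpret a single-output PLA as an on/off/dc partition.

    Cube input parts are expanded to minterms, so the width is capped at
    ``expand_limit`` to keep this honest for interchange-size files.
    """
    if doc.n_outputs != 1:
        raise ValueError("only single-output PLAs map to a TruthFunction")
    if doc.n_inputs > expand_limit:
        raise ValueError(
            f"{doc.n_inputs} inputs exceeds the {expand_limit}-input expansion cap"
        )
    on: set[int] = set()
    off: set[int] = set()
    dc: set[int] = set()
    for ins, outs in doc.cubes:
        target = {"1": on, "0": off, "-": dc, "~": dc}[outs]
        target.update(Cube(ins).minterms())
    dc -= on | off
    off -= on
    explicit_dc = frozenset(dc) if dc else None
    return TruthFunction(
        n_vars=doc.n_inputs,
        on_set=frozenset(on),
        off_set=frozenset(off),
        dc_set=explicit_dc,
    )


def cover_to_pla(
    cover: Cover, input_labels: Optional[Sequence[str]] = None
) -> PLADocument:
    """A minimized cover as a PLA: one line per cube, output 1."""
    return PLADocument(
        n_inputs=cover.n_vars,
        n_outputs=1,
        input_labels=list(input_labels) if input_labels else None,
        cubes=[(c.literals, "1") for c in cover],
        type="fr",
    )


def pla_to_cover(doc: PLADocument) -> Cover:
    if doc.n_outputs != 1:
        raise ValueError("only single-output PLAs map to a Cover")
    cubes = tuple(Cube(ins) for ins, outs in doc.cubes if outs == "1")
    return Cover(cubes, doc.n_inputs)
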