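"""Sequence maps: grid layout of per-residue annotations.

A sequence map lays out one value per residue (a discrete class label or
a real number) on a row-major grid so an entire protein can be inspected
at once. The layout — not any rendered image — is the contract: cells
cover positions 1..length exactly once with
``position = (row - 1) * n_columns + column``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence as TypingSequence

import pandas as pd

from .errors import FormatError, ValidationError
from .sequence import ProteinSequence


@dataclass(frozen=True)
class Cell:
    position: int  # 1-based
    row: int  # 1-based
    column: int  # 1-based
    residue: str
    value: object


@dataclass(frozen=True)
class Annotation:
    """A text marker over a 1-based inclusive position range."""

    start: int
    end: int
    text: str


@dataclass(frozen=True)
class SequenceMapLayout:
    sequence_id: str
    cells: tuple[Cell, ...]
    n_columns: int
    annotations: tuple[Annotation, ...] = ()

    def flatten(self) -> tuple[str, list]:
        """Residue string and value list in (row, column) order.

        Round-trips the inputs of :func:`build_sequence_map` exactly.
        """
        ordered = sorted(self.cells, key=lambda c: (c.row, c.column))
        return "".join(c.residue for c in ordered), [c.value for c in ordered]

    def n_rows(self) -> int:
        return max(c.row for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [c.position for c in self.cells],
                "row": [c.row for c in self.cells],
                "column": [c.column for c in self.cells],
                "residue": [c.residue for c in self.cells],
                "value": [c.value for c in self.cells],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_sequence_map(
    seq: ProteinSequence,
    values: TypingSequence,
    n_columns: int,
    annotations: TypingSequence[Annotation] | None = None,
) -> SequenceMapLayout:
    """Row-major grid of per-residue values (last row may be partial)."""
    if n_columns < 1:
        raise ValidationError(f"n_columns must be positive, got {n_columns}")
    if len(values) != len(seq):
        raise ValidationError(
            f"values length {len(values)} does not match sequence length {len(seq)}"
        )
    anns = tuple(annotations or ())
    for ann in anns:
        if not (1 <= ann.start <= ann.end <= len(seq)):
            raise ValidationError(
                f"annotation {ann.text!r} range {ann.start}..{ann.end} "
                f"outside 1..{len(seq)}"
            )
    cells = tuple(
        Cell(
            position=pos,
            row=(pos - 1) // n_columns + 1,
            column=(pos - 1) % n_columns + 1,
            residue=seq.residues[pos - 1],
            value=values[pos - 1],
        )
        for pos in range(1, len(seq) + 1)
    )
    return SequenceMapLayout(seq.id, cells, n_columns, anns)


def load_annotations(path: str | Path) -> list[Annotation]:
    """Read annotations from ``start<TAB>end<TAB>text`` lines."""
    path = Path(path)
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 'start<TAB>end<TAB>text', got {line!r}"
            )
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer range bounds") from None
        out.append(Annotation(start, end, parts[2]))
    return out
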