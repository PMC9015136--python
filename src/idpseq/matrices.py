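"""Amino-acid substitution matrices.

Reads, validates and writes square scoring matrices in the
NCBI/EMBOSS-style whitespace-delimited text format (header row of
residue codes, one labelled row per residue, '#' comment lines).
Standard BLOSUM/PAM files parse directly, as do IDP-derived matrices
(EDSSMat, Disorder, DUNMat families) distributed in the same format.
The matrix values themselves are not bundled here; matrices are loaded
from user-supplied files and handed to external alignment code.

:func:`score_aligned_pair` scores a pre-aligned pair with affine gap
penalties so matrices can be exercised without an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

from .errors import FormatError, ValidationError

GAP = "-"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix over an ordered alphabet."""

    name: str
    alphabet: tuple[str, ...]
    scores: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(self, "scores", MappingProxyType(dict(self.scores)))
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ValidationError(
                        f"matrix {self.name!r}: missing score for pair ({a}, {b})"
                    )
        for a in self.alphabet:
            for b in self.alphabet:
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValidationError(
                        f"matrix {self.name!r} is asymmetric at ({a}, {b}): "
                        f"{self.scores[(a, b)]} != {self.scores[(b, a)]}"
                    )

    def get(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            bad = a if a not in self.alphabet else b
            raise ValidationError(
                f"residue {bad!r} not in alphabet of matrix {self.name!r}"
            ) from None


def read_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Parse an NCBI/EMBOSS-style square matrix text file."""
    path = Path(path)
    lines = [
        line
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: no matrix content found")
    header = lines[0].split()
    if any(len(tok) != 1 and tok != "*" for tok in header):
        raise FormatError(f"{path}: header must be single-character residue codes")
    alphabet = tuple(header)
    rows = lines[1:]
    if len(rows) != len(alphabet):
        raise FormatError(
            f"{path}: header lists {len(alphabet)} residues but found {len(rows)} rows"
        )
    scores: dict[tuple[str, str], float] = {}
    for i, line in enumerate(rows):
        parts = line.split()
        if len(parts) != len(alphabet) + 1:
            raise FormatError(
                f"{path}: row {i + 1} has {len(parts) - 1} scores, "
                f"expected {len(alphabet)}"
            )
        row_code = parts[0]
        if row_code != alphabet[i]:
            raise FormatError(
                f"{path}: row label {row_code!r} does not match header "
                f"residue {alphabet[i]!r}"
            )
        for j, tok in enumerate(parts[1:]):
            try:
                scores[(row_code, alphabet[j])] = float(tok)
            except ValueError:
                raise FormatError(f"{path}: non-numeric score {tok!r}") from None
    return SubstitutionMatrix(name or path.stem, alphabet, scores)


def write_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write a matrix in the same text format :func:`read_matrix` accepts."""

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with open(path, "w") as fh:
        fh.write(f"# {matrix.name}\n")
        fh.write("   " + "  ".join(matrix.alphabet) + "\n")
        for a in matrix.alphabet:
            row = "  ".join(fmt(matrix.scores[(a, b)]) for b in matrix.alphabet)
            fh.write(f"{a}  {row}\n")


def score_aligned_pair(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Score a pre-aligned (gapped) sequence pair.

    Residue-residue columns score via the matrix; each maximal gap run in
    either sequence costs ``gap_open + (len - 1) * gap_extend``. Penalty
    arguments are the signed amounts added to the score (typically
    negative).
    """
    if len(a) != len(b):
        raise ValidationError(
            f"aligned lengths differ: {len(a)} vs {len(b)}"
        )
    alphabet = set(matrix.alphabet)
    for s in (a, b):
        for ch in s:
            if ch != GAP and ch not in alphabet:
                raise ValidationError(
                    f"residue {ch!r} not in alphabet of matrix {matrix.name!r}"
                )
    total = 0.0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            total += matrix.get(x, y)
    for s, t in ((a, b), (b, a)):
        in_gap = False
        for ch in s:
            if ch == GAP:
                total += gap_extend if in_gap else gap_open
                in_gap = True
            else:
                in_gap = False
    return total
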