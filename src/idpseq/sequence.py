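"""Protein sequence input, validation and normalization.

The universal input type of the package is :class:`ProteinSequence`: an
uppercase one-letter amino-acid string with an identifier. Sequences can
come from plain strings, FASTA files (single or multi record, wrapped or
unwrapped) or, when network access is explicitly enabled, from UniProt.

All residue positions in this package are 1-based and inclusive, matching
the residue numbering conventions of the protein literature (e.g.
"residues 104-140").
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CapabilityError, FormatError, RetrievalError, ValidationError

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Sentinel used by the "mask" unknown-residue policy. Masked positions are
#: excluded from all averages and from any sliding window that covers them.
MASK = "X"

#: Non-standard letters that the "mask" policy replaces with the sentinel.
AMBIGUOUS_AA = frozenset("BJOUXZ")

# UniProt accession syntax (release 2022 rules, both 6- and 10-character forms)
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id:
        Free-text identifier. For FASTA input this is the first
        whitespace-delimited token of the header line.
    residues:
        Uppercase string over the 20 standard one-letter codes, plus the
        mask sentinel ``X`` when the "mask" policy produced it.
    description:
        Full FASTA header (or other free text); informational only.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("sequence is empty after normalization")
        allowed = _STANDARD_SET | {MASK}
        for i, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValidationError(
                    f"illegal residue {ch!r} at position {i} in sequence {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValidationError(
                f"position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]

    def subsequence(self, start: int, end: int, id: str | None = None) -> "ProteinSequence":
        """Residues ``start``..``end``, 1-based inclusive."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValidationError(
                f"range {start}..{end} outside 1..{len(self.residues)}"
            )
        new_id = id if id is not None else f"{self.id}[{start}-{end}]"
        return ProteinSequence(new_id, self.residues[start - 1 : end], self.description)


def parse_sequence(
    raw: str, id: str | None = None, *, policy: str = "strict"
) -> ProteinSequence:
    """Normalize free text into a :class:`ProteinSequence`.

    Whitespace and digits are stripped and letters uppercased, so numbered
    sequence blocks pasted from websites parse directly.

    ``policy`` controls non-standard letters:

    * ``"strict"`` (default): any character outside the 20-letter alphabet
      raises :class:`ValidationError` naming the character and its 1-based
      position in the normalized sequence.
    * ``"mask"``: the ambiguity/rare codes B, J, O, U, X, Z are replaced by
      the sentinel ``X`` (with a warning); masked positions are excluded
      from averages and windowed profiles downstream. Characters outside
      even that extended set still raise.
    """
    if policy not in ("strict", "mask"):
        raise ValidationError(f"unknown residue policy {policy!r}; use 'strict' or 'mask'")
    cleaned = re.sub(r"[\s\d]+", "", raw).upper()
    if not cleaned:
        raise ValidationError("sequence is empty after normalization")
    seq_id = id if id is not None else "seq"
    chars = []
    masked: list[int] = []
    for i, ch in enumerate(cleaned, start=1):
        if ch in _STANDARD_SET:
            chars.append(ch)
        elif policy == "mask" and ch in AMBIGUOUS_AA:
            chars.append(MASK)
            masked.append(i)
        else:
            raise ValidationError(
                f"illegal residue {ch!r} at position {i} in sequence {seq_id!r}"
            )
    if masked:
        warnings.warn(
            f"masked {len(masked)} non-standard residue(s) in {seq_id!r} at "
            f"position(s) {masked}; they are excluded from averages and windows",
            UserWarning,
            stacklevel=2,
        )
    return ProteinSequence(seq_id, "".join(chars), description=id or "")


def read_fasta(path: str | Path, *, policy: str = "strict") -> list[ProteinSequence]:
    """Read all records of a FASTA file, preserving file order.

    The record id is the first whitespace-delimited token of the header;
    the full header is kept as ``description``. Multi-line bodies are
    concatenated.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as e:
        raise FormatError(f"{path}: not a FASTA file ({e})") from None
    if not records:
        raise FormatError(f"{path}: no FASTA records found (no '>' header lines)")
    out = []
    for rec in records:
        body = str(rec.seq)
        if not body:
            raise ValidationError(f"{path}: record {rec.id!r} has an empty body")
        seq = parse_sequence(body, id=rec.id, policy=policy)
        out.append(ProteinSequence(rec.id, seq.residues, description=rec.description))
    return out


def write_fasta(
    sequences: Iterable[ProteinSequence], path: str | Path, *, width: int = 60
) -> None:
    """Write sequences to a FASTA file (wrapped at ``width`` columns)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def fetch_uniprot(
    accession: str, *, network: bool = False, timeout: float = 30.0
) -> ProteinSequence:
    """Fetch the canonical sequence for a UniProt accession.

    Network access is off by default; pass ``network=True`` to enable it.
    The accession is validated against UniProt syntax before any request
    is made.
    """
    if not _UNIPROT_RE.match(accession):
        raise ValidationError(f"{accession!r} is not a valid UniProt accession")
    if not network:
        raise CapabilityError(
            "network access is disabled; call with network=True to fetch from UniProt"
        )
    # stdlib client: this optional convenience must not add a hard dependency
    import urllib.error
    import urllib.request

    url = _UNIPROT_FASTA_URL.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except urllib.error.HTTPError as e:
        raise RetrievalError(f"UniProt returned HTTP {e.code} for {accession}", e.code)
    except urllib.error.URLError as e:
        raise RetrievalError(f"could not reach UniProt: {e.reason}")
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise RetrievalError(f"UniProt response for {accession} is not FASTA")
    header = lines[0][1:]
    body = "".join(lines[1:])
    seq = parse_sequence(body, id=header.split()[0])
    return ProteinSequence(seq.id, seq.residues, description=header)
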