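"""Structural tendency of amino acids.

Disordered proteins are enriched in charged, flexible, hydrophilic and
small residues, while folded proteins favor hydrophobic, aromatic and
disulfide-forming residues. The default scheme classifies:

* disorder-promoting: P, E, S, Q, K, A, G
* order-promoting:    M, N, V, H, L, F, Y, I, W, C
* disorder-neutral:   D, T, R

Users may supply their own scheme as long as the three sets are disjoint
and together cover the 20-letter alphabet exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FormatError, ValidationError
from .sequence import MASK, STANDARD_AA, ProteinSequence

DISORDER_PROMOTING = "disorder-promoting"
ORDER_PROMOTING = "order-promoting"
DISORDER_NEUTRAL = "disorder-neutral"
MASKED_LABEL = "masked"

CLASS_LABELS = (DISORDER_PROMOTING, ORDER_PROMOTING, DISORDER_NEUTRAL)


@dataclass(frozen=True)
class TendencyScheme:
    """Three disjoint residue sets covering the 20-letter alphabet."""

    name: str
    disorder_set: frozenset[str]
    order_set: frozenset[str]
    neutral_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disorder_set", frozenset(self.disorder_set))
        object.__setattr__(self, "order_set", frozenset(self.order_set))
        object.__setattr__(self, "neutral_set", frozenset(self.neutral_set))
        sets = [self.disorder_set, self.order_set, self.neutral_set]
        union = self.disorder_set | self.order_set | self.neutral_set
        total = sum(len(s) for s in sets)
        if total != len(union):
            overlap = sorted(
                (self.disorder_set & self.order_set)
                | (self.disorder_set & self.neutral_set)
                | (self.order_set & self.neutral_set)
            )
            raise ValidationError(
                f"scheme {self.name!r}: classes overlap on {overlap}"
            )
        if union != frozenset(STANDARD_AA):
            missing = sorted(set(STANDARD_AA) - union)
            extra = sorted(union - set(STANDARD_AA))
            raise ValidationError(
                f"scheme {self.name!r} must cover the 20 standard residues exactly "
                f"(missing {missing}, extra {extra})"
            )

    def classify(self, residue: str) -> str:
        if residue in self.disorder_set:
            return DISORDER_PROMOTING
        if residue in self.order_set:
            return ORDER_PROMOTING
        if residue in self.neutral_set:
            return DISORDER_NEUTRAL
        raise ValidationError(f"unknown residue code {residue!r}")


DEFAULT_SCHEME = TendencyScheme(
    "default",
    disorder_set=frozenset("PESQKAG"),
    order_set=frozenset("MNVHLFYIWC"),
    neutral_set=frozenset("DTR"),
)


def classify_residue(residue: str, scheme: TendencyScheme = DEFAULT_SCHEME) -> str:
    """Tendency class of one residue."""
    return scheme.classify(residue)


def tendency_profile(
    seq: ProteinSequence, scheme: TendencyScheme = DEFAULT_SCHEME
) -> list[str]:
    """Per-position class labels (1-based order); masked positions get 'masked'."""
    return [
        MASKED_LABEL if aa == MASK else scheme.classify(aa) for aa in seq.residues
    ]


@dataclass(frozen=True)
class CompositionSummary:
    """Residue composition of a sequence.

    ``fractions`` and ``class_fractions`` are over unmasked residues and
    each sum to 1. ``enrichment`` (present only when a reference
    composition was supplied) is the signed relative deviation
    ``(fraction - reference) / reference`` per residue.
    """

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    class_fractions: Mapping[str, float]
    enrichment: Mapping[str, float] | None = None

    def most_abundant(self) -> str:
        """Residue with the highest count (ties broken alphabetically)."""
        return max(sorted(self.counts), key=lambda aa: self.counts[aa])


def uniform_reference() -> dict[str, float]:
    """A flat 5%-per-residue reference composition."""
    return {aa: 0.05 for aa in STANDARD_AA}


def _validate_reference(reference: Mapping[str, float]) -> None:
    missing = set(STANDARD_AA) - set(reference)
    if missing:
        raise ValidationError(f"reference composition missing residues: {sorted(missing)}")
    if any(reference[aa] <= 0 for aa in STANDARD_AA):
        raise ValidationError("reference fractions must all be positive")
    total = sum(reference[aa] for aa in STANDARD_AA)
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"reference fractions sum to {total}, expected 1")


def composition_summary(
    seq: ProteinSequence,
    scheme: TendencyScheme = DEFAULT_SCHEME,
    reference: Mapping[str, float] | None = None,
) -> CompositionSummary:
    """Counts, fractions, class fractions, and optional enrichment."""
    if reference is not None:
        _validate_reference(reference)
    counts = Counter(aa for aa in seq.residues if aa != MASK)
    n = sum(counts.values())
    if n == 0:
        raise ValidationError(f"sequence {seq.id!r} has no unmasked residues")
    full_counts = {aa: counts.get(aa, 0) for aa in STANDARD_AA}
    fractions = {aa: c / n for aa, c in full_counts.items()}
    class_fractions = {label: 0.0 for label in CLASS_LABELS}
    for aa, frac in fractions.items():
        class_fractions[scheme.classify(aa)] += frac
    enrichment = None
    if reference is not None:
        enrichment = {
            aa: (fractions[aa] - reference[aa]) / reference[aa] for aa in STANDARD_AA
        }
    return CompositionSummary(full_counts, fractions, class_fractions, enrichment)


def load_scheme(path: str | Path, name: str | None = None) -> TendencyScheme:
    """Read a scheme from ``residue<TAB>class`` text.

    Class names accept the full labels or the shorthands
    disorder/order/neutral.
    """
    path = Path(path)
    aliases = {
        "disorder": DISORDER_PROMOTING, DISORDER_PROMOTING: DISORDER_PROMOTING,
        "order": ORDER_PROMOTING, ORDER_PROMOTING: ORDER_PROMOTING,
        "neutral": DISORDER_NEUTRAL, DISORDER_NEUTRAL: DISORDER_NEUTRAL,
    }
    sets: dict[str, set[str]] = {label: set() for label in CLASS_LABELS}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'residue class', got {line!r}")
        residue, label = parts[0].upper(), parts[1].lower()
        if label not in aliases:
            raise FormatError(f"{path}:{lineno}: unknown class {parts[1]!r}")
        sets[aliases[label]].add(residue)
    return TendencyScheme(
        name or path.stem,
        disorder_set=frozenset(sets[DISORDER_PROMOTING]),
        order_set=frozenset(sets[ORDER_PROMOTING]),
        neutral_set=frozenset(sets[DISORDER_NEUTRAL]),
    )


def load_reference(path: str | Path) -> dict[str, float]:
    """Read a reference composition from ``residue<TAB>fraction`` text."""
    path = Path(path)
    reference: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'residue fraction', got {line!r}")
        try:
            reference[parts[0].upper()] = float(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: {parts[1]!r} is not a number") from None
    _validate_reference(reference)
    return reference
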