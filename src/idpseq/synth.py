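"""Synthetic protein sequences with controlled composition.

The generator emits reproducible sequences whose amino-acid composition
is biased toward a named class. Compositions are enforced exactly:
target fractions are converted to integer residue counts by
largest-remainder apportionment and the resulting multiset is shuffled,
so every guarantee tied to composition (e.g. an acidic sequence has
negative net charge at pH 7) holds deterministically, not just in
expectation. The same (kind, length, seed) always yields the same
sequence.

Kinds
-----
disorder-rich
    80% of residues drawn from the disorder-promoting set
    {P,E,S,Q,K,A,G}, the rest spread over the other 13 residues.
order-rich
    80% from the order-promoting set {M,N,V,H,L,F,Y,I,W,C}.
acidic
    60% D/E, remainder from non-ionizable polar/small residues (no
    basic residues at all, so the net charge at neutral pH is negative).
basic
    60% K/R, remainder non-ionizable (net charge positive at pH 7).
mixed
    uniform over the 20 standard residues.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .sequence import STANDARD_AA, ProteinSequence
from .tendency import DEFAULT_SCHEME

_DISORDER = sorted(DEFAULT_SCHEME.disorder_set)
_ORDER = sorted(DEFAULT_SCHEME.order_set)
_OTHER_THAN_DISORDER = sorted(set(STANDARD_AA) - set(_DISORDER))
_OTHER_THAN_ORDER = sorted(set(STANDARD_AA) - set(_ORDER))
# non-ionizable fillers for the charged kinds
_NEUTRAL_FILLER = sorted("GSTANQP")


def _spread(residues: list[str], mass: float) -> dict[str, float]:
    return {aa: mass / len(residues) for aa in residues}


COMPOSITIONS: dict[str, dict[str, float]] = {
    "disorder-rich": {**_spread(_DISORDER, 0.8), **_spread(_OTHER_THAN_DISORDER, 0.2)},
    "order-rich": {**_spread(_ORDER, 0.8), **_spread(_OTHER_THAN_ORDER, 0.2)},
    "acidic": {"E": 0.35, "D": 0.25, **_spread(_NEUTRAL_FILLER, 0.4)},
    "basic": {"K": 0.35, "R": 0.25, **_spread(_NEUTRAL_FILLER, 0.4)},
    "mixed": _spread(list(STANDARD_AA), 1.0),
}

FIXTURE_KINDS = tuple(COMPOSITIONS)


def _apportion(weights: dict[str, float], length: int) -> dict[str, int]:
    """Largest-remainder rounding of ``weights * length`` to integers."""
    residues = sorted(weights)
    raw = {aa: weights[aa] * length for aa in residues}
    counts = {aa: int(raw[aa]) for aa in residues}
    shortfall = length - sum(counts.values())
    # ties broken by residue order for determinism
    by_remainder = sorted(residues, key=lambda aa: (-(raw[aa] - counts[aa]), aa))
    for aa in by_remainder[:shortfall]:
        counts[aa] += 1
    return counts


def generate_fixture(kind: str, length: int, seed: int) -> ProteinSequence:
    """A reproducible sequence with the composition of ``kind``."""
    if kind not in COMPOSITIONS:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; available: {', '.join(FIXTURE_KINDS)}"
        )
    if length < 1:
        raise ValidationError(f"length must be positive, got {length}")
    counts = _apportion(COMPOSITIONS[kind], length)
    pool = np.array([aa for aa in sorted(counts) for _ in range(counts[aa])])
    rng = np.random.default_rng(seed)
    residues = "".join(rng.permutation(pool))
    return ProteinSequence(f"{kind}_{length}_{seed}", residues)
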