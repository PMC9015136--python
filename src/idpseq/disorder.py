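"""Charge-hydropathy disorder classification and FoldIndex.

Whole-sequence classification places a protein on the Uversky
charge-hydropathy plane: extended (natively disordered) proteins combine
high mean net charge with low mean scaled hydropathy and fall above the
boundary lines

    <charge> = +/- (2.785 * <hydropathy> - 1.151)

while compact, folded proteins fall below. Proteins with mean scaled
hydropathy >= 0.7 are flagged insoluble before the boundary is consulted.

FoldIndex applies the same relationship locally: for every full sliding
window (51 residues by default) the score

    2.785 * <hydropathy>_w - |<charge>_w| - 1.151

is reported at the window center; negative scores predict disorder,
positive scores predict order. A score of exactly 0 is called ordered
(strict-inequality rule for disorder) and the position is flagged.
Sequences shorter than the window fall back to a single whole-sequence
window. Window charge never includes terminal groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charge import IPC_PROTEIN, PkaSet, net_charge, per_residue_charges
from .errors import ValidationError
from .hydropathy import KD_SCALED, HydropathyScale, mean_scaled_hydropathy, per_residue_hydropathy
from .profiles import Profile, sliding_mean, validate_window
from .sequence import ProteinSequence

#: Slope and intercept of the charge-hydropathy boundary lines.
CH_SLOPE = 2.785
CH_INTERCEPT = 1.151
#: Mean scaled hydropathy at or above which a protein is called insoluble.
INSOLUBLE_HYDROPATHY = 0.7

EXTENDED = "extended"
COLLAPSED = "collapsed"
INSOLUBLE = "insoluble"

DISORDERED = "disordered"
ORDERED = "ordered"


def classify_charge_hydropathy(mean_hydropathy: float, mean_net_charge: float) -> str:
    """Label a (mean scaled hydropathy, mean net charge) point.

    The insolubility condition overrides the boundary equation; on the
    boundary itself the collapsed label is assigned (extended requires a
    strict inequality). The rule is symmetric in the sign of the charge.
    """
    if not 0.0 <= mean_hydropathy <= 1.0:
        raise ValidationError(
            f"mean scaled hydropathy {mean_hydropathy} outside [0, 1]"
        )
    if mean_hydropathy >= INSOLUBLE_HYDROPATHY:
        return INSOLUBLE
    if abs(mean_net_charge) > CH_SLOPE * mean_hydropathy - CH_INTERCEPT:
        return EXTENDED
    return COLLAPSED


@dataclass(frozen=True)
class ChargeHydropathyPoint:
    """A sequence's coordinates on the charge-hydropathy plane."""

    mean_hydropathy: float
    mean_net_charge: float
    label: str
    ph: float = 7.0
    pka_set: str = IPC_PROTEIN.name
    scale: str = KD_SCALED.name


def charge_hydropathy_point(
    seq: ProteinSequence,
    ph: float = 7.0,
    pka_set: PkaSet = IPC_PROTEIN,
    scale: HydropathyScale = KD_SCALED,
    *,
    include_termini: bool = True,
) -> ChargeHydropathyPoint:
    """Compute and classify a sequence's charge-hydropathy point."""
    h = mean_scaled_hydropathy(seq, scale)
    q = net_charge(seq, ph, pka_set, include_termini=include_termini).mean_net_charge
    return ChargeHydropathyPoint(
        mean_hydropathy=h,
        mean_net_charge=q,
        label=classify_charge_hydropathy(h, q),
        ph=ph,
        pka_set=pka_set.name,
        scale=scale.name,
    )


def foldindex_score(window_hydropathy: float, window_charge: float) -> float:
    """FoldIndex score of one window from its mean hydropathy and charge."""
    return CH_SLOPE * window_hydropathy - abs(window_charge) - CH_INTERCEPT


@dataclass(frozen=True)
class FoldIndexResult:
    """Windowed FoldIndex prediction.

    ``calls[i]`` is 'disordered' or 'ordered' for ``profile.positions[i]``;
    ``regions`` are maximal runs of identically-called consecutive reported
    positions, as (start, end, call) with 1-based inclusive coordinates in
    reported-position space. ``boundary_positions`` flags the measure-zero
    case of a score exactly 0 (called ordered).
    """

    profile: Profile
    calls: tuple[str, ...]
    regions: tuple[tuple[int, int, str], ...]
    window: int
    whole_sequence_window: bool
    boundary_positions: tuple[int, ...] = ()
    ph: float = 7.0
    pka_set: str = IPC_PROTEIN.name
    scale: str = KD_SCALED.name

    def fraction_disordered(self) -> float:
        """Fraction of reported positions called disordered."""
        if not self.calls:
            return math.nan
        return sum(c == DISORDERED for c in self.calls) / len(self.calls)


def segment_calls(
    positions: np.ndarray, calls: tuple[str, ...]
) -> tuple[tuple[int, int, str], ...]:
    """Maximal runs of equal calls over consecutive reported positions.

    A gap in the reported positions (e.g. masked windows) also closes the
    current run, so every region spans contiguous sequence positions.
    """
    regions: list[tuple[int, int, str]] = []
    for pos, call in zip(positions, calls):
        if regions and regions[-1][2] == call and regions[-1][1] == pos - 1:
            regions[-1] = (regions[-1][0], int(pos), call)
        else:
            regions.append((int(pos), int(pos), call))
    return tuple(regions)


def foldindex(
    seq: ProteinSequence,
    window: int = 51,
    ph: float = 7.0,
    pka_set: PkaSet = IPC_PROTEIN,
    scale: HydropathyScale = KD_SCALED,
) -> FoldIndexResult:
    """FoldIndex disorder prediction over a sliding window.

    For sequences shorter than the window, the whole sequence is used as
    a single window (reported at the central position) and
    ``whole_sequence_window`` is set in the result.
    """
    validate_window(window, len(seq), allow_longer=True)
    whole = window > len(seq)
    hyd = per_residue_hydropathy(seq, scale)
    chg = per_residue_charges(seq, ph, pka_set)
    if whole:
        if np.all(np.isnan(hyd)):
            raise ValidationError(f"sequence {seq.id!r} has no unmasked residues")
        h = float(np.nanmean(hyd))
        q = float(np.nanmean(chg))
        center = (len(seq) + 1) // 2
        scores = Profile([center], [foldindex_score(h, q)], len(seq), name="foldindex")
        effective_window = len(seq)
    else:
        h_prof = sliding_mean(hyd, window)
        q_prof = sliding_mean(chg, window)
        # masked windows drop out of both profiles identically
        scores = Profile(
            h_prof.positions,
            CH_SLOPE * h_prof.values - np.abs(q_prof.values) - CH_INTERCEPT,
            window,
            name="foldindex",
        )
        effective_window = window
    calls = tuple(DISORDERED if s < 0 else ORDERED for s in scores.values)
    boundary = tuple(
        int(p) for p, s in zip(scores.positions, scores.values) if s == 0.0
    )
    return FoldIndexResult(
        profile=scores,
        calls=calls,
        regions=segment_calls(scores.positions, calls),
        window=effective_window,
        whole_sequence_window=whole,
        boundary_positions=boundary,
        ph=ph,
        pka_set=pka_set.name,
        scale=scale.name,
    )
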