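"""Scaled Kyte-Doolittle hydropathy.

The raw Kyte-Doolittle values span [-4.5, 4.5] (Arg lowest, Ile highest).
The default scale here is the linear rescaling ``(raw + 4.5) / 9`` onto
[0, 1], anchored at Arg = 0.0 and Ile = 1.0, which is the convention used
by charge-hydropathy disorder classification. Alternative scales can be
loaded from the same key-value text format as pKa sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import FormatError, ValidationError
from .profiles import Profile, sliding_mean
from .sequence import MASK, STANDARD_AA, ProteinSequence

#: Raw Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE_RAW: Mapping[str, float] = MappingProxyType({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})


@dataclass(frozen=True)
class HydropathyScale:
    """A named per-residue hydropathy scale with values in [0, 1]."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))
        missing = set(STANDARD_AA) - set(self.values)
        if missing:
            raise ValidationError(
                f"scale {self.name!r} is missing residues: {sorted(missing)}"
            )
        for aa, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"scale {self.name!r}: value for {aa} = {v} outside [0, 1]"
                )


#: Default scale: Kyte-Doolittle rescaled to Arg = 0.0, Ile = 1.0.
KD_SCALED = HydropathyScale(
    "kyte_doolittle_scaled",
    {aa: (raw + 4.5) / 9.0 for aa, raw in KYTE_DOOLITTLE_RAW.items()},
)

BUILTIN_SCALES: dict[str, HydropathyScale] = {KD_SCALED.name: KD_SCALED}


def get_scale(name: str) -> HydropathyScale:
    try:
        return BUILTIN_SCALES[name]
    except KeyError:
        raise ValidationError(
            f"unknown hydropathy scale {name!r}; available: {', '.join(BUILTIN_SCALES)}"
        ) from None


def load_scale(path: str | Path, name: str | None = None) -> HydropathyScale:
    """Read a scale from ``residue<TAB>value`` text ('#' comments allowed)."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'residue value', got {line!r}")
        try:
            values[parts[0].upper()] = float(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: {parts[1]!r} is not a number") from None
    return HydropathyScale(name or path.stem, values)


def scaled_hydropathy(residue: str, scale: HydropathyScale = KD_SCALED) -> float:
    """Scaled hydropathy of one residue, in [0, 1]."""
    if residue not in STANDARD_AA:
        raise ValidationError(f"unknown residue code {residue!r}")
    return scale.values[residue]


def per_residue_hydropathy(
    seq: ProteinSequence, scale: HydropathyScale = KD_SCALED
) -> np.ndarray:
    """Vector of scaled hydropathy values; masked positions are NaN."""
    table = dict(scale.values)
    table[MASK] = math.nan
    return np.array([table[aa] for aa in seq.residues], dtype=float)


def mean_scaled_hydropathy(seq: ProteinSequence, scale: HydropathyScale = KD_SCALED) -> float:
    """Arithmetic mean of scaled hydropathy over (unmasked) residues."""
    values = per_residue_hydropathy(seq, scale)
    if np.all(np.isnan(values)):
        raise ValidationError(f"sequence {seq.id!r} has no unmasked residues")
    return float(np.nanmean(values))


def local_hydropathy(
    seq: ProteinSequence, window: int = 9, scale: HydropathyScale = KD_SCALED
) -> Profile:
    """Sliding-window mean scaled-hydropathy profile (full windows only)."""
    values = per_residue_hydropathy(seq, scale)
    return sliding_mean(values, window, name="hydropathy")
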