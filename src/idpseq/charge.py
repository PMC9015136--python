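"""Protein charge from the Henderson-Hasselbalch equation.

Each ionizable group carries a fractional charge at a given pH:

* acids (D, E, C, Y side chains and the free C-terminus):
  ``q = -1 / (1 + 10**(pKa - pH))``
* bases (H, K, R side chains and the free N-terminus):
  ``q = +1 / (1 + 10**(pH - pKa))``

Non-ionizable residues contribute exactly 0. Group polarity is fixed by
chemistry and is not configurable; only the pKa values vary between the
named sets. The default set is IPC_protein, with several classical sets
(EMBOSS, Lehninger, ...) available by name. Histidine is treated as an
ordinary base with its set's pKa, giving it a small positive charge at
pH 7.

Terminal groups are included in whole-sequence net charge by default but
never in sliding-window local charge: the interior residues of a window
are not free ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import FormatError, ValidationError
from .profiles import Profile, sliding_mean
from .sequence import MASK, STANDARD_AA, ProteinSequence

#: Side chains deprotonating to a negative charge.
ACIDIC_RESIDUES = frozenset("DECY")
#: Side chains protonating to a positive charge.
BASIC_RESIDUES = frozenset("HKR")
IONIZABLE_RESIDUES = ACIDIC_RESIDUES | BASIC_RESIDUES


@dataclass(frozen=True)
class PkaSet:
    """A named set of acid-dissociation constants.

    ``residue_pkas`` maps the ionizable residues {D,E,C,Y,H,K,R} to pKa;
    ``nterm``/``cterm`` are the free-terminus pKa values. All pKa must lie
    in the open interval (0, 14).
    """

    name: str
    residue_pkas: Mapping[str, float]
    nterm: float
    cterm: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residue_pkas", MappingProxyType(dict(self.residue_pkas))
        )
        extra = set(self.residue_pkas) - IONIZABLE_RESIDUES
        if extra:
            raise ValidationError(
                f"pKa set {self.name!r} lists non-ionizable residues: {sorted(extra)}"
            )
        missing = IONIZABLE_RESIDUES - set(self.residue_pkas)
        if missing:
            raise ValidationError(
                f"pKa set {self.name!r} is missing residues: {sorted(missing)}"
            )
        for key, pka in [*self.residue_pkas.items(), ("NTERM", self.nterm), ("CTERM", self.cterm)]:
            if not 0.0 < pka < 14.0:
                raise ValidationError(
                    f"pKa set {self.name!r}: pKa({key}) = {pka} outside (0, 14)"
                )


# Default set: optimized for folded, whole proteins (IPC_protein).
IPC_PROTEIN = PkaSet(
    "IPC_protein",
    {"C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637, "K": 9.052, "R": 11.84, "Y": 10.85},
    nterm=9.094,
    cterm=2.869,
)

# Classical pKa compilations, addressable by name.
_CLASSICAL = {
    "EMBOSS": ({"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}, 8.6, 3.6),
    "Lehninger": ({"C": 8.18, "D": 3.65, "E": 4.25, "H": 6.0, "K": 10.53, "R": 12.48, "Y": 10.07}, 9.69, 2.34),
    "Bjellqvist": ({"C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0}, 7.5, 3.55),
    "Dawson": ({"C": 8.3, "D": 3.9, "E": 4.3, "H": 6.0, "K": 10.5, "R": 12.0, "Y": 10.1}, 8.2, 3.2),
    "Murray": ({"C": 8.33, "D": 3.68, "E": 4.25, "H": 6.0, "K": 11.5, "R": 11.5, "Y": 10.07}, 9.52, 2.15),
    "Rodwell": ({"C": 8.33, "D": 3.86, "E": 4.25, "H": 6.0, "K": 11.5, "R": 11.5, "Y": 10.7}, 8.0, 3.1),
    "Sillero": ({"C": 9.0, "D": 4.0, "E": 4.5, "H": 6.4, "K": 10.4, "R": 12.0, "Y": 10.0}, 8.2, 3.2),
    "Solomon": ({"C": 8.3, "D": 3.9, "E": 4.3, "H": 6.0, "K": 10.5, "R": 12.5, "Y": 10.1}, 8.2, 3.2),
    "Stryer": ({"C": 8.5, "D": 4.4, "E": 4.4, "H": 6.5, "K": 10.0, "R": 12.0, "Y": 10.0}, 8.2, 3.2),
}

BUILTIN_PKA_SETS: dict[str, PkaSet] = {"IPC_protein": IPC_PROTEIN}
for _name, (_res, _nt, _ct) in _CLASSICAL.items():
    BUILTIN_PKA_SETS[_name] = PkaSet(_name, _res, nterm=_nt, cterm=_ct)


def available_pka_sets() -> list[str]:
    """Names of the built-in pKa sets (default first)."""
    return list(BUILTIN_PKA_SETS)


def get_pka_set(name: str) -> PkaSet:
    try:
        return BUILTIN_PKA_SETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown pKa set {name!r}; available: {', '.join(BUILTIN_PKA_SETS)}"
        ) from None


def load_pka_set(path: str | Path, name: str | None = None) -> PkaSet:
    """Read a pKa set from key-value text.

    One ``residue<TAB>pKa`` pair per line plus ``NTERM`` and ``CTERM``
    rows; '#' lines are comments. Whitespace other than tab also accepted.
    """
    path = Path(path)
    residues: dict[str, float] = {}
    nterm = cterm = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'key value', got {line!r}")
        key, value = parts[0].upper(), parts[1]
        try:
            pka = float(value)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: {value!r} is not a number") from None
        if key == "NTERM":
            nterm = pka
        elif key == "CTERM":
            cterm = pka
        else:
            residues[key] = pka
    if nterm is None or cterm is None:
        raise FormatError(f"{path}: missing NTERM and/or CTERM rows")
    return PkaSet(name or path.stem, residues, nterm=nterm, cterm=cterm)


def _group_charge(ph: float, pka: float, acid: bool) -> float:
    if acid:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _check_ph(ph: float) -> None:
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"pH must be in (0, 14), got {ph}")


def residue_charge(residue: str, ph: float = 7.0, pka_set: PkaSet = IPC_PROTEIN) -> float:
    """Fractional side-chain charge of one residue at the given pH.

    Acids return a value in [-1, 0], bases in [0, +1]; non-ionizable
    residues return exactly 0.
    """
    _check_ph(ph)
    if residue not in STANDARD_AA:
        raise ValidationError(f"unknown residue code {residue!r}")
    if residue in ACIDIC_RESIDUES:
        return _group_charge(ph, pka_set.residue_pkas[residue], acid=True)
    if residue in BASIC_RESIDUES:
        return _group_charge(ph, pka_set.residue_pkas[residue], acid=False)
    return 0.0


def per_residue_charges(
    seq: ProteinSequence, ph: float = 7.0, pka_set: PkaSet = IPC_PROTEIN
) -> np.ndarray:
    """Vector of fractional side-chain charges; masked positions are NaN."""
    _check_ph(ph)
    table = {aa: residue_charge(aa, ph, pka_set) for aa in STANDARD_AA}
    table[MASK] = math.nan
    return np.array([table[aa] for aa in seq.residues], dtype=float)


@dataclass(frozen=True)
class ChargeResult:
    """Net charge of a sequence at one pH.

    ``net_charge`` is in elementary-charge units; ``mean_net_charge`` is
    the net charge divided by the number of (unmasked) residues.
    """

    per_residue: np.ndarray = field(compare=False)
    net_charge: float
    mean_net_charge: float
    ph: float
    include_termini: bool
    pka_set: str


def net_charge(
    seq: ProteinSequence,
    ph: float = 7.0,
    pka_set: PkaSet = IPC_PROTEIN,
    *,
    include_termini: bool = True,
) -> ChargeResult:
    """Henderson-Hasselbalch net charge of a whole sequence.

    Free-terminus contributions are added when ``include_termini`` is
    true (the default for whole chains).
    """
    charges = per_residue_charges(seq, ph, pka_set)
    n_effective = int(np.sum(~np.isnan(charges)))
    if n_effective == 0:
        raise ValidationError(f"sequence {seq.id!r} has no unmasked residues")
    total = float(np.nansum(charges))
    if include_termini:
        total += _group_charge(ph, pka_set.nterm, acid=False)
        total += _group_charge(ph, pka_set.cterm, acid=True)
    return ChargeResult(
        per_residue=charges,
        net_charge=total,
        mean_net_charge=total / n_effective,
        ph=ph,
        include_termini=include_termini,
        pka_set=pka_set.name,
    )


def local_charge(
    seq: ProteinSequence,
    window: int = 9,
    ph: float = 7.0,
    pka_set: PkaSet = IPC_PROTEIN,
) -> Profile:
    """Sliding-window mean charge profile (termini always excluded).

    The window must be odd and no longer than the sequence; only full
    windows are reported, at their center position.
    """
    charges = per_residue_charges(seq, ph, pka_set)
    return sliding_mean(charges, window, name="charge")
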