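"""The full per-sequence disorder profile.

:func:`idprofile` aggregates every native analysis — charge-hydropathy
classification, whole-sequence net charge, local charge and hydropathy
profiles, structural tendency and composition, and FoldIndex — into one
:class:`IdpProfile` computed from a single sequence with one recorded
parameter set. Each component is exactly what the corresponding module
function returns with the same parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import charge as _charge
from . import disorder as _disorder
from . import hydropathy as _hydropathy
from . import tendency as _tendency
from .charge import ChargeResult, PkaSet, get_pka_set
from .disorder import ChargeHydropathyPoint, FoldIndexResult
from .errors import IdpseqError, ValidationError
from .hydropathy import HydropathyScale, get_scale
from .profiles import Profile
from .sequence import ProteinSequence
from .tendency import DEFAULT_SCHEME, CompositionSummary, TendencyScheme


@dataclass(frozen=True)
class ProfileConfig:
    """Run parameters shared by all component analyses."""

    ph: float = 7.0
    window: int = 9  # local charge / hydropathy window
    foldindex_window: int = 51
    pka_set: PkaSet = field(default_factory=lambda: get_pka_set("IPC_protein"))
    scale: HydropathyScale = field(default_factory=lambda: get_scale("kyte_doolittle_scaled"))
    scheme: TendencyScheme = DEFAULT_SCHEME
    reference: dict[str, float] | None = None
    include_termini: bool = True

    def parameters(self) -> dict:
        return {
            "ph": self.ph,
            "window": self.window,
            "foldindex_window": self.foldindex_window,
            "pka_set": self.pka_set.name,
            "scale": self.scale.name,
            "scheme": self.scheme.name,
            "include_termini": self.include_termini,
        }


@dataclass(frozen=True)
class IdpProfile:
    """All native analyses of one sequence under one parameter set."""

    id: str
    residues: str
    parameters: dict
    charge_hydropathy: ChargeHydropathyPoint
    net_charge: ChargeResult
    local_charge: Profile
    local_hydropathy: Profile
    tendency: tuple[str, ...]
    composition: CompositionSummary
    foldindex: FoldIndexResult


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except IdpseqError as e:
        raise type(e)(f"stage {name!r} failed: {e}") from e


def idprofile(seq: ProteinSequence, config: ProfileConfig | None = None) -> IdpProfile:
    """Run every native analysis on one sequence.

    Disorder predictions that require an external web service are not
    part of the profile; see the package documentation.
    """
    cfg = config or ProfileConfig()
    ch = _stage(
        "charge_hydropathy",
        _disorder.charge_hydropathy_point,
        seq, cfg.ph, cfg.pka_set, cfg.scale,
        include_termini=cfg.include_termini,
    )
    nc = _stage(
        "net_charge", _charge.net_charge,
        seq, cfg.ph, cfg.pka_set, include_termini=cfg.include_termini,
    )
    lc = _stage("local_charge", _charge.local_charge, seq, cfg.window, cfg.ph, cfg.pka_set)
    lh = _stage("local_hydropathy", _hydropathy.local_hydropathy, seq, cfg.window, cfg.scale)
    tp = _stage("tendency", _tendency.tendency_profile, seq, cfg.scheme)
    comp = _stage(
        "composition", _tendency.composition_summary, seq, cfg.scheme, cfg.reference
    )
    fi = _stage(
        "foldindex", _disorder.foldindex,
        seq, cfg.foldindex_window, cfg.ph, cfg.pka_set, cfg.scale,
    )
    return IdpProfile(
        id=seq.id,
        residues=seq.residues,
        parameters=cfg.parameters(),
        charge_hydropathy=ch,
        net_charge=nc,
        local_charge=lc,
        local_hydropathy=lh,
        tendency=tuple(tp),
        composition=comp,
        foldindex=fi,
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization — lossless for everything the dataclasses compare on.

def _profile_to_dict(p: Profile) -> dict:
    return {
        "window": p.window,
        "positions": p.positions.tolist(),
        "values": p.values.tolist(),
        "name": p.name,
    }


def _profile_from_dict(d: dict) -> Profile:
    return Profile(d["positions"], d["values"], d["window"], name=d.get("name", ""))


def profile_to_dict(profile: IdpProfile) -> dict:
    ch = profile.charge_hydropathy
    nc = profile.net_charge
    fi = profile.foldindex
    comp = profile.composition
    return {
        "id": profile.id,
        "residues": profile.residues,
        "parameters": profile.parameters,
        "charge_hydropathy": {
            "mean_hydropathy": ch.mean_hydropathy,
            "mean_net_charge": ch.mean_net_charge,
            "label": ch.label,
            "ph": ch.ph,
            "pka_set": ch.pka_set,
            "scale": ch.scale,
        },
        "net_charge": {
            "per_residue": nc.per_residue.tolist(),
            "net_charge": nc.net_charge,
            "mean_net_charge": nc.mean_net_charge,
            "ph": nc.ph,
            "include_termini": nc.include_termini,
            "pka_set": nc.pka_set,
        },
        "local_charge": _profile_to_dict(profile.local_charge),
        "local_hydropathy": _profile_to_dict(profile.local_hydropathy),
        "tendency": list(profile.tendency),
        "composition": {
            "counts": dict(comp.counts),
            "fractions": dict(comp.fractions),
            "class_fractions": dict(comp.class_fractions),
            "enrichment": dict(comp.enrichment) if comp.enrichment is not None else None,
        },
        "foldindex": {
            "profile": _profile_to_dict(fi.profile),
            "calls": list(fi.calls),
            "regions": [list(r) for r in fi.regions],
            "window": fi.window,
            "whole_sequence_window": fi.whole_sequence_window,
            "boundary_positions": list(fi.boundary_positions),
            "ph": fi.ph,
            "pka_set": fi.pka_set,
            "scale": fi.scale,
        },
    }


def profile_from_dict(d: dict) -> IdpProfile:
    ch = d["charge_hydropathy"]
    nc = d["net_charge"]
    fi = d["foldindex"]
    comp = d["composition"]
    return IdpProfile(
        id=d["id"],
        residues=d["residues"],
        parameters=d["parameters"],
        charge_hydropathy=ChargeHydropathyPoint(**ch),
        net_charge=ChargeResult(
            per_residue=np.asarray(nc["per_residue"], dtype=float),
            net_charge=nc["net_charge"],
            mean_net_charge=nc["mean_net_charge"],
            ph=nc["ph"],
            include_termini=nc["include_termini"],
            pka_set=nc["pka_set"],
        ),
        local_charge=_profile_from_dict(d["local_charge"]),
        local_hydropathy=_profile_from_dict(d["local_hydropathy"]),
        tendency=tuple(d["tendency"]),
        composition=CompositionSummary(
            counts=comp["counts"],
            fractions=comp["fractions"],
            class_fractions=comp["class_fractions"],
            enrichment=comp["enrichment"],
        ),
        foldindex=FoldIndexResult(
            profile=_profile_from_dict(fi["profile"]),
            calls=tuple(fi["calls"]),
            regions=tuple((r[0], r[1], r[2]) for r in fi["regions"]),
            window=fi["window"],
            whole_sequence_window=fi["whole_sequence_window"],
            boundary_positions=tuple(fi["boundary_positions"]),
            ph=fi["ph"],
            pka_set=fi["pka_set"],
            scale=fi["scale"],
        ),
    )


def profile_to_json(profile: IdpProfile, path: str | Path | None = None, *, indent: int = 2) -> str:
    text = json.dumps(profile_to_dict(profile), indent=indent)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def profile_from_json(source: str | Path) -> IdpProfile:
    """Load a profile from a JSON string or file path."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    return profile_from_dict(json.loads(text))
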