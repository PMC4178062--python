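"""Fatty-acid profile arithmetic for heart-tissue signature analysis.

Profiles are compositional: each specimen's chromatogram areas are closed to
percentages of the total identified fatty acids. Names follow the shorthand
``Cx:y`` or ``Cx:ywz`` (carbons : double bonds, omega series; the omega sign
may be the Greek letter or an ASCII ``w``). Saturation classes derive from the
double-bond count: SFA (0), MUFA (1), PUFA (>= 2).

Summary statistics mirror the conventional lipidomics table rows: class sums,
omega-series sums, the DHA/EPA ratio, the EPA+DPA+DHA pool, the
unsaturated/saturated ratio, and the unsaturation index
``UI = sum_i percent_i * double_bonds_i`` over unsaturated components.

``select_fa_for_mda`` applies the membrane-phospholipid screening rules used
before discriminant analysis (chain-length window, C14:1 and odd-chain
monounsaturates out, nowhere-detected components out); each rule is
individually toggleable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._exceptions import DegenerateInputError, FattyAcidNameError

__all__ = [
    "FattyAcidDescriptor",
    "LipidSummary",
    "parse_fa_name",
    "normalize_percent",
    "arcsine_transform",
    "class_sums",
    "unsaturation_index",
    "select_fa_for_mda",
    "heart_mass_percent",
    "water_loss_percent",
]

EPA = "C20:5ω3"
DPA = "C22:5ω3"
DHA = "C22:6ω3"

_NAME_RE = re.compile(r"^C(\d+):(\d+)(?:[ωw](\d+))?$")


@dataclass(frozen=True)
class FattyAcidDescriptor:
    name: str
    carbons: int
    double_bonds: int
    omega: int | None
    fa_class: str  # "SFA" | "MUFA" | "PUFA"


def parse_fa_name(name: str) -> FattyAcidDescriptor:
    """Parse ``Cx:y[ωz]`` nomenclature into a descriptor."""
    m = _NAME_RE.match(str(name).strip())
    if m is None:
        pos = _first_bad_position(str(name).strip())
        raise FattyAcidNameError(
            f"malformed fatty-acid name {name!r} (at position {pos})"
        )
    carbons, dbonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) else None
    if carbons < 4:
        raise FattyAcidNameError(f"{name!r}: carbon count must be >= 4")
    fa_class = "SFA" if dbonds == 0 else "MUFA" if dbonds == 1 else "PUFA"
    return FattyAcidDescriptor(str(name).strip(), carbons, dbonds, omega,
                               fa_class)


def _first_bad_position(name: str) -> int:
    for prefix_len in range(len(name), 0, -1):
        if any(
            _NAME_RE.match(name[:prefix_len] + suffix)
            for suffix in ("", "0", ":0", "1:0")
        ):
            return prefix_len
    return 0


def is_parseable(name: str) -> bool:
    return _NAME_RE.match(str(name).strip()) is not None


@dataclass(frozen=True)
class LipidSummary:
    """Class/series sums for one normalized profile (percent units)."""

    sfa: float
    mufa: float
    pufa: float
    pufa_plus_mufa: float
    ufa_sfa_ratio: float
    omega3: float
    omega6: float
    dha_epa_ratio: float | None  # None when EPA is absent (flagged, not inf)
    epa_dpa_dha: float
    unsaturation_index: float


def normalize_percent(areas) -> pd.DataFrame | pd.Series:
    """Close areas (per fatty acid) to percentages summing to 100.

    Accepts a Series (one specimen) or DataFrame (rows = specimens); zeros are
    preserved exactly. All-zero rows raise.
    """
    if isinstance(areas, pd.Series):
        vals = areas.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("areas must be nonnegative")
        total = vals.sum()
        if total <= 0:
            raise DegenerateInputError("all-zero area vector")
        return areas * (100.0 / total)
    frame = pd.DataFrame(areas).astype(float)
    if (frame.to_numpy() < 0).any():
        raise ValueError("areas must be nonnegative")
    totals = frame.sum(axis=1)
    if (totals <= 0).any():
        raise DegenerateInputError("all-zero area vector in at least one row")
    return frame.mul(100.0 / totals, axis=0)


def arcsine_transform(profile):
    """Variance-stabilizing transform t = arcsin(sqrt(p / 100)), radians."""
    vals = np.asarray(profile, dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(vals / 100.0))
    if isinstance(profile, pd.DataFrame):
        return pd.DataFrame(out, index=profile.index, columns=profile.columns)
    if isinstance(profile, pd.Series):
        return pd.Series(out, index=profile.index, name=profile.name)
    return out


def _descriptors(names: Iterable[str]):
    return {name: parse_fa_name(name) for name in names}


def unsaturation_index(profile: pd.Series) -> float:
    """UI = sum of percent x double bonds over unsaturated fatty acids."""
    desc = _descriptors(profile.index)
    return float(
        sum(profile[name] * d.double_bonds for name, d in desc.items())
    )


def class_sums(profile: pd.Series) -> LipidSummary:
    """Lipid-class and omega-series sums of one percentage profile.

    All names must parse; components without an omega annotation (e.g. C20:2)
    count towards their saturation class but no omega series.
    """
    desc = _descriptors(profile.index)
    by_class = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    omega = {3: 0.0, 6: 0.0}
    for name, d in desc.items():
        by_class[d.fa_class] += float(profile[name])
        if d.omega in omega and d.double_bonds >= 1:
            omega[d.omega] += float(profile[name])
    epa = float(profile.get(EPA, 0.0))
    dpa = float(profile.get(DPA, 0.0))
    dha = float(profile.get(DHA, 0.0))
    ufa = by_class["MUFA"] + by_class["PUFA"]
    return LipidSummary(
        sfa=by_class["SFA"],
        mufa=by_class["MUFA"],
        pufa=by_class["PUFA"],
        pufa_plus_mufa=ufa,
        ufa_sfa_ratio=ufa / by_class["SFA"] if by_class["SFA"] > 0 else np.inf,
        omega3=omega[3],
        omega6=omega[6],
        dha_epa_ratio=dha / epa if epa > 0 else None,
        epa_dpa_dha=epa + dpa + dha,
        unsaturation_index=unsaturation_index(profile),
    )


def select_fa_for_mda(profiles: pd.DataFrame, *, group_col: str | None = None,
                      min_chain: int = 10, max_chain: int = 22,
                      exclude_c14_1: bool = True,
                      exclude_odd_monounsaturated: bool = True,
                      exclude_undetected: bool = True,
                      exclude_unparseable: bool = True,
                      chain_rule: bool = True) -> list[str]:
    """Screen fatty-acid columns for discriminant analysis.

    Rules (each toggleable; all disabled -> identity): membrane
    phosphoglycerides carry essentially no acyl chains shorter than 10 or
    longer than 22 carbons (``chain_rule``); C14:1 and odd-chain
    monounsaturates are excluded; components detected in no group (all-zero
    columns, per group when *group_col* is given) are excluded.
    """
    frame = pd.DataFrame(profiles)
    fa_cols = [c for c in frame.columns if c != group_col]
    kept = []
    for name in fa_cols:
        if not is_parseable(name):
            if exclude_unparseable:
                continue
            kept.append(name)
            continue
        d = parse_fa_name(name)
        if chain_rule and not (min_chain <= d.carbons <= max_chain):
            continue
        if exclude_c14_1 and d.carbons == 14 and d.double_bonds == 1:
            continue
        if (
            exclude_odd_monounsaturated
            and d.fa_class == "MUFA"
            and d.carbons % 2 == 1
        ):
            continue
        if exclude_undetected and float(frame[name].abs().sum()) == 0.0:
            continue
        kept.append(name)
    return kept


# -- heart-mass helpers (simple accessors) ----------------------------------

def heart_mass_percent(heart_mass_g, gutted_mass_g):
    """HTM/BGM expressed in percent."""
    return 100.0 * np.asarray(heart_mass_g, float) / np.asarray(
        gutted_mass_g, float
    )


def water_loss_percent(wet_mass_g, dry_mass_g):
    """Percentage of mass lost on lyophilization."""
    wet = np.asarray(wet_mass_g, float)
    dry = np.asarray(dry_mass_g, float)
    return 100.0 * (wet - dry) / wet
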