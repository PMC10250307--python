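"""Interocular asymmetry index between fellow eyes.

For any non-negative paired measurement (right eye OD, left eye OS) the
asymmetry index is

    AI = |OD - OS| / (OD + OS) * 2 * 100   (%)

AI is 0 for identical eyes, 200 when one eye measures zero, symmetric in
its arguments, and invariant to rescaling both eyes by the same positive
factor — which is what makes AIs comparable across devices and
implementations whose raw density units differ.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import math

from .errors import UndefinedAsymmetryError, ValidationError
from .metrics import VascularMetrics

#: AsymmetryProfile column -> (VascularMetrics attribute, layer tag) for the
#: seven quantities the cohort analysis tracks.
AI_METRIC_MAP = {
    "ai_spd": ("perfusion_density", "SRL"),
    "ai_svd": ("vessel_density", "SRL"),
    "ai_dpd": ("perfusion_density", "DRL"),
    "ai_dvd": ("vessel_density", "DRL"),
    "ai_faza": ("faz_area", "SRL"),
    "ai_fazp": ("faz_perimeter", "SRL"),
    "ai_fazc": ("faz_circularity", "SRL"),
}

AI_COLUMNS = tuple(AI_METRIC_MAP)


@dataclass
class EyePairMetrics:
    """One patient's right-eye and left-eye quantification records."""

    patient_id: str
    od: VascularMetrics
    os: VascularMetrics

    def __post_init__(self):
        if self.od.corrected != self.os.corrected:
            raise ValidationError(
                "fellow eyes must both be corrected or both uncorrected"
            )
        if self.od.layer_tag != self.os.layer_tag:
            raise ValidationError("fellow eyes must carry the same layer tag")


@dataclass
class AsymmetryProfile:
    """Per-patient asymmetry indices (%), one per tracked metric.

    A ``None`` entry means the underlying metric was missing or its AI is
    undefined (both eyes zero); it is never imputed.
    """

    patient_id: str
    ai_spd: Optional[float] = None
    ai_svd: Optional[float] = None
    ai_dpd: Optional[float] = None
    ai_dvd: Optional[float] = None
    ai_faza: Optional[float] = None
    ai_fazp: Optional[float] = None
    ai_fazc: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def asymmetry_index(od_value: float, os_value: float) -> float:
    """AI = |OD - OS| / (OD + OS) * 200, in percent.

    Raises :class:`UndefinedAsymmetryError` when both eyes measure zero
    (callers map this to a missing value explicitly; it is never silently
    reported as 0).
    """
    if od_value < 0 or os_value < 0:
        raise ValidationError("asymmetry index requires non-negative measurements")
    total = od_value + os_value
    if total == 0:
        raise UndefinedAsymmetryError("AI undefined: both eyes measure zero")
    return abs(od_value - os_value) / total * 200.0


def pair_asymmetry_profile(pair: EyePairMetrics) -> AsymmetryProfile:
    """Asymmetry indices for the superficial-layer metric set of one pair.

    Maps perfusion density, vessel density and the FAZ shape triplet of the
    pair onto the superficial AI columns (``ai_spd``, ``ai_svd``,
    ``ai_faza``, ``ai_fazp``, ``ai_fazc``) when the pair carries the SRL
    tag (or no tag), and onto the deep columns (``ai_dpd``, ``ai_dvd``)
    when it carries the DRL tag. Undefined AIs become ``None``.
    """
    tag = pair.od.layer_tag
    out = AsymmetryProfile(patient_id=pair.patient_id)
    if tag == "DRL":
        targets = {"ai_dpd": "perfusion_density", "ai_dvd": "vessel_density"}
    else:
        targets = {
            "ai_spd": "perfusion_density",
            "ai_svd": "vessel_density",
            "ai_faza": "faz_area",
            "ai_fazp": "faz_perimeter",
            "ai_fazc": "faz_circularity",
        }
    for ai_col, attr in targets.items():
        od_v = getattr(pair.od, attr)
        os_v = getattr(pair.os, attr)
        if od_v is None or os_v is None:
            continue
        if math.isnan(od_v) or math.isnan(os_v):
            continue
        try:
            setattr(out, ai_col, asymmetry_index(od_v, os_v))
        except UndefinedAsymmetryError:
            pass  # stays None: explicit missingness
    return out


def merge_profiles(
    superficial: AsymmetryProfile, deep: AsymmetryProfile
) -> AsymmetryProfile:
    """Combine SRL and DRL profiles of the same patient into one record."""
    if superficial.patient_id != deep.patient_id:
        raise ValidationError("profiles belong to different patients")
    merged = AsymmetryProfile(patient_id=superficial.patient_id)
    for col in AI_COLUMNS:
        v = getattr(superficial, col)
        if v is None:
            v = getattr(deep, col)
        setattr(merged, col, v)
    return merged
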