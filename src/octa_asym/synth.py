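"""Synthetic paired-eye angiograms and cohorts with known ground truth.

Two levels of simulation are provided:

* **Image level** — :func:`generate_angiogram` grows a branching capillary
  network on a square en-face field, erases a star-convex foveal avascular
  zone (FAZ), deletes a fraction of branch segments (capillary dropout in
  contiguous patches) and adds intensity noise. The ground-truth vessel
  mask and FAZ geometry come back alongside the image, so the measurement
  chain can be validated pixel-for-pixel. :func:`generate_eye_pair` renders
  two fellow eyes from shared parameters and degrades one eye (chosen by a
  fair coin flip) by extra dropout and/or FAZ enlargement.

* **Metric level** — :func:`generate_cohort` draws a whole cohort of
  patients in four diabetic-retinopathy severity groups (no DM, DM without
  DR, NPDR, PDR) with per-group demographics and a half-normal model of
  interocular asymmetry whose scale grows with disease severity, plus an
  additive HbA1c dependence with a known slope. This is the generator used
  for repeated-cohort statistical experiments, where rendering thousands
  of image pairs would be pointless: the asymmetry model is identical to
  the one the image-level simulator realises through dropout, as a
  consistency test verifies on a small batch of rendered pairs.

The generator is a stand-in for a Cirrus-type OCTA device, not a
biophysical model of the retinal vasculature; what it guarantees is known
ground truth and tunable effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from skimage import draw, morphology

from .asym import AI_COLUMNS
from .errors import ParameterError
from .metrics import EnFaceAngiogram

GROUPS = ("no DM", "DM without DR", "NPDR", "PDR")

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


# --------------------------------------------------------------------------
# image-level simulation
# --------------------------------------------------------------------------

@dataclass
class VesselSimParams:
    """Parameters of one synthetic en-face angiogram.

    field_mm/grid_px reproduce a 3x3 mm macular scan sampled on a 245x245
    grid. ``target_perfusion`` is the vessel-pixel fraction the network is
    grown to (before dropout); ``dropout_fraction`` of branch segments are
    then deleted. The FAZ is a disc of mean radius ``faz_radius_mm`` whose
    boundary radius is modulated by a low-order Fourier perturbation of
    relative amplitude ``faz_irregularity``.
    """

    field_mm: float = 3.0
    grid_px: int = 245
    target_perfusion: float = 0.35
    faz_radius_mm: float = 0.30
    faz_irregularity: float = 0.2
    dropout_fraction: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_mm <= 0:
            raise ParameterError("field_mm must be positive")
        if self.grid_px < 16:
            raise ParameterError("grid_px must be at least 16")
        if not 0.0 <= self.target_perfusion <= 1.0:
            raise ParameterError("target_perfusion must be in [0, 1]")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ParameterError("dropout_fraction must be in [0, 1]")
        if not 0.0 <= self.faz_irregularity <= 1.0:
            raise ParameterError("faz_irregularity must be in [0, 1]")
        if self.faz_radius_mm < 0 or self.faz_radius_mm >= self.field_mm / 2:
            raise ParameterError("faz_radius_mm must be in [0, field_mm/2)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    @property
    def pixel_size_mm(self) -> float:
        return self.field_mm / self.grid_px


@dataclass
class AngiogramTruth:
    """Ground truth accompanying one synthetic angiogram."""

    vessel_mask: np.ndarray          # post-dropout, post-FAZ vessel pixels
    faz_mask: np.ndarray             # pixels inside the avascular zone
    faz_contour_mm: np.ndarray       # (n, 2) closed polygon, (row, col) mm
    faz_area_mm2: float              # analytic area of the radius profile
    n_segments: int
    n_dropped: int
    params: VesselSimParams


@dataclass
class PairSimParams:
    """Fellow-eye pair: shared base parameters plus asymmetry deltas.

    The degraded eye (chosen by coin flip) receives
    ``base.dropout_fraction + asymmetry_dropout_delta`` and a FAZ radius
    scaled by ``1 + asymmetry_faz_delta``. With both deltas zero the two
    eyes are i.i.d. draws from the same generator.
    """

    base: VesselSimParams = field(default_factory=VesselSimParams)
    asymmetry_dropout_delta: float = 0.0
    asymmetry_faz_delta: float = 0.0

    def validate(self) -> None:
        self.base.validate()
        if self.asymmetry_dropout_delta < 0 or self.asymmetry_faz_delta < 0:
            raise ParameterError("asymmetry deltas must be non-negative")
        if self.base.dropout_fraction + self.asymmetry_dropout_delta > 1.0:
            raise ParameterError("dropout_fraction + delta exceeds 1")


@dataclass
class PairTruth:
    degraded_eye: str                # "OD" or "OS"
    od: AngiogramTruth
    os: AngiogramTruth


def _faz_radius_profile(
    rng: np.random.Generator, params: VesselSimParams, n_theta: int = 720
) -> Tuple[np.ndarray, np.ndarray]:
    """Star-convex FAZ boundary radius r(theta), in pixels."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r_px = params.faz_radius_mm / params.pixel_size_mm
    pert = np.zeros(n_theta)
    if params.faz_irregularity > 0:
        weights = rng.uniform(-1.0, 1.0, size=4)  # harmonics 2..5
        norm = np.abs(weights).sum() or 1.0
        weights = weights / norm
        phases = rng.uniform(0.0, 2.0 * math.pi, size=4)
        for k, (w, ph) in enumerate(zip(weights, phases), start=2):
            pert += w * np.cos(k * theta + ph)
        pert *= params.faz_irregularity
    return theta, r_px * (1.0 + pert)


def _grow_network(
    rng: np.random.Generator,
    params: VesselSimParams,
    faz_mask: np.ndarray,
) -> list:
    """Grow branching random-walk strokes until the dilated, FAZ-erased
    union of strokes reaches the target vessel-pixel fraction.

    Returns the list of segments; each segment is an (n, 2) int array of
    thin-line pixel coordinates. Contiguous dropout is realised downstream
    by deleting whole segments.
    """
    g = params.grid_px
    center = np.array([g / 2.0, g / 2.0])
    segments: list = []
    thin = np.zeros((g, g), dtype=bool)
    if params.target_perfusion == 0:
        return segments

    def spawn_border_tip():
        side = rng.integers(4)
        t = rng.uniform(0, g - 1)
        pos = {
            0: np.array([0.0, t]),
            1: np.array([g - 1.0, t]),
            2: np.array([t, 0.0]),
            3: np.array([t, g - 1.0]),
        }[side]
        to_center = center - pos
        ang = math.atan2(to_center[0], to_center[1]) + rng.normal(0, 0.5)
        return [pos, ang]

    tips = [spawn_border_tip() for _ in range(max(6, g // 30))]
    step_len = max(3.0, g / 60.0)       # capillary-scale stroke length
    target = params.target_perfusion
    check_every = 60
    max_segments = 800 * g              # hard cap against runaway loops

    n_since_check = 0
    while len(segments) < max_segments:
        if not tips:
            tips.append(spawn_border_tip())
            # also branch from the existing network to fill the interior
            if segments:
                seg = segments[rng.integers(len(segments))]
                p = seg[rng.integers(len(seg))].astype(float)
                tips.append([p, rng.uniform(0, 2 * math.pi)])
        i_tip = int(rng.integers(len(tips)))
        pos, ang = tips[i_tip]
        ang += rng.normal(0.0, 0.55)
        new = pos + step_len * np.array([math.sin(ang), math.cos(ang)])
        rr, cc = draw.line(
            int(round(pos[0])), int(round(pos[1])),
            int(round(new[0])), int(round(new[1])),
        )
        keep = (rr >= 0) & (rr < g) & (cc >= 0) & (cc < g)
        if keep.sum() >= 2:
            seg = np.column_stack([rr[keep], cc[keep]])
            segments.append(seg)
            thin[seg[:, 0], seg[:, 1]] = True
            n_since_check += 1
        if not (0 <= new[0] < g and 0 <= new[1] < g):
            tips.pop(i_tip)
        else:
            tips[i_tip] = [new, ang]
            if rng.random() < 0.18:      # bifurcation
                tips.append([new.copy(), ang + rng.choice([-1.0, 1.0]) * 1.0])
        if len(tips) > 60:
            tips.pop(rng.integers(len(tips)))
        if n_since_check >= check_every:
            n_since_check = 0
            mask = thin.copy()
            mask[faz_mask] = False
            if mask.mean() >= target:
                break
    return segments


def _render(
    segments: list,
    keep: np.ndarray,
    faz_mask: np.ndarray,
    ring_rc: Tuple[np.ndarray, np.ndarray],
    params: VesselSimParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rasterize kept segments into (image, ground-truth mask)."""
    g = params.grid_px
    mask = np.zeros((g, g), dtype=bool)
    for seg, k in zip(segments, keep):
        if k:
            mask[seg[:, 0], seg[:, 1]] = True
    mask[faz_mask] = False
    # terminal capillary ring bounding the FAZ (not subject to dropout)
    mask[ring_rc] = True
    img = np.where(mask, 200.0, 40.0)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


def generate_angiogram(
    params: VesselSimParams,
    laterality: str = "OD",
    signal_strength: int = 9,
) -> Tuple[EnFaceAngiogram, AngiogramTruth]:
    """Render one synthetic en-face angiogram with its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    g = params.grid_px
    theta, r_theta = _faz_radius_profile(rng, params)
    yy, xx = np.mgrid[:g, :g]
    dy, dx = yy - g / 2.0, xx - g / 2.0
    pix_theta = np.mod(np.arctan2(dy, dx), 2 * math.pi)
    idx = np.minimum((pix_theta / (2 * math.pi) * len(theta)).astype(int),
                     len(theta) - 1)
    faz_mask = np.hypot(dy, dx) <= r_theta[idx]

    # terminal capillary ring just outside the avascular zone
    if params.faz_radius_mm > 0:
        ring_r = r_theta + 1.0
        ring_rows = np.clip(np.rint(g / 2.0 + ring_r * np.sin(theta)), 0,
                            g - 1).astype(int)
        ring_cols = np.clip(np.rint(g / 2.0 + ring_r * np.cos(theta)), 0,
                            g - 1).astype(int)
        ring_rc = (ring_rows, ring_cols)
    else:
        ring_rc = (np.array([], dtype=int), np.array([], dtype=int))

    segments = _grow_network(rng, params, faz_mask)
    n_drop = int(round(params.dropout_fraction * len(segments)))
    keep = np.ones(len(segments), dtype=bool)
    if n_drop > 0:
        keep[rng.choice(len(segments), size=n_drop, replace=False)] = False
    img, mask = _render(segments, keep, faz_mask, ring_rc, params, rng)

    ps = params.pixel_size_mm
    contour_px = np.column_stack(
        [g / 2.0 + r_theta * np.sin(theta), g / 2.0 + r_theta * np.cos(theta)]
    )
    contour_mm = np.vstack([contour_px, contour_px[:1]]) * ps
    # polar area integral of the radius profile
    area_mm2 = 0.5 * np.sum(r_theta**2) * (2 * math.pi / len(theta)) * ps**2
    truth = AngiogramTruth(
        vessel_mask=mask,
        faz_mask=faz_mask,
        faz_contour_mm=contour_mm,
        faz_area_mm2=float(area_mm2),
        n_segments=len(segments),
        n_dropped=n_drop,
        params=params,
    )
    image = EnFaceAngiogram(
        pixels=img,
        field_mm=params.field_mm,
        laterality=laterality,
        signal_strength=signal_strength,
        layer_tag="SRL",
    )
    return image, truth


def generate_eye_pair(
    params: PairSimParams,
) -> Tuple[EnFaceAngiogram, EnFaceAngiogram, PairTruth]:
    """Render a fellow-eye pair (OD, OS) with asymmetry ground truth.

    The degraded eye is chosen by a fair coin flip from the pair's RNG
    stream, so sidedness carries no systematic signal.
    """
    params.validate()
    rng = np.random.default_rng(params.base.seed)
    degraded = "OD" if rng.random() < 0.5 else "OS"
    seed_od = int(rng.integers(2**31))
    seed_os = int(rng.integers(2**31))

    def eye_params(lat: str, seed: int) -> VesselSimParams:
        p = replace(params.base, seed=seed)
        if lat == degraded:
            p = replace(
                p,
                dropout_fraction=p.dropout_fraction
                + params.asymmetry_dropout_delta,
                faz_radius_mm=p.faz_radius_mm
                * (1.0 + params.asymmetry_faz_delta),
            )
        return p

    od_img, od_truth = generate_angiogram(eye_params("OD", seed_od), "OD")
    os_img, os_truth = generate_angiogram(eye_params("OS", seed_os), "OS")
    return od_img, os_img, PairTruth(degraded_eye=degraded, od=od_truth, os=os_truth)


# --------------------------------------------------------------------------
# cohort-level simulation
# --------------------------------------------------------------------------

RACES = ("Non-Hispanic White", "Non-Hispanic Black", "Hispanic", "Asian", "Others")


@dataclass
class GroupSpec:
    """One DR-severity group: sample size, demographics, asymmetry scales.

    ``ai_mean`` gives the expected asymmetry index (%) per AI column; the
    generator draws AI = |N(0, tau^2)| with tau = mean / sqrt(2/pi), the
    half-normal scale that reproduces that expectation.
    """

    name: str
    n: int
    ai_mean: Dict[str, float]
    age_mean: float
    age_sd: float
    female_p: float
    race_p: Dict[str, float]
    hba1c_mean: Optional[float]      # None for the non-diabetic group
    hba1c_sd: Optional[float]
    htn_p: float
    hld_p: float
    obesity_p: float
    insulin_p: Optional[float]       # None for the non-diabetic group
    smoking_p: float
    al_mean: float
    al_sd: float
    cmt_mean: float
    cmt_sd: float

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError(f"group {self.name}: sample size must be >= 0")
        for col, m in self.ai_mean.items():
            if m < 0:
                raise ParameterError(f"group {self.name}: ai_mean[{col}] < 0")


@dataclass
class CohortSpec:
    """Whole-cohort generator specification.

    ``hba1c_ai_slope`` injects a known additive linear dependence of each
    AI column on HbA1c (AI% per HbA1c%) within the diabetic groups, so
    correlation- and regression-recovery experiments have a known truth.
    ``pair_params_by_group`` configures the image-level renderer when
    images are requested.
    """

    groups: Tuple[GroupSpec, ...]
    hba1c_ai_slope: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    image_params: VesselSimParams = field(default_factory=VesselSimParams)

    def validate(self) -> None:
        if not self.groups:
            raise ParameterError("cohort spec has no groups")
        if sum(gr.n for gr in self.groups) == 0:
            raise ParameterError("cohort spec generates an empty table")
        for gr in self.groups:
            gr.validate()


# Per-group expected asymmetry indices (%): severity-increasing gradient
# with the PDR group far more asymmetric than the rest, the study
# condition the cohort statistics are exercised under.
_DEFAULT_AI_MEANS = {
    "no DM": dict(ai_spd=3.5, ai_svd=3.8, ai_dpd=5.6, ai_dvd=4.5,
                  ai_faza=10.9, ai_fazp=7.6, ai_fazc=8.1),
    "DM without DR": dict(ai_spd=4.1, ai_svd=4.4, ai_dpd=4.8, ai_dvd=4.5,
                          ai_faza=11.2, ai_fazp=8.0, ai_fazc=9.2),
    "NPDR": dict(ai_spd=5.8, ai_svd=5.8, ai_dpd=5.7, ai_dvd=5.5,
                 ai_faza=13.2, ai_fazp=10.5, ai_fazc=14.7),
    "PDR": dict(ai_spd=22.1, ai_svd=21.5, ai_dpd=10.5, ai_dvd=9.0,
                ai_faza=45.6, ai_fazp=33.0, ai_fazc=24.5),
}

_DEFAULT_DEMOGRAPHICS = {
    # name: (n, age_mean, age_sd, female_p, race counts, hba1c (m, sd),
    #        htn, hld, obesity, insulin, smoking, AL (m, sd), CMT (m, sd))
    "no DM": (60, 49.0, 14.1, 0.50, (9, 10, 29, 9, 3), None,
              0.50, 0.53, 0.45, None, 0.30, (23.67, 1.08), (234, 16)),
    "DM without DR": (132, 53.5, 11.0, 0.55, (12, 16, 63, 28, 13), (7.8, 2.0),
                      0.52, 0.53, 0.43, 0.24, 0.41, (23.50, 1.03), (238, 21)),
    "NPDR": (40, 51.3, 10.9, 0.38, (5, 3, 17, 7, 8), (9.4, 2.3),
             0.53, 0.63, 0.43, 0.20, 0.48, (23.59, 0.95), (244, 18)),
    "PDR": (26, 53.4, 9.4, 0.27, (4, 5, 13, 2, 2), (10.2, 2.8),
            0.50, 0.50, 0.35, 0.31, 0.42, (23.33, 1.63), (241, 25)),
}

#: Additive AI%-per-HbA1c% slopes injected by default within the diabetic
#: groups; FAZ shape asymmetry responds more strongly than density
#: asymmetry.
DEFAULT_HBA1C_AI_SLOPE = {
    "ai_spd": 0.5,
    "ai_svd": 0.5,
    "ai_fazp": 0.8,
    "ai_fazc": 0.8,
}

# per-eye mean metric values by severity: densities decline and the FAZ
# enlarges as retinopathy worsens
_BASE_METRICS = dict(spd=36.0, svd=18.0, dpd=40.0, dvd=19.0,
                     faza=0.28, fazp=2.0, fazc=0.70)
_SEVERITY_DENSITY_FACTOR = {"no DM": 1.00, "DM without DR": 0.97,
                            "NPDR": 0.90, "PDR": 0.80}
_SEVERITY_FAZ_FACTOR = {"no DM": 1.00, "DM without DR": 1.05,
                        "NPDR": 1.20, "PDR": 1.50}
# FAZ boundary irregularity grows with severity, so circularity declines
_SEVERITY_FAZC_FACTOR = {"no DM": 1.00, "DM without DR": 0.96,
                         "NPDR": 0.88, "PDR": 0.75}

_AI_TO_METRIC = {
    "ai_spd": "spd", "ai_svd": "svd", "ai_dpd": "dpd", "ai_dvd": "dvd",
    "ai_faza": "faza", "ai_fazp": "fazp", "ai_fazc": "fazc",
}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default study conditions: a 258-patient, 4-group cohort
    (60 / 132 / 40 / 26) with a severity-increasing asymmetry gradient and
    an HbA1c-asymmetry coupling in the diabetic groups."""
    groups = []
    for name in GROUPS:
        (n, age_m, age_sd, fem, race_counts, hba1c, htn, hld, ob, ins, smk,
         al, cmt) = _DEFAULT_DEMOGRAPHICS[name]
        total = sum(race_counts)
        groups.append(
            GroupSpec(
                name=name,
                n=n,
                ai_mean=dict(_DEFAULT_AI_MEANS[name]),
                age_mean=age_m,
                age_sd=age_sd,
                female_p=fem,
                race_p={r: c / total for r, c in zip(RACES, race_counts)},
                hba1c_mean=None if hba1c is None else hba1c[0],
                hba1c_sd=None if hba1c is None else hba1c[1],
                htn_p=htn,
                hld_p=hld,
                obesity_p=ob,
                insulin_p=ins,
                smoking_p=smk,
                al_mean=al[0],
                al_sd=al[1],
                cmt_mean=cmt[0],
                cmt_sd=cmt[1],
            )
        )
    return CohortSpec(
        groups=tuple(groups),
        hba1c_ai_slope=dict(DEFAULT_HBA1C_AI_SLOPE),
        seed=seed,
    )


def cohort_spec_from_dict(data: dict) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain (YAML/JSON) mapping.

    Starts from :func:`default_cohort_spec` and overrides: ``groups`` is a
    list of mappings keyed by ``name`` whose remaining keys override the
    matching default group (unknown names must specify every field);
    ``hba1c_ai_slope``, ``seed`` and ``image_params`` override wholesale.
    """
    spec = default_cohort_spec(seed=int(data.get("seed", 0)))
    by_name = {g.name: g for g in spec.groups}
    if "groups" in data:
        groups = []
        for gd in data["groups"]:
            gd = dict(gd)
            name = gd.pop("name")
            if name in by_name:
                groups.append(replace(by_name[name], **gd))
            else:
                groups.append(GroupSpec(name=name, **gd))
        spec = replace(spec, groups=tuple(groups))
    if "hba1c_ai_slope" in data:
        spec = replace(spec, hba1c_ai_slope=dict(data["hba1c_ai_slope"]))
    if "image_params" in data:
        spec = replace(spec, image_params=VesselSimParams(**data["image_params"]))
    return spec


def _draw_patient_ais(
    rng: np.random.Generator,
    group: GroupSpec,
    hba1c: Optional[float],
    slopes: Dict[str, float],
) -> Dict[str, float]:
    """Half-normal AI draw per column plus the additive HbA1c term.

    The HbA1c term is centred on the group's HbA1c mean, so it injects a
    within-group slope without shifting the calibrated group AI means and
    stays orthogonal to disease severity. AI is clipped to [0, 199].
    """
    out = {}
    for col in AI_COLUMNS:
        mean = group.ai_mean.get(col, 0.0)
        tau = mean / _HALF_NORMAL_MEAN
        ai = abs(rng.normal(0.0, tau)) if tau > 0 else 0.0
        if hba1c is not None and col in slopes and group.hba1c_mean is not None:
            ai += slopes[col] * (hba1c - group.hba1c_mean)
        out[col] = float(np.clip(ai, 0.0, 199.0))
    return out


def generate_cohort(
    spec: CohortSpec,
    render_images: bool = False,
) -> pd.DataFrame | Tuple[pd.DataFrame, Dict[str, tuple]]:
    """Generate a cohort table (one row per patient).

    Each row carries covariates, per-eye metric values for the seven
    tracked quantities (``spd_od`` ... ``fazc_os``) and the corresponding
    asymmetry-index columns (``ai_spd`` ... ``ai_fazc``). The per-eye
    values are constructed so that ``asymmetry_index(od, os)`` reproduces
    the drawn AI exactly, with the larger eye chosen at random.

    With ``render_images=True`` the function also returns a dict mapping
    patient_id to the rendered ``(od_image, os_image, PairTruth)`` triple,
    with the image-level asymmetry driven by the same drawn AI of
    superficial perfusion density (as a dropout delta on the degraded eye).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    images: Dict[str, tuple] = {}
    pid = 0
    for group in spec.groups:
        for _ in range(group.n):
            pid += 1
            patient_id = f"P{pid:04d}"
            hba1c = (
                None
                if group.hba1c_mean is None
                else max(4.5, rng.normal(group.hba1c_mean, group.hba1c_sd))
            )
            ais = _draw_patient_ais(rng, group, hba1c, spec.hba1c_ai_slope)
            dens_f = _SEVERITY_DENSITY_FACTOR.get(group.name, 1.0)
            faz_f = _SEVERITY_FAZ_FACTOR.get(group.name, 1.0)
            row = {
                "patient_id": patient_id,
                "group": group.name,
                "age": float(np.clip(rng.normal(group.age_mean, group.age_sd),
                                     18, 95)),
                "sex": "F" if rng.random() < group.female_p else "M",
                "race": rng.choice(list(group.race_p),
                                   p=list(group.race_p.values())),
                "hba1c": np.nan if hba1c is None else hba1c,
                "htn": int(rng.random() < group.htn_p),
                "hld": int(rng.random() < group.hld_p),
                "obesity": int(rng.random() < group.obesity_p),
                "insulin": (
                    np.nan if group.insulin_p is None
                    else int(rng.random() < group.insulin_p)
                ),
                "smoking": int(rng.random() < group.smoking_p),
                "axial_length_mm": float(
                    np.clip(rng.normal(group.al_mean, group.al_sd), 20.5, 29.5)
                ),
                "cmt_um": float(rng.normal(group.cmt_mean, group.cmt_sd)),
                "ss_od": int(np.clip(np.rint(rng.normal(9.1, 0.6)), 8, 10)),
                "ss_os": int(np.clip(np.rint(rng.normal(9.1, 0.6)), 8, 10)),
            }
            for ai_col, metric in _AI_TO_METRIC.items():
                base = _BASE_METRICS[metric]
                if metric == "fazc":
                    base *= _SEVERITY_FAZC_FACTOR.get(group.name, 1.0)
                elif metric.startswith("faz"):
                    base *= faz_f
                else:
                    base *= dens_f
                base *= float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15))
                # larger eye carries the base value, the fellow eye is
                # scaled down so the pair reproduces the drawn AI exactly
                # while every per-eye value stays within physical bounds
                t = ais[ai_col] / 200.0
                ratio = (1.0 + t) / (1.0 - t)
                if rng.random() < 0.5:
                    od, os_ = base, base / ratio
                else:
                    od, os_ = base / ratio, base
                row[f"{metric}_od"] = od
                row[f"{metric}_os"] = os_
                row[ai_col] = ais[ai_col]
            rows.append(row)
            if render_images:
                delta = 2.0 * ais["ai_spd"] / (200.0 + ais["ai_spd"])
                pair = PairSimParams(
                    base=replace(spec.image_params,
                                 seed=int(rng.integers(2**31))),
                    asymmetry_dropout_delta=min(delta, 0.9),
                    asymmetry_faz_delta=ais["ai_faza"] / 400.0,
                )
                images[patient_id] = generate_eye_pair(pair)
    table = pd.DataFrame(rows)
    return (table, images) if render_images else table
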