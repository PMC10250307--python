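"""Quantification of a single en-face OCTA angiogram.

The measurement chain mirrors standard OCTA post-processing: binarize the
grayscale flow image, measure perfusion density (area fraction of vessel
pixels, %), thin the vessel mask to centerlines and measure vessel density
(centerline length per unit area, mm^-1), segment the foveal avascular zone
(FAZ) as the central avascular component, and derive its area (mm^2),
perimeter (mm) and circularity (4*pi*A/P^2, dimensionless, 1 for a disc).
Lengths and areas can be rescaled for ocular magnification from axial
length using a Bennett-type linear factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d, label
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateImageError,
    EmptyRoiError,
    NoFazError,
    TooSmallRegionError,
    UnboundedFazError,
    ValidationError,
)

#: digitization tolerance on circularity: a pixelated disc may measure
#: slightly above the analytic bound of 1.
CIRCULARITY_TOL = 0.05

#: Bennett-type magnification model: second nodal point sits ~1.82 mm
#: behind the cornea, so image scale grows linearly with (AL - 1.82).
BENNETT_OFFSET_MM = 1.82

#: reference axial length (mm) at which the device scale is calibrated.
DEFAULT_REFERENCE_AL_MM = 24.46


@dataclass
class EnFaceAngiogram:
    """One eye's 2-D grayscale en-face angiogram with acquisition metadata.

    Parameters
    ----------
    pixels:
        Square 2-D array of flow intensities.
    field_mm:
        Physical side length of the scan, mm (3.0 for a 3x3 mm macular cube).
    laterality:
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    signal_strength:
        Device-reported quality score, 0-10. ``None`` if unknown.
    axial_length_mm:
        Biometry axial length, mm; used for magnification correction.
    layer_tag:
        ``"SRL"`` or ``"DRL"`` slab label. Metadata only.
    """

    pixels: np.ndarray
    field_mm: float = 3.0
    laterality: str = "OD"
    signal_strength: Optional[int] = None
    axial_length_mm: Optional[float] = None
    layer_tag: Optional[str] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError("angiogram must be a square 2-D array")
        if self.field_mm <= 0:
            raise ValidationError("field_mm must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValidationError("laterality must be 'OD' or 'OS'")
        if self.signal_strength is not None and not 0 <= self.signal_strength <= 10:
            raise ValidationError("signal_strength must be in [0, 10]")

    @property
    def grid_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size_mm(self) -> float:
        return self.field_mm / self.grid_px


@dataclass
class BinaryVesselMap:
    """Boolean vessel mask (True = vessel) with its physical pixel size."""

    mask: np.ndarray
    pixel_size_mm: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("vessel mask must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ValidationError("pixel_size_mm must be positive")


@dataclass
class SkeletonMap:
    """One-pixel-wide vessel centerlines with physical pixel size."""

    skeleton: np.ndarray
    pixel_size_mm: float

    def __post_init__(self):
        self.skeleton = np.asarray(self.skeleton, dtype=bool)


@dataclass
class FazRegion:
    """The central avascular region: pixel mask plus sub-pixel contour.

    ``contour`` is an (n, 2) array of (row, col) coordinates in mm.
    """

    mask: np.ndarray
    contour: np.ndarray
    pixel_size_mm: float


@dataclass
class VascularMetrics:
    """Per-eye quantification record.

    perfusion_density is the vessel area fraction in percent (SPD/DPD);
    vessel_density is skeleton length per area in mm^-1 (SVD/DVD); the FAZ
    shape triplet is area (mm^2), perimeter (mm) and circularity
    (dimensionless).
    """

    perfusion_density: float
    vessel_density: float
    faz_area: float
    faz_perimeter: float
    faz_circularity: float
    corrected: bool = False
    layer_tag: Optional[str] = None

    def __post_init__(self):
        # NaN marks a missing measurement and is allowed anywhere
        if not math.isnan(self.perfusion_density) and not (
            0 <= self.perfusion_density <= 100
        ):
            raise ValidationError("perfusion_density must be in [0, 100]")
        for name in ("vessel_density", "faz_area", "faz_perimeter"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not math.isnan(self.faz_circularity) and not (
            0 < self.faz_circularity <= 1 + CIRCULARITY_TOL
        ):
            raise ValidationError(
                f"faz_circularity must be in (0, {1 + CIRCULARITY_TOL}]"
            )


def quality_check(image: EnFaceAngiogram, min_ss: int = 8) -> Tuple[bool, str]:
    """Image-quality gate on device signal strength.

    Scans with signal strength below ``min_ss`` (default 8, i.e. a score of
    7 or less) are excluded from analysis.

    Returns ``(passed, reason)``; ``reason`` names the rule on failure.
    """
    if image.signal_strength is None:
        raise ValidationError("signal strength missing; cannot run quality check")
    if image.signal_strength < min_ss:
        return False, (
            f"signal strength {image.signal_strength} < {min_ss} "
            "(low-quality scan excluded)"
        )
    return True, "ok"


def binarize(
    image: EnFaceAngiogram,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> BinaryVesselMap:
    """Threshold the grayscale angiogram into a binary vessel map.

    ``method="otsu"`` picks the threshold by between-class variance
    maximisation; ``method="fixed"`` marks pixels ``>= threshold`` as vessel.
    A constant image has no Otsu threshold and raises
    :class:`DegenerateImageError`.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValidationError("empty image")
    if method == "fixed":
        if threshold is None:
            raise ValidationError("fixed binarization requires a threshold")
        mask = px >= threshold
    elif method == "otsu":
        if np.ptp(px) == 0:
            raise DegenerateImageError(
                "constant image: Otsu threshold undefined; supply a fixed threshold"
            )
        thr = threshold_otsu(px)
        mask = px > thr
    else:
        raise ValidationError(f"unknown binarization method {method!r}")
    return BinaryVesselMap(mask=mask, pixel_size_mm=image.pixel_size_mm)


def perfusion_density(
    vessels: BinaryVesselMap, roi: Optional[np.ndarray] = None
) -> float:
    """Percentage of ROI pixels occupied by vessels (full image by default)."""
    mask = vessels.mask
    if roi is None:
        roi = np.ones_like(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValidationError("roi shape does not match mask shape")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyRoiError("empty ROI: perfusion density undefined")
    return 100.0 * int((mask & roi).sum()) / n_roi


def skeletonize(vessels: BinaryVesselMap) -> SkeletonMap:
    """Thin the vessel mask to 1-pixel-wide centerlines.

    Uses topology-preserving 2-D thinning (Zhang-Suen style), which keeps
    the number of 8-connected components.
    """
    sk = morphology.skeletonize(vessels.mask, method="zhang")
    return SkeletonMap(skeleton=sk, pixel_size_mm=vessels.pixel_size_mm)


def skeleton_length_mm(skeleton: SkeletonMap) -> float:
    """Total centerline length in mm.

    Each 8-connected adjacency between skeleton pixels counts once: axial
    steps contribute one pixel size, diagonal steps sqrt(2) pixel sizes.
    An isolated pixel (no neighbours) contributes one pixel size, standing
    in for a vessel fragment of sub-pixel extent.
    """
    sk = skeleton.skeleton
    ps = skeleton.pixel_size_mm
    n_axial = int((sk[:, 1:] & sk[:, :-1]).sum() + (sk[1:, :] & sk[:-1, :]).sum())
    n_diag = int(
        (sk[1:, 1:] & sk[:-1, :-1]).sum() + (sk[1:, :-1] & sk[:-1, 1:]).sum()
    )
    # isolated pixels: no neighbour in the 8-neighbourhood
    padded = np.pad(sk, 1)
    neigh = np.zeros(sk.shape, dtype=int)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh += padded[1 + dr : 1 + dr + sk.shape[0],
                            1 + dc : 1 + dc + sk.shape[1]]
    n_isolated = int((sk & (neigh == 0)).sum())
    return (n_axial + math.sqrt(2.0) * n_diag + n_isolated) * ps


def vessel_density(
    skeleton: SkeletonMap, roi: Optional[np.ndarray] = None
) -> float:
    """Skeletonized vessel length per unit area, mm^-1 (ROI = full image)."""
    sk = skeleton.skeleton
    if roi is None:
        roi = np.ones_like(sk, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyRoiError("empty ROI: vessel density undefined")
    area_mm2 = n_roi * skeleton.pixel_size_mm**2
    if roi.all():
        length = skeleton_length_mm(skeleton)
    else:
        masked = SkeletonMap(sk & roi, skeleton.pixel_size_mm)
        length = skeleton_length_mm(masked)
    return length / area_mm2


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def segment_faz(
    vessels: BinaryVesselMap, closing_radius_px: int = 2
) -> FazRegion:
    """Segment the foveal avascular zone.

    Morphologically closes the vessel mask (bridging single-pixel gaps in
    the FAZ border), then takes the 4-connected avascular component that
    contains the image centre. The boundary contour is extracted at
    sub-pixel resolution by iso-contouring the region mask at level 0.5 and
    lightly smoothed along the contour before arc-length measurement.

    Raises :class:`NoFazError` if the centre pixel is vascular after
    closing, and :class:`UnboundedFazError` if the central avascular
    component reaches the image border.
    """
    mask = vessels.mask
    if mask.size == 0:
        raise ValidationError("empty mask")
    if closing_radius_px > 0:
        closed = morphology.closing(mask, morphology.disk(closing_radius_px))
    else:
        closed = mask
    avascular = ~closed
    labels, _ = label(avascular, structure=_FOUR_CONN)
    r0, c0 = mask.shape[0] // 2, mask.shape[1] // 2
    lab = labels[r0, c0]
    if lab == 0:
        raise NoFazError("image centre is vascular after closing: no FAZ found")
    region = labels == lab
    border = (
        region[0, :].any()
        or region[-1, :].any()
        or region[:, 0].any()
        or region[:, -1].any()
    )
    if border:
        raise UnboundedFazError("central avascular region touches the image border")
    contour_px = _region_contour(region)
    return FazRegion(
        mask=region,
        contour=contour_px * vessels.pixel_size_mm,
        pixel_size_mm=vessels.pixel_size_mm,
    )


def _region_contour(region: np.ndarray, smooth_sigma: float = 1.5) -> np.ndarray:
    """Closed sub-pixel boundary of a binary region, in pixel coordinates.

    Marching squares at level 0.5, then circular Gaussian smoothing along
    the polygon. The smoothing removes the stair-step excess that otherwise
    inflates the arc length of digitized smooth boundaries by ~5%.
    """
    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        raise TooSmallRegionError("region has no extractable contour")
    contour = max(contours, key=len)
    closed = np.allclose(contour[0], contour[-1])
    pts = contour[:-1] if closed else contour
    if len(pts) >= 8 and closed:
        pts = np.column_stack(
            [
                gaussian_filter1d(pts[:, 0], smooth_sigma, mode="wrap"),
                gaussian_filter1d(pts[:, 1], smooth_sigma, mode="wrap"),
            ]
        )
    return np.vstack([pts, pts[:1]])


def faz_shape_metrics(region: FazRegion) -> Tuple[float, float, float]:
    """FAZ area (mm^2), perimeter (mm) and circularity.

    Area is the pixel count times the pixel area; perimeter is the arc
    length of the sub-pixel contour; circularity is the isoperimetric ratio
    4*pi*A/P^2, equal to 1 for a disc, capped at the digitization tolerance.
    """
    n_px = int(region.mask.sum())
    if n_px < 4:
        raise TooSmallRegionError(
            f"FAZ region has only {n_px} pixels; shape metrics unreliable"
        )
    area = n_px * region.pixel_size_mm**2
    d = np.diff(region.contour, axis=0)
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())
    circularity = min(4.0 * math.pi * area / perimeter**2, 1.0 + CIRCULARITY_TOL)
    return area, perimeter, circularity


def correct_magnification(
    metrics: VascularMetrics,
    axial_length_mm: float,
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM,
) -> VascularMetrics:
    """Rescale metrics for ocular magnification from axial length.

    A Bennett-type model: the true retinal scale is proportional to
    (AL - 1.82 mm), so measurements made assuming the reference axial
    length are rescaled by f = (AL - 1.82)/(ref - 1.82). Lengths scale by
    f, areas by f^2, and length-per-area densities by 1/f. Dimensionless
    quantities (perfusion density, circularity) are unchanged.
    """
    if not 20.0 <= axial_length_mm <= 30.0:
        raise ValidationError(
            f"axial length {axial_length_mm} mm outside plausible range [20, 30]"
        )
    if metrics.corrected:
        raise ValidationError("metrics already magnification-corrected")
    f = (axial_length_mm - BENNETT_OFFSET_MM) / (reference_al_mm - BENNETT_OFFSET_MM)
    return replace(
        metrics,
        faz_area=metrics.faz_area * f**2,
        faz_perimeter=metrics.faz_perimeter * f,
        vessel_density=metrics.vessel_density / f,
        corrected=True,
    )


def quantify_angiogram(
    image: EnFaceAngiogram,
    binarize_method: str = "otsu",
    threshold: Optional[float] = None,
    closing_radius_px: int = 2,
    correct: bool = False,
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM,
) -> VascularMetrics:
    """Full single-eye quantification: binarize -> densities -> FAZ shape.

    Convenience wrapper chaining the individual operations with their
    default settings; set ``correct=True`` to apply magnification
    correction using the image's ``axial_length_mm``.
    """
    vessels = binarize(image, method=binarize_method, threshold=threshold)
    pd = perfusion_density(vessels)
    vd = vessel_density(skeletonize(vessels))
    faz = segment_faz(vessels, closing_radius_px=closing_radius_px)
    area, perim, circ = faz_shape_metrics(faz)
    out = VascularMetrics(
        perfusion_density=pd,
        vessel_density=vd,
        faz_area=area,
        faz_perimeter=perim,
        faz_circularity=circ,
        layer_tag=image.layer_tag,
    )
    if correct:
        if image.axial_length_mm is None:
            raise ValidationError("axial length required for correction")
        out = correct_magnification(
            out, image.axial_length_mm, reference_al_mm=reference_al_mm
        )
    return out
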