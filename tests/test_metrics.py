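"""Unit and property tests for single-eye angiogram quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octa_asym import errors
from octa_asym.metrics import (
    BinaryVesselMap,
    EnFaceAngiogram,
    SkeletonMap,
    VascularMetrics,
    binarize,
    correct_magnification,
    faz_shape_metrics,
    perfusion_density,
    quality_check,
    quantify_angiogram,
    segment_faz,
    skeleton_length_mm,
    skeletonize,
    vessel_density,
)

from conftest import as_angiogram, disc_mask, vessel_map_with_hole

PS = 3.0 / 245  # pixel size of the reference scan geometry, mm


# ---------------------------------------------------------------- quality

@pytest.mark.parametrize("ss,expected", [(7, False), (8, True), (10, True)])
def test_quality_gate_threshold(ss, expected):
    """Scans with signal strength of 7 or less are excluded; 8+ pass."""
    img = as_angiogram(np.zeros((8, 8)), signal_strength=ss)
    passed, reason = quality_check(img)
    assert passed is expected
    if not passed:
        assert "signal strength" in reason


def test_quality_gate_requires_signal_strength():
    img = as_angiogram(np.zeros((8, 8)), signal_strength=None)
    with pytest.raises(errors.ValidationError):
        quality_check(img)


# ---------------------------------------------------------------- binarize

def test_binarize_fixed_threshold_on_dark_image():
    img = as_angiogram(np.zeros((16, 16)))
    mask = binarize(img, method="fixed", threshold=1).mask
    assert not mask.any()


def test_binarize_otsu_separates_two_level_image():
    rng = np.random.default_rng(0)
    px = np.where(rng.random((32, 32)) < 0.4, 200, 10)
    mask = binarize(as_angiogram(px), method="otsu").mask
    assert (mask == (px == 200)).all()


def test_binarize_otsu_rejects_constant_image():
    with pytest.raises(errors.DegenerateImageError):
        binarize(as_angiogram(np.full((16, 16), 7.0)), method="otsu")


def test_binarize_recovers_generator_truth(clean_angiogram):
    """A noiseless synthetic scan binarizes exactly to its ground truth."""
    image, truth = clean_angiogram
    mask = binarize(image, method="otsu").mask
    assert (mask == truth.vessel_mask).all()


# ------------------------------------------------------- perfusion density

def test_perfusion_density_analytic_values():
    full = BinaryVesselMap(np.ones((10, 10), bool), PS)
    assert perfusion_density(full) == 100.0
    half = np.zeros((10, 10), bool)
    half[:5] = True
    assert perfusion_density(BinaryVesselMap(half, PS)) == 50.0


def test_perfusion_density_brute_force_oracle():
    """Exact agreement with a double-loop pixel count on random masks."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        mask = rng.random((32, 32)) < rng.uniform(0.1, 0.9)
        count = sum(
            1 for i in range(32) for j in range(32) if mask[i, j]
        )
        assert perfusion_density(BinaryVesselMap(mask, PS)) == 100 * count / 1024


def test_perfusion_density_empty_roi_raises():
    vm = BinaryVesselMap(np.ones((4, 4), bool), PS)
    with pytest.raises(errors.EmptyRoiError):
        perfusion_density(vm, roi=np.zeros((4, 4), bool))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_perfusion_density_rotation_and_flip_invariant(seed):
    """Density is unchanged by 90-degree rotations and the OD/OS mirror."""
    mask = np.random.default_rng(seed).random((21, 21)) < 0.4
    base = perfusion_density(BinaryVesselMap(mask, PS))
    for k in (1, 2, 3):
        assert perfusion_density(BinaryVesselMap(np.rot90(mask, k), PS)) == base
    assert perfusion_density(BinaryVesselMap(mask[:, ::-1], PS)) == base


# ----------------------------------------------------- skeleton and length

def test_skeletonize_degenerate_inputs():
    empty = skeletonize(BinaryVesselMap(np.zeros((8, 8), bool), PS))
    assert not empty.skeleton.any()
    single = np.zeros((8, 8), bool)
    single[3, 4] = True
    assert (skeletonize(BinaryVesselMap(single, PS)).skeleton == single).all()


def test_skeletonize_thins_bar_to_single_path():
    """A 5x50 bar thins to a 1-px path of 50 +/- 4 pixels (end effects)."""
    mask = np.zeros((20, 60), bool)
    mask[8:13, 5:55] = True
    sk = skeletonize(BinaryVesselMap(mask, PS)).skeleton
    assert sk.sum() == pytest.approx(50, abs=4)
    assert (sk & ~mask).sum() == 0  # centerline lies on the mask
    # 1-px wide: no 2x2 block fully set
    assert not (sk[1:, 1:] & sk[:-1, 1:] & sk[1:, :-1] & sk[:-1, :-1]).any()


@pytest.mark.parametrize("orientation", ["horizontal", "vertical", "diagonal"])
def test_skeleton_length_closed_forms(orientation):
    """Step-count length: (n-1) axial steps, or (n-1) sqrt(2) diagonal."""
    n = 30
    grid = np.zeros((40, 40), bool)
    if orientation == "horizontal":
        grid[20, 5:5 + n] = True
        expected = (n - 1) * PS
    elif orientation == "vertical":
        grid[5:5 + n, 20] = True
        expected = (n - 1) * PS
    else:
        idx = np.arange(n)
        grid[5 + idx, 5 + idx] = True
        expected = (n - 1) * math.sqrt(2) * PS
    assert skeleton_length_mm(SkeletonMap(grid, PS)) == pytest.approx(expected)


def test_skeleton_length_isolated_pixel_counts_once():
    grid = np.zeros((9, 9), bool)
    grid[4, 4] = True
    assert skeleton_length_mm(SkeletonMap(grid, PS)) == pytest.approx(PS)


def test_vessel_density_straight_runs():
    n, side = 25, 40
    area = side * side * PS**2
    grid = np.zeros((side, side), bool)
    grid[10, 3:3 + n] = True
    assert vessel_density(SkeletonMap(grid, PS)) == pytest.approx(
        (n - 1) * PS / area
    )
    assert vessel_density(SkeletonMap(np.zeros((side, side), bool), PS)) == 0.0


def test_vessel_density_mirror_symmetric():
    """Fellow-eye mirror: a skeleton and its horizontal flip have exactly
    the same centerline length, hence the same vessel density."""
    rng = np.random.default_rng(3)
    sk_mask = skeletonize(
        BinaryVesselMap(rng.random((33, 33)) < 0.3, PS)
    ).skeleton
    sk = SkeletonMap(sk_mask, PS)
    sk_flip = SkeletonMap(sk_mask[:, ::-1], PS)
    assert vessel_density(sk) == vessel_density(sk_flip)


# ---------------------------------------------------------------- FAZ

def test_segment_faz_disc_hole_area():
    """Area of a segmented circular hole is within 2% of pi r^2."""
    for r in (15, 30):
        region = segment_faz(vessel_map_with_hole(r))
        assert region.mask.sum() == pytest.approx(math.pi * r**2, rel=0.02)


def test_segment_faz_fully_avascular_is_unbounded():
    vm = BinaryVesselMap(np.zeros((64, 64), bool), PS)
    with pytest.raises(errors.UnboundedFazError):
        segment_faz(vm)


def test_segment_faz_vascular_center_raises():
    vm = BinaryVesselMap(np.ones((64, 64), bool), PS)
    with pytest.raises(errors.NoFazError):
        segment_faz(vm)


def test_segment_faz_matches_generator_disc(clean_angiogram):
    """With a regular FAZ the segmented region overlaps truth (Dice>0.95)."""
    image, truth = clean_angiogram
    region = segment_faz(binarize(image))
    inter = (region.mask & truth.faz_mask).sum()
    dice = 2 * inter / (region.mask.sum() + truth.faz_mask.sum())
    assert dice > 0.95


@pytest.mark.parametrize("radius", [10, 20, 40, 60])
def test_faz_shape_metrics_discs(radius):
    """Discs: area within 2%, perimeter within 3%, circularity in
    [0.95, 1.05] across the clinically relevant radius range."""
    region = segment_faz(vessel_map_with_hole(radius, pad=12))
    area, perim, circ = faz_shape_metrics(region)
    assert area == pytest.approx(math.pi * (radius * PS) ** 2, rel=0.02)
    assert perim == pytest.approx(2 * math.pi * radius * PS, rel=0.03)
    assert 0.95 <= circ <= 1.05


def test_faz_shape_metrics_square_anchor():
    """A square region has circularity 4*pi*s^2/(4s)^2 = pi/4 exactly."""
    from octa_asym.metrics import FazRegion

    side = 40
    mask = np.zeros((100, 100), bool)
    mask[30:30 + side, 30:30 + side] = True
    s_mm = side * PS
    contour = PS * np.array(
        [[29.5, 29.5], [29.5, 69.5], [69.5, 69.5], [69.5, 29.5], [29.5, 29.5]]
    )
    area, perim, circ = faz_shape_metrics(
        FazRegion(mask=mask, contour=contour, pixel_size_mm=PS)
    )
    assert area == pytest.approx(s_mm**2)
    assert perim == pytest.approx(4 * s_mm)
    assert circ == pytest.approx(math.pi / 4)


def test_faz_square_hole_through_pipeline():
    """Segmenting a square hole reads near pi/4; contour smoothing rounds
    the corners slightly upward, and well below a disc's reading."""
    side = 40
    mask = np.ones((100, 100), bool)
    mask[30:30 + side, 30:30 + side] = False
    _, _, circ = faz_shape_metrics(
        segment_faz(BinaryVesselMap(mask, PS), closing_radius_px=0)
    )
    assert math.pi / 4 - 0.02 <= circ <= math.pi / 4 + 0.08
    _, _, c_disc = faz_shape_metrics(segment_faz(vessel_map_with_hole(22)))
    assert circ < c_disc - 0.1


def test_faz_circularity_penalizes_elongation():
    """Isoperimetric inequality: a 2:1 ellipse is less circular than a
    disc of the same area."""
    n = 140
    yy, xx = np.mgrid[:n, :n]
    ellipse = ((yy - n / 2) / 20) ** 2 + ((xx - n / 2) / 40) ** 2 <= 1
    disc = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= 20 * 40  # equal area
    _, _, c_ell = faz_shape_metrics(segment_faz(BinaryVesselMap(~ellipse, PS)))
    _, _, c_disc = faz_shape_metrics(segment_faz(BinaryVesselMap(~disc, PS)))
    assert c_ell < c_disc


def test_faz_shape_metrics_too_small_region():
    from octa_asym.metrics import FazRegion

    tiny = FazRegion(mask=np.zeros((8, 8), bool),
                     contour=np.zeros((2, 2)), pixel_size_mm=PS)
    with pytest.raises(errors.TooSmallRegionError):
        faz_shape_metrics(tiny)


# ------------------------------------------------- magnification correction

def _metrics():
    return VascularMetrics(perfusion_density=35.0, vessel_density=18.0,
                           faz_area=0.30, faz_perimeter=2.1,
                           faz_circularity=0.85)


def test_magnification_identity_at_reference():
    out = correct_magnification(_metrics(), 24.46)
    for name in ("perfusion_density", "vessel_density", "faz_area",
                 "faz_perimeter", "faz_circularity"):
        assert getattr(out, name) == pytest.approx(getattr(_metrics(), name))
    assert out.corrected


@pytest.mark.parametrize("al", np.linspace(20.0, 30.0, 11).tolist())
def test_magnification_fixed_points(al):
    """Circularity and perfusion density never change with axial length."""
    out = correct_magnification(_metrics(), al)
    assert out.faz_circularity == _metrics().faz_circularity
    assert out.perfusion_density == _metrics().perfusion_density


def test_magnification_bennett_scaling_hand_computed():
    """At the cohort-mean axial length 23.55 mm the linear factor is
    (23.55-1.82)/(24.46-1.82); areas scale by its square."""
    f = (23.55 - 1.82) / (24.46 - 1.82)
    out = correct_magnification(_metrics(), 23.55)
    assert out.faz_area == pytest.approx(0.30 * f**2)
    assert out.faz_perimeter == pytest.approx(2.1 * f)
    assert out.vessel_density == pytest.approx(18.0 / f)


def test_magnification_errors():
    with pytest.raises(errors.ValidationError):
        correct_magnification(_metrics(), 31.0)
    once = correct_magnification(_metrics(), 23.0)
    with pytest.raises(errors.ValidationError):
        correct_magnification(once, 23.0)


# ------------------------------------------------------------- end to end

def test_quantify_angiogram_regular_faz_is_circular(clean_angiogram):
    image, truth = clean_angiogram
    m = quantify_angiogram(image)
    assert m.faz_circularity == pytest.approx(1.0, abs=0.05)
    assert m.faz_area == pytest.approx(truth.faz_area_mm2, rel=0.05)
    assert m.perfusion_density == pytest.approx(
        100 * truth.vessel_mask.mean(), abs=1e-9
    )
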