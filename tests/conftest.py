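"""Shared fixtures: analytic masks and small noiseless synthetic scans."""

import numpy as np
import pytest

from octa_asym.metrics import BinaryVesselMap, EnFaceAngiogram
from octa_asym.synth import VesselSimParams, generate_angiogram


def disc_mask(radius_px: int, pad: int = 10) -> np.ndarray:
    """Boolean disc: pixels whose centre lies within radius of the grid
    centre (inclusive)."""
    n = 2 * radius_px + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    return np.hypot(yy - n // 2, xx - n // 2) <= radius_px


def vessel_map_with_hole(radius_px: int, pad: int = 10,
                         pixel_size_mm: float = 3.0 / 245) -> BinaryVesselMap:
    """Fully vascular field with a central disc-shaped avascular hole."""
    return BinaryVesselMap(mask=~disc_mask(radius_px, pad),
                           pixel_size_mm=pixel_size_mm)


@pytest.fixture(scope="session")
def clean_angiogram():
    """Noiseless, regular-FAZ synthetic scan with its ground truth."""
    params = VesselSimParams(seed=101, noise_sd=0.0, faz_irregularity=0.0)
    return generate_angiogram(params)


@pytest.fixture(scope="session")
def small_angiogram():
    """Fast low-resolution noiseless scan for pipeline-level tests."""
    params = VesselSimParams(grid_px=128, seed=202, noise_sd=0.0)
    return generate_angiogram(params)


def as_angiogram(pixels, **kw) -> EnFaceAngiogram:
    kw.setdefault("signal_strength", 9)
    return EnFaceAngiogram(pixels=np.asarray(pixels), **kw)
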