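import numpy as np
import pytest

from noduletex.imaging_roi import ImagePatch, RoiMask
from noduletex.synthetic_cohort import CohortSpec
from noduletex.texture_features import QuantizedRoi, quantize


@pytest.fixture
def small_spec() -> CohortSpec:
    """Fast cohort spec used throughout the unit tests."""
    return CohortSpec(n_positive=4, n_negative=8, image_size=96,
                      axis_range=(8.0, 20.0), seed=11)


@pytest.fixture
def disk_image():
    """A -50 HU disk on -850 HU background with its truth mask."""
    size = 64
    rows, cols = np.mgrid[0:size, 0:size]
    mask = (rows - 32) ** 2 + (cols - 32) ** 2 <= 10**2
    pixels = np.full((size, size), -850.0)
    pixels[mask] = -50.0
    return ImagePatch(pixels=pixels), RoiMask(mask=mask, reader_id="truth")


def make_quantized(levels: np.ndarray, ng: int) -> QuantizedRoi:
    """Wrap an explicit level grid (0 outside ROI) as a QuantizedRoi."""
    levels = np.asarray(levels, dtype=np.int32)
    roi = levels > 0
    return QuantizedRoi(levels=levels, ng=ng,
                        bin_edges=np.linspace(0, 1, ng + 1), roi=roi)


def random_quantized(rng: np.random.Generator, max_side: int = 8,
                     max_ng: int = 4) -> QuantizedRoi:
    """Random small quantized ROI for oracle-equivalence sweeps."""
    nrow = rng.integers(2, max_side + 1)
    ncol = rng.integers(2, max_side + 1)
    ng = int(rng.integers(2, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=(nrow, ncol)).astype(np.int32)
    roi = rng.random((nrow, ncol)) < 0.8
    if not roi.any():
        roi[rng.integers(nrow), rng.integers(ncol)] = True
    levels[~roi] = 0
    return QuantizedRoi(levels=levels, ng=ng,
                        bin_edges=np.linspace(0, 1, ng + 1), roi=roi)
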