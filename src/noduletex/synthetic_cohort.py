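"""Synthetic part-solid nodule cohorts, feature tables and reader predictions.

Every generator here is a pure function of its arguments and seed, so any
downstream stage can be exercised without external data. The default cohort
mimics the target cohort structure: 16 positive (solid/micropapillary
component present) and 48 negative cases on a 1024-pixel grid with
~0.337 mm pixels; ground-glass around -600 HU, solid around -50 HU, lung
background around -850 HU. Positive-class nodules carry both a larger
solid fraction and stronger intra-nodule speckle so that first-order and
matrix texture features are all informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_roi import HU_MAX, HU_MIN, ImagePatch, RoiMask, write_image, write_mask


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_positive: int = 16
    n_negative: int = 48
    image_size: int = 1024
    pixel_spacing: float = 345.0 / 1024  # 34.5 cm FOV on a 1024 matrix
    hu_lung: float = -850.0
    hu_ggo: float = -600.0
    hu_solid: float = -50.0
    noise_sd: float = 30.0
    solid_fraction_pos: float = 0.40
    solid_fraction_neg: float = 0.05
    speckle_amplitude_pos: float = 120.0
    speckle_amplitude_neg: float = 25.0
    seed: int = 0
    axis_range: Tuple[float, float] = (8.0, 40.0)

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError(
                f"need at least one case per class, got "
                f"{self.n_positive}/{self.n_negative}"
            )
        for name in ("hu_lung", "hu_ggo", "hu_solid"):
            v = getattr(self, name)
            if not (-1024.0 <= v <= 500.0):
                raise ValueError(f"{name}={v} outside [-1024, 500]")
        for name in ("solid_fraction_pos", "solid_fraction_neg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.speckle_amplitude_pos < 0 or self.speckle_amplitude_neg < 0:
            raise ValueError("speckle amplitudes must be >= 0")
        lo, hi = self.axis_range
        if not (2.0 <= lo <= hi):
            raise ValueError(f"axis_range must satisfy 2 <= lo <= hi, got {self.axis_range}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SyntheticCase:
    image: ImagePatch
    truth_mask: RoiMask
    label: int
    case_id: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.truth_mask.n_pixels < 64:
            raise ValueError(
                f"truth mask must have >= 64 pixels, got {self.truth_mask.n_pixels}"
            )


def _ellipse_mask(size: int, center: np.ndarray, axes: np.ndarray,
                  theta: float) -> np.ndarray:
    # evaluate only inside the bounding box; the rest is False by construction
    rad = float(axes.max()) + 1.0
    r0, r1 = max(0, int(center[0] - rad)), min(size, int(center[0] + rad) + 2)
    c0, c1 = max(0, int(center[1] - rad)), min(size, int(center[1] + rad) + 2)
    dr = (np.arange(r0, r1) - center[0])[:, None]
    dc = (np.arange(c0, c1) - center[1])[None, :]
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    box = (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0
    mask = np.zeros((size, size), dtype=bool)
    mask[r0:r1, c0:c1] = box
    return mask


def generate_nodule(spec: CohortSpec, label: int, case_seed: int) -> SyntheticCase:
    """One lung-background image with a single roughly elliptical nodule.

    label=1 mixes ground-glass and solid sub-regions with strong speckle;
    label=0 is predominantly homogeneous ground-glass.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    lo, hi = spec.axis_range
    required = int(2 * np.ceil(hi) + 4)
    if required > spec.image_size:
        raise ValueError(
            f"nodule radius larger than image: max semi-axis {hi} px needs "
            f"{required} px but image_size is {spec.image_size}"
        )

    rng = np.random.default_rng([int(spec.seed), int(case_seed), int(label)])
    size = spec.image_size

    axes = rng.uniform(lo, hi, size=2)
    theta = rng.uniform(0.0, np.pi)
    margin = float(np.ceil(axes.max())) + 2.0
    center = rng.uniform(margin, size - margin, size=2)
    nodule = _ellipse_mask(size, center, axes, theta)

    if label == 1:
        solid_fraction = spec.solid_fraction_pos
        speckle_amp = spec.speckle_amplitude_pos
    else:
        solid_fraction = spec.solid_fraction_neg
        speckle_amp = spec.speckle_amplitude_neg

    image = np.full((size, size), spec.hu_lung, dtype=np.float64)
    image[nodule] = spec.hu_ggo

    nrows, ncols = np.nonzero(nodule)
    b_r0, b_r1 = int(nrows.min()), int(nrows.max()) + 1
    b_c0, b_c1 = int(ncols.min()), int(ncols.max()) + 1

    # solid sub-regions: 1-4 disks seeded at random nodule pixels
    if solid_fraction > 0:
        n_disks = int(rng.integers(1, 5))
        target = solid_fraction * nodule.sum()
        radius = max(1.0, np.sqrt(target / (n_disks * np.pi)))
        idx = np.flatnonzero(nodule)
        centers = np.column_stack(np.unravel_index(rng.choice(idx, n_disks), nodule.shape))
        rows = np.arange(b_r0, b_r1, dtype=float)[:, None]
        cols = np.arange(b_c0, b_c1, dtype=float)[None, :]
        solid_box = np.zeros((b_r1 - b_r0, b_c1 - b_c0), dtype=bool)
        for cr, cc in centers:
            solid_box |= (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
        solid = np.zeros_like(nodule)
        solid[b_r0:b_r1, b_c0:b_c1] = solid_box
        solid &= nodule
        image[solid] = spec.hu_solid

    # low-pass-filtered speckle, unit SD inside the nodule, applied inside only
    if speckle_amp > 0:
        pad = 6  # keep the filter support clear of the box edge
        g_r0, g_r1 = max(0, b_r0 - pad), min(size, b_r1 + pad)
        g_c0, g_c1 = max(0, b_c0 - pad), min(size, b_c1 + pad)
        g = ndimage.gaussian_filter(
            rng.standard_normal((g_r1 - g_r0, g_c1 - g_c0)), sigma=2.0)
        inside_box = nodule[g_r0:g_r1, g_c0:g_c1]
        inside = g[inside_box]
        sd = inside.std()
        if sd > 0:
            image[nodule] += speckle_amp * (inside - inside.mean()) / sd

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=(size, size))
    np.clip(image, HU_MIN, HU_MAX, out=image)

    case_id = f"case_{case_seed:04d}"
    patch = ImagePatch(pixels=image, spacing=(spec.pixel_spacing, spec.pixel_spacing),
                       origin=case_id)
    mask = RoiMask(mask=nodule, reader_id="truth")
    return SyntheticCase(image=patch, truth_mask=mask, label=int(label), case_id=case_id)


def generate_cohort(spec: CohortSpec) -> List[SyntheticCase]:
    """Exactly ``n_positive`` label-1 and ``n_negative`` label-0 cases."""
    labels = [1] * spec.n_positive + [0] * spec.n_negative
    return [generate_nodule(spec, lab, i) for i, lab in enumerate(labels)]


def write_cohort(cases: Sequence[SyntheticCase], out_dir) -> Path:
    """Write one NIfTI image + mask per case plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        img_path = out_dir / f"{case.case_id}_image.nii.gz"
        msk_path = out_dir / f"{case.case_id}_mask.nii.gz"
        write_image(case.image, img_path)
        write_mask(case.truth_mask, case.image.spacing, msk_path)
        rows.append({"case_id": case.case_id, "label": case.label,
                     "image": img_path.name, "mask": msk_path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def generate_feature_table(
    n_cases: int,
    n_features: int,
    informative: Set[int],
    effect_size: float,
    label_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian noise features; informative columns shifted by ``effect_size`` SDs
    in the positive class. Returns a DataFrame with feature columns plus 'label'."""
    if n_cases < 10:
        raise ValueError(f"n_cases must be >= 10 for cross-validation, got {n_cases}")
    informative = set(int(i) for i in informative)
    if not informative <= set(range(n_features)):
        raise ValueError(f"informative indices {informative} outside [0, {n_features})")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not (0.0 < label_fraction < 1.0):
        raise ValueError("label_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_cases, n_features))
    n_pos = int(round(n_cases * label_fraction))
    n_pos = min(max(n_pos, 1), n_cases - 1)
    y = np.zeros(n_cases, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    for j in informative:
        X[y == 1, j] += effect_size

    cols = [f"f{j:02d}" for j in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    return df


def generate_reader_table(
    truth: Sequence[int], sens: float, spec_: float, seed: int = 0
) -> np.ndarray:
    """Binary predictions: positives hit with probability ``sens``, negatives
    correctly rejected with probability ``spec_``, independently per case."""
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("truth must be non-empty")
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec_ <= 1.0):
        raise ValueError("sens and spec_ must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(truth.size)
    pred = np.where(truth == 1, u < sens, u >= spec_)
    return pred.astype(int)
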