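"""Quantization, texture matrices and the 61-feature radiomic vector.

Feature families and defaults:

* 10 first-order features; ``MeanIntensity``/``SDIntensity``/``Range``/
  ``CoefficientVariation``/``Skewness``/``Kurtosis`` on raw HU,
  ``Mean``/``Variance``/``Entropy``/``Uniformity`` on quantized levels.
* 10 gray-level co-occurrence (GLCM) features: distance 1, four directions
  (0/45/90/135 degrees), symmetric, counts pooled over directions.
* 16 run-length (GLRLM) features: same four directions, features averaged
  over directions.
* 16 size-zone (GLSZM) features: zones are 8-connected.
* 5 neighborhood gray-tone-difference (NGTDM) features over 8-neighborhoods.
* 4 shape/size auxiliaries from the ROI mask.

Quantization is equal-width over the ROI's HU range (32 levels by default)
and the entropy log base is natural by default; both are configurable and
recorded in output metadata. Undefined features (zero-variance denominators
and the like) are emitted as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .imaging_roi import ImagePatch, RoiMask

__all__ = [
    "TextureConfig",
    "QuantizedRoi",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "quantize",
    "first_order",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "ngtdm_features",
    "shape_features",
    "extract_all",
    "average_readers",
]

_EIGHT = np.ones((3, 3), dtype=bool)

# ---------------------------------------------------------------------------
# feature registry (data-driven: the analysis reads names from here only)
# ---------------------------------------------------------------------------

_FIRST_ORDER = [
    "MeanIntensity", "SDIntensity", "Range", "CoefficientVariation",
    "Skewness", "Kurtosis", "Mean", "Variance", "Entropy", "Uniformity",
]
_GLCM = [
    "GLCM:Correlation", "GLCM:Contrast", "GLCM:Dissimilarity", "GLCM:Energy",
    "GLCM:Entropy", "GLCM:Homogeneity", "GLCM:Autocorrelation",
    "GLCM:ClusterShade", "GLCM:ClusterProminence", "GLCM:MaximumProbability",
]
_GLRLM = [
    "SRE", "LRE", "GLN", "GLNN", "RLN", "RLNN", "RP", "RLV", "GLVR", "RE",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
]
_GLSZM = [
    "SZE", "LZE", "GLNZ", "GLNZN", "ZSN", "ZSNN", "ZP", "GLV", "ZLV", "ZE",
    "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
]
_NGTDM = [
    "NGTDM:Coarseness", "NGTDM:Contrast", "NGTDM:Busyness",
    "NGTDM:Complexity", "NGTDM:Strength",
]
_SHAPE = ["AreaPixels", "AreaMm2", "PerimeterMm", "Eccentricity"]

FEATURE_FAMILIES: Dict[str, str] = {}
for _names, _fam in [(_FIRST_ORDER, "first_order"), (_GLCM, "glcm"),
                     (_GLRLM, "glrlm"), (_GLSZM, "glszm"),
                     (_NGTDM, "ngtdm"), (_SHAPE, "shape")]:
    for _n in _names:
        FEATURE_FAMILIES[_n] = _fam

#: canonical output order of the 61 features
FEATURE_NAMES: List[str] = _FIRST_ORDER + _GLCM + _GLRLM + _GLSZM + _NGTDM + _SHAPE
assert len(FEATURE_NAMES) == 61


@dataclass(frozen=True)
class TextureConfig:
    n_levels: int = 32
    log_base: str = "e"          # "e" or "2"
    glcm_distance: int = 1
    population_sd: bool = True   # n-denominator SD for CoV / first-order stats

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _log(x: np.ndarray, base: str) -> np.ndarray:
    return np.log2(x) if base == "2" else np.log(x)


@dataclass(frozen=True)
class QuantizedRoi:
    """Integer level grid: 1..Ng inside the ROI, 0 outside."""

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    roi: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.roi.sum())


def quantize(image: ImagePatch, roi: RoiMask, n_levels: int = 32) -> QuantizedRoi:
    """Equal-width binning of the ROI HU range into ``n_levels`` levels.

    A constant ROI maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if image.shape != roi.mask.shape:
        raise ValueError("image and mask shapes differ")
    mask = roi.mask
    vals = image.pixels[mask]
    vmin, vmax = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        edges = np.array([vmin, vmin + 1.0])
    else:
        edges = np.linspace(vmin, vmax, n_levels + 1)
        width = (vmax - vmin) / n_levels
        lv = np.floor((vals - vmin) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
        levels[mask] = lv
    return QuantizedRoi(levels=levels, ng=int(n_levels), bin_edges=edges, roi=mask)


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def first_order(image: ImagePatch, roi: RoiMask, quantized: QuantizedRoi,
                log_base: str = "e", population_sd: bool = True) -> Dict[str, float]:
    vals = image.pixels[roi.mask].astype(np.float64)
    n = vals.size
    ddof = 0 if population_sd else 1
    mean_hu = float(vals.mean())
    sd_hu = float(vals.std(ddof=ddof))

    out: Dict[str, float] = {}
    out["MeanIntensity"] = mean_hu
    out["SDIntensity"] = sd_hu
    out["Range"] = float(vals.max() - vals.min())
    if mean_hu == 0.0:
        warnings.warn("CoefficientVariation undefined: mean HU is 0")
        out["CoefficientVariation"] = np.nan
    else:
        out["CoefficientVariation"] = sd_hu / mean_hu
    centered = vals - mean_hu
    if sd_hu == 0.0:
        warnings.warn("Skewness/Kurtosis undefined for a constant ROI")
        out["Skewness"] = np.nan
        out["Kurtosis"] = np.nan
    else:
        out["Skewness"] = float((centered**3).mean() / sd_hu**3)
        out["Kurtosis"] = float((centered**4).mean() / sd_hu**4)

    lv = quantized.levels[roi.mask].astype(np.float64)
    out["Mean"] = float(lv.mean())
    out["Variance"] = float(lv.var(ddof=ddof))
    counts = np.bincount(lv.astype(int), minlength=quantized.ng + 1)[1:]
    p = counts[counts > 0] / n
    out["Entropy"] = float(-(p * _log(p, log_base)).sum())
    out["Uniformity"] = float((p**2).sum())
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _offsets(distance: int) -> List[Tuple[int, int]]:
    d = int(distance)
    return [(0, d), (-d, d), (-d, 0), (-d, -d)]  # 0, 45, 90, 135 degrees


def build_glcm(quantized: QuantizedRoi, distance: int = 1,
               symmetric: bool = True) -> np.ndarray:
    """Symmetric, direction-pooled, normalized co-occurrence matrix.

    Only pixel pairs with both members inside the ROI are counted.
    """
    lv = quantized.levels
    roi = quantized.roi
    ng = quantized.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    nrow, ncol = lv.shape
    for dr, dc in _offsets(distance):
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        a_roi = roi[r0:r1, c0:c1]
        b_roi = roi[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = a_roi & b_roi
        a = lv[r0:r1, c0:c1][valid] - 1
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid] - 1
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate ROI: no valid co-occurring pixel pair")
    return counts / total


def glcm_features(glcm: np.ndarray, log_base: str = "e") -> Dict[str, float]:
    p = np.asarray(glcm, dtype=np.float64)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    out: Dict[str, float] = {}
    if sd_x * sd_y == 0.0:
        warnings.warn("GLCM Correlation undefined: zero marginal variance")
        out["Correlation"] = np.nan
    else:
        out["Correlation"] = float(((p * ii * jj).sum() - mu_x * mu_y) / (sd_x * sd_y))
    out["Contrast"] = float((p * (ii - jj) ** 2).sum())
    out["Dissimilarity"] = float((p * np.abs(ii - jj)).sum())
    out["Energy"] = float((p**2).sum())
    nz = p[p > 0]
    out["Entropy"] = float(-(nz * _log(nz, log_base)).sum())
    out["Homogeneity"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["Autocorrelation"] = float((p * ii * jj).sum())
    shift = ii + jj - mu_x - mu_y
    out["ClusterShade"] = float((p * shift**3).sum())
    out["ClusterProminence"] = float((p * shift**4).sum())
    out["MaximumProbability"] = float(p.max())
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs(levels_line: np.ndarray, roi_line: np.ndarray) -> Iterable[Tuple[int, int]]:
    """Maximal runs of equal level within ROI segments of a 1D line."""
    cur_level = 0
    cur_len = 0
    for lv, inside in zip(levels_line, roi_line):
        if inside and lv == cur_level and cur_len > 0:
            cur_len += 1
        else:
            if cur_len > 0:
                yield cur_level, cur_len
            if inside:
                cur_level, cur_len = int(lv), 1
            else:
                cur_level, cur_len = 0, 0
    if cur_len > 0:
        yield cur_level, cur_len


def _lines(arr: np.ndarray, direction: str) -> Iterable[np.ndarray]:
    nrow, ncol = arr.shape
    if direction == "0":
        for r in range(nrow):
            yield arr[r]
    elif direction == "90":
        for c in range(ncol):
            yield arr[:, c]
    elif direction == "135":  # down-right diagonals
        for off in range(-nrow + 1, ncol):
            yield arr.diagonal(off)
    elif direction == "45":   # down-left diagonals
        flipped = np.fliplr(arr)
        for off in range(-nrow + 1, ncol):
            yield flipped.diagonal(off)
    else:
        raise ValueError(f"unknown direction {direction!r}")


GLRLM_DIRECTIONS = ("0", "45", "90", "135")


def build_glrlm(quantized: QuantizedRoi,
                directions: Tuple[str, ...] = GLRLM_DIRECTIONS) -> Dict[str, np.ndarray]:
    """Run-count matrix (levels x run length) per direction."""
    ng = quantized.ng
    out: Dict[str, np.ndarray] = {}
    for d in directions:
        runs: List[Tuple[int, int]] = []
        for lv_line, roi_line in zip(_lines(quantized.levels, d),
                                     _lines(quantized.roi, d)):
            runs.extend(_runs(lv_line, roi_line))
        rmax = max((ln for _, ln in runs), default=1)
        mat = np.zeros((ng, rmax), dtype=np.float64)
        for level, length in runs:
            mat[level - 1, length - 1] += 1.0
        out[d] = mat
    return out


def _rlm_single(mat: np.ndarray, n_pixels: int, log_base: str) -> Dict[str, float]:
    nr = mat.sum()
    p = mat / nr
    ng, rmax = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pi).sum())
    mu_j = float((np.arange(1, rmax + 1) * pj).sum())
    nz = p[p > 0]
    return {
        "SRE": float((p / j**2).sum()),
        "LRE": float((p * j**2).sum()),
        "GLN": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GLNN": float((mat.sum(axis=1) ** 2).sum() / nr**2),
        "RLN": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RLNN": float((mat.sum(axis=0) ** 2).sum() / nr**2),
        "RP": float(nr / n_pixels),
        "RLV": float(((np.arange(1, rmax + 1) - mu_j) ** 2 * pj).sum()),
        "GLVR": float(((np.arange(1, ng + 1) - mu_i) ** 2 * pi).sum()),
        "RE": float(-(nz * _log(nz, log_base)).sum()),
        "LGRE": float((p / i**2).sum()),
        "HGRE": float((p * i**2).sum()),
        "SRLGE": float((p / (i**2 * j**2)).sum()),
        "SRHGE": float((p * i**2 / j**2).sum()),
        "LRLGE": float((p * j**2 / i**2).sum()),
        "LRHGE": float((p * i**2 * j**2).sum()),
    }


def glrlm_features(glrlm: Dict[str, np.ndarray], n_pixels: int,
                   log_base: str = "e") -> Dict[str, float]:
    """Run-length features computed per direction and averaged."""
    per_dir = [_rlm_single(mat, n_pixels, log_base) for mat in glrlm.values()]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def build_glszm(quantized: QuantizedRoi) -> np.ndarray:
    """Zone-count matrix (levels x zone size); zones are 8-connected components
    of equal level inside the ROI."""
    ng = quantized.ng
    sizes_by_level: List[Tuple[int, int]] = []
    for level in range(1, ng + 1):
        sel = quantized.roi & (quantized.levels == level)
        if not sel.any():
            continue
        lab, n_comp = ndimage.label(sel, structure=_EIGHT)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n_comp + 1))
        sizes_by_level.extend((level, int(s)) for s in sizes)
    smax = max((s for _, s in sizes_by_level), default=1)
    mat = np.zeros((ng, smax), dtype=np.float64)
    for level, s in sizes_by_level:
        mat[level - 1, s - 1] += 1.0
    return mat


def glszm_features(glszm: np.ndarray, n_pixels: int,
                   log_base: str = "e") -> Dict[str, float]:
    nz_total = glszm.sum()
    p = glszm / nz_total
    ng, smax = glszm.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pi).sum())
    mu_j = float((np.arange(1, smax + 1) * pj).sum())
    nzp = p[p > 0]
    return {
        "SZE": float((p / j**2).sum()),
        "LZE": float((p * j**2).sum()),
        "GLNZ": float((glszm.sum(axis=1) ** 2).sum() / nz_total),
        "GLNZN": float((glszm.sum(axis=1) ** 2).sum() / nz_total**2),
        "ZSN": float((glszm.sum(axis=0) ** 2).sum() / nz_total),
        "ZSNN": float((glszm.sum(axis=0) ** 2).sum() / nz_total**2),
        "ZP": float(nz_total / n_pixels),
        "GLV": float(((np.arange(1, ng + 1) - mu_i) ** 2 * pi).sum()),
        "ZLV": float(((np.arange(1, smax + 1) - mu_j) ** 2 * pj).sum()),
        "ZE": float(-(nzp * _log(nzp, log_base)).sum()),
        "LGZE": float((p / i**2).sum()),
        "HGZE": float((p * i**2).sum()),
        "SZLGE": float((p / (i**2 * j**2)).sum()),
        "SZHGE": float((p * i**2 / j**2).sum()),
        "LZLGE": float((p * j**2 / i**2).sum()),
        "LZHGE": float((p * i**2 * j**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _ngtdm_table(quantized: QuantizedRoi) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence probabilities p_i and absolute-difference sums s_i.

    Only ROI pixels with at least one ROI neighbor (8-neighborhood) contribute.
    Returns (p, s, N) with arrays indexed by level-1.
    """
    lv = quantized.levels.astype(np.float64)
    roi = quantized.roi.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(lv * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(roi, kernel, mode="constant", cval=0.0)
    valid = quantized.roi & (nb_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("NGTDM undefined: no ROI pixel has an ROI neighbor")
    diffs = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    levels = quantized.levels[valid]
    ng = quantized.ng
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    np.add.at(s, levels - 1, diffs)
    np.add.at(n_i, levels - 1, 1.0)
    return n_i / n_valid, s, n_valid


def ngtdm_features(quantized: QuantizedRoi) -> Dict[str, float]:
    p, s, n_valid = _ngtdm_table(quantized)
    present = np.flatnonzero(p > 0)
    ngp = present.size
    i_vals = (present + 1).astype(np.float64)
    p_nz = p[present]
    s_nz = s[present]
    out: Dict[str, float] = {}

    denom = float((p_nz * s_nz).sum())
    if denom == 0.0:
        warnings.warn("NGTDM Coarseness undefined: sum p_i*s_i is 0")
        out["Coarseness"] = np.nan
    else:
        out["Coarseness"] = 1.0 / denom

    if ngp <= 1:
        out["Contrast"] = 0.0
    else:
        pij = np.outer(p_nz, p_nz)
        dij2 = (i_vals[:, None] - i_vals[None, :]) ** 2
        out["Contrast"] = float(
            (pij * dij2).sum() / (ngp * (ngp - 1)) * s_nz.sum() / n_valid
        )

    busy_denom = float(np.abs(i_vals[:, None] * p_nz[:, None]
                              - i_vals[None, :] * p_nz[None, :]).sum())
    if busy_denom == 0.0:
        warnings.warn("NGTDM Busyness undefined: zero denominator")
        out["Busyness"] = np.nan
    else:
        out["Busyness"] = float((p_nz * s_nz).sum() / busy_denom)

    psum = p_nz[:, None] + p_nz[None, :]
    ps = p_nz * s_nz
    out["Complexity"] = float(
        (np.abs(i_vals[:, None] - i_vals[None, :])
         * (ps[:, None] + ps[None, :]) / psum).sum() / n_valid
    )

    s_total = float(s_nz.sum())
    if s_total == 0.0:
        warnings.warn("NGTDM Strength undefined: sum s_i is 0")
        out["Strength"] = np.nan
    else:
        dij2 = (i_vals[:, None] - i_vals[None, :]) ** 2
        out["Strength"] = float((psum * dij2).sum() / s_total)
    return out


# ---------------------------------------------------------------------------
# shape auxiliaries and the full vector
# ---------------------------------------------------------------------------

def shape_features(image: ImagePatch, roi: RoiMask) -> Dict[str, float]:
    props = regionprops(roi.mask.astype(np.uint8))[0]
    sr, sc = image.spacing
    n = roi.n_pixels
    return {
        "AreaPixels": float(n),
        "AreaMm2": float(n * sr * sc),
        "PerimeterMm": float(props.perimeter * (sr + sc) / 2.0),
        "Eccentricity": float(props.eccentricity),
    }


def _crop_to_roi(image: ImagePatch, roi: RoiMask,
                 margin: int = 2) -> Tuple[ImagePatch, RoiMask]:
    """Crop to the ROI bounding box (plus margin); every feature depends only
    on ROI contents, so this is a pure speed optimization."""
    rows, cols = np.nonzero(roi.mask)
    nrow, ncol = image.shape
    r0, r1 = max(0, rows.min() - margin), min(nrow, rows.max() + 1 + margin)
    c0, c1 = max(0, cols.min() - margin), min(ncol, cols.max() + 1 + margin)
    # honor the minimum patch size invariant
    while r1 - r0 < 16:
        r0, r1 = max(0, r0 - 1), min(nrow, r1 + 1)
    while c1 - c0 < 16:
        c0, c1 = max(0, c0 - 1), min(ncol, c1 + 1)
    sub_img = ImagePatch(pixels=image.pixels[r0:r1, c0:c1],
                         spacing=image.spacing, origin=image.origin)
    sub_roi = RoiMask(mask=roi.mask[r0:r1, c0:c1], reader_id=roi.reader_id)
    return sub_img, sub_roi


def extract_all(image: ImagePatch, roi: RoiMask,
                config: TextureConfig = TextureConfig()) -> pd.Series:
    """All 61 named radiomic features of one segmented nodule."""
    if image.shape != roi.mask.shape:
        raise ValueError("image and mask shapes differ")
    image, roi = _crop_to_roi(image, roi)
    q = quantize(image, roi, config.n_levels)
    values: Dict[str, float] = {}
    values.update(first_order(image, roi, q, config.log_base, config.population_sd))
    glcm = build_glcm(q, distance=config.glcm_distance)
    values.update({f"GLCM:{k}": v for k, v in glcm_features(glcm, config.log_base).items()})
    values.update(glrlm_features(build_glrlm(q), q.n_pixels, config.log_base))
    values.update(glszm_features(build_glszm(q), q.n_pixels, config.log_base))
    values.update({f"NGTDM:{k}": v for k, v in ngtdm_features(q).items()})
    values.update(shape_features(image, roi))
    out = pd.Series([values[name] for name in FEATURE_NAMES],
                    index=FEATURE_NAMES, dtype=float)
    return out


def average_readers(a: pd.Series, b: pd.Series) -> pd.Series:
    """Element-wise mean of two feature vectors; NaN propagates."""
    if list(a.index) != list(b.index):
        raise ValueError("feature name mismatch between readers")
    return (a + b) / 2.0
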