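"""The 400-feature CT radiomics vector for a lesion VOI.

Feature families, in the fixed vector order:

1. **10 intensity-histogram features** of the muscle-normalized lesion
   intensities: mean, median, SD, skewness, kurtosis (excess), minimum,
   maximum, range, energy (uniformity of a 64-bin histogram) and entropy
   (base-2, same bins).
2. **195 rotation-invariant GLCM features**: the 13 classical Haralick
   texture statistics computed per spatial offset, aggregated over the 13
   unique 3D directions at Chebyshev distance 1 into average, range and
   angular variance (13 x 3 = 39), repeated at five gray-level
   quantizations G in {8, 16, 32, 64, 128} (39 x 5 = 195).
3. **195 volume-normalized GLCM features**: each GLCM feature divided by
   the lesion volume in mm^3.

Intensities are first z-normalized to a pectoralis-muscle reference VOI
(within-phase normalization), and quantization is equal-width between the
VOI minimum and maximum, so the whole vector is invariant to affine
intensity rescaling of the scanner output. Because the direction set is
closed (up to sign, which symmetric GLCMs ignore) under signed axis
permutations, the aggregated features are invariant to 90-degree
rotations and flips of the volume and masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    AggregationError,
    EmptyGLCMError,
    ValidationError,
    ZeroVarianceError,
)
from .simulate import ImagingStudy

logger = logging.getLogger(__name__)

GRAY_LEVEL_SETTINGS: tuple[int, ...] = (8, 16, 32, 64, 128)

#: 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair of the
#: 26-neighborhood; symmetric GLCMs make d and -d equivalent).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

HARALICK_NAMES: tuple[str, ...] = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

HISTOGRAM_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "sd",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "range",
    "energy",
    "entropy",
)

AGGREGATIONS: tuple[str, ...] = ("avg", "range", "avar")

_HIST_BINS = 64


@dataclass(frozen=True)
class GLCM:
    """A normalized symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray
    direction: tuple[int, int, int]
    distance: int


@dataclass
class FeatureVector:
    """Ordered 400-feature radiomics vector for one lesion VOI."""

    patient_id: str
    lesion_index: int
    values: dict[str, float]
    volume_mm3: float

    def __post_init__(self) -> None:
        canonical = feature_names()
        if len(self.values) == len(canonical) and list(self.values.keys()) != canonical:
            raise ValidationError("feature vector does not match the canonical 400 names")


def feature_names() -> list[str]:
    """The canonical, fixed order of the 400 feature names."""
    names = [f"hist_{s}" for s in HISTOGRAM_NAMES]
    glcm = [
        f"glcm_G{g}_{feat}_{agg}"
        for g in GRAY_LEVEL_SETTINGS
        for feat in HARALICK_NAMES
        for agg in AGGREGATIONS
    ]
    return names + glcm + [f"{n}_voln" for n in glcm]


def normalize_to_muscle(study: ImagingStudy) -> np.ndarray:
    """Z-normalize the whole volume to the muscle reference VOI.

    Returns ``(volume - muscle_mean) / muscle_SD`` voxelwise, making all
    downstream features invariant to affine intensity maps a*x + b (a>0).
    """
    if study.muscle_mask is None or not study.muscle_mask.any():
        raise ValidationError("muscle mask is empty")
    vals = study.volume[study.muscle_mask.astype(bool)]
    sd = float(vals.std())
    if sd == 0.0:
        raise ZeroVarianceError("muscle VOI has constant intensity")
    return (study.volume - float(vals.mean())) / sd


def quantize_voi(volume: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize in-mask intensities to integer levels 1..G (0 outside).

    Equal-width bins between the VOI minimum and maximum; the minimum
    maps to level 1 and the maximum to level G. A constant VOI maps
    entirely to level 1.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("empty mask")
    vals = volume[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    out = np.zeros(volume.shape, dtype=np.int64)
    if vmax == vmin:
        out[mask] = 1
        return out
    levels = np.floor((vals - vmin) / (vmax - vmin) * n_levels).astype(np.int64) + 1
    out[mask] = np.clip(levels, 1, n_levels)
    return out


def compute_glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    direction: tuple[int, int, int],
    n_levels: int,
    distance: int = 1,
) -> GLCM:
    """Symmetric, normalized co-occurrence matrix for one spatial offset.

    Counts every ordered in-mask voxel pair ``(v, v + distance*direction)``,
    adds the transpose, and normalizes to sum 1. Pairs with either voxel
    outside the mask are excluded.
    """
    if distance < 1:
        raise ValidationError("distance must be a positive integer")
    mask = mask.astype(bool)
    offset = tuple(int(distance) * int(d) for d in direction)
    src: list[slice] = []
    dst: list[slice] = []
    for axis, off in enumerate(offset):
        size = quantized.shape[axis]
        if abs(off) >= size:
            raise EmptyGLCMError(f"offset {offset} exceeds volume extent")
        if off >= 0:
            src.append(slice(0, size - off))
            dst.append(slice(off, size))
        else:
            src.append(slice(-off, size))
            dst.append(slice(0, size + off))
    valid = mask[tuple(src)] & mask[tuple(dst)]
    i = quantized[tuple(src)][valid] - 1
    j = quantized[tuple(dst)][valid] - 1
    if i.size == 0:
        raise EmptyGLCMError(f"no in-mask voxel pair for offset {offset}")
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return GLCM(matrix=counts / counts.sum(), direction=tuple(direction), distance=distance)


def _entropy2(p: np.ndarray) -> float:
    """Base-2 entropy with the 0*log0 = 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(glcm: GLCM) -> dict[str, float]:
    """The 13 classical Haralick texture statistics of a normalized GLCM.

    Log terms use base 2 with 0*log0 = 0. Sum variance is computed about
    the sum average. For a single-level GLCM the correlation-type
    features (zero marginal variance) are returned as 0 with a warning.
    """
    p = np.asarray(glcm.matrix, dtype=np.float64)
    g = p.shape[0]
    idx = np.arange(1, g + 1, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    out: dict[str, float] = {}
    out["energy"] = float((p**2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())

    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    var_y = float(((idx - mu_y) ** 2 * py).sum())
    if var_x <= 0 or var_y <= 0:
        logger.warning("degenerate GLCM (zero marginal variance): correlation set to 0")
        out["correlation"] = 0.0
    else:
        out["correlation"] = float(
            ((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
        )
    out["variance"] = var_x
    out["idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # diagonal-sum and diagonal-difference marginals
    p_sum = np.zeros(2 * g - 1)  # k = i+j in 2..2G  -> index k-2
    p_diff = np.zeros(g)  # k = |i-j| in 0..G-1
    for a in range(g):
        for_k = p[a]
        np.add.at(p_sum, a + np.arange(g), for_k)
        np.add.at(p_diff, np.abs(a - np.arange(g)), for_k)
    ks = np.arange(2, 2 * g + 1, dtype=np.float64)
    kd = np.arange(0, g, dtype=np.float64)

    sum_avg = float((ks * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((ks - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy2(p_sum)
    hxy = _entropy2(p)
    out["entropy"] = hxy
    mu_d = float((kd * p_diff).sum())
    out["difference_variance"] = float(((kd - mu_d) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy2(p_diff)

    # information measures of correlation
    pxy = np.outer(px, py)
    joint_nz = p > 0
    hxy1 = float(-(p[joint_nz] * np.log2(pxy[joint_nz])).sum()) if joint_nz.any() else 0.0
    marg_nz = pxy > 0
    hxy2 = float(-(pxy[marg_nz] * np.log2(pxy[marg_nz])).sum())
    hx = _entropy2(px)
    hy = _entropy2(py)
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def aggregate_directions(per_direction: list[dict[str, float]]) -> dict[str, float]:
    """Rotation-invariant aggregation over spatial directions.

    For each of the 13 base features: average, range (max - min) and
    angular variance (population variance across directions), yielding
    39 values keyed ``<feature>_<avg|range|avar>``.
    """
    if len(per_direction) < 2:
        raise AggregationError("need >= 2 directions to aggregate")
    out: dict[str, float] = {}
    for feat in HARALICK_NAMES:
        vals = np.array([d[feat] for d in per_direction], dtype=np.float64)
        out[f"{feat}_avg"] = float(vals.mean())
        spread = float(vals.max() - vals.min())
        out[f"{feat}_range"] = spread
        # exact zero for identical directions (no float dust from the mean)
        out[f"{feat}_avar"] = float(vals.var()) if spread > 0 else 0.0
    return out


def histogram_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Ten first-order statistics of the in-mask intensities."""
    mask = mask.astype(bool)
    n = int(mask.sum())
    if n < 2:
        raise ValidationError("histogram features require a mask with >= 2 voxels")
    vals = volume[mask].astype(np.float64)
    vmin, vmax = float(vals.min()), float(vals.max())
    m = vals.mean()
    centered = vals - m
    m2 = float((centered**2).mean())
    if m2 > 0:
        skew = float((centered**3).mean() / m2**1.5)
        kurt = float((centered**4).mean() / m2**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    if vmax > vmin:
        hist, _ = np.histogram(vals, bins=_HIST_BINS, range=(vmin, vmax))
        probs = hist / hist.sum()
    else:
        probs = np.array([1.0])
    return {
        "mean": float(m),
        "median": float(np.median(vals)),
        "sd": float(np.sqrt(m2)),
        "skewness": skew,
        "kurtosis": kurt,
        "min": vmin,
        "max": vmax,
        "range": vmax - vmin,
        "energy": float((probs**2).sum()),
        "entropy": _entropy2(probs),
    }


def mask_volume(mask: np.ndarray, voxel_spacing_mm: tuple[float, float, float]) -> float:
    """Physical mask volume: voxel count times the voxel volume in mm^3."""
    n = int(np.asarray(mask).astype(bool).sum())
    if n == 0:
        raise ValidationError("empty mask has no volume")
    return n * float(np.prod(voxel_spacing_mm))


def extract_feature_vector(
    study: ImagingStudy,
    lesion_index: int = 0,
    gray_levels: tuple[int, ...] = GRAY_LEVEL_SETTINGS,
    distance: int = 1,
) -> FeatureVector:
    """Extract the full 400-feature vector for one lesion VOI.

    10 histogram features, then 39 rotation-invariant GLCM features per
    gray-level setting (five settings, 195 total), then the same 195
    divided by the lesion volume in mm^3.
    """
    if len(gray_levels) != len(set(gray_levels)):
        raise ValidationError("gray-level settings must be distinct")
    study.validate()
    if not 0 <= lesion_index < len(study.lesion_masks):
        raise ValidationError(f"lesion index {lesion_index} out of range")
    mask = study.lesion_masks[lesion_index].astype(bool)
    normalized = normalize_to_muscle(study)
    volume_mm3 = mask_volume(mask, study.voxel_spacing_mm)

    values: dict[str, float] = {
        f"hist_{k}": v for k, v in histogram_features(normalized, mask).items()
    }
    glcm_part: dict[str, float] = {}
    for g in gray_levels:
        quantized = quantize_voi(normalized, mask, g)
        per_dir: list[dict[str, float]] = []
        for direction in DIRECTIONS_3D:
            try:
                glcm = compute_glcm(quantized, mask, direction, g, distance)
            except EmptyGLCMError:
                logger.warning(
                    "patient %s lesion %d: no pairs for direction %s at G=%d; skipped",
                    study.patient_id,
                    lesion_index,
                    direction,
                    g,
                )
                continue
            per_dir.append(haralick_features(glcm))
        agg = aggregate_directions(per_dir)
        for feat in HARALICK_NAMES:
            for suffix in AGGREGATIONS:
                glcm_part[f"glcm_G{g}_{feat}_{suffix}"] = agg[f"{feat}_{suffix}"]
    values.update(glcm_part)
    values.update({f"{k}_voln": v / volume_mm3 for k, v in glcm_part.items()})
    return FeatureVector(
        patient_id=study.patient_id,
        lesion_index=lesion_index,
        values=values,
        volume_mm3=volume_mm3,
    )


def merge_lesion_features(vectors: list[FeatureVector]) -> dict[str, float]:
    """Volume-weighted average over lesions (whole-body tumor-burden view)."""
    if not vectors:
        raise ValidationError("no feature vectors to merge")
    weights = np.array([v.volume_mm3 for v in vectors])
    weights = weights / weights.sum()
    merged = {
        name: float(sum(w * v.values[name] for w, v in zip(weights, vectors)))
        for name in feature_names()
    }
    return merged
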