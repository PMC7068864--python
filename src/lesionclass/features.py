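"""The 12 color/shape descriptors computed from an RGB image + ROI mask.

Fixed feature order:

==  ==========================  =========================================
#   column name                 meaning
==  ==========================  =========================================
1   f1_mean_r                   mean red over ROI
2   f2_mean_g                   mean green over ROI
3   f3_mean_b                   mean blue over ROI
4   f4_mean_h                   circular mean hue over ROI
5   f5_mean_s                   mean saturation over ROI
6   f6_mean_v                   mean value over ROI
7   f7_color_structure          color-structure entropy (8x8 windows,
                                32-bin HSV quantization), in [0, 1]
8   f8_color_layout_ac1         first non-DC zigzag DCT coefficient (0,1)
                                of the 8x8 mean-color luminance grid,
                                affinely squashed to [0, 1]
9   f9_color_layout_ac2         second zigzag coefficient (1,0), squashed
10  f10_pc_ratio                sqrt(minor/major covariance eigenvalue)
11  f11_filled_ellipse          |ROI ∩ fitted ellipse| / |fitted ellipse|
12  f12_unfilled_ellipse        |ROI \\ fitted ellipse| / |ROI|
==  ==========================  =========================================

The fitted ellipse shares the mask's centroid and covariance orientation
and is rescaled to the mask's exact pixel area, so a compact (near-convex)
lesion scores f11 -> 1 and f12 -> 0 while ragged malignant borders leak
outside the ellipse.  The MPEG-7-style structure/layout descriptors are
reduced to the scalar budget above; the reductions are part of this
package's feature contract and are recorded in the table header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn
from skimage.color import rgb2hsv

from .errors import DegenerateShapeError, DimensionError, EmptyROIError

N_FEATURES = 12

FEATURE_COLUMNS = [
    "f1_mean_r", "f2_mean_g", "f3_mean_b",
    "f4_mean_h", "f5_mean_s", "f6_mean_v",
    "f7_color_structure",
    "f8_color_layout_ac1", "f9_color_layout_ac2",
    "f10_pc_ratio", "f11_filled_ellipse", "f12_unfilled_ellipse",
]

# color-structure descriptor: 32-bin HSV product quantization, 8x8 windows
CSD_WINDOW = 8
CSD_BINS_H, CSD_BINS_S, CSD_BINS_V = 8, 2, 2
CSD_N_BINS = CSD_BINS_H * CSD_BINS_S * CSD_BINS_V  # 32

# color-layout squash: f = clip(CLD_ZERO + coef / CLD_SCALE, 0, 1)
CLD_ZERO = 0.5
CLD_SCALE = 2.0


def _check_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(f"expected (h, w, 3) image, got {image.shape}")
    if mask.shape != image.shape[:2]:
        raise DimensionError("mask shape does not match image")
    if not mask.any():
        raise EmptyROIError("empty ROI mask")
    return mask


def mean_color(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Features f1-f6: mean RGB and mean HSV over the ROI.

    Hue is an angle, so f4 is the circular (vector) mean of hue angles
    mapped back to [0, 1); saturation and value are ordinary means.
    """
    mask = _check_mask(image, mask)
    rgb = image[mask]
    hsv = rgb2hsv(rgb[None, :, :])[0]
    ang = 2 * np.pi * hsv[:, 0]
    hue = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) % 1.0
    return np.array([rgb[:, 0].mean(), rgb[:, 1].mean(), rgb[:, 2].mean(),
                     hue, hsv[:, 1].mean(), hsv[:, 2].mean()])


def quantize_hsv32(image: np.ndarray) -> np.ndarray:
    """Map each pixel to one of 32 HSV product-quantized color bins."""
    hsv = rgb2hsv(image)
    h = np.minimum((hsv[..., 0] * CSD_BINS_H).astype(int), CSD_BINS_H - 1)
    s = np.minimum((hsv[..., 1] * CSD_BINS_S).astype(int), CSD_BINS_S - 1)
    v = np.minimum((hsv[..., 2] * CSD_BINS_V).astype(int), CSD_BINS_V - 1)
    return (h * CSD_BINS_S + s) * CSD_BINS_V + v


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rr, cc = np.nonzero(mask)
    return rr.min(), rr.max() + 1, cc.min(), cc.max() + 1


def color_structure(image: np.ndarray, mask: np.ndarray) -> float:
    """Feature f7: normalized entropy of the color-structure histogram.

    An 8x8 window slides (stride 1) over the ROI bounding box; for every
    quantized color, the histogram counts the number of windows in which at
    least one ROI pixel carries that color.  f7 is the Shannon entropy of
    the normalized histogram divided by log(32), so a single-color lesion
    scores 0 and maximally even color structure scores 1.
    """
    mask = _check_mask(image, mask)
    r0, r1, c0, c1 = _bbox(mask)
    q = quantize_hsv32(image[r0:r1, c0:c1])
    m = mask[r0:r1, c0:c1]
    wh = min(CSD_WINDOW, r1 - r0)
    ww = min(CSD_WINDOW, c1 - c0)
    counts = np.zeros(CSD_N_BINS, dtype=float)
    for color in np.unique(q[m]):
        present = (q == color) & m
        windows = sliding_window_view(present, (wh, ww))
        counts[color] = windows.any(axis=(2, 3)).sum()
    total = counts.sum()
    p = counts[counts > 0] / total
    entropy = float(-(p * np.log(p)).sum())
    return entropy / np.log(CSD_N_BINS)


def color_layout_grid(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """8x8 grid of mean ROI colors over the mask bounding box.

    The bounding box is partitioned into an 8x8 cell grid; each cell holds
    the mean color of its ROI pixels (cells without ROI pixels fall back to
    the overall ROI mean so background never leaks into the descriptor).
    """
    mask = _check_mask(image, mask)
    r0, r1, c0, c1 = _bbox(mask)
    if r1 - r0 < 8 or c1 - c0 < 8:
        raise EmptyROIError("ROI bounding box smaller than 8x8")
    roi_mean = image[mask].mean(axis=0)
    redges = np.linspace(r0, r1, 9).astype(int)
    cedges = np.linspace(c0, c1, 9).astype(int)
    grid = np.empty((8, 8, 3), dtype=float)
    for i in range(8):
        for j in range(8):
            cell_m = mask[redges[i]:redges[i + 1], cedges[j]:cedges[j + 1]]
            cell_px = image[redges[i]:redges[i + 1],
                            cedges[j]:cedges[j + 1]][cell_m]
            grid[i, j] = cell_px.mean(axis=0) if len(cell_px) else roi_mean
    return grid


def color_layout(image: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Features f8-f9: first two non-DC zigzag DCT coefficients.

    The luminance of the 8x8 mean-color grid is transformed with the
    orthonormal 2-D DCT-II; zigzag order after DC visits (0,1) then (1,0).
    Coefficients are squashed to [0, 1] by the fixed affine map
    ``0.5 + c/2`` (clipped), whose zero point 0.5 a constant ROI attains.
    """
    grid = color_layout_grid(image, mask)
    luma = grid @ np.array([0.299, 0.587, 0.114])
    coeffs = dctn(luma, norm="ortho")
    squash = lambda c: float(np.clip(CLD_ZERO + c / CLD_SCALE, 0.0, 1.0))
    return squash(coeffs[0, 1]), squash(coeffs[1, 0])


def fit_mask_ellipse(mask: np.ndarray):
    """Fit the moment ellipse of a binary mask.

    Returns ``(centroid, axes (a, b), rotation matrix, eigenvalues)``: the
    ellipse shares the mask's centroid and second-central-moment
    orientation, with semi-axes scaled so the ellipse area equals the mask
    pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 5:
        raise EmptyROIError("mask area must be at least 5 pixels")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12:
        raise DegenerateShapeError("mask pixels are collinear")
    lam_minor, lam_major = evals
    a0, b0 = 2 * np.sqrt(lam_major), 2 * np.sqrt(lam_minor)
    scale = np.sqrt(len(pts) / (np.pi * a0 * b0))
    axes = (a0 * scale, b0 * scale)
    rot = evecs[:, ::-1]  # columns: major axis, minor axis direction
    return centroid, axes, rot, (lam_major, lam_minor)


def ellipse_mask(shape: tuple[int, int], centroid, axes, rot) -> np.ndarray:
    """Rasterize the fitted ellipse on a pixel grid of ``shape``."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.stack([rows - centroid[0], cols - centroid[1]], axis=-1)
    u = d @ rot  # coordinates in the (major, minor) frame
    return (u[..., 0] / axes[0]) ** 2 + (u[..., 1] / axes[1]) ** 2 <= 1.0


def shape_features(mask: np.ndarray) -> tuple[float, float, float]:
    """Features f10-f12 from the mask's moment ellipse.

    f10 = sqrt(minor/major eigenvalue) in (0, 1]; f11 = fraction of the
    fitted ellipse covered by the ROI; f12 = fraction of the ROI escaping
    the fitted ellipse.
    """
    mask = np.asarray(mask, dtype=bool)
    centroid, axes, rot, (lam_major, lam_minor) = fit_mask_ellipse(mask)
    f10 = float(np.sqrt(lam_minor / lam_major))
    ell = ellipse_mask(mask.shape, centroid, axes, rot)
    n_ell = ell.sum()
    f11 = float((mask & ell).sum() / n_ell) if n_ell else 0.0
    f12 = float((mask & ~ell).sum() / mask.sum())
    return f10, f11, f12


def extract_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The full 12-feature descriptor for one image + ROI mask."""
    f16 = mean_color(image, mask)
    f7 = color_structure(image, mask)
    f8, f9 = color_layout(image, mask)
    f10, f11, f12 = shape_features(mask)
    return np.concatenate([f16, [f7, f8, f9, f10, f11, f12]])


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max learned from a training feature matrix."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        if np.any(self.maximum < self.minimum):
            raise DimensionError("max < min in normalization params")

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(),
                "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(minimum=np.asarray(d["minimum"], dtype=float),
                   maximum=np.asarray(d["maximum"], dtype=float))


def fit_normalizer(feature_matrix: np.ndarray) -> NormalizationParams:
    """Learn per-column min/max from a training matrix (>= 2 rows)."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DimensionError("training matrix must have at least 2 rows")
    return NormalizationParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_normalizer(vector: np.ndarray, params: NormalizationParams
                     ) -> np.ndarray:
    """Min-max map to [0, 1]; out-of-range test values are clamped and
    constant training columns map to 0.5."""
    x = np.asarray(vector, dtype=float)
    if x.shape[-1] != params.minimum.shape[0]:
        raise DimensionError(
            f"vector length {x.shape[-1]} != {params.minimum.shape[0]}")
    span = params.maximum - params.minimum
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - params.minimum) / span
    out = np.where(span > 0, out, 0.5)
    return np.clip(out, 0.0, 1.0)


def features_to_frame(feature_matrix: np.ndarray,
                      labels: list[str] | None = None) -> pd.DataFrame:
    """Wrap a (n, 12) matrix in the canonical CSV column layout."""
    X = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if X.shape[1] != N_FEATURES:
        raise DimensionError(f"expected {N_FEATURES} columns, got {X.shape[1]}")
    frame = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    if labels is not None:
        frame["label"] = list(labels)
    return frame


def frame_to_features(frame: pd.DataFrame
                      ) -> tuple[np.ndarray, list[str] | None]:
    """Inverse of :func:`features_to_frame`."""
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise DimensionError(f"feature table missing columns {missing}")
    X = frame[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels = frame["label"].tolist() if "label" in frame.columns else None
    return X, labels
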