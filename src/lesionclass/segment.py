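"""Preprocessing and POI-seeded region-growing segmentation.

Pipeline order (fixed): grayscale conversion -> 3x3 zero-padded median
filter -> contrast stretch -> seed-relative region growing -> morphological
refinement.  The region-growing similarity criterion compares each candidate
pixel's gray value with the *originating seed's* value, which makes the
result independent of pixel visit order: the grown region from seed ``s`` is
exactly the connected component, containing ``s``, of the indicator image
``|gray - gray[s]| <= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import EmptyROIError, FormatError, ParameterError

#: Rec. 601 luma weights (sum to 1)
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SegmentationConfig:
    similarity_threshold: float = 0.15  # gray-value distance in [0, 1]
    connectivity: int = 8  # pixel adjacency: 4 or 8
    opening_radius: int = 2  # px, scale of hole closing / smoothing
    min_object_size: int = 64  # px, smaller components are dropped

    def __post_init__(self):
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ParameterError("similarity_threshold must be in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.opening_radius < 0 or self.min_object_size < 0:
            raise ParameterError("opening_radius and min_object_size >= 0")


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted RGB -> gray conversion (Rec. 601 weights)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected (h, w, 3) RGB raster, got {image.shape}")
    return image @ _LUMA


def median_filter3(image: np.ndarray) -> np.ndarray:
    """3x3 median with zero padding at the borders.

    Each output pixel is the middle (5th-smallest) of the nine values of its
    zero-padded 3x3 neighbourhood; border pixels therefore see padded zeros,
    which pulls dark halos at image corners — the documented behaviour of the
    zero-fill convention.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError("median_filter3 expects a single-channel image")
    return ndi.median_filter(image, size=3, mode="constant", cval=0.0)


def stretch_contrast(image: np.ndarray) -> np.ndarray:
    """Linear histogram stretch onto the full [0, 1] gray range.

    Constant images are returned unchanged (no range to stretch).
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return image.copy()
    return (image - lo) / (hi - lo)


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def region_grow(image: np.ndarray, seeds: list[tuple[int, int]],
                config: SegmentationConfig | None = None) -> np.ndarray:
    """Grow a region from each seed; return the union mask.

    A pixel belongs to the mask iff it is reachable from some seed through
    pixels whose gray distance to that seed's value is <= the similarity
    threshold.  Equivalent to flood fill on the thresholded indicator image,
    hence deterministic and independent of seed order.
    """
    config = config or SegmentationConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError("region_grow expects a single-channel image")
    if not seeds:
        raise ParameterError("at least one seed point is required")
    h, w = image.shape
    struct = _structure(config.connectivity)
    out = np.zeros((h, w), dtype=bool)
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ParameterError(f"seed ({r}, {c}) outside {h}x{w} image")
        similar = np.abs(image - image[r, c]) <= config.similarity_threshold
        labels, _ = ndi.label(similar, structure=struct)
        out |= labels == labels[r, c]
    return out


def refine_mask(mask: np.ndarray, config: SegmentationConfig | None = None,
                seeds: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Morphological cleanup: close small holes, drop small components.

    Holes smaller than the closing scale (``opening_radius``) are filled via
    binary closing of the complement-bounded interior; components below
    ``min_object_size`` pixels are removed.  If ``seeds`` are given and the
    cleanup removes every seed-containing component, raises
    :class:`EmptyROIError`.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    out = mask
    if config.opening_radius > 0:
        footprint = morphology.disk(config.opening_radius)
        out = morphology.closing(out, footprint).astype(bool)
    if config.min_object_size > 0:
        labels, n = ndi.label(out, structure=_structure(config.connectivity))
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= config.min_object_size
            keep[0] = False
            out = keep[labels]
    if seeds is not None:
        if not any(out[r, c] for r, c in seeds):
            raise EmptyROIError("refinement removed all seeded components")
    if not out.any():
        raise EmptyROIError("refinement produced an empty mask")
    return out


def segment_lesion(image: np.ndarray, pois: list[tuple[int, int]],
                   config: SegmentationConfig | None = None) -> np.ndarray:
    """Full segmentation chain: gray -> median -> stretch -> grow -> refine."""
    config = config or SegmentationConfig()
    gray = stretch_contrast(median_filter3(to_gray(image)))
    grown = region_grow(gray, pois, config)
    return refine_mask(grown, config, seeds=pois)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap |A∩B| / |A∪B| between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mask_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components in a binary mask."""
    return int(measure.label(np.asarray(mask, bool),
                             connectivity=2 if connectivity == 8 else 1).max())
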