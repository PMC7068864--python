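"""Seeded generator of dermoscopy-like benign/malignant lesion images.

The generator produces the two visually separable classes the downstream
pipeline is exercised on:

* **benign** — near-elliptical border, a single homogeneous lesion color;
* **malignant** — irregular border (radial perturbation of the ellipse) and
  several heterogeneous color patches (seeded Voronoi partition).

Lesions are star-convex regions ``dist <= r(theta)`` with

    r(theta) = r_ellipse(theta) * (1 + irregularity * s(theta)),

where ``s`` is a smooth band-limited radial noise normalised to peak
amplitude 1.  Star-convexity guarantees every mask is a single connected,
hole-free component.  All randomness flows from the integer seed; identical
parameters reproduce bit-identical cases.

Images are synthesised as float RGB in [0, 1] and written as 8-bit PNG.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ParameterError

BENIGN = "benign"
MALIGNANT = "malignant"

#: default skin-tone background (light Fitzpatrick-II-like RGB)
DEFAULT_SKIN_TONE = (0.85, 0.66, 0.55)

#: homogeneous light-brown nevus color
BENIGN_PALETTE = ((0.45, 0.28, 0.18),)

#: heterogeneous melanoma palette: dark brown, near-black, red-brown, blue-gray
MALIGNANT_PALETTE = (
    (0.35, 0.20, 0.12),
    (0.12, 0.08, 0.08),
    (0.55, 0.25, 0.20),
    (0.30, 0.30, 0.40),
)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic lesion case.

    ``border_irregularity`` is the radial perturbation amplitude as a
    fraction of the local ellipse radius; ``n_color_patches`` is the number
    of Voronoi color cells inside the lesion; ``noise_sd`` is the additive
    per-channel Gaussian noise standard deviation.
    """

    class_label: str
    image_size: tuple[int, int] = (64, 64)
    border_irregularity: float = 0.0
    n_color_patches: int = 1
    lesion_palette: tuple[tuple[float, float, float], ...] = BENIGN_PALETTE
    skin_tone: tuple[float, float, float] = DEFAULT_SKIN_TONE
    noise_sd: float = 0.02
    seed: int = 0
    #: mean lesion radius as a fraction of min(h, w)
    radius_frac: float = 0.28

    def __post_init__(self):
        if self.class_label not in (BENIGN, MALIGNANT):
            raise ParameterError(f"unknown class_label {self.class_label!r}")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ParameterError("image_size must be at least 32x32")
        if self.border_irregularity < 0:
            raise ParameterError("border_irregularity must be >= 0")
        if self.n_color_patches < 1:
            raise ParameterError("n_color_patches must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if len(self.lesion_palette) < 1:
            raise ParameterError("lesion_palette must be non-empty")


@dataclass
class SyntheticCase:
    """One generated case: RGB image, ground-truth mask, POI seeds, label."""

    image: np.ndarray  # (h, w, 3) float in [0, 1]
    truth_mask: np.ndarray  # (h, w) bool
    poi: list[tuple[int, int]]  # (row, col) seeds, all inside truth_mask
    label: str
    params: SynthParams | None = None


def benign_preset(seed: int = 0, image_size: tuple[int, int] = (64, 64),
                  **overrides) -> SynthParams:
    """Benign preset: near-elliptical, homogeneous color."""
    kwargs = dict(border_irregularity=0.03, n_color_patches=1,
                  lesion_palette=BENIGN_PALETTE)
    kwargs.update(overrides)
    p = SynthParams(class_label=BENIGN, image_size=image_size, seed=seed,
                    **kwargs)
    if p.border_irregularity > 0.05 or p.n_color_patches != 1:
        raise ParameterError("benign preset requires border_irregularity <= "
                             "0.05 and n_color_patches = 1")
    return p


def malignant_preset(seed: int = 0, image_size: tuple[int, int] = (64, 64),
                     **overrides) -> SynthParams:
    """Malignant preset: irregular border, heterogeneous color patches."""
    kwargs = dict(border_irregularity=0.35, n_color_patches=4,
                  lesion_palette=MALIGNANT_PALETTE, radius_frac=0.20)
    kwargs.update(overrides)
    p = SynthParams(class_label=MALIGNANT, image_size=image_size, seed=seed,
                    **kwargs)
    if p.border_irregularity < 0.25 or p.n_color_patches < 3:
        raise ParameterError("malignant preset requires border_irregularity "
                             ">= 0.25 and n_color_patches >= 3")
    return p


def _radial_noise(theta: np.ndarray, rng: np.random.Generator,
                  harmonics: tuple[int, ...] = (2, 3, 4, 5, 6)) -> np.ndarray:
    """Smooth 2*pi-periodic noise, normalised to max |value| = 1."""
    amp = rng.uniform(0.3, 1.0, size=len(harmonics))
    phase = rng.uniform(0.0, 2 * np.pi, size=len(harmonics))
    s = np.zeros_like(theta, dtype=float)
    for a, ph, k in zip(amp, phase, harmonics):
        s += a * np.cos(k * theta + ph)
    peak = np.max(np.abs(s))
    return s / peak if peak > 0 else s


def _ellipse_radius(theta: np.ndarray, a: float, b: float,
                    phi: float) -> np.ndarray:
    """Radius of an (a, b) ellipse rotated by phi, in direction theta."""
    t = theta - phi
    return (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _nearest_mask_pixel(mask: np.ndarray, r: float, c: float) -> tuple[int, int]:
    rr, cc = np.nonzero(mask)
    i = int(np.argmin((rr - r) ** 2 + (cc - c) ** 2))
    return int(rr[i]), int(cc[i])


def generate_case(params: SynthParams) -> SyntheticCase:
    """Generate one synthetic lesion case from ``params``.

    The lesion centroid is placed within the central 50% of the frame and
    the whole lesion (including irregularity excursions) must fit inside the
    image with a 2-pixel margin, else :class:`ParameterError` is raised.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size

    # lesion geometry: jittered centre, mean radius, axis ratio, orientation
    cy = h / 2 + rng.uniform(-0.06, 0.06) * h
    cx = w / 2 + rng.uniform(-0.06, 0.06) * w
    R = params.radius_frac * min(h, w) * rng.uniform(0.85, 1.1)
    q = rng.uniform(0.7, 0.95)  # minor/major axis ratio
    a, b = R / np.sqrt(q), R * np.sqrt(q)  # a*b = R^2
    phi = rng.uniform(0.0, np.pi)

    margin = min(cy, cx, h - 1 - cy, w - 1 - cx)
    if a * (1.0 + params.border_irregularity) > margin - 2:
        raise ParameterError(
            f"lesion radius {a * (1 + params.border_irregularity):.1f} px "
            f"exceeds frame margin {margin - 2:.1f} px")

    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - cy, cols - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    boundary = _ellipse_radius(theta, a, b, phi)
    if params.border_irregularity > 0:
        factor = 1.0 + params.border_irregularity * _radial_noise(theta, rng)
        boundary = boundary * np.maximum(factor, 0.2)
    mask = dist <= boundary

    # color: Voronoi partition of the lesion interior over seeded sites
    lesion_rc = np.column_stack(np.nonzero(mask)).astype(float)
    n_sites = params.n_color_patches
    site_idx = rng.choice(len(lesion_rc), size=n_sites, replace=False)
    sites = lesion_rc[site_idx]
    palette = np.asarray(params.lesion_palette, dtype=float)
    d2 = ((lesion_rc[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    cell = np.argmin(d2, axis=1)  # ties -> lowest site index (deterministic)

    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(params.skin_tone, dtype=float)
    rr = lesion_rc[:, 0].astype(int)
    cc = lesion_rc[:, 1].astype(int)
    image[rr, cc] = palette[cell % len(palette)]

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    # POIs: mask centroid first, then one per color patch
    poi = [_nearest_mask_pixel(mask, float(lesion_rc[:, 0].mean()),
                               float(lesion_rc[:, 1].mean()))]
    if n_sites > 1:
        for s in range(n_sites):
            in_cell = lesion_rc[cell == s]
            if len(in_cell) == 0:
                continue
            pr, pc = in_cell.mean(axis=0)
            # snap to a pixel of this patch so the POI sits on its own color
            j = int(np.argmin((in_cell[:, 0] - pr) ** 2
                              + (in_cell[:, 1] - pc) ** 2))
            poi.append((int(in_cell[j, 0]), int(in_cell[j, 1])))

    return SyntheticCase(image=image, truth_mask=mask, poi=poi,
                         label=params.class_label, params=params)


def default_presets(image_size: tuple[int, int] = (64, 64)
                    ) -> tuple[SynthParams, SynthParams]:
    """The (benign, malignant) preset pair used by the reference benchmark."""
    return benign_preset(image_size=image_size), malignant_preset(image_size=image_size)


def generate_dataset(n_per_class: int,
                     presets: tuple[SynthParams, SynthParams] | None = None,
                     seed: int = 0) -> list[SyntheticCase]:
    """Generate ``n_per_class`` cases of each class.

    Per-case seeds are drawn deterministically from the master ``seed``; the
    returned list alternates benign/malignant so any prefix is near-balanced.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    if presets is None:
        presets = default_presets()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * n_per_class)
    cases: list[SyntheticCase] = []
    for i in range(n_per_class):
        for j, preset in enumerate(presets):
            p = dataclasses.replace(preset, seed=int(case_seeds[2 * i + j]))
            cases.append(generate_case(p))
    return cases


def write_dataset(cases: list[SyntheticCase], out_dir: str) -> pd.DataFrame:
    """Write PNG images + truth masks and a manifest CSV; return the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for i, case in enumerate(cases):
        name = f"case_{i:04d}_{case.label}.png"
        img8 = np.round(case.image * 255.0).astype(np.uint8)
        Image.fromarray(img8).save(os.path.join(out_dir, name))
        mask_name = name.replace(".png", "_mask.png")
        Image.fromarray((case.truth_mask * 255).astype(np.uint8)).save(
            os.path.join(out_dir, mask_name))
        records.append({
            "filename": name,
            "mask_filename": mask_name,
            "label": case.label,
            "poi_row": case.poi[0][0],
            "poi_col": case.poi[0][1],
            "pois": ";".join(f"{r},{c}" for r, c in case.poi),
            "seed": case.params.seed if case.params is not None else -1,
        })
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def read_image(path: str) -> np.ndarray:
    """Read an 8-bit PNG/JPEG as float RGB in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return arr
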