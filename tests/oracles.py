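"""Independent brute-force oracles the implementation is held against.

Everything here is written by definition — explicit Python loops, exhaustive
enumeration, pairwise counting — and deliberately shares no code with the
package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def conv_by_loops(plane: np.ndarray, kernel: np.ndarray,
                  flip: bool = False) -> np.ndarray:
    """Four-nested-loop cross-correlation with zero 'same' padding."""
    plane = np.asarray(plane, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if flip:
        kernel = kernel[::-1, ::-1]
    h, w = plane.shape
    kh, kw = kernel.shape
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for n in range(kh):
                for m in range(kw):
                    r, c = i + n - pt, j + m - pl
                    if 0 <= r < h and 0 <= c < w:
                        acc += plane[r, c] * kernel[n, m]
            out[i, j] = acc
    return out


def maxpool_by_loops(plane: np.ndarray, k: int = 2) -> np.ndarray:
    """Window-by-window max enumeration, floor semantics."""
    h, w = plane.shape
    out = np.empty((h // k, w // k))
    for i in range(h // k):
        for j in range(w // k):
            out[i, j] = max(plane[i * k + a][j * k + b]
                            for a in range(k) for b in range(k))
    return out


def flood_fill(indicator: np.ndarray, seed: tuple[int, int],
               connectivity: int = 8) -> np.ndarray:
    """BFS flood fill over a boolean indicator image."""
    h, w = indicator.shape
    out = np.zeros((h, w), dtype=bool)
    if not indicator[seed]:
        return out
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    stack = [seed]
    out[seed] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and indicator[rr, cc] \
                    and not out[rr, cc]:
                out[rr, cc] = True
                stack.append((rr, cc))
    return out


def region_grow_by_bfs(gray: np.ndarray, seeds, threshold: float,
                       connectivity: int = 8) -> np.ndarray:
    """Region growing by per-seed BFS over the seed-relative indicator."""
    out = np.zeros(gray.shape, dtype=bool)
    for seed in seeds:
        indicator = np.abs(gray - gray[seed]) <= threshold
        out |= flood_fill(indicator, tuple(seed), connectivity)
    return out


def knn_by_sort(X_train: np.ndarray, y_train: np.ndarray, x: np.ndarray,
                k: int) -> tuple[int, float]:
    """All-pairs distance sort + majority vote; ties to nearest's label."""
    d = [(float(np.sqrt(((row - x) ** 2).sum())), i)
         for i, row in enumerate(X_train)]
    d.sort()
    votes = [int(y_train[i]) for _, i in d[:k]]
    score = sum(votes) / k
    if score > 0.5:
        return 1, score
    if score < 0.5:
        return 0, score
    return votes[0], score


def rank_by_distance_matrix(base: np.ndarray, ids: list[str],
                            query: np.ndarray, k: int) -> list[str]:
    """Full distance-matrix sort with (distance, id) tie order."""
    d = [(float(np.sqrt(((row - query) ** 2).sum())), ids[i])
         for i, row in enumerate(base)]
    d.sort()
    return [cid for _, cid in d[:k]]


def auc_by_pair_counting(labels01: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: positive-over-negative pairs, ties half weight."""
    pos = scores[np.asarray(labels01) == 1]
    neg = scores[np.asarray(labels01) == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def dct2_by_sums(grid: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II by its definition sums."""
    n = grid.shape[0]
    out = np.zeros_like(grid, dtype=float)
    for u in range(n):
        for v in range(n):
            acc = 0.0
            for x in range(n):
                for y in range(n):
                    acc += (grid[x, y]
                            * np.cos((2 * x + 1) * u * np.pi / (2 * n))
                            * np.cos((2 * y + 1) * v * np.pi / (2 * n)))
            cu = np.sqrt(1 / n) if u == 0 else np.sqrt(2 / n)
            cv = np.sqrt(1 / n) if v == 0 else np.sqrt(2 / n)
            out[u, v] = cu * cv * acc
    return out


def csd_by_window_enumeration(quantized: np.ndarray, roi: np.ndarray,
                              window: int, n_bins: int) -> float:
    """Direct-count color-structure entropy: explicit window loops."""
    h, w = quantized.shape
    wh, ww = min(window, h), min(window, w)
    counts = np.zeros(n_bins)
    for i in range(h - wh + 1):
        for j in range(w - ww + 1):
            seen = set()
            for a in range(wh):
                for b in range(ww):
                    if roi[i + a, j + b]:
                        seen.add(int(quantized[i + a, j + b]))
            for color in seen:
                counts[color] += 1
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(n_bins))


def ellipse_coverage_by_pixel_loop(mask: np.ndarray, centroid, axes, rot
                                   ) -> tuple[float, float]:
    """f11/f12 by per-pixel quadratic-form membership testing."""
    h, w = mask.shape
    inside = np.zeros((h, w), dtype=bool)
    (cy, cx), (a, b) = centroid, axes
    for r in range(h):
        for c in range(w):
            u = (r - cy) * rot[0, 0] + (c - cx) * rot[1, 0]
            v = (r - cy) * rot[0, 1] + (c - cx) * rot[1, 1]
            inside[r, c] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    f11 = (mask & inside).sum() / inside.sum()
    f12 = (mask & ~inside).sum() / mask.sum()
    return float(f11), float(f12)
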