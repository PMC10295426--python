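"""Independent brute-force reference implementations used only by tests.

Every function here is a literal, loop-based transcription of the
definition it checks, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_erode(mask: np.ndarray, matrix: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """All-placements flat erosion: keep p iff every true element cell,
    anchored at p, lands on a true pixel; cells outside the image are
    ignored (out-of-domain treated as foreground/+inf)."""
    h, w = mask.shape
    cells = [(r - anchor[0], c - anchor[1]) for r, c in zip(*np.nonzero(matrix))]
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for dr, dc in cells:
                r, c = i + dr, j + dc
                if 0 <= r < h and 0 <= c < w and not mask[r, c]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def brute_dilate(mask: np.ndarray, matrix: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """All-placements flat dilation with the element reflected through its
    anchor; out-of-domain treated as background/-inf."""
    h, w = mask.shape
    cells = [(r - anchor[0], c - anchor[1]) for r, c in zip(*np.nonzero(matrix))]
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            hit = False
            for dr, dc in cells:
                r, c = i - dr, j - dc
                if 0 <= r < h and 0 <= c < w and mask[r, c]:
                    hit = True
                    break
            out[i, j] = hit
    return out


def _window(img: np.ndarray, i: int, j: int, size: int) -> np.ndarray:
    """size x size neighbourhood with edge replication."""
    h, w = img.shape
    r = size // 2
    rows = np.clip(np.arange(i - r, i + r + 1), 0, h - 1)
    cols = np.clip(np.arange(j - r, j + r + 1), 0, w - 1)
    return img[np.ix_(rows, cols)]


def brute_min_filter(img: np.ndarray, size: int) -> np.ndarray:
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = _window(img, i, j, size).min()
    return out


def brute_median_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Sort the window and pick the middle element."""
    out = np.empty_like(img)
    k = size * size
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sort(_window(img, i, j, size).ravel())[k // 2]
    return out


def brute_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Double-loop correlation with edge replication, float output."""
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = float((_window(img.astype(float), i, j, kernel.shape[0]) * kernel).sum())
    return out


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by explicit stack-based flood fill."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    next_label = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                next_label += 1
                stack = [(i, j)]
                labels[i, j] = next_label
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = next_label
                            stack.append((rr, cc))
    return labels


def plain_hist_equalize(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization: g -> round(255 * cdf(g) / n)."""
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    lut = np.rint(255.0 * cdf / img.size).astype(np.uint8)
    return lut[img]


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label images induce the same partition of the foreground."""
    fa, fb = a > 0, b > 0
    if not np.array_equal(fa, fb):
        return False
    pairs = {}
    for x, y in zip(a[fa].ravel(), b[fb].ravel()):
        if pairs.setdefault(x, y) != y:
            return False
    rev = {}
    for x, y in pairs.items():
        if rev.setdefault(y, x) != x:
            return False
    return True
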