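"""Image-quality and segmentation-quality scores.

Two sharpness/contrast measures for grayscale images — gradient energy (sum
of squared one-step forward differences along both axes) and the Brenner
score (squared two-step differences along the row direction) — and the
pixelwise confusion counts with Dice, accuracy and sensitivity for
segmentations against a reference mask.

Energy and Brenner are, by default, computed on intensities rescaled to
[0, 1] and averaged over the number of summed terms, so scores are
comparable across image sizes and land in the same sub-unity range used for
denoising comparisons; pass ``normalized=False`` for the raw 8-bit sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from veinseg.io import as_gray_u8, as_mask

__all__ = ["SegmentationScores", "energy", "brenner", "confusion"]


@dataclass(frozen=True)
class SegmentationScores:
    """Pixel confusion counts and derived overlap scores.

    dice = 2 TP / (2 TP + FP + FN); acc = (TP + TN) / total;
    sen = TP / (TP + FN). Degenerate cases: with an empty reference and an
    empty segmentation dice = 1, and sen = 1 whenever the reference is
    empty (there is nothing to miss).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    dice: float
    acc: float
    sen: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _scaled_diffsq(img: np.ndarray, normalized: bool):
    a = as_gray_u8(img).astype(np.float64)
    if normalized:
        a = a / 255.0
    return a


def energy(img: np.ndarray, normalized: bool = True) -> float:
    """Gradient energy: sum over both axes of squared forward differences.

    Requires at least a 2x2 image; zero iff the image is constant.
    """
    a = _scaled_diffsq(img, normalized)
    h, w = a.shape
    if h < 2 or w < 2:
        raise ValueError("energy needs an image of at least 2x2")
    dx = np.diff(a, axis=1)
    dy = np.diff(a, axis=0)
    total = float((dx * dx).sum() + (dy * dy).sum())
    if normalized:
        total /= dx.size + dy.size
    return total


def brenner(img: np.ndarray, normalized: bool = True) -> float:
    """Brenner sharpness: sum of squared lag-2 differences along rows.

    Requires width >= 3.
    """
    a = _scaled_diffsq(img, normalized)
    if a.shape[1] < 3:
        raise ValueError("brenner needs an image width of at least 3")
    d = a[:, 2:] - a[:, :-2]
    total = float((d * d).sum())
    if normalized:
        total /= d.size
    return total


def confusion(seg: np.ndarray, gt: np.ndarray) -> SegmentationScores:
    """Confusion counts and Dice/accuracy/sensitivity of a segmentation
    against a reference mask (*gt* is the reference)."""
    s, g = as_mask(seg), as_mask(gt)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {g.shape}")
    tp = int(np.count_nonzero(s & g))
    fp = int(np.count_nonzero(s & ~g))
    fn = int(np.count_nonzero(~s & g))
    tn = int(np.count_nonzero(~s & ~g))
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    acc = (tp + tn) / s.size
    sen = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    return SegmentationScores(tp=tp, fp=fp, tn=tn, fn=fn, dice=dice, acc=acc, sen=sen)
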