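"""Synthetic near-infrared forearm vessel phantoms.

Real NIR forearm images show a bright, unevenly illuminated background with
darker, elongated, smoothly curving vessels whose edges are blurred by optics
and tissue scattering, plus additive Gaussian sensor noise. The generator
reproduces exactly these ingredients and returns the image together with its
exact vessel mask, so segmentation quality can be scored without clinical
data and expert annotation.

Construction order: illumination field -> dark vessel tubes (spline
centerlines, per-vessel calibre) -> Gaussian edge blur -> Gaussian noise ->
clip to [0, 255]. The ground-truth mask is the *pre-blur* tube footprint:
blur models the optics, the truth is the anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage

__all__ = ["PhantomSpec", "generate_phantom", "add_gaussian_noise"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic vessel phantom.

    Defaults emulate a 548x335 region-of-interest crop of a forearm NIR
    image: a bright background (base 180) with a +/-30 intensity
    illumination tilt, three vessels of 6-12 px calibre about 40 intensity
    units darker than their surround, optical blur sigma 1.5 px, and sensor
    noise sigma 8.
    """

    height: int = 335
    width: int = 548
    n_vessels: int = 3
    width_range: tuple[float, float] = (6.0, 12.0)
    vessel_contrast: float = 40.0
    background_base: float = 180.0
    illumination_gradient: float = 30.0
    edge_blur_sigma: float = 1.5
    noise_sigma: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.width_range[0] < 1 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must satisfy 1 <= min <= max")
        if self.vessel_contrast <= 0:
            raise ValueError("vessel_contrast must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        if self.n_vessels > 0 and min(self.height, self.width) < self.width_range[0]:
            raise ValueError("image too small to place a vessel of the minimum width")


def _illumination(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Linear illumination field spanning +/-illumination_gradient."""
    h, w = spec.height, spec.width
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[0:h, 0:w]
    # signed coordinate along the tilt direction, normalized to [-1, 1]
    u = (rr - (h - 1) / 2) * np.sin(theta) + (cc - (w - 1) / 2) * np.cos(theta)
    span = np.abs(u).max()
    if span > 0:
        u = u / span
    return spec.background_base + spec.illumination_gradient * u


def _vessel_footprint(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one tube: cubic spline through random control points."""
    h, w = spec.height, spec.width
    n_ctrl = int(rng.integers(4, 9))
    # control points ordered along a random principal direction so the
    # curve is elongated rather than self-crossing
    phi = rng.uniform(0, np.pi)
    d = np.array([np.cos(phi), np.sin(phi)])  # (col, row) direction
    t = np.sort(rng.uniform(-0.55, 0.55, n_ctrl))
    lateral = rng.uniform(-0.25, 0.25, n_ctrl)
    cx = (w - 1) * (0.5 + t * d[0] - lateral * d[1])
    cy = (h - 1) * (0.5 + t * d[1] + lateral * d[0])
    try:
        tck, _ = interpolate.splprep([cx, cy], s=0.0, k=min(3, n_ctrl - 1))
    except (ValueError, TypeError):
        # degenerate (coincident) control points: fall back to a straight line
        tck = None
    if tck is not None:
        u = np.linspace(0, 1, 4 * (h + w))
        px, py = interpolate.splev(u, tck)
    else:
        px = np.linspace(cx[0], cx[-1], 4 * (h + w))
        py = np.linspace(cy[0], cy[-1], 4 * (h + w))
    rows = np.clip(np.rint(py), 0, h - 1).astype(int)
    cols = np.clip(np.rint(px), 0, w - 1).astype(int)
    centerline = np.zeros((h, w), dtype=bool)
    centerline[rows, cols] = True
    radius = rng.uniform(*spec.width_range) / 2.0
    dist = ndimage.distance_transform_edt(~centerline)
    return dist <= radius


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a phantom image and its exact vessel mask.

    Returns
    -------
    image : (H, W) uint8
    mask : (H, W) bool
        Pre-blur union of the vessel tube footprints.

    The output is a deterministic function of the spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    field = _illumination(spec, rng)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for _ in range(spec.n_vessels):
        mask |= _vessel_footprint(spec, rng)
    # blur the vessel layer only: the illumination field is already smooth,
    # and a vessel-free phantom must equal the pure field exactly
    vessel_layer = mask.astype(np.float64)
    if spec.edge_blur_sigma > 0:
        vessel_layer = ndimage.gaussian_filter(
            vessel_layer, spec.edge_blur_sigma, mode="nearest"
        )
    img = field - spec.vessel_contrast * vessel_layer
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    return img, mask


def add_gaussian_noise(img: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise of standard deviation *sigma*, clipped
    to [0, 255]. Deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    a = np.asarray(img, dtype=np.float64)
    if sigma == 0:
        return np.rint(np.clip(a, 0, 255)).astype(np.uint8)
    rng = np.random.default_rng(seed)
    noisy = a + rng.normal(0.0, sigma, a.shape)
    return np.rint(np.clip(noisy, 0, 255)).astype(np.uint8)
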