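"""End-to-end vessel segmentation pipeline.

Stage order: CLAHE -> Gaussian denoising -> background estimation (on the
enhanced, denoised image) -> background subtraction -> binarization ->
connected-component area screening -> T-element morphological refinement.
Every stage is configurable and individually switchable; the pipeline is
fully deterministic (no stage consumes randomness).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from veinseg.io import as_gray_u8
from veinseg.enhancement import ClaheParams, GaussianKernelSpec, clahe, gaussian_filter
from veinseg.background import (
    DifferenceMap,
    binarize_difference,
    extract_background,
    subtract_background,
)
from veinseg.components import filter_components
from veinseg.morphology import refine_vessels

__all__ = ["PipelineConfig", "StageTrace", "segment_vessels"]

logger = logging.getLogger("veinseg")


@dataclass
class ClaheStage:
    enabled: bool = True
    tiles_m: int = 8
    tiles_n: int = 8
    clip_factor: float = 2.0


@dataclass
class GaussianStage:
    enabled: bool = True
    size: int = 3
    sigma: float = 1.5


@dataclass
class BackgroundStage:
    min_size: int = 3
    med_size: int = 51
    polarity: str = "dark"
    threshold: float | str = "auto"


@dataclass
class ComponentsStage:
    enabled: bool = True
    area_threshold: int = 1500
    connectivity: int = 8


@dataclass
class MorphologyStage:
    enabled: bool = True
    disk_radius: int = 3


@dataclass
class PipelineConfig:
    """Nested per-stage configuration with documented, valid defaults.

    Round-trips losslessly through YAML; an empty user config runs the
    pipeline with defaults.
    """

    clahe: ClaheStage = field(default_factory=ClaheStage)
    gaussian: GaussianStage = field(default_factory=GaussianStage)
    background: BackgroundStage = field(default_factory=BackgroundStage)
    components: ComponentsStage = field(default_factory=ComponentsStage)
    morphology: MorphologyStage = field(default_factory=MorphologyStage)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict | None) -> "PipelineConfig":
        d = d or {}
        unknown = set(d) - {"clahe", "gaussian", "background", "components", "morphology"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            clahe=ClaheStage(**d.get("clahe", {})),
            gaussian=GaussianStage(**d.get("gaussian", {})),
            background=BackgroundStage(**d.get("background", {})),
            components=ComponentsStage(**d.get("components", {})),
            morphology=MorphologyStage(**d.get("morphology", {})),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


@dataclass
class StageTrace:
    """Ordered record of (stage name, stage output, wall-time seconds)."""

    entries: list[tuple[str, np.ndarray, float]] = field(default_factory=list)

    def add(self, name: str, output: np.ndarray, seconds: float) -> None:
        self.entries.append((name, output, seconds))

    @property
    def stage_names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def output_of(self, name: str) -> np.ndarray:
        for n, out, _ in self.entries:
            if n == name:
                return out
        raise KeyError(f"no stage named {name!r} in trace")


def _staged(trace: StageTrace, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    trace.add(name, out.values if isinstance(out, DifferenceMap) else out, dt)
    logger.info("stage %-12s %.3fs", name, dt)
    return out


def segment_vessels(
    img: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, StageTrace]:
    """Segment dark vessels from a grayscale NIR image.

    Returns the final boolean vessel mask and a :class:`StageTrace` with
    every enabled stage's intermediate output. An all-empty intermediate
    mask is a valid result (logged as a warning), not an error.
    """
    cfg = cfg or PipelineConfig()
    x = as_gray_u8(img)
    trace = StageTrace()

    if cfg.clahe.enabled:
        params = ClaheParams(cfg.clahe.tiles_m, cfg.clahe.tiles_n, cfg.clahe.clip_factor)
        x = _staged(trace, "clahe", clahe, x, params)
    if cfg.gaussian.enabled:
        spec = GaussianKernelSpec(cfg.gaussian.size, cfg.gaussian.sigma)
        x = _staged(trace, "gaussian", gaussian_filter, x, spec)

    bg = _staged(
        trace, "background", extract_background, x, cfg.background.min_size, cfg.background.med_size
    )
    diff = _staged(trace, "subtract", subtract_background, x, bg, cfg.background.polarity)
    mask = _staged(trace, "binarize", binarize_difference, diff, cfg.background.threshold)
    if not mask.any():
        logger.warning("binarization produced an empty mask")

    if cfg.components.enabled:
        mask = _staged(
            trace,
            "components",
            filter_components,
            mask,
            cfg.components.area_threshold,
            cfg.components.connectivity,
        )
        if not mask.any():
            logger.warning("component screening removed every component")
    if cfg.morphology.enabled:
        mask = _staged(trace, "morphology", refine_vessels, mask, cfg.morphology.disk_radius)
    return mask, trace
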