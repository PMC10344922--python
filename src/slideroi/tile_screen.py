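"""Pre-classification block screening: empty/fat rejection, artifact flagging
and a pluggable image-quality gate.

Gate order is empty -> artifact -> quality; the first failing gate assigns
the block state. The empty and artifact tests run on the 1x rendition of a
block, the quality gate on the rendition at the block's own magnification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .pyramid import BlockState, SlidePyramid, TileBlock, read_block_image

__all__ = [
    "ScreenConfig",
    "ScreenError",
    "dark_fraction",
    "default_quality_score",
    "is_empty_block",
    "luminance",
    "register_artifact_evaluator",
    "register_quality_evaluator",
    "screen_block",
]


class ScreenError(RuntimeError):
    """A gate evaluator failed; carries the block coordinates."""


def luminance(image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance, rounded to the nearest integer gray level."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return np.rint(arr.astype(np.float64)).astype(np.int64)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        y = (
            0.299 * arr[..., 0].astype(np.float64)
            + 0.587 * arr[..., 1]
            + 0.114 * arr[..., 2]
        )
        return np.rint(y).astype(np.int64)
    raise ValueError("expected a grayscale or RGB raster")


def default_quality_score(image: np.ndarray) -> float:
    """Sharpness as the variance of a Laplacian response.

    Zero for constant rasters, invariant to 90-degree rotation, and
    monotonically decreasing under Gaussian blur of increasing radius.
    """
    y = luminance(image).astype(np.float64)
    lap = ndimage.laplace(y)
    return float(lap.var())


def dark_fraction(image: np.ndarray, dark_threshold: int = 30) -> float:
    """Fraction of near-black saturated pixels (luminance < threshold)."""
    y = luminance(image)
    return float(np.mean(y < dark_threshold))


QUALITY_EVALUATORS: dict[str, Callable[[np.ndarray], float]] = {
    "laplacian_variance": default_quality_score,
}
ARTIFACT_EVALUATORS: dict[str, Callable[[np.ndarray], float]] = {
    "dark_fraction": dark_fraction,
}


def register_quality_evaluator(name: str, fn: Callable[[np.ndarray], float]) -> None:
    QUALITY_EVALUATORS[name] = fn


def register_artifact_evaluator(name: str, fn: Callable[[np.ndarray], float]) -> None:
    ARTIFACT_EVALUATORS[name] = fn


@dataclass(frozen=True)
class ScreenConfig:
    bright_threshold: int = 200
    bright_fraction: float = 0.75
    quality_evaluator: str = "laplacian_variance"
    quality_threshold: float = 60.0  # Laplacian variance below this = blurry
    artifact_evaluator: str = "dark_fraction"
    artifact_threshold: float = 0.4  # dark-pixel fraction above this = artifact

    def __post_init__(self) -> None:
        if not 0 <= self.bright_threshold <= 255:
            raise ValueError("bright_threshold must be in [0, 255]")
        if not 0.0 <= self.bright_fraction <= 1.0:
            raise ValueError("bright_fraction must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        return cls(**d)


def is_empty_block(image_1x: np.ndarray, config: ScreenConfig | None = None) -> bool:
    """True iff strictly more than ``bright_fraction`` of pixels have
    luminance strictly above ``bright_threshold`` (mostly fat or empty area).
    """
    config = config or ScreenConfig()
    y = luminance(image_1x)
    if y.size == 0:
        raise ValueError("empty raster")
    frac = np.count_nonzero(y > config.bright_threshold) / y.size
    return frac > config.bright_fraction


def screen_block(
    slide: SlidePyramid, block: TileBlock, config: ScreenConfig | None = None
) -> BlockState:
    """Run the screening gates in fixed order and return the block state."""
    config = config or ScreenConfig()
    try:
        low = read_block_image(slide, block, at_mag=1.0)
        if is_empty_block(low, config):
            return BlockState.EMPTY
        artifact_fn = ARTIFACT_EVALUATORS[config.artifact_evaluator]
        if artifact_fn(low) > config.artifact_threshold:
            return BlockState.ARTIFACT
        native = read_block_image(slide, block, at_mag=block.magnification)
        quality_fn = QUALITY_EVALUATORS[config.quality_evaluator]
        if quality_fn(native) < config.quality_threshold:
            return BlockState.POOR_QUALITY
        return BlockState.CANDIDATE
    except KeyError as exc:
        raise ScreenError(
            f"unknown evaluator {exc} for block "
            f"({block.grid_row},{block.grid_col})"
        ) from exc
    except ScreenError:
        raise
    except Exception as exc:  # propagate with block coordinates
        raise ScreenError(
            f"gate failure at block ({block.grid_row},{block.grid_col}): {exc}"
        ) from exc
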