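"""Multi-resolution slide pyramid: levels, tiling, coordinate mapping, ROI maps.

Coordinates are 0-based, half-open, ``(x=col, y=row)`` in pixels at the stated
magnification. Blocks are fixed-size (224 px), non-overlapping and aligned to
a row-major grid; partial edge blocks are dropped, never padded.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np
from PIL import Image, ImageDraw

BLOCK_SIZE = 224

__all__ = [
    "BLOCK_SIZE",
    "BlockState",
    "MagnificationUnavailableError",
    "PyramidLevel",
    "ROIMap",
    "Region",
    "SlidePyramid",
    "TileBlock",
    "block_at_magnification",
    "load_pyramid",
    "read_block_image",
    "render_roi_map",
    "round_half_up",
    "save_pyramid",
    "tile_grid",
]


class MagnificationUnavailableError(ValueError):
    """Requested magnification exceeds the pyramid's base magnification."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (not banker's rounding)."""
    return int(math.floor(x + 0.5))


class BlockState(str, Enum):
    UNSCREENED = "UNSCREENED"
    EMPTY = "EMPTY"
    ARTIFACT = "ARTIFACT"
    POOR_QUALITY = "POOR_QUALITY"
    CANDIDATE = "CANDIDATE"
    REPRESENTATIVE = "REPRESENTATIVE"
    NON_REPRESENTATIVE = "NON_REPRESENTATIVE"


#: Final states a fully processed block may carry.
FINAL_STATES = frozenset(
    {
        BlockState.EMPTY,
        BlockState.ARTIFACT,
        BlockState.POOR_QUALITY,
        BlockState.REPRESENTATIVE,
        BlockState.NON_REPRESENTATIVE,
    }
)

#: Overlay colors for the rendered ROI map.
STATE_COLORS = {
    BlockState.REPRESENTATIVE: (0, 200, 0),
    BlockState.ARTIFACT: (230, 200, 0),
    BlockState.POOR_QUALITY: (150, 0, 180),
}


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle (pixels, half-open) at some magnification."""

    x: int
    y: int
    width: int
    height: int

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def x2(self) -> int:
        return self.x + self.width

    @property
    def y2(self) -> int:
        return self.y + self.height

    def intersection_area(self, other: "Region") -> int:
        w = min(self.x2, other.x2) - max(self.x, other.x)
        h = min(self.y2, other.y2) - max(self.y, other.y)
        return max(0, w) * max(0, h)

    def scaled(self, factor: float) -> "Region":
        return Region(
            x=round_half_up(self.x * factor),
            y=round_half_up(self.y * factor),
            width=max(1, round_half_up(self.width * factor)),
            height=max(1, round_half_up(self.height * factor)),
        )


@dataclass
class PyramidLevel:
    magnification: float
    image: np.ndarray  # HxWx3 uint8

    @property
    def width(self) -> int:
        return int(self.image.shape[1])

    @property
    def height(self) -> int:
        return int(self.image.shape[0])


@dataclass
class SlidePyramid:
    """Ordered stack of magnification levels; ``levels[0]`` is the base."""

    slide_id: str
    levels: list[PyramidLevel]

    def __post_init__(self) -> None:
        self.levels.sort(key=lambda lv: -lv.magnification)
        mags = [lv.magnification for lv in self.levels]
        if len(set(mags)) != len(mags):
            raise ValueError("duplicate magnification levels")

    @property
    def base(self) -> PyramidLevel:
        return self.levels[0]

    @property
    def base_magnification(self) -> float:
        return self.base.magnification

    def magnifications(self) -> list[float]:
        return [lv.magnification for lv in self.levels]

    def level_at(self, magnification: float) -> PyramidLevel | None:
        for lv in self.levels:
            if lv.magnification == magnification:
                return lv
        return None

    def nearest_level_at_least(self, magnification: float) -> PyramidLevel:
        """Smallest stored magnification >= the requested one."""
        if magnification > self.base_magnification:
            raise MagnificationUnavailableError(
                f"magnification {magnification}x above base "
                f"{self.base_magnification}x"
            )
        candidates = [lv for lv in self.levels if lv.magnification >= magnification]
        return min(candidates, key=lambda lv: lv.magnification)

    def dims_at(self, magnification: float) -> tuple[int, int]:
        """(width, height) of the (possibly virtual) level at a magnification."""
        lv = self.level_at(magnification)
        if lv is not None:
            return lv.width, lv.height
        if magnification > self.base_magnification:
            raise MagnificationUnavailableError(
                f"magnification {magnification}x above base "
                f"{self.base_magnification}x"
            )
        f = magnification / self.base_magnification
        return round_half_up(self.base.width * f), round_half_up(self.base.height * f)

    def rebuild_from_base(self) -> None:
        """Recompute every non-base level by area-averaging the base image."""
        for lv in self.levels[1:]:
            f = lv.magnification / self.base_magnification
            w = round_half_up(self.base.width * f)
            h = round_half_up(self.base.height * f)
            lv.image = downsample(self.base.image, (w, h))


def downsample(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Area-average (box filter) resample to ``(width, height)``."""
    pil = Image.fromarray(image)
    return np.asarray(pil.resize(size, Image.Resampling.BOX))


@dataclass
class TileBlock:
    slide_id: str
    grid_row: int
    grid_col: int
    magnification: float
    origin_x: int
    origin_y: int
    size: int = BLOCK_SIZE
    state: BlockState = BlockState.UNSCREENED

    def region(self) -> Region:
        return Region(self.origin_x, self.origin_y, self.size, self.size)


def tile_grid(slide: SlidePyramid, magnification: float) -> list[TileBlock]:
    """All complete 224x224 blocks at a magnification, row-major.

    The level may be virtual (derived by downsampling a higher stored level);
    partial edge blocks are excluded.
    """
    width, height = slide.dims_at(magnification)
    n_cols = width // BLOCK_SIZE
    n_rows = height // BLOCK_SIZE
    return [
        TileBlock(
            slide_id=slide.slide_id,
            grid_row=r,
            grid_col=c,
            magnification=magnification,
            origin_x=c * BLOCK_SIZE,
            origin_y=r * BLOCK_SIZE,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def block_at_magnification(block: TileBlock, target_mag: float) -> Region:
    """Map a block's footprint to pixel coordinates at another magnification."""
    if target_mag <= 0:
        raise ValueError("target magnification must be positive")
    factor = target_mag / block.magnification
    return block.region().scaled(factor)


def read_block_image(
    slide: SlidePyramid, block: TileBlock, at_mag: float | None = None
) -> np.ndarray:
    """Raster of a block at a magnification (default: the block's own).

    When ``at_mag`` has no stored level the raster is resampled by area
    averaging from the nearest stored level with magnification >= ``at_mag``.
    """
    if at_mag is None:
        at_mag = block.magnification
    target = block_at_magnification(block, at_mag)
    src = slide.nearest_level_at_least(at_mag)
    src_region = target.scaled(src.magnification / at_mag)
    if (
        src_region.x < 0
        or src_region.y < 0
        or src_region.x2 > src.width
        or src_region.y2 > src.height
    ):
        raise ValueError(
            f"block ({block.grid_row},{block.grid_col}) maps outside level "
            f"{src.magnification}x bounds"
        )
    crop = src.image[src_region.y : src_region.y2, src_region.x : src_region.x2]
    if src.magnification == at_mag:
        return crop.copy()
    return downsample(crop, (target.width, target.height))


@dataclass
class ROIMap:
    """Final per-block states for one slide at one magnification."""

    slide_id: str
    magnification: float
    blocks: list[TileBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for b in self.blocks:
            key = (b.grid_row, b.grid_col)
            if key in seen:
                raise ValueError(f"duplicate grid cell {key}")
            seen.add(key)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.blocks:
            out[b.state.value] = out.get(b.state.value, 0) + 1
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "slide_id": self.slide_id,
            "magnification": self.magnification,
            "blocks": [
                {
                    "grid_row": b.grid_row,
                    "grid_col": b.grid_col,
                    "origin_x": b.origin_x,
                    "origin_y": b.origin_y,
                    "size": b.size,
                    "state": b.state.value,
                }
                for b in self.blocks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ROIMap":
        with open(path) as fh:
            payload = json.load(fh)
        blocks = [
            TileBlock(
                slide_id=payload["slide_id"],
                grid_row=d["grid_row"],
                grid_col=d["grid_col"],
                magnification=payload["magnification"],
                origin_x=d["origin_x"],
                origin_y=d["origin_y"],
                size=d["size"],
                state=BlockState(d["state"]),
            )
            for d in payload["blocks"]
        ]
        return cls(payload["slide_id"], payload["magnification"], blocks)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["slide_id", "row", "col", "state"])
            for b in self.blocks:
                writer.writerow([b.slide_id, b.grid_row, b.grid_col, b.state.value])


def render_roi_map(
    roi_map: ROIMap,
    slide: SlidePyramid,
    overlay_path: str | os.PathLike | None = None,
    sidecar_path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Overlay colored boxes on the lowest-magnification level.

    Green = representative, yellow = artifact, purple = poor quality.
    Optionally writes the overlay PNG and a JSON sidecar of block states.
    """
    low = slide.levels[-1]
    factor = low.magnification / roi_map.magnification
    img = Image.fromarray(low.image.copy())
    draw = ImageDraw.Draw(img)
    for b in roi_map.blocks:
        color = STATE_COLORS.get(b.state)
        if color is None:
            continue
        r = b.region().scaled(factor)
        draw.rectangle([r.x, r.y, r.x2 - 1, r.y2 - 1], outline=color, width=1)
    out = np.asarray(img)
    if overlay_path is not None:
        img.save(overlay_path)
    if sidecar_path is not None:
        roi_map.to_json(sidecar_path)
    return out


def save_pyramid(slide: SlidePyramid, directory: str | os.PathLike) -> None:
    """Write one PNG per level plus a JSON sidecar describing the levels."""
    os.makedirs(directory, exist_ok=True)
    meta = {"slide_id": slide.slide_id, "levels": []}
    for lv in slide.levels:
        name = f"level_{lv.magnification:g}x.png"
        Image.fromarray(lv.image).save(os.path.join(directory, name))
        meta["levels"].append(
            {
                "magnification": lv.magnification,
                "width": lv.width,
                "height": lv.height,
                "file": name,
            }
        )
    with open(os.path.join(directory, "pyramid.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_pyramid(directory: str | os.PathLike) -> SlidePyramid:
    with open(os.path.join(directory, "pyramid.json")) as fh:
        meta = json.load(fh)
    levels = []
    for entry in meta["levels"]:
        img = np.asarray(Image.open(os.path.join(directory, entry["file"])).convert("RGB"))
        levels.append(PyramidLevel(magnification=entry["magnification"], image=img))
    return SlidePyramid(slide_id=meta["slide_id"], levels=levels)
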