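"""Synthetic pyramidal slides with known ground truth.

Renders H&E-like texture at a base magnification and derives every lower
level by area averaging, so pyramid consistency holds by construction.
Planted content is laid out on the grid of 10x-block-sized cells:

* representative regions — dense dark ellipses ("nuclei"), 2x2 cells, mean
  luminance < 150;
* artifact regions — saturated near-black smudges, 1 cell;
* blur regions — ordinary tissue low-pass filtered in place, 1 cell;
* fat/empty cells — bright (> 200) background;
* everything else — sparse-ellipse tissue.

Only luminance/texture statistics matter downstream; no attempt is made at
stain physics or scanner noise realism.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .pyramid import (
    BLOCK_SIZE,
    PyramidLevel,
    Region,
    SlidePyramid,
    downsample,
    round_half_up,
)

__all__ = [
    "AnnotationSet",
    "GroundTruth",
    "OvercrowdedSpecError",
    "SyntheticAnnotatorSpec",
    "SyntheticSlideSpec",
    "annotations_to_csv",
    "annotations_to_geojson",
    "generate_annotations",
    "generate_signal_table",
    "generate_slide",
    "overlay_artifact",
]

# Rendering palette (RGB); luminance straddles the 200/75% screening rule.
_TISSUE_BG = (210, 180, 200)  # luminance ~191: tissue, but never "bright"
_NUCLEUS_DARK = (80, 40, 90)
_NUCLEUS_LIGHT = (120, 80, 130)
_FAT_BG = (246, 244, 246)
_ARTIFACT_DARK = (16, 10, 16)


class OvercrowdedSpecError(ValueError):
    """Planted-region demand exceeds the available slide area."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    width_px: int
    height_px: int
    base_magnification: float = 20.0
    levels: tuple[float, ...] = (20.0, 10.0, 1.0)
    n_representative_regions: int = 2
    n_artifact_regions: int = 1
    n_blur_regions: int = 1
    fat_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if any(m <= 0 or m > self.base_magnification for m in self.levels):
            raise ValueError("level magnifications must be in (0, base]")
        if min(self.n_representative_regions, self.n_artifact_regions, self.n_blur_regions) < 0:
            raise ValueError("region counts must be >= 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted layout of a synthetic slide, at base magnification."""

    representative_regions: list[Region]
    artifact_regions: list[Region]
    blur_regions: list[Region]
    empty_regions: list[Region]
    representative_mask: np.ndarray  # HxW bool at base magnification


@dataclass(frozen=True)
class SyntheticAnnotatorSpec:
    n_annotators: int = 3
    agreement_prob: float = 1.0
    false_mark_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_annotators < 1:
            raise ValueError("need at least one annotator")
        if not 0.0 <= self.agreement_prob <= 1.0:
            raise ValueError("agreement_prob must be in [0, 1]")
        if self.false_mark_rate < 0:
            raise ValueError("false_mark_rate must be >= 0")


@dataclass
class AnnotationSet:
    """One annotator's marked regions on one slide at a stated magnification."""

    annotator_id: str
    slide_id: str
    magnification: float
    regions: list[Region] = field(default_factory=list)


def _draw_ellipses(
    draw: ImageDraw.ImageDraw,
    rng: np.random.Generator,
    region: Region,
    n: int,
    radii: tuple[int, int],
    colors: Sequence[tuple[int, int, int]],
) -> None:
    for _ in range(n):
        cx = rng.integers(region.x, region.x2)
        cy = rng.integers(region.y, region.y2)
        rx = int(rng.integers(radii[0], radii[1] + 1))
        ry = int(rng.integers(radii[0], radii[1] + 1))
        color = colors[int(rng.integers(len(colors)))]
        draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=color)


def _cell_grid(spec: SyntheticSlideSpec) -> tuple[int, int, int]:
    """(cell_px, n_rows, n_cols) of 10x-block-sized cells at base mag."""
    cell = round_half_up(BLOCK_SIZE * spec.base_magnification / 10.0)
    return cell, spec.height_px // cell, spec.width_px // cell


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlidePyramid, GroundTruth]:
    """Render a deterministic synthetic pyramid and its ground truth.

    Raises :class:`OvercrowdedSpecError` when the planted regions cannot fit
    on the cell grid.
    """
    rng = np.random.default_rng(spec.seed)
    cell, n_rows, n_cols = _cell_grid(spec)
    total_cells = n_rows * n_cols

    # Representative regions occupy 2x2 cells so at least one 10x block is
    # fully covered; artifact and blur regions occupy one cell each.
    demand = 4 * spec.n_representative_regions + spec.n_artifact_regions + spec.n_blur_regions
    if demand > total_cells:
        raise OvercrowdedSpecError(
            f"overcrowded spec: {demand} cells needed, {total_cells} available"
        )

    occupancy = np.full((n_rows, n_cols), "tissue", dtype=object)

    def place(height_cells: int, width_cells: int) -> tuple[int, int]:
        free = [
            (r, c)
            for r in range(n_rows - height_cells + 1)
            for c in range(n_cols - width_cells + 1)
            if (occupancy[r : r + height_cells, c : c + width_cells] == "tissue").all()
        ]
        if not free:
            raise OvercrowdedSpecError("overcrowded spec: no free placement left")
        return free[int(rng.integers(len(free)))]

    rep_regions, artifact_regions, blur_regions = [], [], []
    for _ in range(spec.n_representative_regions):
        r, c = place(2, 2)
        occupancy[r : r + 2, c : c + 2] = "representative"
        rep_regions.append(Region(c * cell, r * cell, 2 * cell, 2 * cell))
    for kind, out, n in (
        ("artifact", artifact_regions, spec.n_artifact_regions),
        ("blur", blur_regions, spec.n_blur_regions),
    ):
        for _ in range(n):
            r, c = place(1, 1)
            occupancy[r, c] = kind
            out.append(Region(c * cell, r * cell, cell, cell))

    tissue_cells = [(r, c) for r in range(n_rows) for c in range(n_cols) if occupancy[r, c] == "tissue"]
    n_fat = round_half_up(spec.fat_fraction * len(tissue_cells))
    fat_idx = rng.choice(len(tissue_cells), size=n_fat, replace=False) if n_fat else []
    empty_regions = []
    for i in fat_idx:
        r, c = tissue_cells[int(i)]
        occupancy[r, c] = "fat"
        empty_regions.append(Region(c * cell, r * cell, cell, cell))

    # --- render base level ---
    base = np.empty((spec.height_px, spec.width_px, 3), dtype=np.uint8)
    base[:] = _FAT_BG  # margin outside the cell grid reads as empty
    img = Image.fromarray(base)
    draw = ImageDraw.Draw(img)
    scale = spec.base_magnification / 20.0  # ellipse radii sized for 20x base
    r_lo, r_hi = max(2, round_half_up(8 * scale)), max(3, round_half_up(16 * scale))
    cell_area = cell * cell
    mean_ellipse = math.pi * ((r_lo + r_hi) / 2) ** 2

    for r in range(n_rows):
        for c in range(n_cols):
            kind = occupancy[r, c]
            region = Region(c * cell, r * cell, cell, cell)
            if kind == "fat":
                continue  # background already bright
            draw.rectangle([region.x, region.y, region.x2 - 1, region.y2 - 1], fill=_TISSUE_BG)
            if kind == "representative":
                n_ell = round_half_up(0.9 * cell_area / mean_ellipse)
                _draw_ellipses(draw, rng, region, n_ell, (r_lo, r_hi), (_NUCLEUS_DARK, _NUCLEUS_LIGHT))
            else:  # tissue, blur, artifact all start from sparse tissue
                n_ell = round_half_up(0.12 * cell_area / mean_ellipse)
                _draw_ellipses(draw, rng, region, n_ell, (r_lo, r_hi), (_NUCLEUS_LIGHT,))
            if kind == "artifact":
                # saturated dark smudge covering most of the cell
                m = cell // 10
                draw.ellipse(
                    [region.x - m, region.y - m, region.x2 + m, region.y2 + m],
                    fill=_ARTIFACT_DARK,
                )

    base = np.array(img)

    # mild deterministic sensor noise
    noise = rng.integers(-5, 6, size=base.shape, dtype=np.int16)
    base = np.clip(base.astype(np.int16) + noise, 0, 255).astype(np.uint8)

    # blur regions: low-pass the rendered tissue in place
    sigma = 4.0 * spec.base_magnification / 10.0
    for region in blur_regions:
        patch = base[region.y : region.y2, region.x : region.x2].astype(np.float32)
        patch = ndimage.gaussian_filter(patch, sigma=(sigma, sigma, 0))
        base[region.y : region.y2, region.x : region.x2] = np.clip(patch, 0, 255).astype(np.uint8)

    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    for region in rep_regions:
        mask[region.y : region.y2, region.x : region.x2] = True

    levels = [PyramidLevel(magnification=spec.base_magnification, image=base)]
    for mag in sorted(set(spec.levels), reverse=True):
        if mag == spec.base_magnification:
            continue
        f = mag / spec.base_magnification
        size = (round_half_up(spec.width_px * f), round_half_up(spec.height_px * f))
        levels.append(PyramidLevel(magnification=mag, image=downsample(base, size)))

    slide = SlidePyramid(slide_id=f"synthetic-{spec.seed}", levels=levels)
    truth = GroundTruth(
        representative_regions=rep_regions,
        artifact_regions=artifact_regions,
        blur_regions=blur_regions,
        empty_regions=empty_regions,
        representative_mask=mask,
    )
    return slide, truth


def overlay_artifact(slide: SlidePyramid, region: Region) -> None:
    """Paint a saturated dark smudge over a base-level region and rebuild."""
    base = slide.base.image
    base[region.y : region.y2, region.x : region.x2] = _ARTIFACT_DARK
    slide.rebuild_from_base()


def generate_annotations(
    truth: GroundTruth,
    aspec: SyntheticAnnotatorSpec,
    slide: SlidePyramid,
) -> list[AnnotationSet]:
    """Simulate annotators with controllable agreement.

    Each annotator marks every true representative region independently with
    probability ``agreement_prob`` and adds ``Poisson(false_mark_rate)``
    spurious cell-sized regions placed outside the true regions.
    """
    rng = np.random.default_rng(aspec.seed)
    cell = round_half_up(BLOCK_SIZE * slide.base_magnification / 10.0)
    w, h = slide.base.width, slide.base.height
    sets = []
    for i in range(aspec.n_annotators):
        regions = [
            r for r in truth.representative_regions if rng.random() < aspec.agreement_prob
        ]
        n_false = int(rng.poisson(aspec.false_mark_rate))
        for _ in range(n_false):
            for _attempt in range(64):
                x = int(rng.integers(0, max(1, w - cell)))
                y = int(rng.integers(0, max(1, h - cell)))
                cand = Region(x, y, cell, cell)
                if all(cand.intersection_area(t) == 0 for t in truth.representative_regions):
                    regions.append(cand)
                    break
        sets.append(
            AnnotationSet(
                annotator_id=f"annotator_{i + 1}",
                slide_id=slide.slide_id,
                magnification=slide.base_magnification,
                regions=regions,
            )
        )
    return sets


def annotations_to_geojson(aset: AnnotationSet, path: str | os.PathLike) -> None:
    features = []
    for r in aset.regions:
        ring = [[r.x, r.y], [r.x2, r.y], [r.x2, r.y2], [r.x, r.y2], [r.x, r.y]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "annotator_id": aset.annotator_id,
                    "slide_id": aset.slide_id,
                    "magnification": aset.magnification,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def annotations_from_geojson(path: str | os.PathLike) -> AnnotationSet:
    with open(path) as fh:
        payload = json.load(fh)
    regions = []
    annotator_id = slide_id = ""
    magnification = 0.0
    for feat in payload["features"]:
        props = feat["properties"]
        annotator_id = props["annotator_id"]
        slide_id = props["slide_id"]
        magnification = props["magnification"]
        ring = feat["geometry"]["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        regions.append(Region(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys)))
    return AnnotationSet(annotator_id, slide_id, magnification, regions)


def annotations_to_csv(
    aset: AnnotationSet, path: str | os.PathLike, block_magnification: float = 10.0
) -> None:
    """Write the annotator's regions as a (slide_id, row, col) block list."""
    factor = block_magnification / aset.magnification
    rows = set()
    for r in aset.regions:
        s = r.scaled(factor)
        for row in range(s.y // BLOCK_SIZE, (s.y2 - 1) // BLOCK_SIZE + 1):
            for col in range(s.x // BLOCK_SIZE, (s.x2 - 1) // BLOCK_SIZE + 1):
                rows.add((row, col))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "row", "col"])
        for row, col in sorted(rows):
            writer.writerow([aset.slide_id, row, col])


def generate_signal_table(
    n_nuclei: int, her2_mean: float, cep17_mean: float, seed: int = 0
):
    """Per-nucleus Poisson HER2/CEP17 signal counts (see her2_grading)."""
    from .her2_grading import EmptyTableError, SignalCountTable

    if n_nuclei < 1:
        raise EmptyTableError("empty table: n_nuclei must be >= 1")
    if her2_mean <= 0 or cep17_mean <= 0:
        raise ValueError("signal means must be positive")
    rng = np.random.default_rng(seed)
    her2 = rng.poisson(her2_mean, size=n_nuclei)
    cep17 = rng.poisson(cep17_mean, size=n_nuclei)
    return SignalCountTable(
        nucleus_ids=list(range(1, n_nuclei + 1)),
        her2_counts=her2.astype(int).tolist(),
        cep17_counts=cep17.astype(int).tolist(),
    )
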