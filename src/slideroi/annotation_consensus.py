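"""Consensus labeling, balanced dataset splitting, stratified k-folds and
on-the-fly augmentation.

A block is positive only when at least ``k_required`` annotators cover at
least ``min_overlap`` of its area (the all-annotators intersection rule).
"""

from __future__ import annotations

import csv
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .pyramid import BLOCK_SIZE, Region, TileBlock, block_at_magnification, downsample
from .synthetic_slide import AnnotationSet

__all__ = [
    "LabeledTileSet",
    "SplitSpec",
    "TileEntry",
    "annotator_covers",
    "augment",
    "consensus_label",
    "split_dataset",
    "stratified_kfold",
    "stratified_kfold_indices",
]

POSITIVE = "positive"
NEGATIVE = "negative"


def _covered_area(block_region: Region, regions: Sequence[Region]) -> int:
    """Area of ``block_region`` covered by the union of ``regions``.

    Rasterized at block resolution — exact for integer-pixel rectangles.
    """
    if not regions:
        return 0
    mask = np.zeros((block_region.height, block_region.width), dtype=bool)
    for r in regions:
        x1 = max(r.x, block_region.x) - block_region.x
        y1 = max(r.y, block_region.y) - block_region.y
        x2 = min(r.x2, block_region.x2) - block_region.x
        y2 = min(r.y2, block_region.y2) - block_region.y
        if x2 > x1 and y2 > y1:
            mask[y1:y2, x1:x2] = True
    return int(mask.sum())


def annotator_covers(
    block: TileBlock, aset: AnnotationSet, min_overlap: float = 0.5
) -> bool:
    """Whether one annotator's regions cover >= ``min_overlap`` of the block."""
    region = block_at_magnification(block, aset.magnification)
    covered = _covered_area(region, aset.regions)
    return covered >= min_overlap * region.area


def consensus_label(
    block: TileBlock,
    annotations: Sequence[AnnotationSet],
    k_required: int = 3,
    min_overlap: float = 0.5,
) -> str:
    """Positive iff >= ``k_required`` annotators selected the block."""
    if k_required > len(annotations):
        raise ValueError(
            f"k_required={k_required} exceeds {len(annotations)} annotators"
        )
    n = sum(annotator_covers(block, a, min_overlap) for a in annotations)
    return POSITIVE if n >= k_required else NEGATIVE


@dataclass(frozen=True)
class TileEntry:
    slide_id: str
    grid_row: int
    grid_col: int
    magnification: float
    label: str
    image_path: str | None = None


@dataclass
class LabeledTileSet:
    entries: list[TileEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [
            (e.slide_id, e.grid_row, e.grid_col, e.magnification) for e in self.entries
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (slide, row, col, magnification) entry")
        bad = {e.label for e in self.entries} - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")

    def class_counts(self) -> dict[str, int]:
        counts = {POSITIVE: 0, NEGATIVE: 0}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | os.PathLike, split: str | None = None) -> None:
        write_header = not os.path.exists(path)
        with open(path, "a", newline="") as fh:
            writer = csv.writer(fh)
            if write_header:
                writer.writerow(
                    ["slide_id", "row", "col", "magnification", "label", "split"]
                )
            for e in self.entries:
                writer.writerow(
                    [e.slide_id, e.grid_row, e.grid_col, e.magnification, e.label, split or ""]
                )


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"split fractions sum to {total}, not 1")


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """(train, val, test) sizes for one class: eval splits ceil, train rest."""
    n_val = math.ceil(spec.val_fraction * n)
    n_test = math.ceil(spec.test_fraction * n)
    return n - n_val - n_test, n_val, n_test


def split_dataset(
    tiles: LabeledTileSet, spec: SplitSpec
) -> tuple[LabeledTileSet, LabeledTileSet, LabeledTileSet]:
    """Balanced 60/20/20 split with ceil-on-eval rounding per class.

    When slide ids are present, whole slides are assigned to the test
    partition first (held-out slides) as far as the exact per-class quotas
    allow; any shortfall is filled with random tiles and a warning is issued.
    """
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[TileEntry]] = {POSITIVE: [], NEGATIVE: []}
    for e in tiles.entries:
        by_class[e.label].append(e)
    quotas = {label: split_sizes(len(v), spec) for label, v in by_class.items()}

    test_entries: list[TileEntry] = []
    remaining: dict[str, list[TileEntry]] = {}

    slide_ids = sorted({e.slide_id for e in tiles.entries})
    if len(slide_ids) > 1:
        order = list(rng.permutation(slide_ids))
        taken: set[str] = set()
        counts = {POSITIVE: 0, NEGATIVE: 0}
        for sid in order:
            slide_counts = {
                lbl: sum(1 for e in by_class[lbl] if e.slide_id == sid)
                for lbl in counts
            }
            if all(
                counts[lbl] + slide_counts[lbl] <= quotas[lbl][2] for lbl in counts
            ):
                taken.add(sid)
                for lbl in counts:
                    counts[lbl] += slide_counts[lbl]
        for lbl, entries in by_class.items():
            in_test = [e for e in entries if e.slide_id in taken]
            rest = [e for e in entries if e.slide_id not in taken]
            shortfall = quotas[lbl][2] - len(in_test)
            if shortfall > 0:
                warnings.warn(
                    "test partition is not fully slide-disjoint: "
                    f"{shortfall} {lbl} tiles drawn from non-held-out slides"
                )
                idx = rng.permutation(len(rest))[:shortfall]
                chosen = set(int(i) for i in idx)
                in_test += [e for i, e in enumerate(rest) if i in chosen]
                rest = [e for i, e in enumerate(rest) if i not in chosen]
            test_entries += in_test
            remaining[lbl] = rest
    else:
        for lbl, entries in by_class.items():
            idx = rng.permutation(len(entries))
            n_test = quotas[lbl][2]
            test_entries += [entries[int(i)] for i in idx[:n_test]]
            remaining[lbl] = [entries[int(i)] for i in idx[n_test:]]

    train_entries: list[TileEntry] = []
    val_entries: list[TileEntry] = []
    for lbl, entries in remaining.items():
        idx = rng.permutation(len(entries))
        n_val = quotas[lbl][1]
        val_entries += [entries[int(i)] for i in idx[:n_val]]
        train_entries += [entries[int(i)] for i in idx[n_val:]]

    return (
        LabeledTileSet(train_entries),
        LabeledTileSet(val_entries),
        LabeledTileSet(test_entries),
    )


def stratified_kfold_indices(
    labels: Sequence, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint fold index arrays with per-class counts within +/-1 per fold."""
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} items")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        # round-robin deal, offset so fold sizes stay even across classes
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset = (offset + len(idx)) % k
    return [np.array(sorted(f), dtype=int) for f in folds]


def stratified_kfold(
    tiles: LabeledTileSet, k: int = 5, seed: int = 0
) -> list[LabeledTileSet]:
    labels = [e.label for e in tiles.entries]
    return [
        LabeledTileSet([tiles.entries[i] for i in idx])
        for idx in stratified_kfold_indices(labels, k, seed)
    ]


def augment(
    image: np.ndarray,
    flip: str | None = None,
    rotate: float = 0.0,
    zoom: float = 1.0,
) -> np.ndarray:
    """Flip / rotate / zoom a 224x224 raster; output stays 224x224.

    ``flip`` is "horizontal" or "vertical"; ``rotate`` is degrees (multiples
    of 90 are exact, other angles are resampled in place); ``zoom`` > 1 is a
    central crop of 1/zoom re-enlarged to full size (1.0 = identity).
    """
    out = np.asarray(image)
    if out.shape[0] != BLOCK_SIZE or out.shape[1] != BLOCK_SIZE:
        raise ValueError("augment expects a 224x224 raster")
    if flip == "horizontal":
        out = out[:, ::-1]
    elif flip == "vertical":
        out = out[::-1, :]
    elif flip is not None:
        raise ValueError(f"unknown flip {flip!r}")
    rotate = float(rotate) % 360.0
    if rotate:
        if rotate in (90.0, 180.0, 270.0):
            out = np.rot90(out, k=int(rotate // 90))
        else:
            out = ndimage.rotate(
                out, angle=rotate, reshape=False, order=1, mode="nearest"
            )
    if zoom < 1.0:
        raise ValueError("zoom must be >= 1")
    if zoom != 1.0:
        crop = max(1, round(BLOCK_SIZE / zoom))
        start = (BLOCK_SIZE - crop) // 2
        patch = out[start : start + crop, start : start + crop]
        pil = Image.fromarray(np.ascontiguousarray(patch))
        out = np.asarray(pil.resize((BLOCK_SIZE, BLOCK_SIZE), Image.Resampling.BILINEAR))
    return np.ascontiguousarray(out)


def random_augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random flip/rotate/zoom combination (the on-the-fly policy)."""
    flip = [None, "horizontal", "vertical"][int(rng.integers(3))]
    rotate = [0, 90, 180, 270][int(rng.integers(4))]
    zoom = float(rng.choice([1.0, 1.1, 1.25]))
    return augment(image, flip=flip, rotate=rotate, zoom=zoom)
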