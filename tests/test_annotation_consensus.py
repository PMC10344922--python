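import math
import warnings

import numpy as np
import pytest

from slideroi.annotation_consensus import (
    NEGATIVE,
    POSITIVE,
    LabeledTileSet,
    SplitSpec,
    TileEntry,
    augment,
    consensus_label,
    split_dataset,
    split_sizes,
    stratified_kfold,
    stratified_kfold_indices,
)
from slideroi.pyramid import BLOCK_SIZE, Region, TileBlock, tile_grid
from slideroi.synthetic_slide import AnnotationSet

from conftest import truth_positive_blocks


def _block(row=0, col=0, mag=10.0):
    return TileBlock("s", row, col, mag, col * BLOCK_SIZE, row * BLOCK_SIZE)


def _aset(regions, annotator="a", mag=10.0):
    return AnnotationSet(annotator, "s", mag, regions)


FULL = Region(0, 0, BLOCK_SIZE, BLOCK_SIZE)


class TestConsensusLabel:
    def test_all_three_positive(self):
        sets = [_aset([FULL], a) for a in "abc"]
        assert consensus_label(_block(), sets) == POSITIVE

    def test_two_of_three_negative(self):
        sets = [_aset([FULL], "a"), _aset([FULL], "b"), _aset([], "c")]
        assert consensus_label(_block(), sets) == NEGATIVE

    def test_none_negative(self):
        sets = [_aset([], a) for a in "abc"]
        assert consensus_label(_block(), sets) == NEGATIVE

    def test_k_required_exceeds_annotators(self):
        with pytest.raises(ValueError):
            consensus_label(_block(), [_aset([FULL])], k_required=3)

    def test_partial_overlap_threshold(self):
        # half the block covered: counts at min_overlap=0.5, not above
        half = Region(0, 0, BLOCK_SIZE, BLOCK_SIZE // 2)
        sets = [_aset([half], a) for a in "abc"]
        assert consensus_label(_block(), sets, min_overlap=0.5) == POSITIVE
        assert consensus_label(_block(), sets, min_overlap=0.6) == NEGATIVE

    def test_union_of_fragments_counts(self):
        # two disjoint rectangles jointly covering the block
        top = Region(0, 0, BLOCK_SIZE, BLOCK_SIZE // 2)
        bottom = Region(0, BLOCK_SIZE // 2, BLOCK_SIZE, BLOCK_SIZE // 2)
        sets = [_aset([top, bottom], a) for a in "abc"]
        assert consensus_label(_block(), sets) == POSITIVE

    def test_monotonicity_adding_marks(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            regions = [
                Region(int(rng.integers(0, 200)), int(rng.integers(0, 200)), 120, 120)
                for _ in range(2)
            ]
            sets = [_aset(list(regions), a) for a in "abc"]
            before = consensus_label(_block(), sets)
            extra = Region(0, 0, BLOCK_SIZE, BLOCK_SIZE)
            sets[0].regions.append(extra)
            after = consensus_label(_block(), sets)
            assert not (before == POSITIVE and after == NEGATIVE)

    def test_matches_ground_truth_full_agreement(self, slide, truth, full_annotations):
        positives = truth_positive_blocks(truth, slide.base_magnification, 10.0)
        for block in tile_grid(slide, 10.0):
            expected = POSITIVE if (block.grid_row, block.grid_col) in positives else NEGATIVE
            assert consensus_label(block, full_annotations) == expected


def _tile_set(n_pos, n_neg, slide_ids=("s",)):
    entries = []
    for i in range(n_pos):
        entries.append(TileEntry(slide_ids[i % len(slide_ids)], i, 0, 10.0, POSITIVE))
    for i in range(n_neg):
        entries.append(TileEntry(slide_ids[i % len(slide_ids)], i, 1, 10.0, NEGATIVE))
    return LabeledTileSet(entries)


class TestSplit:
    def test_paper_counts_7696(self):
        assert split_sizes(7696, SplitSpec()) == (4616, 1540, 1540)

    def test_exact_fractions(self):
        assert split_sizes(10, SplitSpec()) == (6, 2, 2)

    def test_ceil_rounding(self):
        assert split_sizes(7, SplitSpec()) == (3, 2, 2)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.5, val_fraction=0.2, test_fraction=0.2)

    def test_split_conservation_and_disjoint(self):
        tiles = _tile_set(40, 40)
        train, val, test = split_dataset(tiles, SplitSpec(seed=3))
        assert len(train) + len(val) + len(test) == len(tiles)
        for part, n in ((train, 24), (val, 8), (test, 8)):
            counts = part.class_counts()
            assert counts[POSITIVE] == counts[NEGATIVE] == n
        keys = lambda ts: {(e.slide_id, e.grid_row, e.grid_col) for e in ts.entries}
        assert not (keys(train) & keys(val))
        assert not (keys(train) & keys(test))
        assert not (keys(val) & keys(test))

    def test_slide_holdout_when_possible(self):
        # 5 slides x 8+8 tiles; test quota = 16 = exactly one slide
        tiles = _tile_set(40, 40, slide_ids=tuple(f"s{i}" for i in range(5)))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            train, val, test = split_dataset(tiles, SplitSpec(seed=0))
        test_slides = {e.slide_id for e in test.entries}
        other_slides = {e.slide_id for e in train.entries + val.entries}
        assert not (test_slides & other_slides)

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError):
            LabeledTileSet(
                [
                    TileEntry("s", 0, 0, 10.0, POSITIVE),
                    TileEntry("s", 0, 0, 10.0, NEGATIVE),
                ]
            )


class TestStratifiedKFold:
    def test_balanced_5000_5000(self):
        labels = [POSITIVE] * 5000 + [NEGATIVE] * 5000
        folds = stratified_kfold_indices(labels, k=5, seed=0)
        labels = np.array(labels)
        for fold in folds:
            assert len(fold) == 2000
            assert np.sum(labels[fold] == POSITIVE) == 1000
        assert sorted(np.concatenate(folds).tolist()) == list(range(10000))

    def test_singleton_folds(self):
        tiles = _tile_set(3, 3)
        folds = stratified_kfold(tiles, k=6, seed=1)
        assert [len(f) for f in folds] == [1] * 6

    def test_k2_with_3_plus_3_brute_force(self):
        labels = [POSITIVE, POSITIVE, POSITIVE, NEGATIVE, NEGATIVE, NEGATIVE]
        folds = stratified_kfold_indices(labels, k=2, seed=4)
        arr = np.array(labels)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [3, 3]
        global_ratio = 0.5
        for fold in folds:
            n_pos = int(np.sum(arr[fold] == POSITIVE))
            assert abs(n_pos - global_ratio * len(fold)) <= 1
        assert set(np.concatenate(folds).tolist()) == set(range(6))

    def test_k_greater_than_n(self):
        with pytest.raises(ValueError):
            stratified_kfold_indices([POSITIVE, NEGATIVE], k=3)

    def test_determinism(self):
        labels = [POSITIVE] * 10 + [NEGATIVE] * 10
        a = stratified_kfold_indices(labels, k=5, seed=9)
        b = stratified_kfold_indices(labels, k=5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestAugment:
    @pytest.fixture()
    def tile(self):
        rng = np.random.default_rng(0)
        return rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)

    def test_double_flip_identity(self, tile):
        out = augment(augment(tile, flip="horizontal"), flip="horizontal")
        assert np.array_equal(out, tile)

    def test_four_rotations_identity(self, tile):
        out = tile
        for _ in range(4):
            out = augment(out, rotate=90)
        assert np.array_equal(out, tile)

    def test_zoom_one_identity(self, tile):
        assert np.array_equal(augment(tile, zoom=1.0), tile)

    def test_output_shape(self, tile):
        out = augment(tile, flip="vertical", rotate=15, zoom=1.2)
        assert out.shape == tile.shape

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((100, 100, 3), dtype=np.uint8))
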