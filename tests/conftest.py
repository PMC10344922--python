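import numpy as np
import pytest

from slideroi.pyramid import BLOCK_SIZE, Region, SlidePyramid
from slideroi.synthetic_slide import (
    GroundTruth,
    SyntheticAnnotatorSpec,
    SyntheticSlideSpec,
    generate_annotations,
    generate_slide,
)


@pytest.fixture(scope="session")
def slide_spec() -> SyntheticSlideSpec:
    return SyntheticSlideSpec(
        width_px=2240,
        height_px=2240,
        base_magnification=20.0,
        levels=(20.0, 10.0, 1.0),
        n_representative_regions=2,
        n_artifact_regions=1,
        n_blur_regions=1,
        fat_fraction=0.2,
        seed=1,
    )


@pytest.fixture(scope="session")
def slide_and_truth(slide_spec):
    return generate_slide(slide_spec)


@pytest.fixture(scope="session")
def slide(slide_and_truth) -> SlidePyramid:
    return slide_and_truth[0]


@pytest.fixture(scope="session")
def truth(slide_and_truth) -> GroundTruth:
    return slide_and_truth[1]


@pytest.fixture(scope="session")
def full_annotations(slide_and_truth):
    slide_, truth_ = slide_and_truth
    aspec = SyntheticAnnotatorSpec(n_annotators=3, agreement_prob=1.0, seed=5)
    return generate_annotations(truth_, aspec, slide_)


def region_blocks(region: Region, base_mag: float, mag: float = 10.0) -> set[tuple[int, int]]:
    """Grid cells at ``mag`` fully covered by a base-magnification region."""
    f = mag / base_mag
    x1, y1 = region.x * f, region.y * f
    x2, y2 = region.x2 * f, region.y2 * f
    out = set()
    r0 = int(np.ceil(y1 / BLOCK_SIZE - 1e-9))
    c0 = int(np.ceil(x1 / BLOCK_SIZE - 1e-9))
    r, c = r0, c0
    while (r + 1) * BLOCK_SIZE <= y2 + 1e-9:
        c = c0
        while (c + 1) * BLOCK_SIZE <= x2 + 1e-9:
            out.add((r, c))
            c += 1
        r += 1
    return out


def truth_positive_blocks(truth: GroundTruth, base_mag: float, mag: float = 10.0):
    out = set()
    for region in truth.representative_regions:
        out |= region_blocks(region, base_mag, mag)
    return out


class OracleClassifier:
    """Classifies by mean luminance: planted representative tissue is dark."""

    magnification = None

    def __init__(self, threshold: float = 160.0):
        self.threshold = threshold
        self.calls = 0
        self.n_tiles_seen = 0

    def predict_proba(self, images):
        self.calls += 1
        arr = np.asarray(images, dtype=float)
        self.n_tiles_seen += len(arr)
        lum = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        return (lum.mean(axis=(1, 2)) < self.threshold).astype(float)


def luminance_tiles(n: int, seed: int, size: int = 56):
    """Linearly separable tiles: class 1 dark, class 0 bright."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    base = np.where(y == 1, rng.uniform(60, 120, n), rng.uniform(170, 230, n))
    X = base[:, None, None, None] + rng.normal(0, 8, (n, size, size, 3))
    return np.clip(X, 0, 255).astype(np.uint8), y
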