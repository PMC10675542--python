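import numpy as np
import pytest

from slideaug import ArtifactOverlay, FixtureSpec, PreviewSample
from slideaug.synthetic import generate_clean_preview, generate_synthetic_artifact


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_preview():
    """A 96x192 clean synthetic preview with tissue blobs."""
    spec = FixtureSpec(height=96, width=192, blob_radius=(10, 20), seed=42)
    return generate_clean_preview(spec)


@pytest.fixture
def felt_pen_overlay():
    return generate_synthetic_artifact("felt_pen", dims=(48, 48), seed=7)


@pytest.fixture
def bubble_overlay():
    return generate_synthetic_artifact("bubble", dims=(40, 40), seed=11)


@pytest.fixture(params=["felt_pen", "bubble", "dirt", "brand_mark"])
def any_overlay(request):
    return generate_synthetic_artifact(request.param, dims=(36, 36), seed=5)


def random_overlay(rng, category="felt_pen", dims=(24, 24)):
    """A fully random (non-structured) overlay for property tests."""
    h, w = dims
    mask = np.zeros((h, w), dtype=np.uint8)
    while not mask.any():
        mask = (rng.random((h, w)) < 0.4).astype(np.uint8) * 255
    patch = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    return ArtifactOverlay(patch=patch, mask=mask, category=category,
                           source_id="random")


def random_preview(rng, dims=(32, 32)):
    h, w = dims
    image = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    mask = (rng.random((h, w)) < 0.3).astype(np.uint8) * 255
    return PreviewSample(image=image, tissue_mask=mask, identifier="random")
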