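import numpy as np
import pytest

from stomakit.synthetic import AnnotationSet, ImageGenParams, generate_leaf_image


@pytest.fixture(scope="session")
def leaf_image():
    """One default 512x512 synthetic leaf image with ground truth."""
    params = ImageGenParams(target_density_per_mm2=75.0, seed=11)
    image, ann = generate_leaf_image(params, image_id="leaf")
    return image, ann


@pytest.fixture(scope="session")
def small_image_set():
    """A handful of small (256 px) annotated images for fast pipeline tests."""
    images, annotations = {}, {}
    rng = np.random.default_rng(7)
    for i in range(4):
        params = ImageGenParams(
            width_px=256,
            height_px=256,
            target_density_per_mm2=float(rng.uniform(60, 120)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image_id = f"small{i}"
        image, ann = generate_leaf_image(params, image_id=image_id)
        images[image_id] = image
        annotations[image_id] = ann
    return images, annotations


def make_annotation(points, image_id="t"):
    return AnnotationSet(image_id=image_id, points=np.asarray(points, dtype=float))
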