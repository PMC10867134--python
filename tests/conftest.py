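import numpy as np
import pytest

from cxrctr.annot_io import BoundingBox, ImageAnnotation
from cxrctr.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One noise-free phantom mask with its exact ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Mirror-symmetric phantom: both lungs share dome geometry."""
    spec = PhantomSpec(lung_center_cols=(150, 362), dome_apex_rows=(355, 355),
                       dome_radii=(110, 110), heart_center=(330, 256))
    return generate_phantom(spec)


def random_annotation(rng: np.random.Generator, image_id: str = "img",
                      n_boxes: int = 5, size: int = 500) -> ImageAnnotation:
    boxes = []
    for _ in range(n_boxes):
        x0, y0 = rng.integers(0, size - 60, size=2)
        w, h = rng.integers(10, 60, size=2)
        conf = float(np.round(rng.uniform(0.01, 0.99), 6)) if rng.random() < 0.5 else None
        boxes.append(BoundingBox(f"cat{rng.integers(0, 4)}", int(x0), int(y0),
                                 int(x0 + w), int(y0 + h), conf))
    return ImageAnnotation(image_id, size, size, tuple(boxes))
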