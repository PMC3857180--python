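import numpy as np
import pytest

from colonyloc.phantoms import ColonyShape, ground_truth_colony_mask
from colonyloc.segmentation import Colony, colony_from_mask


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_disc_mask(radius: int, pad: int = 5) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def make_disc_colony(radius: int, pad: int = 5) -> Colony:
    return colony_from_mask(make_disc_mask(radius, pad))


def make_ellipse_colony(a: float, b: float, rotation: float = 0.0,
                        pad: int = 6) -> tuple[Colony, ColonyShape]:
    half = int(np.ceil(a)) + pad
    size = 2 * half + 1
    shape = ColonyShape((float(half), float(half)), (a, b), rotation)
    mask = ground_truth_colony_mask(shape, (size, size))
    return colony_from_mask(mask), shape


@pytest.fixture
def disc_colony():
    return make_disc_colony(20)
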