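import numpy as np
import pytest

from ndimg import ImageFactory

BACKENDS = ("array", "cell", "list")


def make_factory(backend: str, type_tag: str = "f64", cell_dims=3) -> ImageFactory:
    return ImageFactory(backend, type_tag, cell_dims=cell_dims)


def fill_random(img, rng: np.random.Generator):
    """Fill an image with a type-appropriate pseudorandom pattern; returns
    the pattern as a dict pos -> value."""
    spec = img.type
    pattern = {}
    for pos in img.interval.positions():
        if spec.tag == "argb":
            v = int(rng.integers(0, 2**32))
        elif spec.integer:
            v = int(rng.integers(0, 2**spec.bits))
            if spec.signed:
                v -= 2 ** (spec.bits - 1)
        elif spec.complex:
            v = complex(rng.normal(), rng.normal())
        else:
            v = float(rng.uniform(-100, 100))
        img.set(pos, v)
        pattern[pos] = img.get(pos)
    return pattern


def random_image(backend, dims, type_tag, rng, cell_dims=3):
    img = make_factory(backend, type_tag, cell_dims).create(dims)
    pattern = fill_random(img, rng)
    return img, pattern


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
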