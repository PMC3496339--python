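"""Deterministic synthetic image generation.

Closed forms: impulse (single 1 among zeros), ramp ``I(p) = sum_d c_d*p_d``,
gaussian_blob ``I(p) = A*exp(-|p-c|^2 / (2*sigma^2))``, squares (nested
centered constant regions), uniform_noise (seeded uniform draws).  The same
spec and seed always produce a bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .storage import ArrayImg, ImageFactory

__all__ = ["FixtureSpec", "generate_fixture", "fixture_array"]

_KINDS = ("impulse", "ramp", "gaussian_blob", "squares", "uniform_noise")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    dims: tuple[int, ...]
    type_tag: str = "f64"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; known {_KINDS}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if any(d < 1 for d in self.dims):
            raise ValueError(f"invalid dims {self.dims}")


def fixture_array(spec: FixtureSpec) -> np.ndarray:
    """The fixture as a numpy array indexed ``arr[p0, p1, ...]``."""
    dims = spec.dims
    n = len(dims)
    p = spec.params
    if spec.kind == "impulse":
        pos = tuple(p.get("position", tuple(d // 2 for d in dims)))
        arr = np.zeros(dims)
        arr[pos] = p.get("amplitude", 1.0)
    elif spec.kind == "ramp":
        coeffs = p.get("coeffs", (1.0,) + (0.0,) * (n - 1))
        offset = p.get("offset", 0.0)
        grids = np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
        arr = np.full(dims, float(offset))
        for c, g in zip(coeffs, grids):
            arr += float(c) * g
    elif spec.kind == "gaussian_blob":
        center = p.get("center", tuple((d - 1) / 2 for d in dims))
        sigma = float(p.get("sigma", 3.0))
        amp = float(p.get("amplitude", 1.0))
        grids = np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
        r2 = sum((g - float(c)) ** 2 for g, c in zip(grids, center))
        arr = amp * np.exp(-r2 / (2.0 * sigma * sigma))
    elif spec.kind == "squares":
        levels = p.get("levels", (10, 200))
        sizes = p.get("sizes")  # side lengths of the nested squares
        if sizes is None:
            sizes = tuple(
                max(1, min(dims) // (2**k)) for k in range(1, len(levels))
            )
        arr = np.full(dims, float(levels[0]))
        for lvl, size in zip(levels[1:], sizes):
            sl = tuple(
                slice((d - min(size, d)) // 2, (d - min(size, d)) // 2 + min(size, d))
                for d in dims
            )
            arr[sl] = float(lvl)
    else:  # uniform_noise
        rng = np.random.default_rng(spec.seed)
        lo, hi = p.get("low", 0.0), p.get("high", 1.0)
        arr = rng.uniform(float(lo), float(hi), size=dims)
    return arr


def generate_fixture(spec: FixtureSpec, factory: ImageFactory | None = None):
    """Materialize the fixture into an image of the requested backend."""
    arr = fixture_array(spec)
    img = ArrayImg.from_numpy(arr, spec.type_tag)
    if factory is None or factory.backend_tag == "array":
        if factory is not None and factory.type_tag != spec.type_tag:
            raise ValueError("factory type_tag must match fixture type_tag")
        return img
    out = ImageFactory(
        factory.backend_tag, spec.type_tag, factory.cell_dims
    ).create(spec.dims)
    for pos in img.interval.positions():
        out.set(pos, img.get(pos))
    return out
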