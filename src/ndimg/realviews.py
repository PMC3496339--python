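"""Continuous-coordinate access: interpolation, n-D affine views and
rasterization back onto the integer grid.

Grid samples sit at integer coordinates (pixel-center convention).  The
nearest-neighbor interpolator rounds half toward +infinity per dimension;
the n-linear interpolator forms the convex combination of the 2**n
surrounding grid samples with weights ``prod_d (1 - |x_d - g_d|)``, which
makes it exact for images affine in the coordinates.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from .base import Accessible, Interval, RealAccessible
from .storage import ImageFactory

__all__ = [
    "AffineTransformND",
    "Interpolated",
    "interpolate",
    "AffineView",
    "affine_view",
    "rasterize",
]


class AffineTransformND:
    """Affine map x -> A @ x + t over R^n."""

    def __init__(self, matrix, translation=None):
        self.matrix = np.asarray(matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square")
        self.translation = (
            np.zeros(n) if translation is None else np.asarray(translation, dtype=float)
        )
        if self.translation.shape != (n,):
            raise ValueError("translation length must match matrix size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, n: int) -> "AffineTransformND":
        return cls(np.eye(n))

    @classmethod
    def translation_by(cls, t) -> "AffineTransformND":
        t = np.asarray(t, dtype=float)
        return cls(np.eye(len(t)), t)

    @classmethod
    def rotation2d(cls, angle: float) -> "AffineTransformND":
        c, s = math.cos(angle), math.sin(angle)
        return cls([[c, -s], [s, c]])

    @classmethod
    def scaling(cls, factors) -> "AffineTransformND":
        return cls(np.diag(np.asarray(factors, dtype=float)))

    def apply(self, x) -> np.ndarray:
        return self.matrix @ np.asarray(x, dtype=float) + self.translation

    def inverse(self) -> "AffineTransformND":
        det = float(np.linalg.det(self.matrix))
        if abs(det) < 1e-12:
            raise ValueError(
                f"affine transform is singular (determinant {det:.3e})"
            )
        inv = np.linalg.inv(self.matrix)
        return AffineTransformND(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransformND") -> "AffineTransformND":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return AffineTransformND(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransformND":
        return cls(d["matrix"], d.get("translation"))


class Interpolated(RealAccessible):
    """Continuous view of a discrete image.

    ``kind``: ``nearest`` or ``nlinear``.  At exact grid coordinates both
    return the grid sample; zero-weight corners are never touched, so an
    unextended source is safe at its own grid points.
    """

    def __init__(self, source: Accessible, kind: str = "nlinear"):
        if kind not in ("nearest", "nlinear"):
            raise ValueError(f"unknown interpolation kind {kind!r}")
        self.source = source
        self.kind = kind
        self.type = source.type
        self.n = source.ndim

    def get_real(self, x):
        src = self.source
        if self.kind == "nearest":
            # round half toward +inf, per dimension
            gp = tuple(math.floor(float(c) + 0.5) for c in x)
            return src.get(gp)
        base = tuple(math.floor(float(c)) for c in x)
        frac = tuple(float(c) - b for c, b in zip(x, base))
        total = 0.0
        for corner in itertools.product((0, 1), repeat=len(base)):
            w = 1.0
            for f, c in zip(frac, corner):
                w *= f if c else 1.0 - f
            if w == 0.0:
                continue
            gp = tuple(b + c for b, c in zip(base, corner))
            total += w * float(src.get(gp))
        return total


def interpolate(img: Accessible, kind: str = "nlinear") -> Interpolated:
    return Interpolated(img, kind)


class AffineView(RealAccessible):
    """Lazy affine-transformed continuous image:
    ``view.get_real(x) == source.get_real(T^-1(x))``."""

    def __init__(self, source: RealAccessible, transform: AffineTransformND):
        self.source = source
        self.transform = transform
        self._inverse = transform.inverse()
        self.type = source.type
        self.n = transform.n

    def get_real(self, x):
        return self.source.get_real(self._inverse.apply(x))


def affine_view(cimg: RealAccessible, transform: AffineTransformND) -> AffineView:
    return AffineView(cimg, transform)


def rasterize(
    cimg: RealAccessible,
    interval: Interval,
    factory: ImageFactory | None = None,
):
    """Evaluate a continuous image at every integer point of ``interval``."""
    if factory is None:
        factory = ImageFactory("array", "f64")
    out = factory.create(interval.dims, interval=interval)
    for p in interval.positions():
        out.set(p, cimg.get_real(p))
    return out
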