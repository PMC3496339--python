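"""Coordinate domains and the accessible (image) contract.

An *accessible* is any mapping from coordinates to values — discrete or
continuous, bounded or unbounded, backed by a buffer or procedural.  Pixel
images, lazy views and sparse-data fields all implement this surface, which
is what lets one algorithm run unchanged over all of them.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator, Sequence

from .types import TypeSpec

__all__ = ["Interval", "Accessible", "RealAccessible", "BoundsError"]


class BoundsError(IndexError):
    """Coordinate outside an accessible's interval (checked mode)."""


class Interval:
    """Integer bounding box; per-dimension min and max, both inclusive.

    Minima may be negative (translated views).  ``dims[d]`` is
    ``max[d] - min[d] + 1``.
    """

    __slots__ = ("min", "max")

    def __init__(self, min: Sequence[int], max: Sequence[int]):
        self.min = tuple(int(m) for m in min)
        self.max = tuple(int(m) for m in max)
        if len(self.min) != len(self.max):
            raise ValueError("min and max must have equal length")
        for d, (lo, hi) in enumerate(zip(self.min, self.max)):
            if lo > hi:
                raise ValueError(f"min[{d}]={lo} > max[{d}]={hi}")

    @classmethod
    def from_dims(cls, dims: Sequence[int]) -> "Interval":
        dims = tuple(int(d) for d in dims)
        if any(d < 1 for d in dims):
            raise ValueError(f"all dims must be >= 1, got {dims}")
        return cls((0,) * len(dims), tuple(d - 1 for d in dims))

    @property
    def ndim(self) -> int:
        return len(self.min)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in zip(self.min, self.max))

    @property
    def num_elements(self) -> int:
        return math.prod(self.dims)

    def contains(self, pos: Sequence[int]) -> bool:
        if len(pos) != self.ndim:
            return False
        return all(
            lo <= p <= hi for p, lo, hi in zip(pos, self.min, self.max)
        )

    def contains_interval(self, other: "Interval") -> bool:
        return all(
            slo <= olo and ohi <= shi
            for slo, olo, ohi, shi in zip(self.min, other.min, other.max, self.max)
        )

    def positions(self) -> Iterator[tuple[int, ...]]:
        """Raster-order positions: dimension 0 varies fastest."""
        ranges = [range(lo, hi + 1) for lo, hi in zip(self.min, self.max)]
        for rev in itertools.product(*reversed(ranges)):
            yield rev[::-1]

    def __eq__(self, other):
        return (
            isinstance(other, Interval)
            and self.min == other.min
            and self.max == other.max
        )

    def __hash__(self):
        return hash((self.min, self.max))

    def __repr__(self):
        return f"Interval(min={self.min}, max={self.max})"


class Accessible:
    """Discrete accessible: values at integer coordinates.

    Subclasses provide ``get``/``set``; bounded ones also an ``interval``
    and an iteration order via ``positions()``.
    """

    type: TypeSpec
    bounded: bool = True
    interval: Interval | None = None

    @property
    def ndim(self) -> int:
        if self.interval is None:
            raise AttributeError("unbounded accessible has no fixed interval")
        return self.interval.ndim

    def get(self, pos):  # pragma: no cover - interface
        raise NotImplementedError

    def set(self, pos, value):  # pragma: no cover - interface
        raise NotImplementedError

    def iteration_order(self):
        """Descriptor deciding whether two images may be co-iterated."""
        return None

    def positions(self) -> Iterator[tuple[int, ...]]:
        if not self.bounded or self.interval is None:
            raise NotImplementedError("unbounded accessible is not iterable")
        return self.interval.positions()

    def cursor(self):
        from .access import Cursor

        return Cursor(self)

    def random_access(self):
        from .access import RandomAccess

        return RandomAccess(self)

    def _check_bounds(self, pos) -> None:
        if self.interval is not None and not self.interval.contains(pos):
            raise BoundsError(f"position {tuple(pos)} outside {self.interval}")


class RealAccessible:
    """Continuous accessible: values at real-valued coordinates."""

    type: TypeSpec
    bounded: bool = False
    n: int | None = None

    def get_real(self, x):  # pragma: no cover - interface
        raise NotImplementedError
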