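"""Accessors: random access at arbitrary coordinates and exhaustive
iteration with localization.

Iteration order is a property of the backing layout (flat raster for
array/list storage, cell-by-cell for cell storage) and is exposed as a
descriptor so that two images are only ever co-iterated sample-aligned when
their orders match.
"""

from __future__ import annotations

from typing import Iterator

from .base import Accessible, BoundsError
from .storage import ArrayImg
from .types import BufferProxy, FuncProxy, ValueProxy

__all__ = ["RandomAccess", "Cursor", "iterate", "iteration_order", "random_access_get"]


class RandomAccess:
    """Positionable accessor; movement cost is independent of distance."""

    __slots__ = ("img", "pos", "_proxy")

    def __init__(self, img: Accessible):
        self.img = img
        self.pos: tuple[int, ...] | None = None
        self._proxy = FuncProxy(img)

    def set_position(self, pos) -> "RandomAccess":
        self.pos = tuple(int(p) for p in pos)
        self._proxy.point_to(self.pos)
        return self

    def move(self, offset) -> "RandomAccess":
        if self.pos is None:
            raise RuntimeError("random access has not been positioned")
        return self.set_position(tuple(p + int(o) for p, o in zip(self.pos, offset)))

    def localize(self) -> tuple[int, ...]:
        if self.pos is None:
            raise RuntimeError("random access has not been positioned")
        return tuple(self.pos)  # copy, never a live internal vector

    def get(self):
        return self.img.get(self.pos)

    def set(self, value) -> None:
        self.img.set(self.pos, value)

    def proxy(self) -> ValueProxy:
        return self._proxy


class Cursor:
    """Exhaustive iteration in the image's own order, with localization.

    One proxy instance is re-positioned for the whole run: the handle
    returned by :meth:`fwd`/:meth:`get_proxy` is invalidated by the next
    advance; ``copy()`` it to keep a value.
    """

    def __init__(self, img: Accessible):
        if not img.bounded:
            raise NotImplementedError("unbounded accessible is not iterable")
        self.img = img
        if isinstance(img, ArrayImg) and img.interval.min == (0,) * img.ndim:
            self._proxy: ValueProxy = BufferProxy(img.buffer, -1, img.type)
            self._flat = True
        else:
            self._proxy = FuncProxy(img)
            self._flat = False
        self.reset()

    def reset(self) -> None:
        self._positions: Iterator[tuple[int, ...]] = iter(self.img.positions())
        self._pos: tuple[int, ...] | None = None
        self._offset = -1
        self._remaining = self.img.interval.num_elements

    def has_next(self) -> bool:
        return self._remaining > 0

    def fwd(self) -> ValueProxy:
        self._pos = next(self._positions)
        self._remaining -= 1
        if self._flat:
            self._offset += 1
            self._proxy.point_to(self.img.buffer, self._offset)
        else:
            self._proxy.point_to(self._pos)
        return self._proxy

    def localize(self) -> tuple[int, ...]:
        if self._pos is None:
            raise RuntimeError("cursor has not been advanced")
        return tuple(self._pos)

    def get(self):
        return self._proxy.get()

    def set(self, value) -> None:
        self._proxy.set(value)

    def get_proxy(self) -> ValueProxy:
        return self._proxy

    def __iter__(self):
        while self.has_next():
            proxy = self.fwd()
            yield self.localize(), proxy


def iterate(img: Accessible):
    """Yield ``(coordinate, value_proxy)`` for every sample, in the image's
    iteration order.  The proxy is live; copy values that must survive the
    next step."""
    return iter(Cursor(img))


def iteration_order(img: Accessible):
    return img.iteration_order()


def random_access_get(img: Accessible, pos):
    """Value stored at ``pos`` (bounds-checked unless the image opts out)."""
    return img.get(tuple(int(p) for p in pos))
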