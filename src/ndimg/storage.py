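"""Pixel-image storage backends behind one factory interface.

Three layouts with identical access semantics:

* :class:`ArrayImg` — one flat primitive buffer, raster order, capped at
  2**31 elements (so a square 2-D image maxes out at 46,340 px per side);
* :class:`CellImg` — the domain tiled into an n-D grid of fixed-size cells,
  each with its own flat buffer, lifting the single-buffer cap to >= 2**62
  addressable pixels;
* :class:`ListImg` — one value object per pixel; supports arbitrary value
  types, does not scale.

The flat-buffer cap is enforced deliberately even though Python would allow
larger allocations, so capacity behaviour is reproducible; pass
``enforce_capacity=False`` to an :class:`ImageFactory` to lift it.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .base import Accessible, BoundsError, Interval
from .types import TypeSpec, get_type

__all__ = [
    "FLAT_BUFFER_LIMIT",
    "DEFAULT_CELL_DIMS",
    "linear_index",
    "linear_position",
    "max_square_side",
    "cell_capacity_pixels",
    "ArrayImg",
    "CellImg",
    "ListImg",
    "ImageFactory",
    "create_image",
    "CapacityError",
]

FLAT_BUFFER_LIMIT = 2**31
DEFAULT_CELL_DIMS = 64  # per dimension; power of two, well under the cap


class CapacityError(ValueError):
    """Image exceeds a backend's addressable-capacity limit."""


def linear_index(pos: Sequence[int], dims: Sequence[int]) -> int:
    """Raster-order flat index: dimension 0 varies fastest.

    ``pos[0] + dims[0]*(pos[1] + dims[1]*(pos[2] + ...))``; bijective onto
    ``[0, prod(dims))``.
    """
    idx = 0
    for p, d in zip(reversed(pos), reversed(dims)):
        if not 0 <= p < d:
            raise BoundsError(f"position {tuple(pos)} outside dims {tuple(dims)}")
        idx = idx * d + p
    return idx


def linear_position(index: int, dims: Sequence[int]) -> tuple[int, ...]:
    """Inverse of :func:`linear_index`."""
    if not 0 <= index < math.prod(dims):
        raise BoundsError(f"index {index} outside [0, {math.prod(dims)})")
    pos = []
    for d in dims:
        pos.append(index % d)
        index //= d
    return tuple(pos)


def max_square_side(capacity: int) -> int:
    """Largest L with L*L <= capacity (side length of the largest square
    image a flat buffer of ``capacity`` elements can hold)."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    return math.isqrt(capacity)


def cell_capacity_pixels(
    max_cell_elements: int = FLAT_BUFFER_LIMIT, index_bits: int = 63
) -> int:
    """Total addressable pixels for cell storage.

    The cell grid is itself flat-addressed (so at most 2**31 cells), each
    cell holding at most ``max_cell_elements`` samples; the total is further
    capped by what a signed 64-bit pixel index can address.
    """
    return min(max_cell_elements * FLAT_BUFFER_LIMIT, 2**index_bits)


class _PixelImg(Accessible):
    """Shared bounds/typing plumbing for the concrete backends."""

    backend = ""

    def __init__(self, interval: Interval, spec: TypeSpec, checked: bool = True):
        self.interval = interval
        self.type = spec
        self.checked = checked

    @property
    def dims(self) -> tuple[int, ...]:
        return self.interval.dims

    def _rel(self, pos) -> tuple[int, ...]:
        lo = self.interval.min
        return tuple(int(p) - m for p, m in zip(pos, lo))


class ArrayImg(_PixelImg):
    """Image over a single flat primitive buffer in raster order."""

    backend = "array"

    def __init__(self, interval, spec, buffer=None, checked=True):
        super().__init__(interval, spec, checked)
        n = interval.num_elements
        if buffer is None:
            buffer = np.zeros(n, dtype=spec.dtype)
        if len(buffer) != n:
            raise ValueError(f"buffer length {len(buffer)} != {n} elements")
        self.buffer = buffer

    def get(self, pos):
        if self.checked:
            self._check_bounds(pos)
        return self.buffer[linear_index(self._rel(pos), self.dims)].item()

    def set(self, pos, value):
        if self.checked:
            self._check_bounds(pos)
        self.buffer[linear_index(self._rel(pos), self.dims)] = self.type.cast(value)

    def iteration_order(self):
        return ("flat", self.dims)

    # -- numpy bridging (I/O, fixtures, direct-buffer benchmark variants) --
    @classmethod
    def from_numpy(cls, arr: np.ndarray, type_tag: str) -> "ArrayImg":
        """Wrap an array indexed ``arr[p0, p1, ...]`` (no copy of values:
        the flat buffer is the column-major ravel of ``arr``)."""
        spec = get_type(type_tag)
        interval = Interval.from_dims(arr.shape)
        buf = np.ascontiguousarray(arr.astype(spec.dtype, copy=False).ravel(order="F"))
        return cls(interval, spec, buffer=buf)

    def to_numpy(self) -> np.ndarray:
        return self.buffer.reshape(self.dims, order="F")


class CellImg(_PixelImg):
    """Image tiled into an n-D grid of cells, one flat buffer per cell.

    Interior cells have exactly ``cell_dims`` shape; border cells are
    truncated.  The union of cells tiles the interval exactly once.
    """

    backend = "cell"

    def __init__(self, interval, spec, cell_dims=None, checked=True):
        super().__init__(interval, spec, checked)
        dims = interval.dims
        n = interval.ndim
        if cell_dims is None:
            cell_dims = (DEFAULT_CELL_DIMS,) * n
        cell_dims = tuple(int(c) for c in cell_dims)
        if len(cell_dims) != n or any(c < 1 for c in cell_dims):
            raise ValueError(f"bad cell_dims {cell_dims} for {n}-D image")
        if math.prod(cell_dims) > FLAT_BUFFER_LIMIT:
            raise CapacityError(
                f"cell of {math.prod(cell_dims)} elements exceeds the "
                f"{FLAT_BUFFER_LIMIT} flat-buffer limit"
            )
        self.cell_dims = cell_dims
        self.grid_dims = tuple(
            -(-d // c) for d, c in zip(dims, cell_dims)
        )  # ceil division
        self.cells: list[np.ndarray] = []
        for ci in range(math.prod(self.grid_dims)):
            gpos = linear_position(ci, self.grid_dims)
            shape = self._cell_shape(gpos)
            self.cells.append(np.zeros(math.prod(shape), dtype=spec.dtype))

    def _cell_shape(self, gpos) -> tuple[int, ...]:
        return tuple(
            min(c, d - g * c)
            for g, c, d in zip(gpos, self.cell_dims, self.dims)
        )

    def _locate(self, rel) -> tuple[int, int]:
        gpos = tuple(p // c for p, c in zip(rel, self.cell_dims))
        inpos = tuple(p % c for p, c in zip(rel, self.cell_dims))
        ci = linear_index(gpos, self.grid_dims)
        return ci, linear_index(inpos, self._cell_shape(gpos))

    def get(self, pos):
        if self.checked:
            self._check_bounds(pos)
        ci, off = self._locate(self._rel(pos))
        return self.cells[ci][off].item()

    def set(self, pos, value):
        if self.checked:
            self._check_bounds(pos)
        ci, off = self._locate(self._rel(pos))
        self.cells[ci][off] = self.type.cast(value)

    def iteration_order(self):
        return ("cell", self.dims, self.cell_dims)

    def positions(self):
        """Cells in raster order of the cell grid; raster order within."""
        lo = self.interval.min
        for ci in range(len(self.cells)):
            gpos = linear_position(ci, self.grid_dims)
            shape = self._cell_shape(gpos)
            base = tuple(g * c + m for g, c, m in zip(gpos, self.cell_dims, lo))
            for off in range(math.prod(shape)):
                inpos = linear_position(off, shape)
                yield tuple(b + i for b, i in zip(base, inpos))


class ListImg(_PixelImg):
    """Image storing each pixel as an independent value object."""

    backend = "list"

    def __init__(self, interval, spec, checked=True):
        super().__init__(interval, spec, checked)
        self.samples: list = [spec.zero] * interval.num_elements

    def get(self, pos):
        if self.checked:
            self._check_bounds(pos)
        return self.samples[linear_index(self._rel(pos), self.dims)]

    def set(self, pos, value):
        if self.checked:
            self._check_bounds(pos)
        self.samples[linear_index(self._rel(pos), self.dims)] = self.type.cast(value)

    def iteration_order(self):
        return ("flat", self.dims)


class ImageFactory:
    """Creates images of one backend/type; lets generic code switch storage
    layouts without touching algorithm code."""

    def __init__(
        self,
        backend_tag: str = "array",
        type_tag: str = "f64",
        cell_dims: Sequence[int] | int | None = None,
        enforce_capacity: bool = True,
    ):
        if backend_tag not in ("array", "cell", "list"):
            raise ValueError(f"unknown backend {backend_tag!r}")
        self.backend_tag = backend_tag
        self.type_tag = type_tag
        self.cell_dims = cell_dims
        self.enforce_capacity = enforce_capacity

    def create(self, dims: Sequence[int], *, interval: Interval | None = None):
        """Zero-initialized image with min = 0 (or the given interval)."""
        if interval is None:
            interval = Interval.from_dims(dims)
        spec = get_type(self.type_tag)
        n = interval.num_elements
        if self.backend_tag == "array":
            if self.enforce_capacity and n > FLAT_BUFFER_LIMIT:
                raise CapacityError(
                    f"array backend holds at most {FLAT_BUFFER_LIMIT} elements "
                    f"({n} requested, e.g. a square 2d image of at most "
                    f"{max_square_side(FLAT_BUFFER_LIMIT)} px side length); "
                    f"use the cell backend for larger images"
                )
            return ArrayImg(interval, spec)
        if self.backend_tag == "cell":
            cd = self.cell_dims
            if isinstance(cd, int):
                cd = (cd,) * interval.ndim
            return CellImg(interval, spec, cell_dims=cd)
        return ListImg(interval, spec)

    def like(self, img, type_tag: str | None = None) -> "Accessible":
        """An empty image with ``img``'s interval, optionally retyped."""
        f = ImageFactory(
            self.backend_tag,
            type_tag or self.type_tag,
            self.cell_dims,
            self.enforce_capacity,
        )
        return f.create(img.interval.dims, interval=img.interval)


def create_image(factory: ImageFactory, dims: Sequence[int]):
    return factory.create(dims)
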