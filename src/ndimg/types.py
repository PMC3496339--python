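"""Value-type algebra: families of sample types with arithmetic contracts.

Samples live in primitive buffers (numpy arrays or plain lists); access goes
through light-weight proxies that are *re-positioned* rather than re-created
per sample.  A module-level allocation counter makes the "zero per-sample
allocations during iteration" contract testable.

Type tags
---------
``bit`` {0,1} - ``u8`` - ``i16`` - ``u16`` - ``i32`` - ``f32`` - ``f64`` -
``cf32`` (complex, stored as a complex scalar) - ``argb`` (four 8-bit
channels packed into 32 bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "TypeSpec",
    "TYPES",
    "get_type",
    "NumericValue",
    "ValueProxy",
    "BufferProxy",
    "FuncProxy",
    "Converter",
    "ConvertedImg",
    "convert_view",
    "numeric_add",
    "numeric_sub",
    "numeric_mul",
    "numeric_div",
    "argb_pack",
    "argb_unpack",
    "identity_converter",
    "clamp_round_converter",
    "invert_converter",
    "allocation_count",
]

# counts allocations of value objects (NumericValue, proxies); tests assert
# iteration does not grow this per sample
_ALLOCATIONS = 0


def allocation_count() -> int:
    return _ALLOCATIONS


def _count_allocation() -> None:
    global _ALLOCATIONS
    _ALLOCATIONS += 1


class ContractViolation(TypeError):
    """Raised when a value-type contract is broken (tag mismatch, range)."""


@dataclass(frozen=True)
class TypeSpec:
    """Storage and arithmetic semantics of one value type."""

    tag: str
    dtype: np.dtype          # buffer dtype
    bits: int                # storage bits (0 for float/complex: no wrapping)
    signed: bool
    ordered: bool            # supports < comparison
    integer: bool
    complex: bool = False
    argb: bool = False

    # -- storage semantics ------------------------------------------------
    def cast(self, v):
        """Coerce ``v`` into the type's value set (wrap-around for ints)."""
        if self.argb:
            return int(v) & 0xFFFFFFFF
        if self.complex:
            return self.dtype.type(complex(v)).item()
        if self.integer:
            v = int(v)
            if self.bits == 1:
                return v & 1
            span = 1 << self.bits
            if self.signed:
                half = span >> 1
                return (v + half) % span - half
            return v % span
        # quantize to the storage precision so every backend agrees bitwise
        return self.dtype.type(float(v)).item()

    @property
    def zero(self):
        if self.complex:
            return 0j
        if self.integer or self.argb:
            return 0
        return 0.0

    # -- arithmetic --------------------------------------------------------
    def add(self, a, b):
        if self.argb:
            return _argb_channelwise(a, b, lambda x, y: min(255, x + y))
        return self.cast(a + b)

    def sub(self, a, b):
        if self.argb:
            return _argb_channelwise(a, b, lambda x, y: max(0, x - y))
        return self.cast(a - b)

    def mul(self, a, b):
        if self.argb:
            return _argb_channelwise(a, b, lambda x, y: min(255, x * y))
        return self.cast(a * b)

    def div(self, a, b):
        if self.argb:
            raise ContractViolation("argb division is not defined")
        if self.complex:
            return complex(a) / complex(b)
        if self.integer:
            if b == 0:
                raise ZeroDivisionError(
                    f"integer division by zero for type {self.tag!r}"
                )
            return self.cast(math.trunc(a / b))
        if b == 0:  # IEEE semantics: inf/nan, not a Python exception
            if a == 0:
                return math.nan
            return math.copysign(math.inf, a) * math.copysign(1.0, b)
        return self.cast(a / b)

    def compare(self, a, b) -> int:
        if not self.ordered:
            raise ContractViolation(f"type {self.tag!r} is not ordered")
        return (a > b) - (a < b)


def _argb_channelwise(a: int, b: int, op: Callable[[int, int], int]) -> int:
    ca, cb = argb_unpack(a), argb_unpack(b)
    return argb_pack(*(op(x, y) for x, y in zip(ca, cb)))


TYPES: dict[str, TypeSpec] = {
    "bit": TypeSpec("bit", np.dtype(np.uint8), 1, False, True, True),
    "u8": TypeSpec("u8", np.dtype(np.uint8), 8, False, True, True),
    "i16": TypeSpec("i16", np.dtype(np.int16), 16, True, True, True),
    "u16": TypeSpec("u16", np.dtype(np.uint16), 16, False, True, True),
    "i32": TypeSpec("i32", np.dtype(np.int32), 32, True, True, True),
    "f32": TypeSpec("f32", np.dtype(np.float32), 0, True, True, False),
    "f64": TypeSpec("f64", np.dtype(np.float64), 0, True, True, False),
    "cf32": TypeSpec(
        "cf32", np.dtype(np.complex64), 0, True, False, False, complex=True
    ),
    "argb": TypeSpec(
        "argb", np.dtype(np.uint32), 32, False, False, True, argb=True
    ),
}


def get_type(tag: str) -> TypeSpec:
    try:
        return TYPES[tag]
    except KeyError:
        raise KeyError(
            f"unknown value type {tag!r}; known: {sorted(TYPES)}"
        ) from None


# ---------------------------------------------------------------------------
# boxed values and proxies
# ---------------------------------------------------------------------------


class NumericValue:
    """A boxed sample value carrying its type tag.

    Arithmetic follows the type's storage semantics (unsigned wrap-around,
    IEEE float behaviour, component-wise complex, channel-wise clamped ARGB).
    """

    __slots__ = ("spec", "value")

    def __init__(self, spec: TypeSpec | str, value):
        _count_allocation()
        if isinstance(spec, str):
            spec = get_type(spec)
        self.spec = spec
        self.value = spec.cast(value)

    def _check(self, other: "NumericValue") -> None:
        if not isinstance(other, NumericValue) or other.spec.tag != self.spec.tag:
            raise ContractViolation(
                f"type tag mismatch: {self.spec.tag!r} vs "
                f"{getattr(getattr(other, 'spec', None), 'tag', type(other).__name__)!r}"
            )

    def __add__(self, other):
        self._check(other)
        return NumericValue(self.spec, self.spec.add(self.value, other.value))

    def __sub__(self, other):
        self._check(other)
        return NumericValue(self.spec, self.spec.sub(self.value, other.value))

    def __mul__(self, other):
        self._check(other)
        return NumericValue(self.spec, self.spec.mul(self.value, other.value))

    def __truediv__(self, other):
        self._check(other)
        return NumericValue(self.spec, self.spec.div(self.value, other.value))

    def __lt__(self, other):
        self._check(other)
        return self.spec.compare(self.value, other.value) < 0

    def __eq__(self, other):
        if not isinstance(other, NumericValue):
            return NotImplemented
        return self.spec.tag == other.spec.tag and self.value == other.value

    def __hash__(self):
        return hash((self.spec.tag, self.value))

    def __repr__(self):
        return f"NumericValue({self.spec.tag!r}, {self.value!r})"


class ValueProxy:
    """Mutable handle onto one sample; re-positioned, never re-created.

    The handle yielded by a cursor is only valid until the next advance —
    callers who need the value afterwards must ``copy()`` it.
    """

    __slots__ = ()

    def get(self):  # pragma: no cover - interface
        raise NotImplementedError

    def set(self, value) -> None:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def spec(self) -> TypeSpec:  # pragma: no cover - interface
        raise NotImplementedError

    def copy(self) -> NumericValue:
        """Snapshot the current sample as an immutable-position boxed value."""
        return NumericValue(self.spec, self.get())


class BufferProxy(ValueProxy):
    """Proxy pointing at ``buffer[offset]`` of a flat primitive buffer."""

    __slots__ = ("buffer", "offset", "_spec")

    def __init__(self, buffer, offset: int, spec: TypeSpec):
        _count_allocation()
        self.buffer = buffer
        self.offset = offset
        self._spec = spec

    @property
    def spec(self) -> TypeSpec:
        return self._spec

    def point_to(self, buffer, offset: int) -> None:
        self.buffer = buffer
        self.offset = offset

    def get(self):
        return self.buffer[self.offset].item() if hasattr(
            self.buffer, "dtype"
        ) else self.buffer[self.offset]

    def set(self, value) -> None:
        self.buffer[self.offset] = self._spec.cast(value)


class FuncProxy(ValueProxy):
    """Proxy reading/writing through an accessible's get/set at a position.

    Used by views, whose samples have no single backing buffer slot.
    """

    __slots__ = ("img", "pos")

    def __init__(self, img, pos=None):
        _count_allocation()
        self.img = img
        self.pos = pos

    @property
    def spec(self) -> TypeSpec:
        return self.img.type

    def point_to(self, pos) -> None:
        self.pos = pos

    def get(self):
        return self.img.get(self.pos)

    def set(self, value) -> None:
        self.img.set(self.pos, value)


# ---------------------------------------------------------------------------
# free-function algebra (used by the CLI and by tests)
# ---------------------------------------------------------------------------


def numeric_add(a: NumericValue, b: NumericValue) -> NumericValue:
    return a + b


def numeric_sub(a: NumericValue, b: NumericValue) -> NumericValue:
    return a - b


def numeric_mul(a: NumericValue, b: NumericValue) -> NumericValue:
    return a * b


def numeric_div(a: NumericValue, b: NumericValue) -> NumericValue:
    return a / b


def argb_pack(a: int, r: int, g: int, b: int) -> int:
    """Pack four 8-bit channels: bits 31-24=A, 23-16=R, 15-8=G, 7-0=B."""
    for name, c in (("a", a), ("r", r), ("g", g), ("b", b)):
        if not (0 <= int(c) <= 255):
            raise ContractViolation(f"channel {name}={c} outside [0, 255]")
    return (int(a) << 24) | (int(r) << 16) | (int(g) << 8) | int(b)


def argb_unpack(packed: int) -> tuple[int, int, int, int]:
    p = int(packed)
    return ((p >> 24) & 0xFF, (p >> 16) & 0xFF, (p >> 8) & 0xFF, p & 0xFF)


# ---------------------------------------------------------------------------
# converters: lazy value transformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Converter:
    """Pure value mapping applied on access, never materialized.

    ``inverse`` enables writes through the converted view; without it the
    view is read-only.
    """

    fn: Callable
    source_tag: str
    target_tag: str
    inverse: Callable | None = None


def identity_converter(tag: str) -> Converter:
    return Converter(lambda v: v, tag, tag, inverse=lambda v: v)


def clamp_round_converter(source_tag: str, target_tag: str) -> Converter:
    """Real -> bounded integer by round-then-clamp to the target's range."""
    spec = get_type(target_tag)
    if not spec.integer or spec.argb:
        raise ValueError("clamp_round targets a bounded integer type")
    if spec.bits == 1:
        lo, hi = 0, 1
    elif spec.signed:
        hi = (1 << (spec.bits - 1)) - 1
        lo = -(1 << (spec.bits - 1))
    else:
        lo, hi = 0, (1 << spec.bits) - 1

    def fn(v):
        return min(hi, max(lo, int(round(float(v)))))

    return Converter(fn, source_tag, target_tag)


def invert_converter(tag: str) -> Converter:
    """Order-reversing map v -> max-v (ints) or -v (reals).

    Turns a max-tree of the converted image into a min-tree of the source.
    """
    spec = get_type(tag)
    if not spec.ordered:
        raise ContractViolation(f"type {tag!r} is not ordered")
    if spec.integer:
        hi = (1 << spec.bits) - 1 if not spec.signed else (1 << (spec.bits - 1)) - 1
        return Converter(lambda v: hi - v, tag, tag, inverse=lambda v: hi - v)
    return Converter(lambda v: -v, tag, tag, inverse=lambda v: -v)


class ConvertedImg:
    """Lazy value-converted accessible; no pixel data copied.

    Implements the same get/set/cursor surface as pixel images (see
    :mod:`ndimg.base`); defined here to keep the Converters framework with
    the type algebra.
    """

    bounded = True

    def __init__(self, source, conv: Converter):
        if source.type.tag != conv.source_tag:
            raise ContractViolation(
                f"converter expects source type {conv.source_tag!r}, "
                f"image has {source.type.tag!r}"
            )
        self.source = source
        self.conv = conv
        self.type = get_type(conv.target_tag)
        self.bounded = source.bounded

    @property
    def interval(self):
        return self.source.interval

    @property
    def ndim(self):
        return self.source.ndim

    def get(self, pos):
        return self.conv.fn(self.source.get(pos))

    def set(self, pos, value):
        if self.conv.inverse is None:
            raise NotImplementedError(
                "write through one-way converter is unsupported"
            )
        self.source.set(pos, self.conv.inverse(value))

    def iteration_order(self):
        return self.source.iteration_order()

    def positions(self):
        return self.source.positions()

    def cursor(self):
        from .access import Cursor

        return Cursor(self)


def convert_view(img, conv: Converter) -> ConvertedImg:
    """Address ``img`` as another value type through ``conv`` on the fly."""
    return ConvertedImg(img, conv)
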