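"""Lazy integer-coordinate views: translation, permutation, 90-degree
rotation, axis inversion, slicing, windowing and out-of-bounds extension.

A view stores a :class:`MixedTransform` mapping *view* coordinates to
*source* coordinates plus a (possibly reduced-dimensionality) interval; no
pixel data is copied, and writes through invertible views reach the source.
Consecutive transform views are fused into a single transform at
construction time (disable with :func:`set_auto_simplify` to compare
against the sequential chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .base import Accessible, BoundsError, Interval

__all__ = [
    "MixedTransform",
    "TransformView",
    "ExtensionStrategy",
    "ExtendedImg",
    "translate",
    "permute",
    "rotate90",
    "invert_axis",
    "hyperslice",
    "window",
    "zero_min",
    "extend",
    "simplify",
    "view_depth",
    "set_auto_simplify",
    "mirror_single",
    "mirror_double",
    "periodic",
    "constant",
]

_AUTO_SIMPLIFY = True


def set_auto_simplify(flag: bool) -> bool:
    """Toggle fusion of consecutive transforms; returns the previous state."""
    global _AUTO_SIMPLIFY
    prev, _AUTO_SIMPLIFY = _AUTO_SIMPLIFY, bool(flag)
    return prev


class MixedTransform:
    """Composed integer transform: permutation + axis inversion +
    translation + slicing.

    Maps an ``n_target``-D view coordinate ``p`` to an ``n_source``-D
    source coordinate ``q``: for each source dimension ``s``,
    ``q[s] = (-1 if invert[s] else 1) * p[component[s]] + translation[s]``,
    or ``q[s] = constant[s]`` when ``component[s]`` is None (sliced-away
    dimension).
    """

    __slots__ = ("n_target", "n_source", "component", "invert", "translation", "constant")

    def __init__(self, n_target, n_source, component, invert, translation, constant):
        self.n_target = int(n_target)
        self.n_source = int(n_source)
        self.component = tuple(component)
        self.invert = tuple(bool(b) for b in invert)
        self.translation = tuple(int(t) for t in translation)
        self.constant = tuple(constant)
        assert len(self.component) == self.n_source

    @classmethod
    def identity(cls, n: int) -> "MixedTransform":
        return cls(n, n, range(n), [False] * n, [0] * n, [None] * n)

    def is_identity(self) -> bool:
        return (
            self.n_target == self.n_source
            and self.component == tuple(range(self.n_source))
            and not any(self.invert)
            and not any(self.translation)
        )

    def apply(self, p: Sequence[int]) -> tuple[int, ...]:
        """View coordinate -> source coordinate."""
        q = []
        for s in range(self.n_source):
            c = self.component[s]
            if c is None:
                q.append(self.constant[s])
            else:
                x = p[c]
                q.append((-x if self.invert[s] else x) + self.translation[s])
        return tuple(q)

    def compose(self, inner: "MixedTransform") -> "MixedTransform":
        """Transform equal to ``p -> self.apply(inner? ...)``.

        ``outer.compose(inner)`` maps ``p`` through ``inner`` first is NOT
        what views need; see :func:`compose` below.
        """
        raise NotImplementedError("use the module-level compose()")

    def transform_interval(self, source_interval: Interval) -> Interval:
        """The view interval whose image under this transform is exactly
        the source interval (square, non-slicing dims only contribute)."""
        lo = [None] * self.n_target
        hi = [None] * self.n_target
        for s in range(self.n_source):
            c = self.component[s]
            if c is None:
                continue
            sign = -1 if self.invert[s] else 1
            a = sign * (source_interval.min[s] - self.translation[s])
            b = sign * (source_interval.max[s] - self.translation[s])
            lo[c], hi[c] = min(a, b), max(a, b)
        if any(v is None for v in lo):
            raise ValueError("transform leaves a view dimension unconstrained")
        return Interval(lo, hi)

    def __repr__(self):
        return (
            f"MixedTransform({self.n_target}->{self.n_source}, comp={self.component}, "
            f"inv={self.invert}, t={self.translation}, const={self.constant})"
        )


def compose(first: MixedTransform, second: MixedTransform) -> MixedTransform:
    """Single transform equal to applying ``second`` then ``first``.

    ``second`` maps outer-view coords to mid coords; ``first`` maps mid
    coords to source coords (``first.n_target == second.n_source``).
    """
    if first.n_target != second.n_source:
        raise ValueError("dimensionality mismatch in transform composition")
    component, invert, translation, constant = [], [], [], []
    for s in range(first.n_source):
        c1 = first.component[s]
        if c1 is None:
            component.append(None)
            invert.append(False)
            translation.append(0)
            constant.append(first.constant[s])
            continue
        sign1 = -1 if first.invert[s] else 1
        c2 = second.component[c1]
        if c2 is None:
            component.append(None)
            invert.append(False)
            translation.append(0)
            constant.append(sign1 * second.constant[c1] + first.translation[s])
        else:
            component.append(c2)
            invert.append(first.invert[s] != second.invert[c1])
            translation.append(
                sign1 * second.translation[c1] + first.translation[s]
            )
            constant.append(None)
    return MixedTransform(
        second.n_target, first.n_source, component, invert, translation, constant
    )


class TransformView(Accessible):
    """Lazy coordinate-transformed view; any accessible can be the source,
    so views cascade and act as both input and output."""

    def __init__(
        self,
        source: Accessible,
        transform: MixedTransform,
        interval: Interval | None,
        checked: bool = True,
    ):
        if _AUTO_SIMPLIFY and isinstance(source, TransformView):
            transform = compose(source.transform, transform)
            source = source.source
        self.source = source
        self.transform = transform
        self.interval = interval
        self.bounded = interval is not None
        self.type = source.type
        self.checked = checked

    def get(self, pos):
        if self.checked and self.bounded:
            self._check_bounds(pos)
        return self.source.get(self.transform.apply(pos))

    def set(self, pos, value):
        if self.checked and self.bounded:
            self._check_bounds(pos)
        self.source.set(self.transform.apply(pos), value)

    def iteration_order(self):
        if not self.bounded:
            return None
        return ("flat", self.interval.dims)


def view_depth(img: Accessible) -> int:
    """Number of chained transform views above the first non-view source."""
    depth = 0
    while isinstance(img, TransformView):
        depth += 1
        img = img.source
    return depth


def simplify(img: Accessible) -> Accessible:
    """Fuse a chain of integer-transform views into a single view.

    Extension or interpolation nodes are not fused through; only the
    maximal run of transform views on top is reduced.
    """
    if not isinstance(img, TransformView):
        return img
    transform = img.transform
    interval = img.interval
    source = img.source
    while isinstance(source, TransformView):
        transform = compose(source.transform, transform)
        source = source.source
    prev = set_auto_simplify(False)
    try:
        return TransformView(source, transform, interval, checked=img.checked)
    finally:
        set_auto_simplify(prev)


# ---------------------------------------------------------------------------
# view builders
# ---------------------------------------------------------------------------


def _require_ndim(img: Accessible, *dims: int) -> int:
    n = img.interval.ndim if img.interval is not None else None
    if n is None:
        raise ValueError("view builder requires a source with an interval")
    for d in dims:
        if not 0 <= d < n:
            raise ValueError(f"dimension {d} invalid for {n}-D image")
    return n


def translate(img: Accessible, offset: Sequence[int]) -> TransformView:
    """View shifted by ``offset``: ``view.get(p) == img.get(p - offset)``."""
    n = _require_ndim(img)
    offset = tuple(int(o) for o in offset)
    t = MixedTransform(
        n, n, range(n), [False] * n, [-o for o in offset], [None] * n
    )
    iv = Interval(
        [m + o for m, o in zip(img.interval.min, offset)],
        [m + o for m, o in zip(img.interval.max, offset)],
    )
    return TransformView(img, t, iv)


def permute(img: Accessible, d1: int, d2: int) -> TransformView:
    """Swap axes ``d1`` and ``d2``: ``view.get(..j..i..) == img.get(..i..j..)``."""
    n = _require_ndim(img, d1, d2)
    comp = list(range(n))
    comp[d1], comp[d2] = d2, d1
    t = MixedTransform(n, n, comp, [False] * n, [0] * n, [None] * n)
    return TransformView(img, t, t.transform_interval(img.interval))


def invert_axis(img: Accessible, d: int) -> TransformView:
    """Mirror along axis ``d`` about the origin: view coord p[d] reads -p[d]."""
    n = _require_ndim(img, d)
    inv = [False] * n
    inv[d] = True
    t = MixedTransform(n, n, range(n), inv, [0] * n, [None] * n)
    return TransformView(img, t, t.transform_interval(img.interval))


def rotate90(img: Accessible, from_d: int, to_d: int) -> TransformView:
    """Rotate the (from_d, to_d) plane by 90 degrees.

    A sample at source coordinate (f, t) lands at view coordinate
    (to_d = f, from_d = max_t - t), so four applications are the identity
    on any image whose interval starts at 0 along these axes.
    """
    n = _require_ndim(img, from_d, to_d)
    if from_d == to_d:
        raise ValueError("rotate90 requires two distinct dimensions")
    comp = list(range(n))
    inv = [False] * n
    tr = [0] * n
    # q[from_d] = p[to_d];  q[to_d] = max_to - p[from_d]
    comp[from_d] = to_d
    comp[to_d] = from_d
    inv[to_d] = True
    tr[to_d] = img.interval.max[to_d] + img.interval.min[to_d]
    t = MixedTransform(n, n, comp, inv, tr, [None] * n)
    return TransformView(img, t, t.transform_interval(img.interval))


def hyperslice(img: Accessible, fixed_dim: int, fixed_pos: int) -> TransformView:
    """(n-1)-D view at ``fixed_dim == fixed_pos``; writes propagate."""
    n = _require_ndim(img, fixed_dim)
    if not (img.interval.min[fixed_dim] <= fixed_pos <= img.interval.max[fixed_dim]):
        raise BoundsError(
            f"slice position {fixed_pos} outside "
            f"[{img.interval.min[fixed_dim]}, {img.interval.max[fixed_dim]}]"
        )
    comp, inv, tr, const = [], [], [], []
    for s in range(n):
        if s == fixed_dim:
            comp.append(None)
            const.append(int(fixed_pos))
        else:
            comp.append(s if s < fixed_dim else s - 1)
            const.append(None)
        inv.append(False)
        tr.append(0)
    t = MixedTransform(n - 1, n, comp, inv, tr, const)
    lo = [m for d, m in enumerate(img.interval.min) if d != fixed_dim]
    hi = [m for d, m in enumerate(img.interval.max) if d != fixed_dim]
    return TransformView(img, t, Interval(lo, hi))


def window(img: Accessible, interval: Interval) -> TransformView:
    """Bounded view over a sub-interval (identity coordinates)."""
    if img.interval is not None and not img.interval.contains_interval(interval):
        raise BoundsError(f"{interval} not contained in {img.interval}")
    t = MixedTransform.identity(interval.ndim)
    return TransformView(img, t, interval)


def zero_min(img: Accessible) -> TransformView:
    """Translate so the interval minimum becomes the zero vector."""
    return translate(img, [-m for m in img.interval.min])


# ---------------------------------------------------------------------------
# out-of-bounds extension
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtensionStrategy:
    """Rule generating values outside the source interval.

    ``mirror_single`` folds at the boundary without repeating the border
    sample ([a b c] -> ... b | a b c | b a ...); ``mirror_double`` repeats
    it (... a | a b c | c ...); ``periodic`` wraps modulo the side length;
    ``constant`` returns ``constant_value``.
    """

    kind: str
    constant_value: object = 0

    def __post_init__(self):
        if self.kind not in ("mirror_single", "mirror_double", "periodic", "constant"):
            raise ValueError(f"unknown extension strategy {self.kind!r}")


mirror_single = ExtensionStrategy("mirror_single")
mirror_double = ExtensionStrategy("mirror_double")
periodic = ExtensionStrategy("periodic")


def constant(value) -> ExtensionStrategy:
    return ExtensionStrategy("constant", value)


def fold_index(i: int, n: int, kind: str) -> int:
    """Fold a 0-based out-of-range index into [0, n) by the given rule."""
    if 0 <= i < n:
        return i
    if kind == "periodic":
        return i % n
    if kind == "mirror_single":
        if n == 1:
            return 0
        period = 2 * n - 2
        j = i % period
        return j if j < n else period - j
    if kind == "mirror_double":
        period = 2 * n
        j = i % period
        return j if j < n else period - 1 - j
    raise ValueError(kind)


class ExtendedImg(Accessible):
    """Unbounded view: inside the source interval it equals the source;
    outside, values are generated on demand by the strategy."""

    bounded = False

    def __init__(self, source: Accessible, strategy: ExtensionStrategy):
        if not source.bounded or source.interval is None:
            raise ValueError("extension requires a bounded source")
        self.source = source
        self.strategy = strategy
        self.type = source.type
        self.interval = None
        self.source_interval = source.interval

    @property
    def ndim(self) -> int:
        return self.source_interval.ndim

    def get(self, pos):
        iv = self.source_interval
        if self.strategy.kind == "constant":
            if not iv.contains(pos):
                return self.strategy.constant_value
            return self.source.get(tuple(pos))
        q = tuple(
            fold_index(int(p) - lo, hi - lo + 1, self.strategy.kind) + lo
            for p, lo, hi in zip(pos, iv.min, iv.max)
        )
        return self.source.get(q)

    def set(self, pos, value):
        if not self.source_interval.contains(pos):
            raise BoundsError("cannot write outside the source interval")
        self.source.set(tuple(pos), value)


def extend(img: Accessible, strategy: ExtensionStrategy = mirror_single) -> ExtendedImg:
    return ExtendedImg(img, strategy)
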