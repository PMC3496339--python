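"""Generic n-D algorithms written only against the accessor/type contracts:
separable Gaussian convolution, Sobel gradients, difference-of-Gaussians
interest points, max-tree component analysis with MSER selection, and
Perona-Malik anisotropic diffusion.

Every routine touches pixels exclusively through ``get``/``set`` on
accessibles, so it runs unchanged over any storage backend, any
dimensionality and through any view.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .base import Accessible, Interval
from .storage import ImageFactory
from .types import get_type
from .views import ExtensionStrategy, extend, mirror_double, mirror_single

__all__ = [
    "gaussian_kernel",
    "separable_convolve",
    "gaussian_convolve",
    "sobel",
    "InterestPoint",
    "dog_detect",
    "ComponentNode",
    "ComponentTree",
    "build_component_tree",
    "mser_detect",
    "anisotropic_diffusion",
]


def _out_like(img: Accessible, factory: ImageFactory | None, type_tag="f64"):
    if factory is None:
        factory = ImageFactory("array", type_tag)
    return factory.like(img, type_tag=type_tag)


# ---------------------------------------------------------------------------
# separable convolution
# ---------------------------------------------------------------------------


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Sampled Gaussian, truncated at max(2, ceil(3*sigma)) samples each
    side, normalized to sum 1.  sigma == 0 degenerates to the identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.array([1.0])
    r = max(2, math.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def separable_convolve(
    img: Accessible,
    kernels: Sequence[np.ndarray],
    extension: ExtensionStrategy = mirror_single,
    factory: ImageFactory | None = None,
):
    """One 1-D convolution pass per dimension; boundary values come from
    the extension strategy.  Output is a real-valued (f64) image on the
    same interval."""
    n = img.ndim
    if len(kernels) != n:
        raise ValueError(f"{len(kernels)} kernels for {n}-D image")
    cur = img
    interval = img.interval
    for d, kernel in enumerate(kernels):
        kernel = np.asarray(kernel, dtype=float)
        r = len(kernel) // 2
        out = _out_like(img, factory)
        if len(kernel) == 1 and kernel[0] == 1.0 and cur is img:
            src = cur  # pure copy pass
            for p in interval.positions():
                out.set(p, float(src.get(p)))
        else:
            ext = extend(cur, extension)
            for p in interval.positions():
                s = 0.0
                for i in range(len(kernel)):
                    q = list(p)
                    q[d] = p[d] + (i - r)
                    s += kernel[i] * float(ext.get(tuple(q)))
                out.set(p, s)
        cur = out
    return cur


def gaussian_convolve(
    img: Accessible,
    sigmas,
    extension: ExtensionStrategy = mirror_single,
    factory: ImageFactory | None = None,
):
    """Separable Gaussian smoothing with per-dimension sigmas (a scalar is
    broadcast to all dimensions)."""
    n = img.ndim
    if np.isscalar(sigmas):
        sigmas = [float(sigmas)] * n
    sigmas = [float(s) for s in sigmas]
    if len(sigmas) != n:
        raise ValueError(f"{len(sigmas)} sigmas for {n}-D image")
    kernels = [gaussian_kernel(s) for s in sigmas]
    return separable_convolve(img, kernels, extension, factory)


def sobel(
    img: Accessible,
    extension: ExtensionStrategy = mirror_single,
    factory: ImageFactory | None = None,
) -> list:
    """n-D separable Sobel: per gradient dimension d the derivative kernel
    [-1, 0, 1] along d and the smoothing kernel [1, 2, 1] along every other
    dimension.  Returns one gradient image per dimension."""
    n = img.ndim
    deriv = np.array([-1.0, 0.0, 1.0])
    smooth = np.array([1.0, 2.0, 1.0])
    grads = []
    for d in range(n):
        kernels = [deriv if e == d else smooth for e in range(n)]
        grads.append(separable_convolve(img, kernels, extension, factory))
    return grads


# ---------------------------------------------------------------------------
# difference-of-Gaussians interest points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterestPoint:
    coords: tuple[int, ...]
    scale: float
    response: float


def _neighbor_offsets(n: int):
    return [
        off
        for off in itertools.product((-1, 0, 1), repeat=n)
        if any(off)
    ]


def dog_detect(
    img: Accessible,
    sigma1: float,
    sigma2: float,
    threshold: float,
    extension: ExtensionStrategy = mirror_single,
) -> list[InterestPoint]:
    """Blob detection via the raw difference of Gaussians.

    Response = gaussian(sigma2) - gaussian(sigma1) (no band normalization,
    so the threshold applies to the raw difference).  Detections are the
    strict local extrema over the full 3^n - 1 neighborhood (plateaus yield
    nothing; border pixels, whose neighborhoods leave the interval, are not
    candidates), kept if |response| >= threshold and sorted by |response|
    descending.  The reported scale is sqrt(sigma1*sigma2).
    """
    if not 0 < sigma1 < sigma2:
        raise ValueError(f"need 0 < sigma1 < sigma2, got {sigma1}, {sigma2}")
    g1 = gaussian_convolve(img, sigma1, extension)
    g2 = gaussian_convolve(img, sigma2, extension)
    interval = img.interval
    response = _out_like(img, None)
    for p in interval.positions():
        response.set(p, float(g2.get(p)) - float(g1.get(p)))
    offsets = _neighbor_offsets(interval.ndim)
    scale = math.sqrt(sigma1 * sigma2)
    found = []
    for p in interval.positions():
        if any(
            not (interval.min[d] < p[d] < interval.max[d])
            for d in range(interval.ndim)
        ):
            continue
        v = response.get(p)
        if abs(v) < threshold:
            continue
        is_max = is_min = True
        for off in offsets:
            w = response.get(tuple(a + b for a, b in zip(p, off)))
            if w >= v:
                is_max = False
            if w <= v:
                is_min = False
            if not (is_max or is_min):
                break
        if is_max or is_min:
            found.append(InterestPoint(tuple(p), scale, v))
    found.sort(key=lambda ip: (-abs(ip.response), ip.coords))
    return found


# ---------------------------------------------------------------------------
# max-tree / component tree and MSER
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ComponentNode:
    """One component of the max-tree: the connected component of the
    threshold set {p : I(p) >= level} that appears at ``level``.

    ``pixels`` holds only the pixels whose gray value equals ``level``;
    the full component is the union over the node's subtree.
    """

    level: float
    pixels: list = field(default_factory=list)
    children: list = field(default_factory=list)
    parent: "ComponentNode | None" = None
    size: int = 0  # cumulative (set after construction)

    def iter_pixels(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield from node.pixels
            stack.extend(node.children)

    def pixel_set(self) -> frozenset:
        return frozenset(self.iter_pixels())


class ComponentTree:
    """Max-tree of an ordered-scalar image: components of upper threshold
    sets, nested by gray level; the root is the whole image at the global
    minimum."""

    def __init__(self, root: ComponentNode, interval: Interval):
        self.root = root
        self.interval = interval

    def nodes(self) -> list[ComponentNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaves(self) -> list[ComponentNode]:
        return [n for n in self.nodes() if not n.children]

    def components_at(self, level) -> list[frozenset]:
        """Connected components of {p : I(p) >= level}, as pixel sets."""
        comps = []

        def rec(node):
            if node.level >= level:
                comps.append(node.pixel_set())
            else:
                for c in node.children:
                    rec(c)

        rec(self.root)
        return comps


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def make(self, x):
        self.parent[x] = x

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def build_component_tree(img: Accessible, connectivity: str = "face") -> ComponentTree:
    """Max-tree construction by descending-level flooding with union-find.

    ``connectivity``: ``face`` (2n neighbors, default) or ``full``
    (3^n - 1 neighbors).
    """
    if not img.type.ordered:
        raise TypeError(
            f"component tree requires an ordered value type, got {img.type.tag!r}"
        )
    interval = img.interval
    n = interval.ndim
    if connectivity == "face":
        offsets = []
        for d in range(n):
            for s in (-1, 1):
                off = [0] * n
                off[d] = s
                offsets.append(tuple(off))
    elif connectivity == "full":
        offsets = _neighbor_offsets(n)
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")

    by_level: dict = {}
    for p in interval.positions():
        by_level.setdefault(img.get(p), []).append(p)

    uf = _UnionFind()
    node_of: dict = {}  # union-find root -> current ComponentNode
    active: set = set()
    for level in sorted(by_level, reverse=True):
        pixels = by_level[level]
        for p in pixels:
            uf.make(p)
            node_of[p] = ComponentNode(level, pixels=[p])
        for p in pixels:
            active.add(p)
        for p in pixels:
            for off in offsets:
                q = tuple(a + b for a, b in zip(p, off))
                if q not in active:
                    continue
                rp, rq = uf.find(p), uf.find(q)
                if rp == rq:
                    continue
                np_, nq = node_of[rp], node_of[rq]
                if np_.level == level and nq.level == level:
                    np_.pixels.extend(nq.pixels)
                    np_.children.extend(nq.children)
                    for c in nq.children:
                        c.parent = np_
                    keep = np_
                elif np_.level == level:
                    np_.children.append(nq)
                    nq.parent = np_
                    keep = np_
                else:  # nq.level == level (np_ belongs to a higher level)
                    nq.children.append(np_)
                    np_.parent = nq
                    keep = nq
                r = uf.union(rp, rq)
                node_of[r] = keep
    # distinct maxima still separate at the global minimum level merge into
    # a shared root only if connected; a bounded image is connected through
    # its own pixels, so all remaining roots share the lowest level
    roots = {node_of[uf.find(p)] for p in active}
    if len(roots) == 1:
        root = roots.pop()
    else:  # disconnected interval cannot happen for a box domain
        root = ComponentNode(min(r.level for r in roots))
        for r in sorted(roots, key=lambda r: r.level):
            root.children.append(r)
            r.parent = root

    def fill_sizes(node: ComponentNode) -> int:
        node.size = len(node.pixels) + sum(fill_sizes(c) for c in node.children)
        return node.size

    fill_sizes(root)
    return ComponentTree(root, interval)


def _branch_size_at(branch: list[ComponentNode], level: float) -> int:
    """Size of the component active at gray level ``level`` along a
    root-to-leaf branch.

    A node at level l with parent at level lp is the component for
    thresholds in (lp, l].  Levels at or below the root's clamp to the
    whole image; levels above the leaf's clamp to the leaf (the component
    is treated as persisting at its own extremum).
    """
    for node in branch:  # root -> leaf, levels strictly increasing
        if level <= node.level:
            return node.size
    return branch[-1].size


def mser_detect(
    tree: ComponentTree,
    delta: float,
    min_size: int = 1,
    max_size: int | None = None,
    max_rate: float = math.inf,
) -> list[ComponentNode]:
    """Maximally stable extremal regions from a max-tree.

    For node i at gray level l_i on a root-to-leaf branch, the stability
    rate is ``q(i) = (|Q_{l_i - delta}| - |Q_{l_i + delta}|) / |Q_i]``
    with sizes taken along the branch.  A node is selected iff q is a
    local minimum along every branch through it (non-strict against parent
    and children), q <= max_rate and min_size <= |Q_i| <= max_size.  The
    root (the whole image) is never a region.
    """
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    if max_size is None:
        max_size = tree.root.size

    # q per node, computed on its root path (identical along any branch
    # through the node, since the clamp only engages below the node)
    q: dict[int, float] = {}
    nodes = tree.nodes()
    for node in nodes:
        branch = []
        a = node
        while a is not None:
            branch.append(a)
            a = a.parent
        branch.reverse()
        # extend past the node with the largest-level descendant chain so
        # l_i + delta resolves on an actual branch; any branch through the
        # node gives the same sizes down to the node, and below the node we
        # take the child continuing toward the largest component
        b = node
        while b.children:
            b = sorted(b.children, key=lambda c: (-c.size, c.level, min(c.pixels)))[0]
            branch.append(b)
        lo = _branch_size_at(branch, node.level - delta)
        hi = _branch_size_at(branch, node.level + delta)
        q[id(node)] = (lo - hi) / node.size

    selected = []
    for node in nodes:
        if node is tree.root:
            continue
        if not (min_size <= node.size <= max_size):
            continue
        qi = q[id(node)]
        if qi > max_rate:
            continue
        if node.parent is not None and qi > q[id(node.parent)]:
            continue
        if any(qi > q[id(c)] for c in node.children):
            continue
        selected.append(node)
    selected.sort(key=lambda n: (-n.level, min(n.pixels)))
    return selected


# ---------------------------------------------------------------------------
# anisotropic diffusion
# ---------------------------------------------------------------------------


def anisotropic_diffusion(
    img: Accessible,
    n_iter: int,
    kappa: float,
    lam: float,
    conductance: str = "exponential",
    factory: ImageFactory | None = None,
):
    """Perona-Malik edge-preserving smoothing, explicit scheme.

    ``I <- I + lam * sum_d [g(grad+_d)*grad+_d + g(grad-_d)*grad-_d]`` with
    ``g(s) = exp(-(s/kappa)^2)`` (or the rational ``1/(1+(s/kappa)^2)``).
    The boundary uses the border-repeating mirror, so boundary flux is zero
    and the global mean is conserved.  Stability requires
    ``0 < lam <= 1/(2n)``.
    """
    n = img.ndim
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if not 0 < lam <= 1.0 / (2 * n):
        raise ValueError(
            f"lam={lam} outside stability range (0, {1.0 / (2 * n)}] for {n}-D"
        )
    if conductance == "exponential":
        g = lambda s: math.exp(-((s / kappa) ** 2))
    elif conductance == "rational":
        g = lambda s: 1.0 / (1.0 + (s / kappa) ** 2)
    else:
        raise ValueError(f"unknown conductance {conductance!r}")

    interval = img.interval
    cur = _out_like(img, factory)
    for p in interval.positions():
        cur.set(p, float(img.get(p)))
    for _ in range(n_iter):
        ext = extend(cur, mirror_double)
        nxt = _out_like(img, factory)
        for p in interval.positions():
            v = cur.get(p)
            flux = 0.0
            for d in range(n):
                for s in (-1, 1):
                    qp = list(p)
                    qp[d] += s
                    grad = float(ext.get(tuple(qp))) - v
                    flux += g(grad) * grad
            nxt.set(p, v + lam * flux)
        cur = nxt
    return cur
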