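"""Sparsely and irregularly sampled data: sample lists and a k-d tree with
nearest-neighbor, k-NN and radius search, plus nearest-neighbor
extrapolation into a continuous (Voronoi) image.

The tree is built by median split with the split dimension cycling by
depth, giving depth <= ceil(log2(N)) + 1.  All searches use the Euclidean
metric; ties are broken by insertion order, so results are deterministic
and identical to a linear scan of the sample list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .base import RealAccessible
from .types import get_type

__all__ = [
    "SamplePoint",
    "KDNode",
    "KDTree",
    "build_kdtree",
    "nn_search",
    "knn_search",
    "radius_search",
    "linear_nn_search",
    "nn_extrapolate",
    "NearestNeighborField",
    "read_points_csv",
    "write_points_csv",
]


@dataclass(frozen=True)
class SamplePoint:
    """A real-coordinate sample: position plus value."""

    coords: tuple[float, ...]
    value: object

    def __post_init__(self):
        object.__setattr__(self, "coords", tuple(float(c) for c in self.coords))
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates {self.coords}")

    @property
    def ndim(self) -> int:
        return len(self.coords)


@dataclass
class KDNode:
    index: int                     # insertion index into the point list
    split_dim: int
    left: "KDNode | None" = None
    right: "KDNode | None" = None


def _sq_dist(a: Sequence[float], b: Sequence[float]) -> float:
    return sum((x - y) ** 2 for x, y in zip(a, b))


class KDTree:
    """Balanced k-d tree over a list of :class:`SamplePoint`.

    Left subtree coordinates along the split dimension are <= the node's,
    right subtree >=; the tree contains exactly the input multiset.
    """

    def __init__(self, points: Sequence[SamplePoint]):
        points = list(points)
        if not points:
            raise ValueError("k-d tree requires at least one point")
        n = points[0].ndim
        if any(p.ndim != n for p in points):
            raise ValueError("mixed dimensionality in point list")
        self.points = points
        self.ndim = n
        self.root = self._build(list(range(len(points))), 0)

    def _build(self, idx: list[int], depth: int) -> KDNode | None:
        if not idx:
            return None
        d = depth % self.ndim
        idx.sort(key=lambda i: (self.points[i].coords[d], i))
        mid = len(idx) // 2
        node = KDNode(idx[mid], d)
        node.left = self._build(idx[:mid], depth + 1)
        node.right = self._build(idx[mid + 1:], depth + 1)
        return node

    # -- structure ---------------------------------------------------------
    def depth(self) -> int:
        def rec(node):
            if node is None:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    def traverse(self) -> list[SamplePoint]:
        """In-order traversal; contains every input point exactly once."""
        out: list[SamplePoint] = []

        def rec(node):
            if node is None:
                return
            rec(node.left)
            out.append(self.points[node.index])
            rec(node.right)

        rec(self.root)
        return out

    def _check_query(self, q) -> tuple[float, ...]:
        q = tuple(float(c) for c in q)
        if len(q) != self.ndim:
            raise ValueError(
                f"query dimensionality {len(q)} != tree dimensionality {self.ndim}"
            )
        if not all(math.isfinite(c) for c in q):
            raise ValueError(f"non-finite query {q}")
        return q

    # -- searches ----------------------------------------------------------
    def nn(self, q) -> SamplePoint:
        q = self._check_query(q)
        best = [math.inf, -1]  # squared distance, insertion index

        def rec(node):
            if node is None:
                return
            c = self.points[node.index].coords
            d2 = _sq_dist(c, q)
            if d2 < best[0] or (d2 == best[0] and node.index < best[1]):
                best[0], best[1] = d2, node.index
            diff = q[node.split_dim] - c[node.split_dim]
            near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
            rec(near)
            if diff * diff <= best[0]:
                rec(far)

        rec(self.root)
        return self.points[best[1]]

    def knn(self, q, k: int) -> list[SamplePoint]:
        q = self._check_query(q)
        if not 1 <= k <= len(self.points):
            raise ValueError(f"k={k} outside [1, {len(self.points)}]")
        # kept sorted by (squared distance, insertion index), worst last
        best: list[tuple[float, int]] = []

        def worst() -> tuple[float, int]:
            return best[-1] if len(best) == k else (math.inf, -1)

        def rec(node):
            if node is None:
                return
            c = self.points[node.index].coords
            cand = (_sq_dist(c, q), node.index)
            if len(best) < k or cand < worst():
                lo, hi = 0, len(best)
                while lo < hi:
                    mid = (lo + hi) // 2
                    if best[mid] < cand:
                        lo = mid + 1
                    else:
                        hi = mid
                best.insert(lo, cand)
                if len(best) > k:
                    best.pop()
            diff = q[node.split_dim] - c[node.split_dim]
            near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
            rec(near)
            if len(best) < k or diff * diff <= worst()[0]:
                rec(far)

        rec(self.root)
        return [self.points[i] for _, i in best]

    def radius(self, q, r: float) -> list[SamplePoint]:
        q = self._check_query(q)
        if r < 0:
            raise ValueError("radius must be >= 0")
        r2 = r * r
        hits: list[tuple[float, int]] = []

        def rec(node):
            if node is None:
                return
            c = self.points[node.index].coords
            d2 = _sq_dist(c, q)
            if d2 <= r2:
                hits.append((d2, node.index))
            diff = q[node.split_dim] - c[node.split_dim]
            near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
            rec(near)
            if diff * diff <= r2:
                rec(far)

        rec(self.root)
        hits.sort()
        return [self.points[i] for _, i in hits]


# -- module-level operation surface ----------------------------------------


def build_kdtree(points: Sequence[SamplePoint]) -> KDTree:
    return KDTree(points)


def nn_search(tree: KDTree, q) -> SamplePoint:
    return tree.nn(q)


def knn_search(tree: KDTree, q, k: int) -> list[SamplePoint]:
    return tree.knn(q, k)


def radius_search(tree: KDTree, q, r: float) -> list[SamplePoint]:
    return tree.radius(q, r)


def linear_nn_search(points: Sequence[SamplePoint], q) -> SamplePoint:
    """Sample-list linear scan; the reference the tree must agree with."""
    q = tuple(float(c) for c in q)
    best_d, best_i = math.inf, -1
    for i, p in enumerate(points):
        d2 = _sq_dist(p.coords, q)
        if d2 < best_d:
            best_d, best_i = d2, i
    return points[best_i]


class NearestNeighborField(RealAccessible):
    """Piecewise-constant (Voronoi) continuous image over all of R^n:
    the value at x is the value of the nearest sample point."""

    def __init__(self, points: Sequence[SamplePoint], type_tag: str = "f64"):
        self.tree = KDTree(points)
        self.n = self.tree.ndim
        self.type = get_type(type_tag)

    def get_real(self, x):
        return self.tree.nn(x).value


def nn_extrapolate(
    points: Sequence[SamplePoint], type_tag: str = "f64"
) -> NearestNeighborField:
    return NearestNeighborField(points, type_tag)


# -- CSV interchange --------------------------------------------------------


def write_points_csv(points: Sequence[SamplePoint], path) -> None:
    """One row per point: coordinate columns x0..x{n-1}, then value."""
    n = points[0].ndim
    cols = {f"x{d}": [p.coords[d] for p in points] for d in range(n)}
    cols["value"] = [p.value for p in points]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_points_csv(path) -> list[SamplePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    coord_cols = [c for c in df.columns if c.startswith("x")]
    if "value" not in df.columns or not coord_cols:
        raise ValueError(
            f"{path}: expected header x0,...,x{{n-1}},value, got {list(df.columns)}"
        )
    coord_cols.sort(key=lambda c: int(c[1:]))
    return [
        SamplePoint(tuple(row[c] for c in coord_cols), row["value"])
        for _, row in df.iterrows()
    ]
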