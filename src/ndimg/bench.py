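"""Benchmark harness: generic accessor code versus direct-buffer code.

Each task exists in two variants that are verified to produce identical
numbers before any timing happens; the harness then reports median-of-reps
wall times and their ratio.  Ratios are reported, never asserted — they are
a property of the host, not of the library.

Task stand-ins: ``pixel_sum`` (reduce), ``per_pixel_op`` (multiply-add into
an output image) and ``nd_inner_loop`` (box-neighborhood mean, whose inner
loop runs over the a-priori-unknown number of dimensions).
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage

from .access import Cursor
from .fixtures import FixtureSpec, generate_fixture
from .storage import ArrayImg
from .views import extend, mirror_double

__all__ = ["BenchResult", "run_benchmark", "TASKS"]

TASKS = ("pixel_sum", "per_pixel_op", "nd_inner_loop")


@dataclass
class BenchResult:
    task: str
    variant: str
    dims: tuple[int, ...]
    reps: int
    median_time: float
    ratio_vs_direct: float | None = None
    machine: str = field(default_factory=platform.platform)


class VariantMismatch(AssertionError):
    """Generic and direct variants disagree — benchmark aborted."""


def _generic_pixel_sum(img) -> float:
    total = 0.0
    cur = Cursor(img)
    while cur.has_next():
        cur.fwd()
        total += cur.get()
    return total


def _generic_per_pixel_op(img, a=3.0, b=1.0) -> np.ndarray:
    out = np.empty(img.interval.num_elements)
    i = 0
    cur = Cursor(img)
    while cur.has_next():
        cur.fwd()
        out[i] = a * cur.get() + b
        i += 1
    return out


def _generic_box_mean(img) -> np.ndarray:
    """Radius-1 box mean; the inner loop walks 3^n offsets for unknown n."""
    n = img.ndim
    offsets = [
        tuple(o)
        for o in np.stack(
            np.meshgrid(*([[-1, 0, 1]] * n), indexing="ij"), axis=-1
        ).reshape(-1, n)
    ]
    ext = extend(img, mirror_double)
    inv = 1.0 / len(offsets)
    out = np.empty(img.interval.num_elements)
    for i, p in enumerate(img.positions()):
        s = 0.0
        for off in offsets:
            s += ext.get(tuple(a + b for a, b in zip(p, off)))
        out[i] = s * inv
    return out


def _direct(task: str, arr: np.ndarray):
    if task == "pixel_sum":
        return float(arr.sum(dtype=np.float64))
    if task == "per_pixel_op":
        return (3.0 * arr.astype(np.float64) + 1.0).ravel(order="F")
    # scipy 'reflect' mode is the border-repeating mirror
    return scipy.ndimage.uniform_filter(
        arr.astype(np.float64), size=3, mode="reflect"
    ).ravel(order="F")


def _generic(task: str, img):
    if task == "pixel_sum":
        return _generic_pixel_sum(img)
    if task == "per_pixel_op":
        return _generic_per_pixel_op(img)
    return _generic_box_mean(img)


def run_benchmark(
    tasks: Sequence[str] = TASKS,
    dims_list: Sequence[Sequence[int]] = ((64, 64),),
    reps: int = 3,
    seed: int = 42,
) -> list[BenchResult]:
    results = []
    for dims in dims_list:
        dims = tuple(int(d) for d in dims)
        img = generate_fixture(
            FixtureSpec("uniform_noise", dims, "f64", seed, {"low": 0.0, "high": 255.0})
        )
        arr = img.to_numpy()
        for task in tasks:
            if task not in TASKS:
                raise ValueError(f"unknown benchmark task {task!r}")
            g, d = _generic(task, img), _direct(task, arr)
            if not np.allclose(np.asarray(g), np.asarray(d), rtol=1e-10, atol=1e-8):
                raise VariantMismatch(
                    f"{task} on {dims}: generic and direct variants disagree"
                )
            times = {"generic_iterate": [], "direct_buffer": []}
            for _ in range(max(1, reps)):
                t0 = time.perf_counter()
                _generic(task, img)
                times["generic_iterate"].append(time.perf_counter() - t0)
                t0 = time.perf_counter()
                _direct(task, arr)
                times["direct_buffer"].append(time.perf_counter() - t0)
            med = {k: float(np.median(v)) for k, v in times.items()}
            ratio = med["generic_iterate"] / max(med["direct_buffer"], 1e-12)
            for variant in ("generic_iterate", "direct_buffer"):
                results.append(
                    BenchResult(
                        task,
                        variant,
                        dims,
                        max(1, reps),
                        med[variant],
                        ratio if variant == "generic_iterate" else None,
                    )
                )
    return results
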