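"""End-to-end demo pipeline on a synthetic source image.

Three panels, mirroring the library's capability showcase:

* panel a — the source virtually extended by mirroring, with four
  algorithms applied to sub-image views (anisotropic diffusion, MSER,
  Sobel, Gaussian convolution);
* panel b — 2,000 points randomly sampled from a window of the source,
  indexed in a k-d tree and nearest-neighbor-extrapolated back into a
  continuous image, then rasterized;
* panel c — an n-linear interpolated, affine-transformed (rotated) view of
  a tilted window, rasterized.

Everything is a pure function of the seed: re-running writes bit-identical
outputs.  Parameters are illustrative defaults, recorded in params.json.
"""

from __future__ import annotations

import json
import math
import os

import numpy as np

from .algorithms import (
    anisotropic_diffusion,
    build_component_tree,
    gaussian_convolve,
    mser_detect,
    sobel,
)
from .base import Interval
from .fixtures import FixtureSpec, generate_fixture
from .io import write_image
from .realviews import AffineTransformND, affine_view, interpolate, rasterize
from .sparse import SamplePoint, nn_extrapolate, write_points_csv
from .storage import ArrayImg, ImageFactory
from .types import clamp_round_converter, convert_view
from .views import extend, mirror_single, window

__all__ = ["demo_figure1", "DEFAULT_N_POINTS"]

DEFAULT_N_POINTS = 2000


def _to_u8(img) -> ArrayImg:
    lo = min(img.get(p) for p in img.interval.positions())
    hi = max(img.get(p) for p in img.interval.positions())
    span = (hi - lo) or 1.0
    out = ImageFactory("array", "u8").create(img.interval.dims, interval=img.interval)
    for p in img.interval.positions():
        out.set(p, int(round(255.0 * (img.get(p) - lo) / span)))
    return out


def _source_image(size: int, seed: int) -> ArrayImg:
    """Blobs on a noisy background: enough structure for every panel."""
    rng = np.random.default_rng(seed)
    base = generate_fixture(
        FixtureSpec(
            "uniform_noise", (size, size), "f64", seed, {"low": 0.0, "high": 40.0}
        )
    ).to_numpy()
    for _ in range(6):
        c = rng.uniform(0.2 * size, 0.8 * size, size=2)
        s = rng.uniform(0.03 * size, 0.08 * size)
        amp = rng.uniform(120.0, 215.0)
        gx, gy = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        base += amp * np.exp(-((gx - c[0]) ** 2 + (gy - c[1]) ** 2) / (2 * s * s))
    return ArrayImg.from_numpy(np.clip(base, 0, 255), "f64")


def demo_figure1(seed: int = 42, out_dir: str = "demo_out", size: int = 64) -> dict:
    """Run all three panels; returns a manifest of written files."""
    os.makedirs(out_dir, exist_ok=True)
    src = _source_image(size, seed)
    files: dict[str, str] = {}
    params = {"seed": seed, "size": size, "n_points": DEFAULT_N_POINTS}

    # panel a: mirrored extension + four algorithms on sub-windows
    q = size // 2
    quads = [
        Interval((0, 0), (q - 1, q - 1)),
        Interval((q, 0), (size - 1, q - 1)),
        Interval((0, q), (q - 1, size - 1)),
        Interval((q, q), (size - 1, size - 1)),
    ]
    sub = [window(src, iv) for iv in quads]
    diffused = anisotropic_diffusion(sub[0], n_iter=5, kappa=20.0, lam=0.2)
    u8 = convert_view(sub[1], clamp_round_converter("f64", "u8"))
    u8_copy = ImageFactory("array", "u8").create(
        u8.interval.dims, interval=u8.interval
    )
    for p in u8.interval.positions():
        u8_copy.set(p, u8.get(p))
    tree = build_component_tree(u8_copy)
    regions = mser_detect(tree, delta=10, min_size=8, max_size=q * q // 2, max_rate=2.0)
    labels = ImageFactory("array", "u16").create(u8.interval.dims, interval=u8.interval)
    for i, node in enumerate(regions, start=1):
        for p in node.iter_pixels():
            labels.set(p, i)
    grads = sobel(sub[2])
    grad_mag = ImageFactory("array", "f64").create(
        sub[2].interval.dims, interval=sub[2].interval
    )
    for p in sub[2].interval.positions():
        grad_mag.set(p, math.hypot(grads[0].get(p), grads[1].get(p)))
    smoothed = gaussian_convolve(sub[3], 2.0)

    for name, img in (
        ("panel_a_diffusion", diffused),
        ("panel_a_mser_labels", labels),
        ("panel_a_sobel", grad_mag),
        ("panel_a_gauss", smoothed),
    ):
        path = os.path.join(out_dir, f"{name}.tif")
        write_image(_to_u8(img) if img.type.tag == "f64" else img, path)
        files[name] = path
    params["panel_a"] = {
        "diffusion": {"n_iter": 5, "kappa": 20.0, "lam": 0.2},
        "mser": {"delta": 10, "min_size": 8, "max_size": q * q // 2, "max_rate": 2.0},
        "gauss_sigma": 2.0,
        "mser_regions": len(regions),
    }

    # panel b: sample 2,000 random points, k-d tree NN extrapolation
    rng = np.random.default_rng(seed + 1)
    ext = extend(src, mirror_single)
    pts = []
    for _ in range(DEFAULT_N_POINTS):
        x = rng.uniform(0, size - 1, size=2)
        val = src.get(tuple(int(round(c)) for c in x))
        pts.append(SamplePoint(tuple(x), val))
    csv_path = os.path.join(out_dir, "panel_b_points.csv")
    write_points_csv(pts, csv_path)
    field = nn_extrapolate(pts)
    panel_b = rasterize(field, Interval.from_dims((size, size)))
    b_path = os.path.join(out_dir, "panel_b_extrapolated.tif")
    write_image(_to_u8(panel_b), b_path)
    files["panel_b_points"] = csv_path
    files["panel_b_extrapolated"] = b_path

    # panel c: interpolated + affine transformed (tilted) window
    angle = math.radians(30.0)
    center = np.array([size / 2, size / 2])
    rot = AffineTransformND.rotation2d(angle)
    about_center = AffineTransformND.translation_by(center).compose(
        rot.compose(AffineTransformND.translation_by(-center))
    )
    continuous = interpolate(ext, "nlinear")
    tilted = affine_view(continuous, about_center)
    c_lo, c_hi = size // 4, 3 * size // 4 - 1
    panel_c = rasterize(tilted, Interval((c_lo, c_lo), (c_hi, c_hi)))
    c_path = os.path.join(out_dir, "panel_c_affine.tif")
    write_image(_to_u8(panel_c), c_path)
    files["panel_c_affine"] = c_path
    params["panel_c"] = {"angle_deg": 30.0, "interpolation": "nlinear"}

    params_path = os.path.join(out_dir, "params.json")
    with open(params_path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
    files["params"] = params_path
    return files
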