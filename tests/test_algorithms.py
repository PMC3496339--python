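"""Generic algorithms against brute-force and scipy oracles, plus the
central genericity property: identical results across backends and views."""

import itertools
import math

import numpy as np
import pytest
import scipy.ndimage

import ndimg as ni
from ndimg.algorithms import gaussian_kernel
from ndimg.fixtures import FixtureSpec, generate_fixture
from conftest import BACKENDS, make_factory


def dense_convolve(arr, kernels):
    """Brute-force n-D convolution with the separable product kernel,
    mirror_single boundary (scipy 'mirror' mode)."""
    full = kernels[0]
    for k in kernels[1:]:
        full = np.multiply.outer(full, k)
    return scipy.ndimage.correlate(arr, full, mode="mirror")


# --- Gaussian --------------------------------------------------------------


def test_gaussian_kernel_mass_is_one():
    for sigma in (0.3, 0.8, 1.5, 2.0, 4.5):
        assert abs(gaussian_kernel(sigma).sum() - 1.0) < 1e-12


def test_gaussian_kernel_truncation_radius():
    assert len(gaussian_kernel(0.1)) == 5          # max(2, ceil(0.3)) = 2
    assert len(gaussian_kernel(2.0)) == 13         # ceil(6) = 6 each side


def test_gaussian_sigma_zero_is_identity(rng):
    arr = rng.uniform(0, 1, (6, 6))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    out = ni.gaussian_convolve(img, (0.0, 0.0))
    assert np.allclose(out.to_numpy(), arr)


def test_gaussian_rejects_negative_sigma(rng):
    with pytest.raises(ValueError):
        ni.gaussian_convolve(ni.ArrayImg.from_numpy(np.zeros((3, 3)), "f64"), -1.0)


def test_gaussian_constant_image_unchanged():
    img = ni.ArrayImg.from_numpy(np.full((8, 8), 3.5), "f64")
    out = ni.gaussian_convolve(img, 1.5)
    assert np.allclose(out.to_numpy(), 3.5, atol=1e-6)


def test_gaussian_impulse_reproduces_product_kernel():
    img = generate_fixture(FixtureSpec("impulse", (21, 21)))
    out = ni.gaussian_convolve(img, 2.0).to_numpy()
    k = gaussian_kernel(2.0)
    expected = np.outer(k, k)
    center = 10
    r = len(k) // 2
    got = out[center - r : center + r + 1, center - r : center + r + 1]
    assert np.max(np.abs(got - expected)) < 1e-6


@pytest.mark.parametrize("dims,sigmas", [((9, 9), (1.5, 0.8)), ((7, 7, 5), (1.0, 0.6, 0.8))])
def test_separable_equals_dense_convolution(dims, sigmas, rng):
    arr = rng.uniform(0, 1, dims)
    img = ni.ArrayImg.from_numpy(arr, "f64")
    mine = ni.gaussian_convolve(img, sigmas).to_numpy()
    ref = dense_convolve(arr, [gaussian_kernel(s) for s in sigmas])
    assert np.max(np.abs(mine - ref)) < 1e-6


# --- Sobel -----------------------------------------------------------------


def test_sobel_constant_image_zero_gradient():
    img = ni.ArrayImg.from_numpy(np.full((7, 7), 9.0), "f64")
    for g in ni.sobel(img):
        assert np.allclose(g.to_numpy(), 0.0, atol=1e-12)


def test_sobel_ramp_interior_response():
    # I(x, y) = x: d/dx kernel gain 2 times smoothing mass 4 -> 8
    arr = np.add.outer(np.arange(8.0), np.zeros(8))
    gx, gy = ni.sobel(ni.ArrayImg.from_numpy(arr, "f64"))
    assert np.allclose(gx.to_numpy()[1:-1, 1:-1], 8.0)
    assert np.allclose(gy.to_numpy()[1:-1, 1:-1], 0.0)


def test_sobel_matches_dense_3x3_kernels(rng):
    arr = rng.uniform(0, 1, (8, 8))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    grads = ni.sobel(img)
    deriv, smooth = np.array([-1.0, 0.0, 1.0]), np.array([1.0, 2.0, 1.0])
    for d, g in enumerate(grads):
        kernels = [deriv if e == d else smooth for e in range(2)]
        ref = dense_convolve(arr, kernels)
        assert np.max(np.abs(g.to_numpy() - ref)) < 1e-6


# --- DoG -------------------------------------------------------------------


def test_dog_constant_image_no_detections():
    img = ni.ArrayImg.from_numpy(np.full((12, 12), 5.0), "f64")
    assert ni.dog_detect(img, 2.0, 4.0, 1e-9) == []


def test_dog_rejects_bad_sigma_order(rng):
    img = ni.ArrayImg.from_numpy(np.zeros((5, 5)), "f64")
    with pytest.raises(ValueError):
        ni.dog_detect(img, 4.0, 2.0, 1.0)


def test_dog_single_blob_detected_at_center():
    img = generate_fixture(
        FixtureSpec(
            "gaussian_blob", (25, 25), params={"sigma": 3.0, "amplitude": 100.0}
        )
    )
    dets = ni.dog_detect(img, 2.0, 4.0, 5.0)
    assert len(dets) == 1
    assert dets[0].coords == (12, 12)


def test_dog_matches_brute_force_extremum_scan(rng):
    arr = rng.uniform(0, 1, (14, 14))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    s1, s2, thr = 1.0, 2.0, 0.01
    dets = ni.dog_detect(img, s1, s2, thr)
    resp = ni.gaussian_convolve(img, s2).to_numpy() - ni.gaussian_convolve(
        img, s1
    ).to_numpy()
    expected = set()
    for x in range(1, 13):
        for y in range(1, 13):
            v = resp[x, y]
            neigh = [
                resp[x + dx, y + dy]
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)
            ]
            if abs(v) >= thr and (all(v > w for w in neigh) or all(v < w for w in neigh)):
                expected.add((x, y))
    assert {d.coords for d in dets} == expected
    mags = [abs(d.response) for d in dets]
    assert mags == sorted(mags, reverse=True)


# --- component tree and MSER ----------------------------------------------


def flood_components(arr, level):
    """Connected components of {p : arr >= level} (face connectivity)."""
    mask = arr >= level
    labels, n = scipy.ndimage.label(mask)
    return {
        frozenset(zip(*np.nonzero(labels == i))) for i in range(1, n + 1)
    }


def test_component_tree_constant_image_single_root():
    img = ni.ArrayImg.from_numpy(np.full((4, 4), 3.0), "u8")
    t = ni.build_component_tree(img)
    assert t.root.level == 3
    assert t.root.size == 16
    assert t.root.children == []


def test_component_tree_1d_two_peaks():
    img = ni.ArrayImg.from_numpy(np.array([0.0, 2.0, 0.0, 3.0, 0.0]), "f64")
    t = ni.build_component_tree(img)
    assert t.root.level == 0 and t.root.size == 5
    leaves = sorted((n.level, n.pixel_set()) for n in t.leaves())
    assert leaves == [(2.0, frozenset({(1,)})), (3.0, frozenset({(3,)}))]


def test_component_tree_rejects_unordered_type():
    img = ni.ImageFactory("array", "cf32").create((3, 3))
    with pytest.raises(TypeError):
        ni.build_component_tree(img)


def test_tree_partitions_equal_flood_fill_at_every_level(rng):
    for _ in range(8):
        arr = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        t = ni.build_component_tree(ni.ArrayImg.from_numpy(arr, "u8"))
        for level in np.unique(arr):
            assert set(t.components_at(level)) == flood_components(arr, level)


def test_component_sizes_non_decreasing_leaf_to_root(rng):
    arr = rng.integers(0, 5, (10, 10)).astype(np.uint8)
    t = ni.build_component_tree(ni.ArrayImg.from_numpy(arr, "u8"))
    for node in t.nodes():
        for c in node.children:
            assert c.size <= node.size


def test_min_tree_via_value_inversion_converter(rng):
    """The min-tree is the max-tree of the inverted image (no duplicate
    code path): dark blobs become bright leaves."""
    arr = np.full((9, 9), 200, dtype=np.uint8)
    arr[2:4, 2:4] = 10
    img = ni.ArrayImg.from_numpy(arr, "u8")
    inv = ni.convert_view(img, ni.invert_converter("u8"))
    t = ni.build_component_tree(inv)
    leaves = t.leaves()
    assert len(leaves) == 1
    assert leaves[0].pixel_set() == frozenset(
        (x, y) for x in (2, 3) for y in (2, 3)
    )


def test_mser_constant_image_no_regions():
    img = ni.ArrayImg.from_numpy(np.full((8, 8), 7.0), "u8")
    assert ni.mser_detect(ni.build_component_tree(img), delta=5) == []


def test_mser_rejects_delta_below_one(rng):
    img = ni.ArrayImg.from_numpy(np.zeros((4, 4)), "u8")
    with pytest.raises(ValueError):
        ni.mser_detect(ni.build_component_tree(img), delta=0.5)


def test_mser_bright_square_is_the_single_region():
    arr = np.full((32, 32), 10.0)
    arr[12:20, 12:20] = 200.0
    t = ni.build_component_tree(ni.ArrayImg.from_numpy(arr, "u8"))
    regions = ni.mser_detect(t, delta=5)
    assert len(regions) == 1
    assert regions[0].size == 64
    assert regions[0].pixel_set() == frozenset(
        (x, y) for x in range(12, 20) for y in range(12, 20)
    )


def test_mser_selection_matches_brute_force_rules(rng):
    """Node-by-node re-evaluation of the stability rate and selection rules
    with independent code."""
    from ndimg.algorithms import _branch_size_at

    arr = rng.integers(0, 6, (10, 10)).astype(np.uint8)
    t = ni.build_component_tree(ni.ArrayImg.from_numpy(arr, "u8"))
    delta, max_rate, min_size, max_size = 2, 1.5, 2, 60
    got = set(id(n) for n in ni.mser_detect(t, delta, min_size, max_size, max_rate))

    def q_of(node):
        up = []
        a = node
        while a is not None:
            up.append(a)
            a = a.parent
        up.reverse()
        b = node
        while b.children:
            b = sorted(b.children, key=lambda c: (-c.size, c.level, min(c.pixels)))[0]
            up.append(b)
        return (
            _branch_size_at(up, node.level - delta)
            - _branch_size_at(up, node.level + delta)
        ) / node.size

    expected = set()
    for node in t.nodes():
        if node is t.root or not (min_size <= node.size <= max_size):
            continue
        qi = q_of(node)
        if qi > max_rate:
            continue
        if node.parent is not None and qi > q_of(node.parent):
            continue
        if any(qi > q_of(c) for c in node.children):
            continue
        expected.add(id(node))
    assert got == expected


# --- anisotropic diffusion -------------------------------------------------


def test_diffusion_constant_image_unchanged():
    img = ni.ArrayImg.from_numpy(np.full((6, 6), 4.0), "f64")
    out = ni.anisotropic_diffusion(img, 10, 10.0, 0.25)
    assert np.allclose(out.to_numpy(), 4.0, atol=1e-12)


def test_diffusion_zero_iterations_is_identity(rng):
    arr = rng.uniform(0, 255, (6, 6))
    out = ni.anisotropic_diffusion(ni.ArrayImg.from_numpy(arr, "f64"), 0, 10.0, 0.25)
    assert np.allclose(out.to_numpy(), arr)


def test_diffusion_rejects_unstable_lambda(rng):
    img = ni.ArrayImg.from_numpy(np.zeros((4, 4)), "f64")
    with pytest.raises(ValueError, match="0.25"):
        ni.anisotropic_diffusion(img, 1, 10.0, 0.3)


def test_diffusion_conserves_global_mean(rng):
    arr = rng.uniform(0, 255, (16, 16))
    out = ni.anisotropic_diffusion(ni.ArrayImg.from_numpy(arr, "f64"), 20, 15.0, 0.25)
    assert abs(out.to_numpy().mean() - arr.mean()) < 1e-6


def test_diffusion_reduces_variance(rng):
    arr = rng.uniform(0, 255, (12, 12))
    out = ni.anisotropic_diffusion(ni.ArrayImg.from_numpy(arr, "f64"), 5, 50.0, 0.25)
    assert out.to_numpy().var() < arr.var()


# --- genericity: identical results across backends and through views -------


def _run_all(img):
    """Run every algorithm; returns a flat list of output samples."""
    out = []
    g = ni.gaussian_convolve(img, 1.2)
    out.extend(g.get(p) for p in g.interval.positions())
    for grad in ni.sobel(img):
        out.extend(grad.get(p) for p in grad.interval.positions())
    out.extend(
        (d.coords, round(abs(d.response), 9)) for d in ni.dog_detect(img, 1.0, 2.0, 0.05)
    )
    u8 = ni.ImageFactory("array", "u8").create(img.interval.dims, interval=img.interval)
    for p in img.interval.positions():
        u8.set(p, int(round(img.get(p))))
    t = ni.build_component_tree(u8)
    out.append(sorted((n.level, n.size) for n in t.nodes()))
    out.append(
        sorted((r.level, r.size) for r in ni.mser_detect(t, 3, 2, 80, 2.0))
    )
    d = ni.anisotropic_diffusion(img, 3, 20.0, 0.25)
    out.extend(d.get(p) for p in d.interval.positions())
    return out


def test_algorithms_identical_across_backends(rng):
    arr = rng.uniform(0, 100, (9, 9))
    results = []
    for backend in BACKENDS:
        img = make_factory(backend, "f64", cell_dims=4).create((9, 9))
        for p in img.interval.positions():
            img.set(p, arr[p])
        results.append(_run_all(img))
    assert results[0] == results[1] == results[2]


def test_algorithms_identical_through_views(rng):
    """Running on a permuted/translated view equals running on the
    equivalently transformed input."""
    arr = rng.uniform(0, 100, (8, 6))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    direct = ni.ArrayImg.from_numpy(arr.T.copy(), "f64")
    viewed = ni.permute(img, 0, 1)
    assert _run_all(ni.zero_min(viewed)) == _run_all(direct)

    shifted_view = ni.zero_min(ni.translate(img, (3, -2)))
    assert _run_all(shifted_view) == _run_all(img)
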