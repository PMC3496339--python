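"""Lazy integer views: transforms, composition/simplification, extension."""

import numpy as np
import pytest

import ndimg as ni
from ndimg.base import BoundsError, Interval
from ndimg.types import allocation_count
from ndimg.views import (
    TransformView,
    fold_index,
    set_auto_simplify,
    simplify,
    view_depth,
)


def ramp2d(w=4, h=4):
    return ni.ArrayImg.from_numpy(
        np.add.outer(np.arange(float(w)), np.zeros(h)), "f64"
    )


def test_translate_shifts_coordinates():
    img = ramp2d()
    v = ni.translate(img, (2, 3))
    assert v.get((2, 3)) == img.get((0, 0))
    assert v.interval.min == (2, 3)


def test_permute_is_transpose(rng):
    arr = rng.uniform(0, 1, (2, 3))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    v = ni.permute(img, 0, 1)
    assert v.interval.dims == (3, 2)
    for i in range(2):
        for j in range(3):
            assert v.get((j, i)) == img.get((i, j))


def test_rotate90_four_times_is_identity(rng):
    img = ni.ArrayImg.from_numpy(rng.uniform(0, 1, (5, 4)), "f64")
    v = img
    for _ in range(4):
        v = ni.rotate90(v, 0, 1)
    assert v.interval == img.interval
    assert all(v.get(p) == img.get(p) for p in img.interval.positions())


def test_invert_axis_mirrors_about_origin():
    img = ni.ArrayImg.from_numpy(np.arange(4.0), "f64")
    v = ni.invert_axis(img, 0)
    assert v.interval.min == (-3,) and v.interval.max == (0,)
    assert all(v.get((-i,)) == img.get((i,)) for i in range(4))


def test_hyperslice_extracts_plane(rng):
    arr = rng.uniform(0, 1, (4, 4, 2))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    sl = ni.hyperslice(img, 2, 0)
    assert sl.interval.dims == (4, 4)
    assert all(sl.get((x, y)) == arr[x, y, 0] for x in range(4) for y in range(4))


def test_hyperslice_write_through_touches_only_the_plane():
    img = ni.ImageFactory("array", "f64").create((3, 3, 2))
    sl = ni.hyperslice(img, 2, 1)
    sl.set((1, 2), 9.0)
    assert img.get((1, 2, 1)) == 9.0
    assert img.get((1, 2, 0)) == 0.0


def test_hyperslice_rejects_out_of_interval_position():
    with pytest.raises(BoundsError):
        ni.hyperslice(ramp2d(), 1, 4)


def test_slice_of_permuted_equals_permute_of_sliced(rng):
    arr = rng.uniform(0, 1, (3, 4, 2))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    a = ni.hyperslice(ni.permute(img, 0, 1), 2, 1)     # (y, x) plane z=1
    b = ni.permute(ni.hyperslice(img, 2, 1), 0, 1)
    assert a.interval == b.interval
    assert all(a.get(p) == b.get(p) for p in a.interval.positions())


def test_window_full_interval_is_identity(rng):
    img = ni.ArrayImg.from_numpy(rng.uniform(0, 1, (4, 4)), "f64")
    w = ni.window(img, img.interval)
    assert all(w.get(p) == img.get(p) for p in img.interval.positions())


def test_window_center_block_of_ramp():
    img = ramp2d()
    w = ni.window(img, Interval((1, 1), (2, 2)))
    vals = sorted(v.get() for _, v in ni.iterate(w))
    assert vals == [1.0, 1.0, 2.0, 2.0]
    assert set(c for c, _ in ni.iterate(w)) == {(1, 1), (2, 1), (1, 2), (2, 2)}


def test_window_rejects_non_contained_interval():
    with pytest.raises(BoundsError):
        ni.window(ramp2d(), Interval((0, 0), (4, 4)))


def test_zero_min_translates_to_origin():
    v = ni.zero_min(ni.translate(ramp2d(), (5, -3)))
    assert v.interval.min == (0, 0)


def test_write_through_view_equals_direct_write(rng):
    img = ni.ImageFactory("array", "f64").create((4, 5))
    v = ni.rotate90(ni.permute(img, 0, 1), 0, 1)
    for p in v.interval.positions():
        v.set(p, float(rng.uniform()))
    for p in v.interval.positions():
        assert v.get(p) == img.get(v.transform.apply(p))


# --- extension -------------------------------------------------------------


def one_d():
    return ni.ArrayImg.from_numpy(np.array([10.0, 20.0, 30.0]), "f64")


@pytest.mark.parametrize(
    "strategy,at_minus1,at_3",
    [
        (ni.mirror_single, 20.0, 20.0),
        (ni.mirror_double, 10.0, 30.0),
        (ni.periodic, 30.0, 10.0),
        (ni.constant(0.0), 0.0, 0.0),
    ],
)
def test_extension_stated_folding_rules(strategy, at_minus1, at_3):
    e = ni.extend(one_d(), strategy)
    assert e.get((-1,)) == at_minus1
    assert e.get((3,)) == at_3


def brute_fold(i, n, kind):
    """Index-folding oracle by explicit search over the folded sequence."""
    if kind == "periodic":
        return i % n
    if kind == "mirror_single":
        seq = list(range(n)) + list(range(n - 2, 0, -1)) if n > 1 else [0]
        return seq[i % len(seq)]
    seq = list(range(n)) + list(range(n - 1, -1, -1))
    return seq[i % len(seq)]


@pytest.mark.parametrize("kind", ["mirror_single", "mirror_double", "periodic"])
@pytest.mark.parametrize("dims", [(5,), (4, 3), (3, 4, 2)])
def test_extension_matches_folding_oracle(kind, dims, rng):
    arr = rng.uniform(0, 1, dims)
    img = ni.ArrayImg.from_numpy(arr, "f64")
    e = ni.extend(img, ni.ExtensionStrategy(kind))
    margin = 10
    probes = [
        tuple(int(rng.integers(-margin, d + margin)) for d in dims)
        for _ in range(200)
    ]
    for p in probes:
        q = tuple(brute_fold(c, d, kind) for c, d in zip(p, dims))
        assert e.get(p) == arr[q]


def test_extended_view_equals_source_inside(rng):
    arr = rng.uniform(0, 1, (4, 4))
    img = ni.ArrayImg.from_numpy(arr, "f64")
    for strat in (ni.mirror_single, ni.mirror_double, ni.periodic, ni.constant(7.0)):
        e = ni.extend(img, strat)
        assert all(e.get(p) == img.get(p) for p in img.interval.positions())


# --- simplification --------------------------------------------------------


def random_chain(img, rng, depth):
    """A chain of random square integer-transform views."""
    v = img
    for _ in range(depth):
        op = rng.integers(0, 4)
        n = v.interval.ndim
        if op == 0:
            v = ni.translate(v, [int(rng.integers(-3, 4)) for _ in range(n)])
        elif op == 1 and n >= 2:
            d1, d2 = rng.choice(n, size=2, replace=False)
            v = ni.permute(v, int(d1), int(d2))
        elif op == 2 and n >= 2:
            d1, d2 = rng.choice(n, size=2, replace=False)
            v = ni.rotate90(v, int(d1), int(d2))
        else:
            v = ni.invert_axis(v, int(rng.integers(0, n)))
    return v


def test_translate_translate_fuses_to_single_translation():
    img = ramp2d()
    v = ni.translate(ni.translate(img, (1, 2)), (3, 4))
    assert view_depth(v) == 1
    assert v.transform.translation == (-4, -6)
    assert v.get((4, 6)) == img.get((0, 0))


def test_permute_twice_is_identity_transform():
    v = ni.permute(ni.permute(ramp2d(), 0, 1), 0, 1)
    assert view_depth(v) == 1
    assert v.transform.is_identity()


def test_simplified_chain_matches_sequential_oracle(rng):
    """Fused single-transform access equals the unfused chain everywhere."""
    img = ni.ArrayImg.from_numpy(rng.uniform(0, 1, (4, 5, 3)), "f64")
    for _ in range(25):
        prev = set_auto_simplify(False)
        try:
            chain = random_chain(img, rng, depth=5)
            assert view_depth(chain) == 5
            fused = simplify(chain)
        finally:
            set_auto_simplify(prev)
        assert view_depth(fused) == 1
        assert fused.interval == chain.interval
        for p in chain.interval.positions():
            assert fused.get(p) == chain.get(p)


def test_auto_simplify_keeps_depth_one(rng):
    v = random_chain(ramp2d(), rng, depth=5)
    assert view_depth(v) == 1


def test_simplify_stops_at_extension_nodes(rng):
    """Only the maximal run of transform views above an extension is fused;
    the extension node (and anything below it) survives untouched."""
    img = ramp2d()
    ext = ni.extend(ni.translate(img, (1, 1)), ni.periodic)
    bounded = TransformView(
        ext, ni.MixedTransform.identity(2), Interval((-2, -2), (5, 5))
    )
    chain = ni.translate(ni.permute(bounded, 0, 1), (1, 0))
    s = simplify(chain)
    assert view_depth(s) == 1
    assert s.source is ext
    for p in chain.interval.positions():
        assert s.get(p) == chain.get(p)


def test_view_construction_allocates_no_pixel_storage(rng):
    img = ni.ArrayImg.from_numpy(rng.uniform(0, 1, (50, 50)), "f64")
    before = allocation_count()
    v = ni.rotate90(ni.translate(ni.permute(img, 0, 1), (3, 3)), 0, 1)
    assert allocation_count() == before
    assert not hasattr(v, "buffer")
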