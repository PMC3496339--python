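# Methods

This note records the models, conventions and numerical choices behind
`ndimg`, and what the test suite does and does not establish.

## Images, intervals and accessors

An image is any mapping from coordinates to values. Bounded discrete
images carry an `Interval` — per-dimension inclusive min/max, 0-based by
default, with negative minima allowed so translated views remain
first-class. `num_elements = prod(max-min+1)`.

Access is virtualized: a `RandomAccess` is positioned at arbitrary
coordinates; a `Cursor` visits every sample exactly once in the backend's
own order (flat raster with dimension 0 fastest for array/list storage;
cell-by-cell, raster within each cell, for cell storage). Iteration order
is exposed as a descriptor; two images may only be co-iterated
positionlessly when their descriptors are equal — otherwise a cursor must
be paired with a random access. Cursors re-position one value proxy for
the entire run (a module-level allocation counter makes the
zero-allocations-per-sample contract testable); the proxy yielded at each
step is invalidated by the next advance, and `copy()` snapshots a value
that must survive. `localize()` always returns a copy, never a live
internal vector — aliasing safety was judged worth the small cost.

Bounds are checked by default; `checked = False` opts an image out for
inner loops.

## Value types

Nine types behind string tags (`bit, u8, i16, u16, i32, f32, f64, cf32,
argb`). Storage semantics are the contract:

* integer writes wrap modulo 2^bits (raw-storage semantics; clamping is an
  explicit converter, never implicit). Integer division truncates toward
  zero and division by zero is an error; real division by zero yields IEEE
  inf/nan.
* floats are quantized to their storage precision on write, so list
  storage (Python objects) and array storage (float32 buffers) agree
  bitwise — without this the backends would diverge in the last ulp.
* complex arithmetic is componentwise; complex has no ordering.
* ARGB packs A,R,G,B into bits 31–24, 23–16, 15–8, 7–0; arithmetic is per
  channel with clamping at 255, since arithmetic on the packed word is
  meaningless.

Converters transform values lazily on access (never materialized); writes
through a converter require an explicit inverse. The min-tree is obtained
by composing the max-tree with the order-reversing converter rather than
by a second code path.

## Storage backends

`ArrayImg` enforces a 2³¹-element flat-buffer limit even though Python
would allow more, so capacity behaviour is reproducible and the documented
limits are real; a factory flag lifts it. The largest square 2-D image a
flat buffer holds is isqrt(2³¹) = 46,340 px per side. `CellImg` tiles the
domain into cells (default 64 per dimension — a power of two that keeps
any supported type's cell under the flat limit); interior cells are full
size, border cells truncated, and the cells tile the interval exactly
once. Its addressable capacity is modeled as min(elements-per-cell × 2³¹
cells, 2⁶³), i.e. 2⁶² pixels at the defaults — the cell grid itself is
flat-addressed under the same limit. Images are zero-initialized
(deterministic tests).

## Views

A view stores a `MixedTransform` — per-source-dimension component choice
(or a constant, for sliced-away dimensions), inversion flag and integer
translation — mapping view coordinates to source coordinates. All builders
(translate, permute, rotate90, invert_axis, hyperslice, window, zero_min)
reduce to this one form, so consecutive views fuse by symbolic composition
into a single transform at construction time. A debug switch
(`set_auto_simplify(False)`) disables fusion so tests can compare fused
access against the sequential chain; `simplify()` fuses only the maximal
run of transform views above a non-transform node (extension,
interpolation).

`rotate90(from_d, to_d)` maps a source point (f, t) to view point
(to_d = f, from_d = (max+min) - t): permutation plus one axis inversion,
chosen so the interval stays in place along the rotated axes and four
applications are the identity.

Out-of-bounds extension has four strategies. With 0-based index i and side
n: `periodic` folds i mod n; `mirror_single` folds over period 2n-2
(border sample not repeated); `mirror_double` over period 2n (border
repeated); `constant` returns a fixed value. Both mirror variants exist
because the convolution literature uses both; `mirror_single` is the
default for the filtering algorithms (no doubled border mass).

## Continuous access

Grid samples sit at integer coordinates (pixel-center convention; results
differ under corner conventions, hence documented). `nearest` rounds half
toward +infinity per dimension — deterministic ties. `nlinear` is the
convex combination of the 2^n surrounding samples with weights
`prod_d (1-|x_d-g_d|)`; zero-weight corners are skipped, so unextended
sources are safe at their own grid points, and the scheme is exact for
images affine in the coordinates. Affine views hold an n×n matrix plus
translation; `A.compose(B)` applies B first; singular matrices are
rejected by determinant (threshold 1e-12). Rasterization evaluates the
continuous image lazily at every integer point of a target interval.

## Sparse data

The k-d tree is built by median split (stable sort by coordinate, then
insertion index) with the split dimension cycling by depth, giving depth
≤ ceil(log2 N)+1. All searches are Euclidean (the metric is a deliberate
single choice, not a parameter yet) and break ties by insertion order;
pruning uses ≤ on the splitting-plane distance so equal-distance
candidates on the far side are always visited, which makes tree results
bit-identical to a linear scan of the sample list — the central
correctness property, asserted against brute force throughout the tests.
Nearest-neighbor extrapolation turns a point list into a piecewise
constant (Voronoi) image defined on all of real space. CSV interchange
uses `%.17g` formatting and round-trip float parsing so coordinates
survive exactly.

## Algorithms

All algorithms touch pixels only through `get`/`set`, which is what makes
them backend-, dimension- and view-agnostic; the genericity tests assert
bit-equal outputs across array/cell/list storage and through
permuted/translated views.

* **Gaussian convolution** — separable, one 1-D pass per dimension; the
  kernel is the sampled Gaussian truncated at max(2, ceil(3σ)) samples per
  side and normalized to sum 1 (σ = 0 degenerates to the identity).
  Output is f64.
* **Sobel** — per gradient dimension, derivative kernel [-1, 0, 1] along
  it and smoothing [1, 2, 1] along all others; on a unit ramp the interior
  response is 8 (derivative gain 2 × smoothing mass 4).
* **DoG interest points** — response g(σ₂) − g(σ₁) without 1/(σ₂−σ₁)
  normalization, so the threshold applies to the raw difference.
  Detections are strict extrema over the full 3^n−1 neighborhood
  (plateaus yield nothing — deterministic); border pixels whose
  neighborhood leaves the interval are not candidates. Reported scale is
  the geometric mean sqrt(σ₁σ₂).
* **Component tree** — max-tree (bright components) built by
  descending-level flooding with union-find, face connectivity by
  default; node sizes are cumulative and non-decreasing toward the root.
  The min-tree is the max-tree of the value-inverted converter view.
* **MSER** — for a node at level l on a root-to-leaf branch the stability
  rate is q = (|Q(l−Δ)| − |Q(l+Δ)|)/|Q(l)|, where Q(g) is the component
  active at threshold g along the branch (a node at level l with parent at
  level lp is active for lp < g ≤ l). Two boundary choices close the
  definition: levels past a leaf clamp to the leaf's size (the component
  persists at its own extremum — otherwise every leaf would score q = 1
  and could never be a branch minimum), and the root (the whole image) is
  never selectable (with the clamp it would otherwise score q = 0 on a
  constant image). A node is selected iff q is a non-strict local minimum
  against its parent and children, q ≤ max_rate, and its size lies in
  [min_size, max_size]. Δ is in gray-level units.
* **Anisotropic diffusion** — explicit Perona–Malik scheme with
  exponential conductance g(s) = exp(−(s/κ)²) (rational variant by
  option); stability requires 0 < λ ≤ 1/(2n), enforced with the bound in
  the error message. The boundary uses the border-repeating mirror
  (`mirror_double`), not the algorithms' usual `mirror_single`: repeating
  the border makes the gradient across the boundary zero, so boundary
  flux vanishes, interior fluxes cancel pairwise, and the global mean is
  conserved exactly — a property the tests assert to 1e-6.

## Synthetic data and what the tests show

Fixtures are closed forms (impulse, affine ramp, Gaussian blob, nested
constant squares) plus seeded uniform noise; the same spec and seed are
bit-reproducible. They exercise every contract — boundaries, extrema,
nesting, determinism — but are not natural micrographs: no shot noise,
no anisotropic PSF, no illumination gradients. Passing tests establish the
*algebraic* guarantees (oracle agreement, backend/view invariance,
conservation laws, exactness classes), not detection performance on real
specimens; parameter defaults in the demo are illustrative, not tuned.

Problem sizes in the tests and acceptance script (images ≤ 20 px per
side for equivalence sweeps, 9×9 / 7×7×5 convolution fixtures, 200-point
trees with 1,000 queries, a 40-px demo) are chosen as the smallest scales
at which every property is non-trivially exercised — exhaustive
coordinate-by-coordinate comparison is the point, and it is quadratic in
image size.

## Benchmark harness

Three task stand-ins cover the generic-versus-specialized comparison:
pixel sum, per-pixel multiply-add, and a radius-1 box mean whose inner
loop runs over the a-priori-unknown number of dimensions. Each exists as
generic accessor code and as direct numpy buffer code; the harness
verifies the two produce identical numbers before timing and then reports
median-of-reps times and their ratio with machine info attached. Ratios
are context, never acceptance values: they measure the host's interpreter
overhead, not the library's correctness.

## Known limitations

* Pure-Python accessor loops are orders of magnitude slower than
  vectorized numpy; the architecture is the point here, and `ArrayImg`
  exposes `to_numpy()/from_numpy()` bridges where throughput matters.
* Integer view transforms cover permutation/inversion/translation/slicing
  compositions only — no general unimodular matrices.
* Interpolation is nearest/n-linear; Lanczos and B-spline are extension
  points without implementations.
* MSER's branch rate uses one canonical downward continuation per node
  (toward the largest child component, deterministic tie-breaks); nodes on
  several branches are scored once, not per branch.
* No disk-backed paging, compression or remote tiles; no Fourier-domain
  algorithms.
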