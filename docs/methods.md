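# Methods

This note documents the models implemented in `convef`, the numerical
choices behind them, the synthetic data the benchmarks run on, and what
the passing (and failing) tests do and do not establish.

## Force models

**Edge map.** All forces are sourced by a nonnegative edge map `q`,
normalized to max 1. Three constructions are provided: the gradient
magnitude `|∇(G_σ * I)|` (default for intensity images), its square
(sharpens strong-vs-weak edge contrast), and the identity (for panels and
line drawings whose drawn features already are the charges). Gaussian
smoothing uses a kernel truncated at radius `ceil(4σ)` and renormalized to
unit sum, with reflective borders; gradients are central differences with
replicated (Neumann) borders.

**VEF / VFC / CONVEF.** Each is a linear convolution of `q` with a radial
vector kernel, evaluated by FFT with zero padding (circular wrap-around
would create phantom forces across image borders). The CONVEF kernel pair
is `1/r_h^n` (potential) and `−(x, y)/r_h^{n+2}` (field), with
`r_h = sqrt(x² + y² + h)`; a constant factor `n` relating the two is
dropped, so fields are defined up to a positive scalar and all tests use
directions and relative magnitudes. At `h = 0` the kernel origin is set to
zero — a charge exerts no force on itself — which makes CONVEF(h=0, n=1)
coincide with VEF to rounding error. VFC kernels are `m(r)·(−x/r, −y/r)`
with `m₁ = 1/r^γ` or `m₂ = exp(−r²/ζ²)`.

The default kernel support is a square of half-width `max(rows, cols)//2`,
i.e. kernel side comparable to the image side. Note that a truncated
square support breaks the exact gradient structure of the field near the
support boundary; the curl-freeness test therefore uses full offset
coverage, where the discrete curl vanishes to central-difference
truncation (relative error ~1e−3, asserted < 1e−2 in a charge-free
region).

**GVF.** The gradient vector flow field diffuses `∇f` by the explicit
scheme `u ← u + dt·(μ ∇²u − (u − f_x)(f_x² + f_y²))` (5-point Laplacian,
Neumann borders), initialized at `∇f`. The commonly quoted stability
condition `dt·μ ≤ 1/4` covers only the diffusion term; with the
data-fidelity term the scheme diverges at that bound (verified on the
U-shape edge map, where the energy grows without bound). The package
therefore uses the full von Neumann bound `dt = 2/(8μ + max(f_x²+f_y²))`
as the run-time default and rejects larger steps, while still enforcing
`dt·μ ≤ 1/4` as a necessary condition at construction. The monitored
energy uses forward differences for the smoothness term so that it is
exactly the Lyapunov function of the 5-point scheme; with that pairing it
is non-increasing at the bound, which the tests assert over 200
iterations at μ = 0.2.

## Snake

The contour is a closed polyline evolved semi-implicitly: internal forces
(elasticity α on the second difference, rigidity β on the fourth) are
treated implicitly through the cyclic pentadiagonal system
`(I + τA) c_new = c_old + τκ F(c_old)`, solved exactly in O(N log N) by
diagonalizing the circulant matrix with the FFT (verified against a dense
solve to 1e−10). The external field is sampled at pre-step positions by
bilinear interpolation, with nearest-border values outside the domain.

Vertices are redistributed to uniform spacing every `resample_every`
iterations. Arc-length redistribution is iterated until consecutive chord
lengths are uniform (CV < 1e−4); for contours smooth at the spacing scale
this preserves total length well within 1%, while sharp corners are
progressively rounded — inherent to polyline snakes.

**Convergence.** With a unit-normalized external force the discrete
dynamics generally settles into a small limit cycle (vertices overshoot
the zero-crossing line by a fraction of `τκ` each step) rather than a
fixed point, so a per-iteration displacement threshold never fires. Two
convergence routes are therefore implemented: the classical one (max
vertex displacement below `tol` for `conv_window` consecutive
iterations), and recurrence of the resampled configuration over several
consecutive resampling periods, which detects the limit cycle without
mistaking slow creep (e.g. a pocket still descending into a concavity)
for convergence. Degenerate collapse (perimeter below four spacings) and
runaway growth terminate evolution as non-converged.

**Normalization.** Whether the external field should be normalized to
unit magnitude is a genuine design fork: unit forces give every edge —
however weak — full holding power, but also give every residual noise
basin full trapping power; raw magnitudes rank features correctly but let
contour tension tear folds off weak or damaged edges whose local field is
orders of magnitude below the global maximum. The default is
normalization (`SnakeParams.normalize=True`), with the raw field
available behind the flag; the benchmark protocols record which they use.

## Synthetic fixtures

The generator draws every image class the benchmarks use, deterministically
from a spec: an impulse/strong-edge/weak-edge panel (single-pixel impulse
and full-height lines; default charges 1.0, 1.0, 0.85 on background 0 —
the weak-edge contrast 0.85 is configurable, as is polarity); the 64×64
U-shape (36×28 block, 12-wide × 24-deep top notch) and its S/3 variants
(two notches); a C-shape (ring R=19, r=8, 40° mouth — the mouth is
narrower than the cavity, which is what makes the C "semi-closed"); a
G-shape (1.25-turn Archimedean spiral band, stroke width 5 — a concavity
whose orientation rotates); thin line drawings at any N; and a two-object
scene (gray disk of intensity 0.4 next to a white rectangle across a 3-px
background gap). Ground truth (boundary, mask, concavity / forbidden
regions) is emitted alongside. Salt-&-pepper noise follows MATLAB
`imnoise` semantics: each pixel independently corrupted with probability
`var`, to 0 or 1 with equal probability.

What these fixtures emulate is geometry — concavities, weak edges, narrow
gaps, impulsive corruption. What they do not emulate is real acquisition
physics: no speckle, no intensity inhomogeneity, no texture, no partial
volume effects. A battery passing here shows the force field has the
claimed geometric behaviour, not that a clinical segmentation pipeline is
complete.

## Benchmark protocols (frozen in `convef.benchmarks`)

* **Streamline panel** — CONVEF(n=1, h=20) vs VEF on the identity edge
  map of the panel; 81 seeds on a step-2 grid over the impulse's ±4 px
  neighbourhood. Farther seeds are uninformative: the full-height weak
  line out-charges the single impulse, so both fields send >97% of them
  to edges; the contrast lives where the impulse competes. Measured:
  CONVEF sends 100% of neighbourhood streamlines to an edge, VEF 20%.
* **Noise battery** — U-shape, var ∈ {0.1…0.4}, one base seed with
  per-level offsets (a single shared seed would nest the corruption masks
  across levels). The noisy image stays intact — no Gaussian presmoothing
  for either method — and the edge map is the raw gradient magnitude.
  Snake: α=0.05, β=0, τ=0.5, κ=1, spacing 0.5, resampling every 5,
  normalized field. Per level, (n, h) is chosen from the 4×5 grid
  {1.5, 2, 2.5, 3} × {5, 10, 20, 30, 45} by coverage then distance.
* **Concavity battery** — C/G shapes, same gentle snake with α=0.01,
  CONVEF (n ≤ 1, h ≤ 5) grid vs GVF (μ=0.2, 200 iterations), both from
  the same outside circle.
* **Separation test** — two-object scene, σ=1 edge map, init circle
  around the disk; CONVEF(n=3, h=0) vs VEF with default snake
  parameters. The VEF field has no zero crossing at the weak disk edge
  (verified on the field profile), so its snake crosses the 3-px gap and
  parks on the rectangle's border; the reported `gap_overreach`
  (contour's maximum x minus the disk's rightmost pixel) makes that
  crossing visible even though the strict-interior leakage count, which
  by convention excludes border pixels, remains 0 for a border-parked
  contour.
* **Initialization insensitivity** — clean U-shape, CONVEF(n=2, h=6),
  snakes started inside, outside and across the boundary; each final is
  compared to the outside-initialized final by directed mean distance
  (the same convention as `boundary_distance`). The directed form is
  deliberate: a parametric snake without a balloon term started strictly
  inside a solid non-convex shape cannot wrap protruding arms, so the
  meaningful claim is that every final lies on the common boundary
  contour, not that all finals are identical point sets.

## Known limitations

* At 64×64 with intact (unsmoothed) noisy edge maps, the noisy U-shape
  battery does not reach the targets mean distance < 2 px *and* concavity
  coverage > 0.8 at every noise level: corrupted pixels inside and around
  the 12-px notch anchor or sever the arm-top fold of the contour
  (measured best per level: distance 1.5–2.4 px, coverage 0.48–0.79).
  Gaussian presmoothing rescues the CONVEF snake at most levels but also
  rescues the VEF baseline, erasing the contrast the battery exists to
  show; it is therefore not applied.
* On the C- and G-shape fixtures the small-n CONVEF snake enters the
  cavity (mean distance < 1 px) but plateaus at 61–71% concavity
  coverage: the strands spanning the narrow mouth/channel do not hug the
  full cavity wall. GVF coverage is 39% (C) and 55% (G) under the same
  protocol.
* Kernel truncation below full image coverage slightly breaks the
  gradient (curl-free) structure of the convolution fields near the
  support boundary; use the default image-sized support where that
  matters.
* The snake performs no topology changes, no balloon inflation, and no
  automatic initialization.
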