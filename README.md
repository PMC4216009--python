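# convef

External force fields for parametric active contours (snakes): the
**convolutional virtual electric field (CONVEF)** together with the family
it extends — gradient vector flow (GVF), the virtual electric field (VEF)
and vector field convolution (VFC) — plus a snake evolver, synthetic
benchmark images, and quantitative convergence metrics.

The package is aimed at researchers in biological and medical image
analysis who segment object boundaries with edge-based deformable models
and need an external force that simultaneously has a large capture range,
converges into boundary concavities, suppresses impulsive noise without
erasing weak edges, and separates closely neighbouring objects.

## The model

A snake is a closed curve **c**(s) minimizing

```
E = ∫ ½ ( α |c′(s)|² + β |c″(s)|² ) + E_ext(c(s)) ds
```

whose Euler–Lagrange force balance is `α c″ − β c⁗ + F_ext = 0`.  The
package's subject is the external force `F_ext`.

Treating the edge map `q(x, y) ≥ 0` of an image as a charge distribution,
the VEF is the summed Coulomb attraction, computable as a convolution
`F = q ⊛ k` with vector kernel `k(x, y) = −(x, y)/r³`.  CONVEF keeps the
convolution structure but modifies the distance and the decay:

```
r_h = sqrt(x² + y² + h)            modified distance, h ≥ 0
VEP kernel      1 / r_h^n          scalar potential (virtual electric potential)
field kernel    −(x, y) / r_h^(n+2)
```

* `h` acts like a scale-space parameter: a larger `h` down-weights nearby
  charges relative to distant ones, so isolated impulses (salt-&-pepper
  noise) lose influence while extended edges keep it.
* `n` sets how fast influence decays with distance: large `n` (≥ 2)
  localizes the force, preserving weak edges next to strong ones and
  separating neighbouring objects; small `n` (≤ 1) weighs distant charges
  more, letting the field reach into semi-closed, blob-like concavities.
* `h = 0, n = 1` recovers the VEF exactly; VFC with magnitude `1/r^γ` is
  the `h = 0` sub-family, and `γ = 2` is again the VEF.

All convolution fields are evaluated by FFT (zero-padded linear
convolution), so their cost is a few FFTs regardless of parameters; GVF by
contrast iterates an explicit diffusion scheme, included here both as a
baseline and as a reference implementation.

## Worked example

Extract the classic U-shape from its own synthetic fixture:

```python
from convef import (ShapeSpec, make_shape_image, edge_map, KernelSpec,
                    convef_field, init_contour, SnakeParams, evolve,
                    score_contour)

img, gt = make_shape_image(ShapeSpec(family="ushape"))        # 64x64, white U
em = edge_map(img, sigma=1.0, mode="magnitude")               # |grad(G_sigma * I)|
field, potential = convef_field(em, KernelSpec(family="convef", n=2.0, h=6.0))
c0 = init_contour("circle", {"center": (31.5, 31.5), "radius": 28}, 200)
result = evolve(c0, field, SnakeParams(alpha=0.05, beta=0.0, tau=0.5,
                                       max_iters=1500))
report = score_contour(result.final, gt)
print(f"converged: {result.converged} after {result.iterations_run} iterations")
print(f"mean boundary distance: {report.mean_distance:.2f} px")
print(f"max boundary distance:  {report.max_distance:.2f} px")
print(f"concavity coverage:     {report.concavity_coverage:.2f}")
```

prints

```
converged: True after 320 iterations
mean boundary distance: 0.53 px
max boundary distance:  2.09 px
concavity coverage:     0.96
```

i.e. the snake, started well outside the object, lands on the true
boundary to half a pixel on average and traces 96% of the concavity-facing
boundary to within 2 px — including the notch a plain gradient force
cannot enter.

The same pipeline is available from the shell:

```
convef synth ushape -o u.png --gt gt.json
convef field u.png --method convef --n 2 --h 6 --sigma 1 -o field.tif
convef snake field.tif --center 31.5 31.5 --radius 28 --alpha 0.05 \
       --beta 0 --tau 0.5 -o contour.csv
convef score contour.csv --gt gt.json -o report.json
```

Other subcommands: `edgemap`, `streamline`, and `run` (config-driven
experiment). All fixture families (`impulse_edges`, `ushape`, `sshape`,
`threeshape`, `cshape`, `gshape`, `line_drawing`, `two_objects`) are drawn
deterministically; salt-&-pepper noise takes an explicit seed.

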