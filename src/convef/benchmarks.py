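"""Frozen benchmark protocols for the behaviour batteries.

Each function runs one of the package's standard synthetic experiments end
to end — streamline analysis on the impulse/strong/weak panel, the noisy
U-shape battery, blob-concavity convergence on the C/G shapes, two-object
separation, and initialization insensitivity — and returns plain numbers.
The protocols (fixture geometry, edge-map construction, snake settings,
parameter grids) are fixed here so that the test suite and the acceptance
script measure exactly the same quantities; the methods note documents the
choices.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import cKDTree

from .edgemap import edge_map
from .fixtures import NoiseSpec, ShapeSpec, add_salt_pepper, make_shape_image
from .forces import GvfParams, KernelSpec, convef_field, gvf_field, vef_field
from .metrics import _densify, boundary_distance, concavity_coverage, leakage_check
from .snake import SnakeParams, evolve, init_contour, trace_streamline

__all__ = [
    "streamline_panel",
    "noise_battery",
    "concavity_battery",
    "separation_test",
    "init_insensitivity",
    "NOISE_GRID",
    "CONCAVITY_GRID",
]

# (n, h) grids searched per battery; documented in docs/methods.md
NOISE_GRID = tuple(itertools.product((1.5, 2.0, 2.5, 3.0), (5.0, 10.0, 20.0, 30.0, 45.0)))
CONCAVITY_GRID = tuple(itertools.product((0.3, 0.5, 0.8, 1.0), (0.0, 2.0, 5.0)))

# gentle contour dynamics used by the batteries: low tension so thin folds
# (notch arms, cavity pockets) survive, fine spacing for fold support
_GENTLE = dict(alpha=0.05, beta=0.0, tau=0.5, kappa=1.0, spacing=0.5, resample_every=5)


def streamline_panel(n: float = 1.0, h: float = 20.0) -> dict:
    """Fraction of streamlines ending at an edge vs the impulse.

    Seeds form a 9x9 grid (step 2) over the impulse's +-4 px neighbourhood
    on the corridor toward the weak edge — the region where the impulse
    competes with the edges; farther seeds flow to the edges under every
    force model.
    """
    img, gt = make_shape_image(ShapeSpec(family="impulse_edges"))
    em = edge_map(img, sigma=0, mode="identity")
    iy, ix = np.argwhere(gt.regions["impulse"])[0]
    weak_col = int(np.argmax(gt.regions["weak_edge"].any(axis=0)))
    strong_col = int(np.argmax(gt.regions["strong_edge"].any(axis=0)))
    seeds = [
        (float(x), float(y))
        for x in range(ix - 4, ix + 5, 2)
        for y in range(iy - 4, iy + 5, 2)
    ]

    def edge_fraction(field):
        n_edge = 0
        for seed in seeds:
            tx, ty = trace_streamline(field, seed, step=0.5, max_steps=600)[-1]
            if abs(tx - weak_col) <= 2 or abs(tx - strong_col) <= 2:
                n_edge += 1
        return n_edge / len(seeds)

    f_convef, _ = convef_field(em, KernelSpec(family="convef", n=n, h=h))
    f_vef = vef_field(em)
    return {
        "convef_edge_fraction": edge_fraction(f_convef),
        "vef_edge_fraction": edge_fraction(f_vef),
        "n_seeds": len(seeds),
    }


def _ushape_run(field, gt, max_iters=2000):
    c0 = init_contour("circle", {"center": (31.5, 31.5), "radius": 28}, 240)
    r = evolve(c0, field, SnakeParams(max_iters=max_iters, **_GENTLE))
    md, _ = boundary_distance(r.final, gt)
    return md, concavity_coverage(r.final, gt)


def noise_battery(seed: int = 7, var_levels=(0.1, 0.2, 0.3, 0.4)) -> dict:
    """Noisy U-shape extraction with per-level (n, h) grid search.

    The noisy image stays intact (no Gaussian presmoothing) for both the
    CONVEF and the VEF snake; the edge map is the raw gradient magnitude.
    For each noise level the CONVEF (n, h) is chosen from ``NOISE_GRID`` by
    highest concavity coverage, ties broken by mean distance.
    """
    img0, gt = make_shape_image(ShapeSpec(family="ushape"))
    out = {}
    for i, var in enumerate(var_levels):
        img = add_salt_pepper(img0, NoiseSpec(var=var, seed=seed + i))
        em = edge_map(img, sigma=0, mode="magnitude")
        best = None
        for n, h in NOISE_GRID:
            f, _ = convef_field(em, KernelSpec(family="convef", n=n, h=h))
            md, cov = _ushape_run(f, gt)
            key = (cov, -md)
            if best is None or key > best[0]:
                best = (key, md, cov, n, h)
        vef_md, vef_cov = _ushape_run(vef_field(em), gt)
        out[var] = {
            "convef_mean_distance": best[1],
            "convef_coverage": best[2],
            "convef_n": best[3],
            "convef_h": best[4],
            "vef_mean_distance": vef_md,
            "vef_coverage": vef_cov,
        }
    return out


def concavity_battery(families=("cshape", "gshape")) -> dict:
    """Blob-like concavity convergence: CONVEF small-n vs GVF.

    Both snakes use the same gentle dynamics; CONVEF picks (n, h) from
    ``CONCAVITY_GRID`` (n <= 1) by highest coverage; GVF uses mu=0.2 and
    200 diffusion iterations.
    """
    out = {}
    for family in families:
        img, gt = make_shape_image(ShapeSpec(family=family))
        em = edge_map(img, sigma=0, mode="magnitude")
        c0 = init_contour("circle", {"center": (31.5, 31.5), "radius": 27}, 240)
        params = SnakeParams(max_iters=6000, tol=0.01, **{**_GENTLE, "alpha": 0.01})
        best = None
        for n, h in CONCAVITY_GRID:
            f, _ = convef_field(em, KernelSpec(family="convef", n=n, h=h))
            r = evolve(c0, f, params)
            md, _ = boundary_distance(r.final, gt)
            cov = concavity_coverage(r.final, gt)
            if best is None or (cov, -md) > best[0]:
                best = ((cov, -md), md, cov, n, h)
        g = gvf_field(em, GvfParams(mu=0.2, iterations=200))
        rg = evolve(c0, g, params)
        gvf_md, _ = boundary_distance(rg.final, gt)
        out[family] = {
            "convef_coverage": best[2],
            "convef_mean_distance": best[1],
            "convef_n": best[3],
            "convef_h": best[4],
            "gvf_coverage": concavity_coverage(rg.final, gt),
            "gvf_mean_distance": gvf_md,
        }
    return out


def separation_test() -> dict:
    """Weak disk next to a strong rectangle across a 3-px gap.

    Both snakes start on the same circle around the disk.  Reports leakage
    into the rectangle interior, mean distance to the disk boundary, and
    how far each contour reaches toward/past the gap (its maximum x),
    which exposes the VEF contour's gap crossing even when it parks on the
    rectangle's border rather than strictly inside it.
    """
    img, gt = make_shape_image(ShapeSpec(family="two_objects"))
    em = edge_map(img, sigma=1.0, mode="magnitude")
    c0 = init_contour("circle", {"center": (20.0, 32.0), "radius": 15.0}, 120)
    out = {}
    fields = {
        "convef": convef_field(em, KernelSpec(family="convef", n=3.0, h=0.0))[0],
        "vef": vef_field(em),
    }
    ys, xs = np.nonzero(gt.object_mask)
    disk_right = float(xs.max())
    for name, f in fields.items():
        r = evolve(c0, f, SnakeParams(max_iters=1500))
        md, _ = boundary_distance(r.final, gt)
        out[name] = {
            "mean_distance": md,
            "leakage": leakage_check(r.final, gt),
            "max_x": float(r.final[:, 0].max()),
        }
    out["disk_right_x"] = disk_right
    return out


def init_insensitivity() -> dict:
    """CONVEF finals from inside/outside/across inits vs the outside final.

    Distances are directed (mean over each contour's densified points of
    the distance to the nearest point of the outside-initialized final),
    matching the convention of :func:`convef.metrics.boundary_distance`.
    """
    img, gt = make_shape_image(ShapeSpec(family="ushape"))
    em = edge_map(img, sigma=1.0, mode="magnitude")
    f, _ = convef_field(em, KernelSpec(family="convef", n=2.0, h=6.0))
    inits = {
        "outside": init_contour("circle", {"center": (31.5, 31.5), "radius": 28}, 240),
        "inside": init_contour("circle", {"center": (31.5, 43.0), "radius": 5}, 80),
        "across": init_contour("circle", {"center": (20.0, 32.0), "radius": 12}, 140),
    }
    finals = {
        name: evolve(c0, f, SnakeParams(max_iters=3000, **_GENTLE)).final
        for name, c0 in inits.items()
    }
    ref = cKDTree(_densify(finals["outside"]))
    return {
        name: float(ref.query(_densify(c))[0].mean()) for name, c in finals.items()
    }
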