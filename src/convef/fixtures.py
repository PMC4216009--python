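"""Seeded generators for the synthetic test images and their ground truth.

Every experiment in the package runs on images produced here rather than on
external data: an impulse/strong-edge/weak-edge panel for streamline
analysis, the classic U-shape and its harder relatives (S, 3, C, G) for
concavity convergence, thin line drawings for timing-style workloads, and a
two-object scene (weak-edged gray disk next to a strong white rectangle,
separated by a thin background gap) for neighbouring-object separation.

All shapes are drawn deterministically from a :class:`ShapeSpec`; only
:func:`add_salt_pepper` consumes randomness, through an explicit seed.
Exact arm widths, mouth angles and spiral turns are fixed named defaults —
reproducible geometry is worth more than eyeballed likeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
from skimage import measure

__all__ = [
    "SHAPE_FAMILIES",
    "ShapeSpec",
    "NoiseSpec",
    "GroundTruth",
    "make_shape_image",
    "ground_truth_regions",
    "add_salt_pepper",
]

SHAPE_FAMILIES = (
    "impulse_edges",
    "ushape",
    "sshape",
    "threeshape",
    "cshape",
    "gshape",
    "line_drawing",
    "two_objects",
)


@dataclass
class ShapeSpec:
    """Which synthetic image to draw, at what size, with what geometry.

    ``geometry`` holds family-specific parameters (documented in the
    builder for each family); ``intensities`` maps feature names to values
    in [0, 1] so the polarity/contrast of every feature can be overridden.
    """

    family: str
    size: tuple[int, int] = (64, 64)
    geometry: dict[str, Any] = dc_field(default_factory=dict)
    intensities: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        rows, cols = self.size
        if rows < 16 or cols < 16:
            raise ValueError(f"size must be at least 16x16, got {self.size}")
        for name, val in self.intensities.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"intensity {name!r}={val} outside [0, 1]")


@dataclass
class NoiseSpec:
    """Salt-&-pepper corruption: each pixel is replaced with probability ``var``."""

    kind: str = "salt_pepper"
    var: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "salt_pepper":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.var <= 1.0:
            raise ValueError(f"noise var must lie in [0, 1], got {self.var}")


@dataclass
class GroundTruth:
    """Ideal boundary, object mask and named scoring regions for a fixture.

    ``regions`` may contain a ``"concavity"`` mask (the indentation a snake
    should enter) and/or a ``"forbidden"`` mask (an area the target contour
    must not invade, e.g. the neighbouring object's interior).
    """

    boundary: np.ndarray  # (N, 2) array of (x, y) points, implicitly closed
    object_mask: np.ndarray  # bool grid
    regions: dict[str, np.ndarray] = dc_field(default_factory=dict)


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a binary mask, as (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    longest = max(contours, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


def _check_fits(name: str, lo: float, hi: float, limit: int) -> None:
    if lo < 2 or hi > limit - 2:
        raise ValueError(
            f"geometry parameter {name!r} does not fit the grid with a 2-pixel margin"
        )


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# family builders


def _build_impulse_edges(spec: ShapeSpec):
    """One single-pixel impulse, one full-height strong edge, one weak edge.

    Geometry: ``impulse`` (x, y) position, ``weak_col``, ``strong_col``.
    Intensities: ``impulse`` (1.0), ``strong`` (1.0), ``weak`` (0.85),
    ``background`` (0.0).  Defaults render features as high-charge pixels on
    a zero background; flip the values to get the opposite polarity.
    """
    rows, cols = spec.size
    g = spec.geometry
    ix, iy = g.get("impulse", (cols // 4, rows // 2))
    weak_col = g.get("weak_col", (5 * cols) // 8)
    strong_col = g.get("strong_col", (7 * cols) // 8)
    _check_fits("impulse", min(ix, iy), max(ix, iy), min(rows, cols))
    _check_fits("weak_col", weak_col, weak_col, cols)
    _check_fits("strong_col", strong_col, strong_col, cols)
    vals = spec.intensities
    img = np.full((rows, cols), vals.get("background", 0.0))
    img[iy, ix] = vals.get("impulse", 1.0)
    img[:, weak_col] = vals.get("weak", 0.85)
    img[:, strong_col] = vals.get("strong", 1.0)

    impulse_mask = np.zeros((rows, cols), dtype=bool)
    impulse_mask[iy, ix] = True
    weak_mask = np.zeros_like(impulse_mask)
    weak_mask[:, weak_col] = True
    strong_mask = np.zeros_like(impulse_mask)
    strong_mask[:, strong_col] = True
    object_mask = weak_mask | strong_mask
    boundary = _mask_boundary(weak_mask)
    regions = {"impulse": impulse_mask, "weak_edge": weak_mask, "strong_edge": strong_mask}
    return img, GroundTruth(boundary, object_mask, regions)


def _notched_block(spec: ShapeSpec, notches):
    """Rectangular block with axis-aligned notches; shared by U/S/3 shapes."""
    rows, cols = spec.size
    sy, sx = rows / 64.0, cols / 64.0  # geometry scales with the canvas
    g = spec.geometry
    r0 = g.get("top", round(14 * sy))
    r1 = g.get("bottom", round(50 * sy))
    c0 = g.get("left", round(18 * sx))
    c1 = g.get("right", round(46 * sx))
    _check_fits("top/bottom", r0, r1, rows)
    _check_fits("left/right", c0, c1, cols)
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r1, c0:c1] = True
    concavity = np.zeros_like(mask)
    for nr0, nr1, nc0, nc1 in notches(r0, r1, c0, c1, sy, sx):
        mask[nr0:nr1, nc0:nc1] = False
        concavity[nr0:nr1, nc0:nc1] = True
    img = np.full((rows, cols), spec.intensities.get("background", 0.0))
    img[mask] = spec.intensities.get("object", 1.0)
    gt = GroundTruth(_mask_boundary(mask), mask, {"concavity": concavity})
    return img, gt


def _build_ushape(spec: ShapeSpec):
    """Block with one notch entering from the top: the classic open U."""

    def notches(r0, r1, c0, c1, sy, sx):
        w = spec.geometry.get("notch_width", round(12 * sx))
        d = spec.geometry.get("notch_depth", round(24 * sy))
        cmid = (c0 + c1) // 2
        return [(r0, r0 + d, cmid - w // 2, cmid - w // 2 + w)]

    return _notched_block(spec, notches)


def _build_sshape(spec: ShapeSpec):
    """Two U-shapes glued head-to-tail: notches from the left and the right."""

    def notches(r0, r1, c0, c1, sy, sx):
        w = spec.geometry.get("notch_width", round(10 * sy))
        d = spec.geometry.get("notch_depth", round(20 * sx))
        third = (r1 - r0) // 3
        return [
            (r0 + third - w // 2, r0 + third + w - w // 2, c0, c0 + d),
            (r1 - third - w // 2, r1 - third + w - w // 2, c1 - d, c1),
        ]

    return _notched_block(spec, notches)


def _build_threeshape(spec: ShapeSpec):
    """Two U-shapes stacked the same way: both notches open to the left."""

    def notches(r0, r1, c0, c1, sy, sx):
        w = spec.geometry.get("notch_width", round(10 * sy))
        d = spec.geometry.get("notch_depth", round(20 * sx))
        third = (r1 - r0) // 3
        return [
            (r0 + third - w // 2, r0 + third + w - w // 2, c0, c0 + d),
            (r1 - third - w // 2, r1 - third + w - w // 2, c0, c0 + d),
        ]

    return _notched_block(spec, notches)


def _build_cshape(spec: ShapeSpec):
    """Annulus with a narrow angular mouth: a semi-closed, blob-like concavity.

    Geometry: ``outer_radius`` (19·scale), ``inner_radius`` (8·scale),
    ``mouth_deg`` (40, full opening angle, centered on the +x axis).
    The mouth is narrower than the interior, which is what makes the C
    harder than the open U.
    """
    rows, cols = spec.size
    scale = min(rows, cols) / 64.0
    g = spec.geometry
    R = g.get("outer_radius", 19 * scale)
    rin = g.get("inner_radius", 8 * scale)
    mouth = np.deg2rad(g.get("mouth_deg", 40.0)) / 2.0
    cy, cx = rows / 2.0 - 0.5, cols / 2.0 - 0.5
    _check_fits("outer_radius", cy - R, cy + R, rows)
    if rin >= R:
        raise ValueError("geometry parameter 'inner_radius' must be below 'outer_radius'")
    yy, xx = np.mgrid[0:rows, 0:cols]
    rho = np.hypot(yy - cy, xx - cx)
    phi = np.arctan2(yy - cy, xx - cx)
    ring = (rho <= R) & (rho >= rin)
    mask = ring & (np.abs(phi) > mouth)
    concavity = (rho <= R) & ~mask
    img = np.full((rows, cols), spec.intensities.get("background", 0.0))
    img[mask] = spec.intensities.get("object", 1.0)
    return img, GroundTruth(_mask_boundary(mask), mask, {"concavity": concavity})


def _build_gshape(spec: ShapeSpec):
    """Inward-spiralling stroke: a concavity whose orientation rotates.

    An Archimedean band from the outer radius down to an inner radius over
    ``turns`` revolutions.  Geometry: ``outer_radius`` (19·scale),
    ``inner_radius`` (6·scale), ``turns`` (1.25), ``stroke_width`` (5·scale).
    The concavity (everything inside the outer radius that is not stroke)
    is a rotating channel, larger than the C-shape's interior at the same
    bounding box.
    """
    rows, cols = spec.size
    scale = min(rows, cols) / 64.0
    g = spec.geometry
    R = g.get("outer_radius", 19 * scale)
    rin = g.get("inner_radius", 6 * scale)
    turns = g.get("turns", 1.25)
    half_w = g.get("stroke_width", 5 * scale) / 2.0
    cy, cx = rows / 2.0 - 0.5, cols / 2.0 - 0.5
    _check_fits("outer_radius", cy - R, cy + R, rows)
    theta_max = turns * 2.0 * np.pi
    yy, xx = np.mgrid[0:rows, 0:cols]
    rho = np.hypot(yy - cy, xx - cx)
    phi = np.mod(np.arctan2(yy - cy, xx - cx), 2.0 * np.pi)
    mask = np.zeros((rows, cols), dtype=bool)
    # stroke radius decreases linearly with unwound angle theta = phi + 2*pi*k
    k_max = int(np.ceil(turns)) + 1
    for k in range(k_max):
        theta = phi + 2.0 * np.pi * k
        on_turn = theta <= theta_max
        r_stroke = R - (R - rin) * theta / theta_max
        mask |= on_turn & (np.abs(rho - r_stroke) <= half_w)
    concavity = (rho <= R) & ~mask
    img = np.full((rows, cols), spec.intensities.get("background", 0.0))
    img[mask] = spec.intensities.get("object", 1.0)
    return img, GroundTruth(_mask_boundary(mask), mask, {"concavity": concavity})


def _build_line_drawing(spec: ShapeSpec):
    """Thin curves on an N x N grid: a circle, a diagonal and a sine arc.

    The drawn pixels are the charges (use the identity edge-map mode).
    Scales to any N so it doubles as a workload generator for timing the
    convolution-based fields.
    """
    rows, cols = spec.size
    from skimage import draw

    img = np.full((rows, cols), spec.intensities.get("background", 0.0))
    ink = spec.intensities.get("ink", 1.0)
    cy, cx = rows // 2, cols // 2
    radius = min(rows, cols) // 4
    rr, cc = draw.circle_perimeter(cy, cx, radius, shape=img.shape)
    img[rr, cc] = ink
    rr, cc = draw.line(2, 2, rows - 3, cols - 3)
    img[rr, cc] = ink
    x = np.arange(2, cols - 2)
    y = (rows // 6 + (rows // 12) * np.sin(4.0 * np.pi * x / cols)).round().astype(int)
    img[np.clip(y, 0, rows - 1), x] = ink
    mask = img > 0
    return img, GroundTruth(_mask_boundary(mask), mask, {})


def _build_two_objects(spec: ShapeSpec):
    """Gray disk and white rectangle separated by a thin background gap.

    Geometry: ``disk_center`` (x, y), ``disk_radius`` (10·scale), ``gap``
    (3 px of background between the disk's rightmost pixel and the
    rectangle).  Intensities: ``disk`` 0.4 (weak edge), ``rectangle`` 1.0
    (strong edge), ``background`` 0.  The ground-truth boundary is the
    disk's — the snake's target — and the rectangle interior is the
    forbidden region for leakage scoring.
    """
    rows, cols = spec.size
    scale = min(rows, cols) / 64.0
    g = spec.geometry
    radius = g.get("disk_radius", round(10 * scale))
    dcx, dcy = g.get("disk_center", (round(20 * scale), rows // 2))
    gap = g.get("gap", 3)
    _check_fits("disk_radius", min(dcx, dcy) - radius, max(dcx, dcy) + radius, min(rows, cols))
    rect_left = dcx + radius + 1 + gap
    rect_right = g.get("rect_right", cols - round(12 * scale))
    rect_top = g.get("rect_top", round(14 * scale))
    rect_bottom = g.get("rect_bottom", rows - round(14 * scale))
    _check_fits("gap", rect_left, rect_right, cols)
    disk = _disk_mask((rows, cols), dcy, dcx, radius)
    rect = np.zeros((rows, cols), dtype=bool)
    rect[rect_top:rect_bottom, rect_left:rect_right] = True
    img = np.full((rows, cols), spec.intensities.get("background", 0.0))
    img[disk] = spec.intensities.get("disk", 0.4)
    img[rect] = spec.intensities.get("rectangle", 1.0)
    return img, GroundTruth(_mask_boundary(disk), disk, {"forbidden": rect})


_BUILDERS = {
    "impulse_edges": _build_impulse_edges,
    "ushape": _build_ushape,
    "sshape": _build_sshape,
    "threeshape": _build_threeshape,
    "cshape": _build_cshape,
    "gshape": _build_gshape,
    "line_drawing": _build_line_drawing,
    "two_objects": _build_two_objects,
}


def make_shape_image(spec: ShapeSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw the requested fixture; deterministic for a given spec."""
    img, gt = _BUILDERS[spec.family](spec)
    assert img.min() >= 0.0 and img.max() <= 1.0
    return img, gt


def ground_truth_regions(spec: ShapeSpec) -> GroundTruth:
    """Ground truth only (boundary, mask, named scoring regions)."""
    _, gt = make_shape_image(spec)
    return gt


def add_salt_pepper(img: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Salt-&-pepper corruption with MATLAB ``imnoise`` semantics.

    Each pixel is independently corrupted with probability ``noise.var``;
    a corrupted pixel becomes 0 or 1 with equal probability.  The same
    seed always yields the same output.
    """
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    rng = np.random.default_rng(noise.seed)
    corrupt = rng.random(img.shape) < noise.var
    salt = rng.random(img.shape) < 0.5
    out = img.copy()
    out[corrupt & salt] = 1.0
    out[corrupt & ~salt] = 0.0
    return out
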