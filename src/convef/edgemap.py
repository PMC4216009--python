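"""Gaussian smoothing, finite-difference gradients and edge-map construction.

Every external force in :mod:`convef.forces` is sourced by a nonnegative
edge map ``f`` (equivalently a "charge" image ``q``): a scalar grid that is
large near the boundaries the snake should be attracted to.  This module
builds that map from a grayscale image.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, origin at the top-left, pixel centers at
integer coordinates.  A :class:`VectorField` therefore stores the
x-component ``u`` and the y-component ``v`` as two grids of equal shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["VectorField", "EdgeMap", "smooth", "gradient", "edge_map", "EDGE_MODES"]

EDGE_MODES = ("magnitude", "squared_magnitude", "identity")


@dataclass
class VectorField:
    """A per-pixel 2-D vector field: ``u`` holds x-components, ``v`` y-components."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError(f"component shapes differ: {self.u.shape} vs {self.v.shape}")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("vector field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def normalized(self, eps: float = 1e-12) -> "VectorField":
        """Unit vectors where magnitude exceeds ``eps``, zero elsewhere."""
        if eps <= 0:
            raise ValueError("eps must be positive")
        mag = self.magnitude()
        scale = np.where(mag > eps, 1.0 / np.maximum(mag, eps), 0.0)
        return VectorField(self.u * scale, self.v * scale)


@dataclass
class EdgeMap:
    """Nonnegative scalar grid acting as the charge distribution q.

    ``values`` is normalized so its maximum is 1 when nonzero; ``sigma`` and
    ``mode`` record how the map was derived from its source image.
    """

    values: np.ndarray
    sigma: float = 0.0
    mode: str = "identity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("edge map must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth an image.

    The kernel is truncated at radius ``ceil(4*sigma)`` and renormalized to
    unit sum, so constant images pass through unchanged.  Borders are
    handled by reflection.  ``sigma=0`` is the identity.
    """
    img = np.asarray(img, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return img.copy()
    radius = math.ceil(4.0 * sigma)
    return ndimage.gaussian_filter(img, sigma, mode="reflect", radius=radius)


def gradient(grid: np.ndarray) -> VectorField:
    """Finite-difference gradient of a scalar grid.

    Central differences in the interior; at the borders the grid is treated
    as replicated (Neumann), i.e. the outside neighbour equals the border
    value.  Returns (u, v) = (d/dx, d/dy).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or min(grid.shape) < 3:
        raise ValueError("gradient requires a 2-D grid of at least 3x3")
    padded = np.pad(grid, 1, mode="edge")
    u = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    v = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    return VectorField(u, v)


def edge_map(img: np.ndarray, sigma: float = 0.0, mode: str = "magnitude") -> EdgeMap:
    """Build the edge map / charge image from a grayscale image.

    Modes
    -----
    ``magnitude``
        ``|grad(G_sigma * I)|`` normalized to max 1 — the usual choice for
        intensity images with step boundaries.
    ``squared_magnitude``
        Same, squared before normalization; sharpens the contrast between
        strong and weak edges.
    ``identity``
        The (smoothed) image itself.  Used for charge-style inputs such as
        line drawings or the impulse/strong/weak panel, where the drawn
        features already *are* the charges.
    """
    if mode not in EDGE_MODES:
        raise ValueError(f"unknown edge-map mode {mode!r}; choose from {EDGE_MODES}")
    blurred = smooth(img, sigma)
    if mode == "identity":
        values = np.maximum(blurred, 0.0)
    else:
        g = gradient(blurred)
        values = g.magnitude()
        if mode == "squared_magnitude":
            values = values**2
    peak = values.max()
    if peak > 0:
        values = values / peak
    return EdgeMap(values=values, sigma=sigma, mode=mode)
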