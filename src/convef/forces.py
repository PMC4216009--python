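"""The external-force family: GVF, VEF, VFC and CONVEF.

All fields here share one job: turn an edge map into a vector field that
pulls a snake toward boundaries from far away.  Two computational routes
exist.

* **GVF** (gradient vector flow) diffuses the edge-map gradient by
  iterating an explicit finite-difference scheme for a pair of PDEs — the
  classic, but expensive, choice.
* **VEF / VFC / CONVEF** are single convolutions of the edge map with a
  radial vector kernel, evaluated by FFT, so their cost is independent of
  the number of iterations GVF would need.

Treating each edge pixel as a point charge of magnitude ``q`` gives the
virtual electric field (VEF): per charge, a Coulomb-style attraction with
kernel ``-(x, y) / r^3``.  Vector field convolution (VFC) generalizes the
radial profile to ``m1(r) = 1/r^gamma`` or ``m2(r) = exp(-r^2/zeta^2)``.
CONVEF keeps the electrostatic derivation but modifies the distance to
``r_h = sqrt(x^2 + y^2 + h)`` and relaxes the potential decay exponent to
``n``:

    potential kernel  1 / r_h^n
    field kernel      -(x, y) / r_h^(n+2)    (a constant factor n dropped)

``h`` acts like a scale-space parameter (larger ``h`` down-weights nearby
charges, suppressing impulsive noise); ``n`` controls how fast influence
decays with distance (large ``n`` preserves weak edges and separates
neighbouring objects, small ``n`` lets the field reach into semi-closed
concavities).  At ``h=0, n=1`` CONVEF reduces exactly to VEF.

Fields are defined up to a positive scalar (dropped constants); users
should rely on direction and relative magnitude, or normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal

from .edgemap import EdgeMap, VectorField, gradient

__all__ = [
    "KernelSpec",
    "GvfParams",
    "fft_convolve",
    "convef_field",
    "vef_field",
    "vfc_field",
    "gvf_field",
    "gvf_energy",
    "normalize_field",
    "convef_kernels",
    "vfc_kernel",
]

KERNEL_FAMILIES = ("vef", "vfc_m1", "vfc_m2", "convef")


@dataclass
class KernelSpec:
    """Parametric description of a convolution kernel.

    Parameters irrelevant to the chosen family are ignored.  ``radius``
    is the half-width ``t`` of the square support ``[-t, t]^2``; ``None``
    means "as large as the image" (kernel side comparable to the image
    side), the default used throughout the experiments.
    """

    family: str = "convef"
    n: float = 1.0
    h: float = 0.0
    gamma: float = 2.0
    zeta: float = 3.0
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "convef":
            if self.n <= 0:
                raise ValueError("CONVEF exponent n must be positive")
            if self.h < 0:
                raise ValueError("CONVEF smoothing factor h must be nonnegative")
        if self.family == "vfc_m1" and self.gamma <= 0:
            raise ValueError("VFC m1 exponent gamma must be positive")
        if self.family == "vfc_m2" and self.zeta <= 0:
            raise ValueError("VFC m2 scale zeta must be positive")
        if self.radius is not None and self.radius < 1:
            raise ValueError("kernel radius must be >= 1")


@dataclass
class GvfParams:
    """GVF diffusion parameters.

    ``dt=None`` selects the explicit-scheme stability bound at run time:
    ``dt = 2 / (8*mu + max(f_x^2 + f_y^2))`` for unit pixel spacing.  The
    diffusion-only bound ``dt*mu <= 1/4`` is necessary but not sufficient —
    the data-fidelity term tightens it wherever the edge gradient is
    nonzero, and ignoring it makes the iteration diverge.
    """

    mu: float = 0.2
    iterations: int = 200
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")
        if self.dt is not None and self.dt * self.mu > 0.25 + 1e-12:
            raise ValueError(
                f"explicit scheme unstable: dt*mu = {self.dt * self.mu:.4g} > 1/4; "
                f"use dt <= {0.25 / self.mu:.4g}"
            )

    def stable_dt(self, b_max: float) -> float:
        """Largest stable explicit time step given the data-term ceiling ``b_max``."""
        return 2.0 / (8.0 * self.mu + b_max)


def fft_convolve(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Linear (zero-padded) 2-D convolution via FFT, cropped to ``grid.shape``.

    The output is centered on the kernel origin, so convolving with a unit
    impulse at the kernel center is the identity.  Kernel sides must be odd
    so the origin is unambiguous.
    """
    grid = np.asarray(grid, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if grid.size == 0 or kernel.size == 0:
        raise ValueError("empty input to fft_convolve")
    if any(s % 2 == 0 for s in kernel.shape):
        raise ValueError(f"kernel sides must be odd, got {kernel.shape}")
    return signal.fftconvolve(grid, kernel, mode="same")


def _charges(q: "EdgeMap | np.ndarray") -> np.ndarray:
    values = q.values if isinstance(q, EdgeMap) else np.asarray(q, dtype=float)
    if values.ndim != 2:
        raise ValueError("edge map must be 2-D")
    if np.any(values < 0):
        raise ValueError("edge map must be nonnegative")
    return values


def _offsets(shape: tuple[int, int], radius: int | None) -> tuple[np.ndarray, np.ndarray]:
    if radius is None:
        # kernel side comparable to the image side
        radius = max(shape) // 2
    radius = int(radius)
    o = np.arange(-radius, radius + 1, dtype=float)
    x, y = np.meshgrid(o, o)  # x varies along columns, y along rows
    return x, y


def convef_kernels(
    shape: tuple[int, int], n: float, h: float, radius: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CONVEF potential kernel ``1/r_h^n`` and vector kernel ``-(x,y)/r_h^(n+2)``.

    With ``h=0`` the origin value is set to 0 (a charge exerts no force on
    itself, matching the VEF convention).
    """
    x, y = _offsets(shape, radius)
    r2h = x**2 + y**2 + h
    center = (x.shape[0] // 2, x.shape[1] // 2)
    if h == 0:
        r2h[center] = 1.0  # placeholder, zeroed below
    pot = r2h ** (-n / 2.0)
    kx = -x * r2h ** (-(n + 2.0) / 2.0)
    ky = -y * r2h ** (-(n + 2.0) / 2.0)
    if h == 0:
        pot[center] = 0.0
    kx[center] = 0.0
    ky[center] = 0.0
    return pot, kx, ky


def vfc_kernel(
    shape: tuple[int, int], spec: KernelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """VFC vector kernel ``m(r) * (-x/r, -y/r)`` for magnitude m1 or m2."""
    x, y = _offsets(shape, spec.radius)
    r = np.hypot(x, y)
    center = (x.shape[0] // 2, x.shape[1] // 2)
    r[center] = 1.0  # direction undefined at the origin; zeroed below
    if spec.family == "vfc_m1":
        m = r ** (-spec.gamma)
    else:
        m = np.exp(-(r**2) / spec.zeta**2)
    kx = -m * x / r
    ky = -m * y / r
    kx[center] = 0.0
    ky[center] = 0.0
    return kx, ky


def convef_field(
    q: "EdgeMap | np.ndarray", spec: KernelSpec | None = None, **kwargs
) -> tuple[VectorField, np.ndarray]:
    """CONVEF external force and its scalar potential (VEP).

    Returns ``(field, potential)`` where ``field = q (*) vector kernel`` and
    ``potential = q (*) potential kernel``; the field is the (continuous)
    gradient of the potential up to the dropped constant ``n`` and the
    attractive sign convention — vectors point toward charges.
    """
    if spec is None:
        spec = KernelSpec(family="convef", **kwargs)
    if spec.family != "convef":
        raise ValueError("convef_field requires a 'convef' KernelSpec")
    values = _charges(q)
    pot_k, kx, ky = convef_kernels(values.shape, spec.n, spec.h, spec.radius)
    u = fft_convolve(values, kx)
    v = fft_convolve(values, ky)
    potential = fft_convolve(values, pot_k)
    return VectorField(u, v), potential


def vef_field(q: "EdgeMap | np.ndarray", radius: int | None = None) -> VectorField:
    """Virtual electric field: Coulomb attraction summed over all charges.

    Identical to :func:`convef_field` with ``h=0, n=1`` (per-charge force
    magnitude proportional to ``1/r^2``).
    """
    field, _ = convef_field(q, KernelSpec(family="convef", n=1.0, h=0.0, radius=radius))
    return field


def vfc_field(q: "EdgeMap | np.ndarray", spec: KernelSpec) -> VectorField:
    """Vector field convolution with magnitude ``m1 = 1/r^gamma`` or ``m2 = exp(-r^2/zeta^2)``."""
    if spec.family not in ("vfc_m1", "vfc_m2"):
        raise ValueError("vfc_field requires a 'vfc_m1' or 'vfc_m2' KernelSpec")
    values = _charges(q)
    kx, ky = vfc_kernel(values.shape, spec)
    return VectorField(fft_convolve(values, kx), fft_convolve(values, ky))


def _laplacian(a: np.ndarray) -> np.ndarray:
    """5-point Laplacian with replicated (Neumann) borders."""
    p = np.pad(a, 1, mode="edge")
    return p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1] - 4.0 * a


def gvf_field(
    f: "EdgeMap | np.ndarray",
    params: GvfParams | None = None,
    return_energy: bool = False,
) -> "VectorField | tuple[VectorField, np.ndarray]":
    """Gradient vector flow by explicit-scheme diffusion.

    Starting from the edge-map gradient ``(f_x, f_y)``, each component is
    iterated as ``u <- u + dt * (mu * lap(u) - (u - f_x) * (f_x^2 + f_y^2))``
    and likewise for ``v``.  With ``iterations=0`` the result is exactly the
    gradient of ``f``.  When ``return_energy`` is set, the per-iteration
    discrete GVF energy (smoothness plus data-fidelity terms, summed over
    pixels) is returned alongside the field for convergence monitoring.
    """
    if params is None:
        params = GvfParams()
    values = f.values if isinstance(f, EdgeMap) else np.asarray(f, dtype=float)
    g = gradient(values)
    fx, fy = g.u, g.v
    b = fx**2 + fy**2
    bound = params.stable_dt(float(b.max()))
    if params.dt is None:
        params = GvfParams(mu=params.mu, iterations=params.iterations, dt=bound)
    elif params.dt > bound + 1e-12:
        raise ValueError(
            f"explicit scheme unstable for this edge map: dt = {params.dt:.4g} "
            f"exceeds the admissible bound {bound:.4g}"
        )
    u = fx.copy()
    v = fy.copy()
    energies = np.empty(params.iterations + 1)
    if return_energy:
        energies[0] = gvf_energy(VectorField(u, v), fx, fy, params.mu)
    for it in range(params.iterations):
        u = u + params.dt * (params.mu * _laplacian(u) - (u - fx) * b)
        v = v + params.dt * (params.mu * _laplacian(v) - (v - fy) * b)
        if return_energy:
            energies[it + 1] = gvf_energy(VectorField(u, v), fx, fy, params.mu)
    field = VectorField(u, v)
    if return_energy:
        return field, energies
    return field


def gvf_energy(field: VectorField, fx: np.ndarray, fy: np.ndarray, mu: float) -> float:
    """Discrete GVF functional: mu * |grad(u,v)|^2 + |grad f|^2 * |(u,v)-(f_x,f_y)|^2.

    The smoothness term uses forward differences so that the 5-point
    Laplacian of the explicit scheme is exactly its negative gradient —
    this makes the returned energy the Lyapunov function of the iteration.
    """
    smoothness = 0.0
    for a in (field.u, field.v):
        smoothness += np.sum(np.diff(a, axis=0) ** 2) + np.sum(np.diff(a, axis=1) ** 2)
    data = np.sum((fx**2 + fy**2) * ((field.u - fx) ** 2 + (field.v - fy) ** 2))
    return float(mu * smoothness + data)


def normalize_field(field: VectorField, eps: float = 1e-12) -> VectorField:
    """Scale each vector to unit length where its magnitude exceeds ``eps``."""
    return field.normalized(eps)
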