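"""Config-driven experiment runs: fixture -> edge map -> field -> snake -> score.

A :class:`RunConfig` captures everything needed to reproduce one
segmentation run on a synthetic fixture.  Unknown keys are rejected at
parse time, and every run can persist its resolved configuration next to
its outputs, so any artifact is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as cio
from .edgemap import edge_map
from .fixtures import NoiseSpec, ShapeSpec, add_salt_pepper, make_shape_image
from .forces import GvfParams, KernelSpec, convef_field, gvf_field, vef_field, vfc_field
from .metrics import ConvergenceReport, score_contour
from .snake import SnakeParams, evolve, init_contour

__all__ = ["RunConfig", "compute_field", "run_experiment"]

METHODS = ("gvf", "vef", "vfc_m1", "vfc_m2", "convef")


@dataclass
class RunConfig:
    """Resolved configuration for one fixture-to-report run."""

    family: str = "ushape"
    size: tuple[int, int] = (64, 64)
    geometry: dict[str, Any] = dc_field(default_factory=dict)
    intensities: dict[str, float] = dc_field(default_factory=dict)
    noise_var: float = 0.0
    seed: int = 0

    sigma: float = 0.0
    edge_mode: str = "magnitude"

    method: str = "convef"
    n: float = 2.0
    h: float = 6.0
    gamma: float = 2.0
    zeta: float = 3.0
    radius: int | None = None
    mu: float = 0.2
    iterations: int = 200

    init_kind: str = "circle"
    init_center: tuple[float, float] | None = None
    init_radius: float | None = None
    init_points: int = 100
    alpha: float = 0.5
    beta: float = 0.1
    tau: float = 1.0
    kappa: float = 1.0
    max_iters: int = 400
    tol: float = 0.05
    d_tol: float = 2.0

    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(data)
        for key in ("size", "init_center"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_field(config: RunConfig, em):
    """Dispatch the external-force computation for the configured method."""
    if config.method == "gvf":
        return gvf_field(em, GvfParams(mu=config.mu, iterations=config.iterations))
    if config.method == "vef":
        return vef_field(em, radius=config.radius)
    if config.method in ("vfc_m1", "vfc_m2"):
        spec = KernelSpec(
            family=config.method, gamma=config.gamma, zeta=config.zeta, radius=config.radius
        )
        return vfc_field(em, spec)
    field, _ = convef_field(
        em, KernelSpec(family="convef", n=config.n, h=config.h, radius=config.radius)
    )
    return field


def run_experiment(config: RunConfig) -> ConvergenceReport:
    """Run the full pipeline on a synthetic fixture and score the result.

    Deterministic for a given config (the only randomness is the noise
    seed).  If ``config.output_dir`` is set, the image, field, final
    contour, report and the resolved config are persisted there.
    """
    spec = ShapeSpec(
        family=config.family,
        size=config.size,
        geometry=config.geometry,
        intensities=config.intensities,
    )
    try:
        img, gt = make_shape_image(spec)
        if config.noise_var > 0:
            img = add_salt_pepper(img, NoiseSpec(var=config.noise_var, seed=config.seed))
    except Exception as exc:
        raise RuntimeError(f"fixture stage failed: {exc}") from exc

    try:
        em = edge_map(img, sigma=config.sigma, mode=config.edge_mode)
    except Exception as exc:
        raise RuntimeError(f"edge-map stage failed: {exc}") from exc

    try:
        field = compute_field(config, em)
    except Exception as exc:
        raise RuntimeError(f"field stage failed: {exc}") from exc

    try:
        center = config.init_center
        radius = config.init_radius
        if center is None or radius is None:
            ys, xs = np.nonzero(gt.object_mask)
            auto_center = (float(xs.mean()), float(ys.mean()))
            spread = float(np.hypot(xs - auto_center[0], ys - auto_center[1]).max())
            center = center or auto_center
            radius = radius or 1.3 * spread
        c0 = init_contour(
            config.init_kind, {"center": center, "radius": radius}, config.init_points
        )
        params = SnakeParams(
            alpha=config.alpha,
            beta=config.beta,
            tau=config.tau,
            kappa=config.kappa,
            max_iters=config.max_iters,
            tol=config.tol,
        )
        result = evolve(c0, field, params)
    except Exception as exc:
        raise RuntimeError(f"snake stage failed: {exc}") from exc

    try:
        report = score_contour(result.final, gt, converged=result.converged, d_tol=config.d_tol)
    except Exception as exc:
        raise RuntimeError(f"metrics stage failed: {exc}") from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_image(img, out / "image.png")
        cio.write_field(field, out / "field.tif", {"method": config.method})
        cio.write_contour(result.final, out / "contour.csv")
        cio.write_ground_truth(gt, out / "ground_truth.json")
        (out / "report.json").write_text(json.dumps(dataclasses.asdict(report)))
        (out / "config.json").write_text(json.dumps(config.to_dict()))
    return report
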