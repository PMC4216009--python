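"""Reading images, persisting vector fields, contours and ground truth.

Vector fields travel as 2-band 32-bit float TIFFs (band 1 = u, band 2 = v)
with a JSON metadata blob in the image description — portable, lossless
and readable from any raster stack.  Contours are plain CSV ("x,y" per
vertex); ground truth round-trips through JSON with run-length-encoded
masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .edgemap import VectorField
from .fixtures import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "write_field",
    "read_field",
    "write_contour",
    "read_contour",
    "write_ground_truth",
    "read_ground_truth",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF as a float image in [0, 1].

    Multi-channel images are collapsed by the channel mean; integer data is
    rescaled by the dtype's maximum, float data is clipped to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    data = np.asarray(iio.imread(path))
    if data.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if data.ndim == 3:
        data = data.mean(axis=-1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return data.astype(float) / info.max
    return np.clip(data.astype(float), 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path, depth: str = "uint8") -> None:
    """Write a [0, 1] image as 8-bit PNG/TIFF or 32-bit float TIFF."""
    path = Path(path)
    img = np.asarray(img, dtype=float)
    if depth == "uint8":
        iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))
    elif depth == "float32":
        tifffile.imwrite(path, img.astype(np.float32))
    else:
        raise ValueError(f"unsupported depth {depth!r}")


def write_field(field: VectorField, path: str | Path, metadata: dict | None = None) -> None:
    """Persist a vector field as a 2-band float32 TIFF with JSON metadata."""
    stack = np.stack([field.u, field.v]).astype(np.float32)
    tifffile.imwrite(Path(path), stack, description=json.dumps(metadata or {}))


def read_field(path: str | Path) -> tuple[VectorField, dict]:
    """Inverse of :func:`write_field`; returns the field and its metadata."""
    with tifffile.TiffFile(Path(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or "{}"
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"expected a 2-band field file, got shape {stack.shape}")
    return VectorField(stack[0].astype(float), stack[1].astype(float)), json.loads(desc)


def write_contour(c: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(c, dtype=float), fmt="%.6f", delimiter=",", header="x,y")


def read_contour(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    return {
        "shape": list(mask.shape),
        "first": bool(flat[0]) if flat.size else False,
        "lengths": lengths.tolist(),
    }


def _rle_decode(blob: dict) -> np.ndarray:
    flat = np.empty(int(np.prod(blob["shape"])), dtype=bool)
    val = blob["first"]
    pos = 0
    for run in blob["lengths"]:
        flat[pos : pos + run] = val
        pos += run
        val = not val
    return flat.reshape(blob["shape"])


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "boundary": np.asarray(gt.boundary, dtype=float).tolist(),
        "object_mask": _rle_encode(gt.object_mask),
        "regions": {name: _rle_encode(mask) for name, mask in gt.regions.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        boundary=np.asarray(payload["boundary"], dtype=float),
        object_mask=_rle_decode(payload["object_mask"]),
        regions={name: _rle_decode(blob) for name, blob in payload["regions"].items()},
    )
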