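"""Raster I/O: TIFF reading and writing for 2D images and 3D stacks."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_raster", "write_raster"]

log = logging.getLogger("blindau")


def read_raster(path: str | Path) -> np.ndarray:
    """Read a TIFF into a float array; multi-page stacks come back page-major
    with shape ``(pages, H, W)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such raster file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"could not read {path} as TIFF: {exc}") from exc
    return np.asarray(data, dtype=float)


def write_raster(
    raster: np.ndarray,
    path: str | Path,
    dtype: str = "float32",
    scale_16bit: bool = False,
) -> None:
    """Write a raster as TIFF.

    ``dtype="float32"`` round-trips values losslessly (up to float32
    precision).  ``dtype="uint16"`` clips negatives to 0 (with a logged
    warning) and, when ``scale_16bit`` is set, rescales the maximum to
    65535 before quantizing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "float32":
        tifffile.imwrite(path, np.asarray(raster, dtype=np.float32))
    elif dtype == "uint16":
        data = np.asarray(raster, dtype=float)
        if np.any(data < 0):
            log.warning("negative values clipped to 0 while writing %s as uint16", path)
            data = np.clip(data, 0, None)
        if scale_16bit and data.max() > 0:
            data = data * (65535.0 / data.max())
        tifffile.imwrite(path, np.clip(data, 0, 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'float32' or 'uint16'")
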