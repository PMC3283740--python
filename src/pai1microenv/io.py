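"""Reading and writing fields, masks and results in plain-text and raster formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import ConfigurationError
from .lattice import Grid, OccupancyMask, ScalarField

__all__ = [
    "save_field_txt",
    "load_field_txt",
    "save_field_tiff",
    "load_field_tiff",
    "save_mask_png",
    "load_mask_png",
    "save_json",
    "load_json",
]


def save_field_txt(field: ScalarField, path: str | Path) -> None:
    """Delimited text grid, one row per lattice row."""
    np.savetxt(path, field.values, fmt="%.10g", delimiter="\t")


def load_field_txt(path: str | Path, spacing: float = 1.0) -> ScalarField:
    vals = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    h, w = vals.shape
    return ScalarField(Grid(w, h, spacing), vals)


def save_field_tiff(field: ScalarField, path: str | Path) -> None:
    tifffile.imwrite(str(path), field.values.astype(np.float32))


def load_field_tiff(path: str | Path, spacing: float = 1.0) -> ScalarField:
    vals = tifffile.imread(str(path)).astype(np.float64)
    if vals.ndim != 2:
        raise ConfigurationError(f"expected single-plane TIFF, got shape {vals.shape}")
    h, w = vals.shape
    return ScalarField(Grid(w, h, spacing), vals)


def save_mask_png(mask: OccupancyMask, path: str | Path) -> None:
    """8-bit PNG, 0 = empty matrix, 255 = tumor-occupied."""
    img = (mask.occupied.astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(str(path))


def load_mask_png(path: str | Path, spacing: float = 1.0) -> OccupancyMask:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    h, w = arr.shape
    return OccupancyMask(Grid(w, h, spacing), arr >= 128)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
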