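"""Artifact I/O: multiband TIFF rasters, CSV tables, JSON and hashing.

Rasters are plain (non-georeferenced) TIFFs; row/col pixel coordinates are
the only geometry the package carries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_tiff", "read_tiff", "write_json", "read_json", "sha256_of"]


def write_tiff(path, array: np.ndarray, band_names=None) -> Path:
    """Write a (bands, rows, cols) or (rows, cols) array as float32 TIFF."""
    path = Path(path)
    arr = np.asarray(array, dtype=np.float32)
    meta = {}
    if band_names is not None:
        meta["band_names"] = list(map(str, band_names))
    tifffile.imwrite(path, arr, metadata=meta)
    return path


def read_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
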