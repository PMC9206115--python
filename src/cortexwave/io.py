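"""Movie and result I/O with provenance manifests.

TIFF is the canonical movie container (grayscale, one file per channel);
metadata (dt, dx) travels in a YAML sidecar or via explicit arguments.
Every result directory gets a ``manifest.json`` recording file hashes,
package version, seed and the full parameter echo.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .wave_metrics import Movie

__all__ = ["read_movie", "write_movie", "write_outputs"]


def read_movie(path: Union[str, Path], dt: Optional[float] = None,
               dx: Optional[float] = None) -> Movie:
    """Load a multi-frame grayscale TIFF (or .npy stack) as a Movie.

    Integer intensities become float without rescaling.  dt/dx default
    to a ``<stem>.yaml`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".yaml")
    if (dt is None or dx is None) and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        dt = meta.get("dt") if dt is None else dt
        dx = meta.get("dx") if dx is None else dx
    if dt is None or dx is None:
        raise ValueError("dt and dx must be given (argument or sidecar)")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a (time, y, x) stack, "
                         f"got shape {data.shape}")
    return Movie(data.astype(float), float(dt), float(dx),
                 channel=path.stem)


def write_movie(movie: Movie, path: Union[str, Path]) -> Path:
    """Write a Movie as float32 TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.data.astype(np.float32))
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump(dict(dt=movie.dt, dx=movie.dx, channel=movie.channel)))
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_outputs(tables: dict, out_dir: Union[str, Path],
                  seed: Optional[int] = None,
                  params: Optional[dict] = None) -> dict:
    """Write named DataFrames/dicts as CSV/JSON plus a manifest.

    ``tables`` maps file stems to pandas DataFrames (written as CSV) or
    JSON-serializable objects.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for stem, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            fp = out_dir / f"{stem}.csv"
            obj.to_csv(fp, index=not isinstance(obj.index, pd.RangeIndex))
        else:
            fp = out_dir / f"{stem}.json"
            fp.write_text(json.dumps(_to_jsonable(obj), indent=2,
                                     sort_keys=True) + "\n")
        written[fp.name] = _sha256(fp)
    manifest = dict(version=__version__, seed=seed,
                    params=_to_jsonable(params) if params else None,
                    files=written)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
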