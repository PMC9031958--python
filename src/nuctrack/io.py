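"""Readers and writers.

Movies travel as multi-page grayscale TIFF (one page per frame) with a
JSON sidecar carrying the physical calibration (``pixel_size_um``,
``frame_interval_min``); a movie without calibration is a hard error —
pixel size is never assumed.

Tracked-object tables travel as CSV in the package's long schema
(track_id, frame, x_um, y_um, area_um2, length_c_um, length_b_um,
orientation_deg, ...).  CSV exports from Imaris surface tracking are also
accepted: their headers ("Position X", "BoundingBoxOO Length C",
"TrackID", "Time", ...) are mapped onto the internal schema and the
exported "Area" — which counts both faces of the 3D surface — is halved
exactly once, with the raw value kept in ``area_um2_raw`` for provenance.
Re-importing this package's own exports applies no correction.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometrics import correct_imaris_area
from .segmentation import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_table",
    "read_table",
    "import_imaris_csv",
    "write_ground_truth",
]

logger = logging.getLogger(__name__)

#: float precision used when writing tables (round-trips to < 1e-9)
_FLOAT_FORMAT = "%.12g"


def _sidecar_path(movie_path: Path) -> Path:
    return movie_path.with_suffix(".json")


def write_movie(path, frames: np.ndarray, pixel_size_um: float, frame_interval_min: float) -> Path:
    """Write a (n_frames, H, W) stack as multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a 3D (n_frames, H, W) stack")
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "pixel_size_um": float(pixel_size_um),
        "frame_interval_min": float(frame_interval_min),
        "n_frames": int(frames.shape[0]),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_movie(
    path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
) -> Movie:
    """Read a multi-page TIFF movie with its calibration.

    Calibration comes from the JSON sidecar next to the file, or from the
    explicit arguments (which take precedence).  If neither supplies both
    ``pixel_size_um`` and ``frame_interval_min``, this is an error.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a 2D+time single-series stack, got shape {frames.shape}"
        )
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = (
        frame_interval_min
        if frame_interval_min is not None
        else meta.get("frame_interval_min")
    )
    if px is None or dt is None:
        raise ValueError(
            f"{path}: missing calibration; supply pixel_size_um and "
            "frame_interval_min via the sidecar JSON or explicit arguments"
        )
    if "n_frames" in meta and int(meta["n_frames"]) != frames.shape[0]:
        raise ValueError(
            f"{path}: sidecar says {meta['n_frames']} frames but file has "
            f"{frames.shape[0]} pages (truncated file?)"
        )
    return Movie(frames=frames, pixel_size_um=float(px), frame_interval_min=float(dt))


def write_table(path, table: pd.DataFrame) -> Path:
    """Write a table as CSV with stable column order and full precision."""
    path = Path(path)
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_ground_truth(path, truth: pd.DataFrame) -> Path:
    """Write a simulator ground-truth table (CSV, full precision)."""
    return write_table(path, truth)


# --- Imaris CSV dialect -----------------------------------------------------

# header-substring -> internal column name (matching is case-insensitive and
# ignores unit suffixes like "Position X [µm]")
_IMARIS_COLUMN_MAP = [
    (r"track\s*id", "track_id"),
    (r"bounding\s*box\s*oo\s*length\s*c|boundingboxoo\s*length\s*c", "length_c_um"),
    (r"bounding\s*box\s*oo\s*length\s*b|boundingboxoo\s*length\s*b", "length_b_um"),
    (r"position\s*x", "x_um"),
    (r"position\s*y", "y_um"),
    (r"^area", "area_um2_raw"),
    (r"^time$|time\s*\[|time\s*index", "frame"),
]


def import_imaris_csv(path) -> pd.DataFrame:
    """Import an Imaris surface-tracking CSV export into the internal schema.

    Recognizes Imaris-style headers, renames them, converts the 1-based
    Imaris time index to 0-based frames, and applies the divide-by-2 area
    correction exactly once (raw values preserved in ``area_um2_raw``).

    A file already in this package's own schema (``x_um``/``track_id``
    columns) is returned unchanged — in particular no area correction is
    applied twice.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if {"track_id", "frame", "x_um", "y_um"}.issubset(cols):
        logger.info("%s: native schema detected, no Imaris correction applied", path)
        return df

    rename: dict[str, str] = {}
    for col in cols:
        key = col.strip().lower()
        for pattern, target in _IMARIS_COLUMN_MAP:
            if target not in rename.values() and re.search(pattern, key):
                rename[col] = target
                break
    required = {"track_id", "frame"}
    if not required.issubset(set(rename.values())):
        raise ValueError(
            f"{path}: no recognizable Imaris headers for {sorted(required - set(rename.values()))}; "
            f"columns found: {cols}"
        )
    out = df[list(rename)].rename(columns=rename)

    n_before = len(out)
    out = out.dropna(subset=["track_id", "frame"])
    if len(out) < n_before:
        logger.warning("%s: dropped %d unparseable rows", path, n_before - len(out))
    out["track_id"] = out["track_id"].astype(int)
    out["frame"] = out["frame"].astype(int) - 1  # Imaris time index is 1-based

    if "area_um2_raw" in out.columns:
        out["area_um2"] = correct_imaris_area(out["area_um2_raw"].to_numpy(float))
    if {"length_c_um", "length_b_um"}.issubset(out.columns):
        out["cb_ratio"] = out["length_c_um"] / out["length_b_um"]
    return out.sort_values(["track_id", "frame"], ignore_index=True)
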