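"""Per-track migration metrics and their population summaries.

Definitions:

* **Track Length** — the sum of Euclidean displacements between consecutive
  occupied frames of a track (µm).
* **Track Displacement** — the straight-line distance between the first and
  last position (µm).
* **Track Straightness** — Displacement / Length, in [0, 1]: 1 for a
  perfectly straight monotone path, near 0 for a closed or wandering path.
* **Instantaneous speed** — displacement between adjacent occupied frames
  divided by the elapsed time, in µm/h.
* **Alignment angle** — the acute angle between the nuclear major axis and
  the local track direction (degrees in [0, 90]); near-circular nuclei
  (C/B < 1.05) and near-stationary windows are masked.

Stationary tracks (length exactly 0) are assigned straightness 1 and
flagged, so the degenerate 0/0 case is auditable and excludable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .morphometrics import LOW_CONFIDENCE_CB

__all__ = [
    "TrackMetrics",
    "track_metrics",
    "track_metrics_table",
    "instantaneous_speeds",
    "StraightnessHistogram",
    "straightness_histogram",
    "reflected_kde",
    "alignment_series",
    "alignment_summary",
]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    track_length_um: float
    track_displacement_um: float
    straightness: float
    n_steps: int
    max_speed_um_hr: float
    stationary: bool = False


def _positions(track) -> tuple[int, np.ndarray, np.ndarray]:
    """Accept a Track or a per-track long DataFrame; return (id, frames, xy)."""
    if hasattr(track, "objects"):
        df, track_id = track.objects, track.track_id
    else:
        df = track
        ids = df["track_id"].unique() if "track_id" in df.columns else [-1]
        if len(ids) != 1:
            raise ValueError("expected a single track, got multiple track_ids")
        track_id = int(ids[0])
    df = df.sort_values("frame")
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    return int(track_id), frames, xy


def track_metrics(track, frame_interval_min: float = 5.0) -> TrackMetrics:
    """Compute length, displacement, straightness and peak speed of a track."""
    track_id, frames, xy = _positions(track)
    if len(xy) < 2:
        raise ValueError(f"track {track_id}: need >= 2 positions")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dframes = np.diff(frames)
    length = float(steps.sum())
    displacement = float(np.linalg.norm(xy[-1] - xy[0]))
    stationary = length == 0.0
    straightness = 1.0 if stationary else displacement / length
    speeds = steps * 60.0 / (dframes * frame_interval_min)
    return TrackMetrics(
        track_id=track_id,
        track_length_um=length,
        track_displacement_um=displacement,
        straightness=float(np.clip(straightness, 0.0, 1.0)),
        n_steps=len(steps),
        max_speed_um_hr=float(speeds.max()),
        stationary=stationary,
    )


def track_metrics_table(
    table: pd.DataFrame, frame_interval_min: float = 5.0
) -> pd.DataFrame:
    """Per-track metrics for every track in a long track table."""
    rows = [
        track_metrics(g, frame_interval_min)
        for _, g in table.groupby("track_id")
        if len(g) >= 2
    ]
    return pd.DataFrame([vars(m) for m in rows])


def instantaneous_speeds(
    table_or_track, frame_interval_min: float = 5.0
) -> pd.DataFrame:
    """Speed reads between adjacent occupied frames, in µm/h.

    Returns one row per step with ``track_id``, ``frame_start``,
    ``frame_end``, ``t_mid_min`` (midpoint time of the step, with frame f
    at f × frame_interval_min) and ``speed_um_hr``.  Steps over a gap
    divide by the actual elapsed time.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if hasattr(table_or_track, "objects") or "track_id" not in getattr(
        table_or_track, "columns", []
    ):
        groups = [_positions(table_or_track)]
    else:
        groups = [_positions(g) for _, g in table_or_track.groupby("track_id")]
    out = []
    for track_id, frames, xy in groups:
        if len(xy) < 2:
            continue
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        f0, f1 = frames[:-1], frames[1:]
        speed = steps * 60.0 / ((f1 - f0) * frame_interval_min)
        out.append(
            pd.DataFrame(
                {
                    "track_id": track_id,
                    "frame_start": f0,
                    "frame_end": f1,
                    "t_mid_min": (f0 + f1) / 2.0 * frame_interval_min,
                    "speed_um_hr": speed,
                }
            )
        )
    cols = ["track_id", "frame_start", "frame_end", "t_mid_min", "speed_um_hr"]
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=cols)


@dataclass
class StraightnessHistogram:
    """Binned straightness distribution with the top-bin summary.

    ``top_bin_fraction_pct`` is the percentage of tracks with straightness
    0.9 or greater (the last bin is closed at 1.0); None when the input is
    empty.
    """

    edges: np.ndarray
    counts: np.ndarray
    n_tracks: int
    top_bin_fraction_pct: float | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "count": self.counts,
            }
        )


def straightness_histogram(
    straightness, bin_width: float = 0.1
) -> StraightnessHistogram:
    """Histogram straightness values on [0, 1] and report the top-bin share."""
    values = np.asarray(straightness, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("straightness values must lie in [0, 1]")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(values, bins=edges)  # last bin closed at 1.0
    n = int(values.size)
    top = None if n == 0 else 100.0 * counts[-1] / n
    return StraightnessHistogram(
        edges=edges, counts=counts, n_tracks=n, top_bin_fraction_pct=top
    )


def reflected_kde(values, grid, lower: float = 0.0, upper: float = 1.0) -> np.ndarray:
    """Gaussian KDE with boundary reflection on a bounded support.

    Silverman-bandwidth Gaussian KDE whose mass outside [lower, upper] is
    reflected back in, so density estimates of straightness (or any
    bounded feature) do not leak past the boundaries.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("need >= 2 distinct values for a density estimate")
    kde = gaussian_kde(values, bw_method="silverman")
    dens = (
        kde.evaluate(grid)
        + kde.evaluate(2.0 * lower - grid)
        + kde.evaluate(2.0 * upper - grid)
    )
    dens[(grid < lower) | (grid > upper)] = 0.0
    return dens


#: Window displacements shorter than this (µm) count as "not moving" and
#: mask the alignment angle.
MIN_ALIGNMENT_STEP_UM = 0.5


def alignment_series(track, frame_interval_min: float = 5.0) -> pd.DataFrame:
    """Angle between the nuclear major axis and the local track direction.

    The local direction at frame t is the displacement over a centered
    3-frame window (one-sided at the track ends).  The angle is acute
    (degrees in [0, 90]) because the nuclear axis is undirected.  Frames
    where the nucleus is near-circular (C/B < 1.05) or the window
    displacement is negligible are masked (``valid=False``, angle NaN).

    Tracks with fewer than 3 frames return a fully masked series.
    """
    if hasattr(track, "objects"):
        df, track_id = track.objects, track.track_id
    else:
        df = track
        track_id = int(df["track_id"].iloc[0]) if "track_id" in df.columns else -1
    df = df.sort_values("frame").reset_index(drop=True)
    n = len(df)
    frames = df["frame"].to_numpy(dtype=int)
    angles = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n >= 3:
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        orient = df["orientation_deg"].to_numpy(dtype=float)
        cb = df["cb_ratio"].to_numpy(dtype=float)
        for i in range(n):
            lo, hi = max(0, i - 1), min(n - 1, i + 1)
            disp = xy[hi] - xy[lo]
            mag = np.linalg.norm(disp)
            if mag < MIN_ALIGNMENT_STEP_UM or cb[i] < LOW_CONFIDENCE_CB:
                continue
            direction = np.degrees(np.arctan2(disp[1], disp[0])) % 180.0
            diff = abs(orient[i] - direction) % 180.0
            angles[i] = min(diff, 180.0 - diff)
            valid[i] = True
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": frames,
            "alignment_deg": angles,
            "valid": valid,
        }
    )


def alignment_summary(series: pd.DataFrame) -> dict:
    """Median valid alignment angle and the fraction of frames above 45°."""
    ok = series.loc[series["valid"], "alignment_deg"]
    if ok.empty:
        return {"n_valid": 0, "median_deg": None, "frac_above_45": None}
    return {
        "n_valid": int(len(ok)),
        "median_deg": float(ok.median()),
        "frac_above_45": float((ok > 45.0).mean()),
    }
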