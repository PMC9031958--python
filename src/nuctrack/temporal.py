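"""Time-resolved population summaries.

For a feature observed across many nuclei at every frame (instantaneous
speed, nuclear area, C/B ratio) these helpers build the per-frame quantile
fan (median, 25/75% and 10/90% quantiles), per-frame medians and sample
variances, strict threshold-exceedance counts, and windowed
median-of-median summaries (the per-track median within a time window,
then the median across tracks).

Conventions: quantiles use linear interpolation between order statistics
(type 7); variance uses the n−1 divisor; frame f maps to time
f × frame_interval_min with 0-based frames; a speed read spanning frames
(f, f+1) belongs to the window containing its midpoint time, with windows
half-open on the left, (start, end].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "per_frame_summaries",
    "threshold_exceedance",
    "WindowSummary",
    "windowed_median_of_medians",
    "variance_trend_slope",
]

#: Frames with fewer values than this are flagged low-n in the summaries.
LOW_N = 5


def per_frame_summaries(values: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Median, sample variance and quantile fan of a feature per frame.

    ``values`` is a long table with at least ``frame`` and ``value_col``
    columns.  Returns one row per frame present, with columns ``frame, n,
    median, variance, q10, q25, q75, q90, low_n``; the variance is NaN for
    single-observation frames.
    """
    if values.empty:
        return pd.DataFrame(
            columns=["frame", "n", "median", "variance", "q10", "q25", "q75", "q90", "low_n"]
        )
    v = values[["frame", value_col]].dropna()
    if not np.all(np.isfinite(v[value_col])):
        raise ValueError("values must be finite")

    def summarize(g: pd.Series) -> pd.Series:
        arr = g.to_numpy(dtype=float)
        q10, q25, q50, q75, q90 = np.quantile(arr, [0.1, 0.25, 0.5, 0.75, 0.9])
        return pd.Series(
            {
                "n": len(arr),
                "median": q50,
                "variance": arr.var(ddof=1) if len(arr) > 1 else np.nan,
                "q10": q10,
                "q25": q25,
                "q75": q75,
                "q90": q90,
            }
        )

    out = v.groupby("frame")[value_col].apply(summarize).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    out["low_n"] = out["n"] < LOW_N
    return out.sort_values("frame", ignore_index=True)


def threshold_exceedance(
    values: pd.DataFrame, threshold: float, value_col: str = "value"
) -> tuple[int, pd.DataFrame]:
    """Count values strictly greater than ``threshold``; return the subset."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if values.empty:
        return 0, values
    mask = values[value_col] > threshold
    subset = values.loc[mask]
    return int(mask.sum()), subset


@dataclass
class WindowSummary:
    """Per-track medians within a time window, and their median."""

    window_min: tuple[float, float]
    per_track_medians: pd.Series  # indexed by track_id
    median_of_medians: float | None

    @property
    def n_tracks(self) -> int:
        return int(len(self.per_track_medians))


def windowed_median_of_medians(
    speeds: pd.DataFrame,
    window_min: tuple[float, float],
    value_col: str = "speed_um_hr",
) -> WindowSummary:
    """Median across tracks of each track's median feature value in a window.

    A read belongs to the window when its midpoint time ``t_mid_min`` lies
    in (start, end].  Tracks with no reads in the window are excluded; an
    empty window yields ``median_of_medians=None``.
    """
    start, end = window_min
    if not start < end:
        raise ValueError(f"window start {start} must be < end {end}")
    sel = speeds[(speeds["t_mid_min"] > start) & (speeds["t_mid_min"] <= end)]
    per_track = sel.groupby("track_id")[value_col].median()
    mom = float(per_track.median()) if len(per_track) else None
    return WindowSummary(
        window_min=(start, end), per_track_medians=per_track, median_of_medians=mom
    )


def variance_trend_slope(summaries: pd.DataFrame) -> float:
    """OLS slope of the per-frame variance against frame number.

    Positive when a population's spread grows over the recording (the
    temporal-heterogeneity signature), negative when it homogenizes.
    """
    sub = summaries.dropna(subset=["variance"])
    if len(sub) < 2:
        raise ValueError("need variance summaries at >= 2 frames")
    slope, _ = np.polyfit(sub["frame"].to_numpy(float), sub["variance"].to_numpy(float), 1)
    return float(slope)
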