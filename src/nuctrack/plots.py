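"""Report figures: quantile fans, histogram overlays, density curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .track_metrics import reflected_kde

__all__ = ["quantile_fan", "histogram_overlay", "save_report_figures"]

_FAN_STYLE = [
    ("median", "red", "median"),
    ("q25", "goldenrod", "25% / 75%"),
    ("q75", "goldenrod", None),
    ("q10", "green", "10% / 90%"),
    ("q90", "green", None),
]


def quantile_fan(summaries: pd.DataFrame, ax=None, title: str = "", ylabel: str = ""):
    """Plot per-frame median and 25/75, 10/90 quantile curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col, color, label in _FAN_STYLE:
        ax.plot(summaries["frame"], summaries[col], color=color, label=label, lw=1.5)
    ax.set_xlabel("frame")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def histogram_overlay(
    values_by_group: dict[str, np.ndarray],
    bin_width: float = 0.1,
    support: tuple[float, float] = (0.0, 1.0),
    ax=None,
    xlabel: str = "",
):
    """Overlaid histograms plus boundary-reflected density curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    lo, hi = support
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    grid = np.linspace(lo, hi, 256)
    for (name, vals), color in zip(values_by_group.items(), ("C0", "C1", "C2")):
        vals = np.asarray(vals, dtype=float)
        ax.hist(vals, bins=edges, density=True, alpha=0.35, color=color, label=name)
        if len(vals) > 1 and np.ptp(vals) > 0:
            ax.plot(grid, reflected_kde(vals, grid, lo, hi), color=color, lw=2)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    return ax


def save_report_figures(run_dir, out_dir=None) -> list[Path]:
    """Render the standard figures for one pipeline run directory."""
    from .temporal import per_frame_summaries
    from .track_metrics import instantaneous_speeds, track_metrics_table

    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir else run_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks = pd.read_csv(run_dir / "tracks.csv")
    written: list[Path] = []
    if tracks.empty:
        return written

    speeds = instantaneous_speeds(tracks)
    speed_summ = per_frame_summaries(
        speeds.rename(columns={"frame_end": "frame"}), "speed_um_hr"
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    quantile_fan(speed_summ, ax=ax, title="Instantaneous speed", ylabel="µm/h")
    p = out_dir / "speed_fan.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    metrics = track_metrics_table(tracks)
    fig, ax = plt.subplots(figsize=(6, 4))
    histogram_overlay({"tracks": metrics["straightness"]}, ax=ax, xlabel="straightness")
    p = out_dir / "straightness_hist.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    if "area_um2" in tracks.columns:
        area_summ = per_frame_summaries(
            tracks.rename(columns={"area_um2": "value"}), "value"
        )
        fig, ax = plt.subplots(figsize=(6, 4))
        quantile_fan(area_summ, ax=ax, title="Nuclear size", ylabel="µm²")
        p = out_dir / "area_fan.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
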