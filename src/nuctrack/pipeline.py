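"""End-to-end pipeline orchestration.

``run_pipeline`` drives one condition from configuration to report bundle:
simulate (or ingest) a movie, segment, link, measure, summarize over time,
and write every table plus a JSON summary of the headline statistics
(medians, variances, top-bin fractions, exceedance counts).  ``compare``
runs the full two-group test battery between two such runs.

All quantities use the package-wide unit conventions: distances in µm,
times in minutes, speeds in µm/h, areas in µm².
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from . import synthetic
from .segmentation import Movie, segment_movie
from .stats import fligner_killeen, per_frame_variance_tests, wilcoxon_rank_sum
from .temporal import (
    per_frame_summaries,
    threshold_exceedance,
    variance_trend_slope,
    windowed_median_of_medians,
)
from .track_metrics import (
    instantaneous_speeds,
    straightness_histogram,
    track_metrics_table,
)
from .tracking import LinkerParams, link_movie, track_table

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "summarize_tracks",
    "compare",
    "validate_summary",
    "SUMMARY_SCHEMA",
]

logger = logging.getLogger(__name__)

#: Analysis thresholds: speed reads above 100 µm/h and nuclear areas above
#: 300 / 400 µm² are counted as exceedance events; the straightness "top
#: bin" is [0.9, 1.0].
SPEED_THRESHOLD_UM_HR = 100.0
AREA_THRESHOLDS_UM2 = (300.0, 400.0)
EARLY_WINDOW_MIN = (0.0, 120.0)  # "first 2 h"


@dataclass
class PipelineConfig:
    """One reproducible pipeline run (simulated or ingested input)."""

    out_dir: str
    preset: str | None = "control_like"  # None when ingesting
    movie_path: str | None = None  # ingest a TIFF instead of simulating
    tracks_path: str | None = None  # or start from an existing track table
    n_cells: int = 50
    n_frames: int = 100
    seed: int = 0
    render: bool = False  # render+segment, or analyze ground-truth tracks
    pixel_size_um: float = 0.5
    frame_interval_min: float = 5.0
    linker: LinkerParams = field(default_factory=LinkerParams)
    min_area_um2: float = 30.0
    split_touching: bool = False


def summarize_tracks(tracks: pd.DataFrame, frame_interval_min: float = 5.0) -> dict:
    """Headline statistics of one condition's track table.

    Returns a JSON-serializable dict covering the migration and morphology
    summaries reported for each population: straightness distribution and
    top-bin fraction, track-length stats, speed quantile trends and
    exceedance counts, windowed median-of-median speeds, nuclear-size
    trends and exceedance counts, and the C/B distribution.
    """
    n_tracks = int(tracks["track_id"].nunique()) if len(tracks) else 0
    summary: dict = {"n_tracks": n_tracks, "n_objects": int(len(tracks))}
    if n_tracks == 0:
        summary["undefined"] = True
        return summary

    metrics = track_metrics_table(tracks, frame_interval_min)
    speeds = instantaneous_speeds(tracks, frame_interval_min)
    hist = straightness_histogram(metrics["straightness"])
    total_min = (tracks["frame"].max()) * frame_interval_min

    speed_frames = speeds.rename(columns={"frame_end": "frame"})
    speed_summ = per_frame_summaries(speed_frames, "speed_um_hr")
    n_speed_gt, _ = threshold_exceedance(speeds, SPEED_THRESHOLD_UM_HR, "speed_um_hr")
    early = windowed_median_of_medians(speeds, EARLY_WINDOW_MIN)
    late = (
        windowed_median_of_medians(speeds, (EARLY_WINDOW_MIN[1], float(total_min)))
        if total_min > EARLY_WINDOW_MIN[1]
        else None
    )

    summary.update(
        {
            "straightness": {
                "mean": float(metrics["straightness"].mean()),
                "median": float(metrics["straightness"].median()),
                "top_bin_counts": int(hist.counts[-1]),
                "top_bin_fraction_pct": hist.top_bin_fraction_pct,
            },
            "track_length_um": {
                "mean": float(metrics["track_length_um"].mean()),
                "sd": float(metrics["track_length_um"].std(ddof=1)),
                "max": float(metrics["track_length_um"].max()),
            },
            "speed_um_hr": {
                "n_reads": int(len(speeds)),
                "max": float(speeds["speed_um_hr"].max()),
                "n_above_100": n_speed_gt,
                "median_of_medians_first2h": early.median_of_medians,
                "median_of_medians_after2h": (
                    late.median_of_medians if late is not None else None
                ),
                "variance_slope": variance_trend_slope(speed_summ),
            },
        }
    )
    if "area_um2" in tracks.columns:
        area_summ = per_frame_summaries(
            tracks.rename(columns={"area_um2": "value"}), "value"
        )
        summary["area_um2"] = {
            "median": float(tracks["area_um2"].median()),
            "n_above_300": threshold_exceedance(tracks, 300.0, "area_um2")[0],
            "n_above_400": threshold_exceedance(tracks, 400.0, "area_um2")[0],
            "variance_slope": variance_trend_slope(area_summ),
        }
    if "cb_ratio" in tracks.columns:
        summary["cb_ratio"] = {
            "median": float(tracks["cb_ratio"].median()),
            "mean": float(tracks["cb_ratio"].mean()),
        }
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one condition end to end; write tables and the JSON summary.

    Returns the summary dict (also written to ``summary.json``).  Output
    bundle: ``truth.csv`` (simulated runs), ``movie.tif`` (+ sidecar,
    rendered runs), ``objects.csv``, ``tracks.csv``, ``track_metrics.csv``,
    ``speeds.csv``, ``summary.json``, ``run_log.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.tracks_path:
            tracks = nio.read_table(config.tracks_path)
            frame_interval = config.frame_interval_min
        else:
            if config.movie_path:
                stage = "read_movie"
                movie = nio.read_movie(config.movie_path)
            else:
                stage = "simulate"
                sim = synthetic.preset(
                    config.preset,
                    n_cells=config.n_cells,
                    n_frames=config.n_frames,
                    pixel_size_um=config.pixel_size_um,
                    frame_interval_min=config.frame_interval_min,
                    seed=config.seed,
                )
                truth = synthetic.simulate_tracks(sim)
                nio.write_ground_truth(out / "truth.csv", truth)
                if config.render:
                    stage = "render"
                    frames = synthetic.render_movie(truth, sim)
                    nio.write_movie(
                        out / "movie.tif",
                        frames,
                        sim.pixel_size_um,
                        sim.frame_interval_min,
                    )
                    movie = Movie(frames, sim.pixel_size_um, sim.frame_interval_min)
                else:
                    # analyze ground-truth tracks directly (no imaging noise)
                    tracks = truth.rename(columns={"cell_id": "track_id"}).drop(
                        columns=["step_um"]
                    )
                    tracks["cb_ratio"] = tracks["length_c_um"] / tracks["length_b_um"]
                    movie = None
            if config.movie_path or config.render:
                stage = "segment"
                objects = segment_movie(
                    movie,
                    min_area_um2=config.min_area_um2,
                    split_touching=config.split_touching,
                )
                nio.write_table(out / "objects.csv", objects)
                stage = "track"
                result = link_movie(objects, config.linker)
                logger.info(
                    "linked %d tracks (%d discarded short)",
                    len(result.tracks),
                    len(result.discarded),
                )
                tracks = track_table(result.tracks)
            frame_interval = config.frame_interval_min

        stage = "features"
        nio.write_table(out / "tracks.csv", tracks)
        if len(tracks):
            nio.write_table(
                out / "track_metrics.csv", track_metrics_table(tracks, frame_interval)
            )
            nio.write_table(
                out / "speeds.csv", instantaneous_speeds(tracks, frame_interval)
            )
        stage = "summarize"
        summary = summarize_tracks(tracks, frame_interval)
        validate_summary(summary)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log = {
            "seed": config.seed,
            "config": _config_dict(config),
            "n_tracks": summary.get("n_tracks", 0),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        return summary
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def compare(
    tracks_a: pd.DataFrame,
    tracks_b: pd.DataFrame,
    frame_interval_min: float = 5.0,
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> pd.DataFrame:
    """Run the full two-group battery between two track tables.

    Wilcoxon rank-sum on straightness, track length, early/late per-track
    median speeds, nuclear area and C/B ratio, plus Fligner–Killeen on C/B
    and on speed at the first and last common frame.  Returns a tidy table
    (one row per test).
    """
    rows = []

    def add(test, feature, window, res):
        rows.append(
            {
                "test": test,
                "feature": feature,
                "window": window,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                **{f"{k}_{labels[0]}": v for k, v in [
                    ("median", res.group_summaries["median_1"]),
                    ("variance", res.group_summaries["variance_1"]),
                ]},
                **{f"{k}_{labels[1]}": v for k, v in [
                    ("median", res.group_summaries["median_2"]),
                    ("variance", res.group_summaries["variance_2"]),
                ]},
            }
        )

    ma = track_metrics_table(tracks_a, frame_interval_min)
    mb = track_metrics_table(tracks_b, frame_interval_min)
    add("wilcoxon_rank_sum", "straightness", "all",
        wilcoxon_rank_sum(ma["straightness"], mb["straightness"]))
    add("wilcoxon_rank_sum", "track_length_um", "all",
        wilcoxon_rank_sum(ma["track_length_um"], mb["track_length_um"]))

    sa = instantaneous_speeds(tracks_a, frame_interval_min)
    sb = instantaneous_speeds(tracks_b, frame_interval_min)
    t_end = float(
        max(sa["t_mid_min"].max(), sb["t_mid_min"].max())
    )
    windows = [EARLY_WINDOW_MIN] if t_end <= EARLY_WINDOW_MIN[1] else [
        EARLY_WINDOW_MIN, (EARLY_WINDOW_MIN[1], t_end)
    ]
    for window in windows:
        wa = windowed_median_of_medians(sa, window)
        wb = windowed_median_of_medians(sb, window)
        if wa.n_tracks and wb.n_tracks:
            add(
                "wilcoxon_rank_sum",
                "speed_um_hr_track_median",
                f"{window[0]:g}-{window[1]:g} min",
                wilcoxon_rank_sum(wa.per_track_medians, wb.per_track_medians),
            )

    for col in ("area_um2", "cb_ratio"):
        if col in tracks_a.columns and col in tracks_b.columns:
            add("wilcoxon_rank_sum", col, "all",
                wilcoxon_rank_sum(tracks_a[col], tracks_b[col]))
    if "cb_ratio" in tracks_a.columns and "cb_ratio" in tracks_b.columns:
        add("fligner_killeen", "cb_ratio", "all",
            fligner_killeen(tracks_a["cb_ratio"], tracks_b["cb_ratio"]))

    fa = sa.rename(columns={"frame_end": "frame", "speed_um_hr": "value"})
    fb = sb.rename(columns={"frame_end": "frame", "speed_um_hr": "value"})
    common = sorted(set(fa["frame"]) & set(fb["frame"]))
    if common:
        fk = per_frame_variance_tests(fa, fb, [common[0], common[-1]])
        for rec in fk.to_dict("records"):
            rows.append(
                {
                    "test": "fligner_killeen",
                    "feature": "speed_um_hr",
                    "window": f"frame {int(rec['frame'])}",
                    "statistic": rec["statistic"],
                    "p_value": rec["p_value"],
                    "n1": rec["n1"],
                    "n2": rec["n2"],
                    f"median_{labels[0]}": np.nan,
                    f"variance_{labels[0]}": rec["variance_1"],
                    f"median_{labels[1]}": np.nan,
                    f"variance_{labels[1]}": rec["variance_2"],
                }
            )
    return pd.DataFrame(rows)


# --- summary schema ---------------------------------------------------------

#: Minimal schema of the JSON summary: required keys and their types.
SUMMARY_SCHEMA = {
    "n_tracks": int,
    "n_objects": int,
    "straightness": dict,
    "track_length_um": dict,
    "speed_um_hr": dict,
}


def validate_summary(summary: dict) -> None:
    """Check a summary dict against :data:`SUMMARY_SCHEMA`.

    Degenerate runs (zero tracks) are exempt from the feature sections but
    must be flagged ``undefined``.
    """
    if summary.get("n_tracks", 0) == 0:
        if not summary.get("undefined"):
            raise ValueError("empty summary must set undefined=true")
        return
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary[{key!r}] must be {typ.__name__}")
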