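"""Ground-truthed synthetic nuclear-migration movies.

Simulates populations of Hoechst-like nuclei (bright ellipses on a dark
background) migrating as persistent random walks over a 2D field, then
rasterizes them into multi-page 16-bit movies.  The generator covers the
two phenotypes the analysis is designed to separate:

``control_like``
    Highly persistent, directional migration that decelerates over the
    recording; stable nuclear size; elongated nuclei whose major axis
    follows the direction of motion.

``cd_like``
    Weakly persistent, haphazard migration that accelerates; nuclear size
    drifting upward with growing cell-to-cell variance; rounder nuclei
    whose major axis alternates between aligned and perpendicular epochs.

The motion model is an AR(1) process on the heading direction: each frame
the unit heading is mixed with a fresh random unit vector with weight
``1 - persistence`` and renormalized, so persistence maps monotonically
from Brownian motion (0) to ballistic motion (1).  Step magnitudes are
drawn around a linearly trending mean speed; the noise scale follows the
same trend factor, so a decelerating population also becomes more
homogeneous over time and an accelerating one more heterogeneous —
mirroring the coupled median/variance trajectories seen in live recordings.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "SimulationConfig",
    "simulate_tracks",
    "render_movie",
    "preset",
    "PRESET_NAMES",
    "TRUTH_COLUMNS",
]

#: Column schema of a ground-truth table (one row per cell per frame).
TRUTH_COLUMNS = [
    "cell_id",
    "frame",
    "x_um",
    "y_um",
    "area_um2",
    "length_c_um",
    "length_b_um",
    "orientation_deg",
    "step_um",
]

_ORIENTATION_MODES = ("aligned", "random", "switching")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic nuclear-migration experiment.

    Times are in minutes, lengths in µm, speeds in µm/h; the per-frame
    speed trend is a signed fraction of the baseline mean per frame
    (negative = deceleration).  ``area_drift_rate`` moves the population
    median (µm²/frame) and ``area_var_growth`` grows the cross-sectional
    variance (µm⁴/frame).  ``elongation_mean`` is the target C/B ratio.
    """

    n_cells: int = 50
    n_frames: int = 100
    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.5
    field_size_px: tuple[int, int] = (1024, 1024)  # (height, width)
    persistence: float = 0.7
    speed_mean_um_per_hr: float = 30.0
    speed_trend: float = 0.0
    speed_noise_sd: float = 8.0
    area_mean_um2: float = 160.0
    area_sd_um2: float = 20.0
    area_drift_rate: float = 0.0
    area_var_growth: float = 0.0
    elongation_mean: float = 1.4
    elongation_sd: float = 0.15
    orientation_mode: str = "aligned"
    #: Excluded-volume interaction: nuclei are pushed apart whenever their
    #: centers come closer than this (µm).  None disables the interaction
    #: (ideal non-interacting walkers, e.g. for closed-form checks).
    min_separation_um: float | None = None
    seed: int = 0

    def validate(self) -> None:
        def _check(cond: bool, fieldname: str, msg: str) -> None:
            if not cond:
                raise ValueError(f"SimulationConfig.{fieldname}: {msg}")

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                _check(math.isfinite(v), f.name, f"non-finite value {v!r}")
        _check(self.n_cells >= 0, "n_cells", "must be >= 0")
        _check(self.n_frames >= 2, "n_frames", "must be >= 2")
        _check(self.frame_interval_min > 0, "frame_interval_min", "must be > 0")
        _check(self.pixel_size_um > 0, "pixel_size_um", "must be > 0")
        _check(
            len(self.field_size_px) == 2 and min(self.field_size_px) >= 8,
            "field_size_px",
            "must be (height, width) with both >= 8",
        )
        _check(0.0 <= self.persistence <= 1.0, "persistence", "must be in [0, 1]")
        _check(self.speed_mean_um_per_hr >= 0, "speed_mean_um_per_hr", "must be >= 0")
        _check(self.speed_noise_sd >= 0, "speed_noise_sd", "must be >= 0")
        _check(self.area_mean_um2 > 0, "area_mean_um2", "must be > 0")
        _check(self.area_sd_um2 >= 0, "area_sd_um2", "must be >= 0")
        _check(self.area_var_growth >= 0, "area_var_growth", "must be >= 0")
        _check(self.elongation_mean >= 1.0, "elongation_mean", "must be >= 1")
        if self.min_separation_um is not None:
            _check(self.min_separation_um > 0, "min_separation_um", "must be > 0")
        _check(self.elongation_sd >= 0, "elongation_sd", "must be >= 0")
        _check(
            self.orientation_mode in _ORIENTATION_MODES,
            "orientation_mode",
            f"must be one of {_ORIENTATION_MODES}",
        )

    @property
    def field_size_um(self) -> tuple[float, float]:
        h, w = self.field_size_px
        return (h * self.pixel_size_um, w * self.pixel_size_um)


_PRESETS: dict[str, dict] = {
    # Directional, decelerating, stable size, elongated, axis tracks motion.
    "control_like": dict(
        persistence=0.9,
        speed_mean_um_per_hr=30.0,
        speed_trend=-0.003,
        speed_noise_sd=8.0,
        area_mean_um2=160.0,
        area_sd_um2=20.0,
        area_drift_rate=0.0,
        area_var_growth=0.0,
        elongation_mean=1.4,
        elongation_sd=0.15,
        orientation_mode="aligned",
        min_separation_um=20.0,
    ),
    # Random, accelerating, growing size variance, rounded, axis switching.
    "cd_like": dict(
        persistence=0.4,
        speed_mean_um_per_hr=22.0,
        speed_trend=0.005,
        speed_noise_sd=8.0,
        area_mean_um2=150.0,
        area_sd_um2=20.0,
        area_drift_rate=0.25,
        area_var_growth=25.0,
        elongation_mean=1.2,
        elongation_sd=0.10,
        orientation_mode="switching",
        min_separation_um=20.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)

#: Frames per epoch in the "switching" orientation mode (aligned epochs
#: alternate with perpendicular ones).
SWITCH_EPOCH_FRAMES = 15


def preset(name: str, **overrides) -> SimulationConfig:
    """Return the configuration of a named phenotype.

    Keyword overrides (e.g. ``n_cells=200, seed=7``) are applied on top of
    the preset values.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = SimulationConfig(**_PRESETS[name])
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown SimulationConfig field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([np.cos(theta), np.sin(theta)])


def _resolve_overlaps(
    pos: np.ndarray,
    d_min: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    max_iter: int = 100,
) -> np.ndarray:
    """Push apart pairs of centers closer than ``d_min`` (excluded volume).

    Each violating pair is moved symmetrically along its center line until
    separated; a few sweeps resolve chains.  Positions stay in the field.
    """
    w_um, h_um = bounds
    pos = pos.copy()
    for _ in range(max_iter):
        pairs = cKDTree(pos).query_pairs(d_min, output_type="ndarray")
        if len(pairs) == 0:
            break
        for i, j in pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]:
            delta = pos[j] - pos[i]
            d = float(np.linalg.norm(delta))
            if d < 1e-9:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                delta, d = np.array([np.cos(theta), np.sin(theta)]), 1.0
            # separate to slightly beyond d_min so reflections cannot
            # leave the pair marginally inside the exclusion radius
            shift = 0.5 * (1.001 * d_min - d) * delta / d
            pos[i] -= shift
            pos[j] += shift
        pos[:, 0] = _reflect(pos[:, 0], 0.0, w_um)
        pos[:, 1] = _reflect(pos[:, 1], 0.0, h_um)
    return pos


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by reflection at the walls."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def simulate_tracks(config: SimulationConfig) -> pd.DataFrame:
    """Simulate persistent-random-walk nuclei; return the ground-truth table.

    Returns a DataFrame with :data:`TRUTH_COLUMNS`: per cell and frame the
    true centroid (µm), nuclear area (µm²), principal-axis lengths C and B
    (µm), major-axis orientation (degrees, mod 180), and the realized step
    magnitude from the previous frame (``step_um``; NaN at the first
    frame).  Positions are reflected at the field boundary; the recorded
    step magnitude is the realized centroid displacement, so summed steps
    equal the measured track length exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, t_total = config.n_cells, config.n_frames
    if n == 0:
        return pd.DataFrame(columns=TRUTH_COLUMNS)

    h_um, w_um = config.field_size_um
    margin = 2.0 * math.sqrt(config.area_mean_um2)  # keep nuclei initially inside
    lo_x, hi_x = min(margin, w_um / 4), w_um - min(margin, w_um / 4)
    lo_y, hi_y = min(margin, h_um / 4), h_um - min(margin, h_um / 4)

    pos = np.column_stack(
        [rng.uniform(lo_x, hi_x, size=n), rng.uniform(lo_y, hi_y, size=n)]
    )
    if config.min_separation_um is not None and n > 1:
        pos = _resolve_overlaps(
            pos, config.min_separation_um, (w_um, h_um), rng, max_iter=200
        )
    heading = _random_unit(rng, n)
    step_per_frame = config.frame_interval_min / 60.0  # hours per frame

    # per-cell latent size/shape parameters
    z_size = rng.standard_normal(n)  # cell's place in the size distribution
    elong = np.clip(
        rng.normal(config.elongation_mean, config.elongation_sd, size=n), 1.0, None
    )
    # random orientation mode: slowly wandering axis, independent of motion
    axis_angle = rng.uniform(0.0, 180.0, size=n)
    # switching mode: per-cell epoch phase so cells do not switch in unison
    epoch_offset = rng.integers(0, SWITCH_EPOCH_FRAMES, size=n)

    records = []
    prev_pos = pos.copy()
    for t in range(t_total):
        if t > 0:
            fresh = _random_unit(rng, n)
            mixed = config.persistence * heading + (1.0 - config.persistence) * fresh
            norm = np.linalg.norm(mixed, axis=1, keepdims=True)
            # renormalize; if persistence*h and fresh cancel exactly, keep fresh
            degenerate = norm[:, 0] < 1e-12
            if degenerate.any():
                mixed[degenerate] = fresh[degenerate]
                norm = np.linalg.norm(mixed, axis=1, keepdims=True)
            heading = mixed / norm

            trend_factor = max(0.0, 1.0 + config.speed_trend * t)
            speed = rng.normal(
                config.speed_mean_um_per_hr * trend_factor,
                config.speed_noise_sd * trend_factor,
                size=n,
            )
            speed = np.clip(speed, 0.0, None)
            prev_pos = pos
            pos = pos + heading * (speed * step_per_frame)[:, None]
            pos = np.column_stack(
                [_reflect(pos[:, 0], 0.0, w_um), _reflect(pos[:, 1], 0.0, h_um)]
            )
            if config.min_separation_um is not None and n > 1:
                pos = _resolve_overlaps(
                    pos, config.min_separation_um, (w_um, h_um), rng
                )
        step = np.linalg.norm(pos - prev_pos, axis=1) if t > 0 else np.full(n, np.nan)

        # nuclear area: population median drifts linearly; cross-sectional
        # variance grows linearly via each cell's fixed quantile z_size
        sd_t = math.sqrt(config.area_sd_um2**2 + config.area_var_growth * t)
        area = (
            config.area_mean_um2
            + config.area_drift_rate * t
            + z_size * sd_t
            + rng.normal(0.0, 3.0, size=n)  # small frame-to-frame jitter
        )
        area = np.clip(area, 40.0, None)

        length_c = 2.0 * np.sqrt(area * elong / np.pi)
        length_b = 2.0 * np.sqrt(area / (elong * np.pi))

        heading_deg = np.degrees(np.arctan2(heading[:, 1], heading[:, 0])) % 180.0
        if config.orientation_mode == "aligned":
            orient = heading_deg
        elif config.orientation_mode == "random":
            axis_angle = (axis_angle + rng.normal(0.0, 10.0, size=n)) % 180.0
            orient = axis_angle
        else:  # switching: alternate aligned / perpendicular epochs
            epoch = (t + epoch_offset) // SWITCH_EPOCH_FRAMES
            perpendicular = (epoch % 2).astype(bool)
            orient = np.where(perpendicular, (heading_deg + 90.0) % 180.0, heading_deg)

        records.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(n),
                    "frame": t,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "area_um2": area,
                    "length_c_um": length_c,
                    "length_b_um": length_b,
                    "orientation_deg": orient,
                    "step_um": step,
                }
            )
        )
    truth = pd.concat(records, ignore_index=True)
    return truth.sort_values(["cell_id", "frame"], ignore_index=True)


def render_movie(
    truth: pd.DataFrame,
    config: SimulationConfig,
    background: float = 400.0,
    amplitude: float = 2000.0,
    noise_sd: float = 30.0,
    blur_sigma_px: float = 1.0,
) -> np.ndarray:
    """Rasterize a ground-truth table into a (n_frames, H, W) uint16 stack.

    Each nucleus is drawn as a filled ellipse (full axes C and B, rotated to
    its orientation), blurred with a Gaussian of ``blur_sigma_px`` and
    overlaid with additive Gaussian read noise.  Nuclei whose centers fall
    outside the field are simply absent from that frame.
    """
    config.validate()
    h_px, w_px = config.field_size_px
    px = config.pixel_size_um
    if min(h_px, w_px) * px < 2.0 * math.sqrt(config.area_mean_um2 / math.pi):
        raise ValueError("field too small to contain a nucleus")

    frames = np.zeros((config.n_frames, h_px, w_px), dtype=float)
    if len(truth):
        for t, group in truth.groupby("frame"):
            canvas = frames[int(t)]
            for row in group.itertuples(index=False):
                _draw_ellipse(
                    canvas,
                    cx=row.x_um / px,
                    cy=row.y_um / px,
                    semi_c=row.length_c_um / (2.0 * px),
                    semi_b=row.length_b_um / (2.0 * px),
                    angle_deg=row.orientation_deg,
                    value=amplitude,
                )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    for t in range(config.n_frames):
        frame = frames[t]
        if blur_sigma_px > 0:
            frame = ndi.gaussian_filter(frame, blur_sigma_px)
        frame = frame + background
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[t] = frame
    return np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def _draw_ellipse(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    semi_c: float,
    semi_b: float,
    angle_deg: float,
    value: float,
) -> None:
    """Add ``value`` to pixels inside a rotated ellipse (pixel-center test)."""
    h, w = canvas.shape
    if not (0.0 <= cx < w and 0.0 <= cy < h):
        return  # center out of field: nucleus absent this frame
    r = math.ceil(max(semi_c, semi_b)) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    theta = math.radians(angle_deg)
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / semi_c) ** 2 + (v / semi_b) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][inside] += value
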