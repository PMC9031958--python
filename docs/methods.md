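# Methods

This note documents the models and numerical conventions behind
`nuctrack`, the choices that were genuinely open, and what the synthetic
data does and does not establish about real recordings.

## Motion model (simulator)

Nuclei migrate as persistent random walks on a 2D field. The unit heading
vector follows an AR(1) process with renormalization:

    h_{t+1} = normalize( p · h_t + (1 − p) · u_t ),

where `u_t` is a fresh uniformly random unit vector and `p ∈ [0, 1]` is the
persistence. The AR(1) acts on the heading, not the raw velocity, so `p`
maps monotonically from Brownian motion (p = 0, independent headings) to
ballistic motion (p = 1) without coupling directionality to speed.

Step magnitudes are drawn per frame from a Gaussian around a linearly
trending mean,

    speed_t ~ N( μ₀ · f_t ,  (σ₀ · f_t)² ),   f_t = max(0, 1 + β·t),

floored at zero, with `μ₀` the baseline mean speed (µm/h), `σ₀` the
baseline noise SD, and `β` the signed per-frame trend. The noise SD scales
with the same trend factor as the mean: a decelerating population
(β < 0) therefore also homogenizes over time and an accelerating one
(β > 0) becomes more heterogeneous. This one-knob coupling is the
simulator's mechanism for the paired median/variance trajectories that
live-cell speed data show; it means the per-frame speed variance trend is
`sign(β)`, which the temporal-statistics module must recover. The Gaussian
family itself is a modeling choice — real instantaneous-speed
distributions are right-skewed with rare fast excursions (reads above
100 µm/h), which this simulator deliberately does not reproduce; tail
comparisons on synthetic data therefore use thresholds inside the
simulated dynamic range.

The field boundary is reflective, so tracks are never truncated at the
edge (truncation would distort straightness distributions). Recorded step
magnitudes are the realized post-reflection displacements, which keeps the
identity "track length = sum of step magnitudes" exact.

Nuclei are impenetrable: an excluded-volume interaction
(`min_separation_um`, 20 µm in both presets) iteratively pushes centers
apart whenever they come closer than the exclusion radius. Without it,
point walkers freely overlap and any rendered movie contains merged
nuclear images that no segmentation can split reliably. Setting
`min_separation_um=None` recovers ideal non-interacting walkers, which the
closed-form Brownian checks use: for persistence 0 and fixed step length,
the mean straightness of an n-step walk is √(π/(4n)) (Rayleigh asymptotics
of the displacement), and the simulator reproduces it within Monte-Carlo
error.

## Size, shape, and orientation

Per-cell nuclear area follows

    A_i(t) = A₀ + δ·t + z_i · sqrt(σ_A² + γ·t) + ε_{i,t},

with `δ` the median drift (µm²/frame), `γ` the cross-sectional variance
growth (µm⁴/frame), `z_i` a fixed per-cell standard normal (each cell
keeps its place in the population size distribution), and `ε` a small
(SD 3 µm²) frame-to-frame jitter. The cross-sectional variance at frame t
is σ_A² + γ·t by construction, so the variance-vs-frame slope recovers γ.
Areas are floored at 40 µm².

Each cell has a fixed elongation `e_i ≥ 1` (target C/B ratio); the
rendered ellipse axes are C = 2√(A·e/π) and B = 2√(A/(e·π)), so the
ellipse area equals the simulated area exactly. Orientation modes:
`aligned` (major axis tracks the heading), `random` (slowly wandering axis,
10°/frame SD), and `switching` (epochs of ~15 frames alternating between
aligned and perpendicular, with per-cell phase offsets).

Presets: `control_like` (persistence 0.9, 30 µm/h decelerating at
−0.3 %/frame, stable area 160 ± 20 µm², elongation 1.4, aligned) and
`cd_like` (persistence 0.4, 22 µm/h accelerating at +0.5 %/frame, area
drifting +0.25 µm²/frame with variance growing 25 µm⁴/frame, elongation
1.2, switching). The speed and area scales sit at the medians reported for
passage-matched control and cadmium-exposed fibroid populations
(~21–33 µm/h medians, ~160 µm² nuclei); the persistence/trend values are
chosen so the rendered phenotypes reproduce the qualitative contrasts the
analysis is designed to detect, and are fixed study conditions, not
fitting targets.

## Rendering and segmentation

Nuclei are rasterized as filled rotated ellipses (pixel-center test),
amplitude 2000 counts over a 400-count background, blurred with a σ = 1 px
Gaussian, plus additive Gaussian read noise (SD 30) into 16-bit frames.

Segmentation thresholds each frame with Otsu's method, fills interior
holes before measuring (area is the footprint of the nuclear mask), labels
8-connected components, and discards components below 30 µm² — well below
nuclear scale, so only noise specks are removed. Because Otsu always
bisects a histogram, a guard rejects thresholds that fail to clear the
background median by 5 robust SDs; signal-free frames therefore yield zero
objects rather than percolating noise. Optional marker-based watershed
(markers = smoothed distance-transform maxima) splits touching nuclei.
Coordinates are pixel centers, x = column, y = row, 0-based; physical
coordinate = index × pixel size.

## Oriented bounding box

The object-oriented bounding box uses the PCA-extent construction: the
axes are the eigenvectors of the pixel-coordinate covariance matrix and
the extents are max − min of the projections, ordered so C ≥ B. For
rasterized objects the extents are padded by one pixel size, since pixel
centers under-represent the pixel squares' footprint. Orientation is
reported mod 180° (a nuclear axis is undirected). Near-circular objects
(C/B < 1.05) carry a low-confidence flag and are masked out of alignment
statistics, because the major axis of a circle is numerically arbitrary.
Commercial implementations do not publish their box algorithm; PCA extents
reproduce the defining behavior (circle → 1, elongation → large C/B) and
are stated here rather than claimed identical.

## Tracking

Linking is autoregressive-predictive: each active track predicts
`x̂ = x_last + m · Δx_last` with momentum `m ∈ [0, 1]`, and each frame pair
is linked by the Hungarian algorithm on the prediction–candidate distance
matrix, with links beyond `max_link_distance_um` forbidden. Defaults:
gate 20 µm (≈4× the largest plausible 5-min displacement given maximum
observed nuclear speeds near 220 µm/h), momentum 0.8, one-frame gap
tolerance, minimum track length 10 frames. Unmatched objects seed new
tracks; gaps are never interpolated — step metrics divide by the actual
elapsed time. With momentum 0 the linker reduces to optimal
nearest-assignment matching. Cost-matrix rows and columns are ordered by
(track_id, object_id), fixing tie-breaks deterministically.

## Metrics and temporal statistics

* Stationary tracks (length exactly 0) get straightness 1 with a flag, so
  the 0/0 case is auditable and excludable rather than silently dropped.
* The straightness histogram uses bin width 0.1 with the last bin closed:
  straightness exactly 1.0 counts as "0.9 or greater". Top-bin fractions
  are reported at full precision (107/478 = 22.38…%, which prints as 22.4%
  at one decimal).
* Density overlays use a Silverman-bandwidth Gaussian KDE with reflection
  at the support boundaries, so no probability mass leaks outside [0, 1].
* Alignment angles use the track direction over a centered 3-frame window
  (one-sided at track ends); raw single-step directions are noise-dominated
  at 5-minute sampling.
* Quantiles are linear-interpolation (type 7); variances use the n − 1
  divisor, consistent with the scale test's framing.
* Frame f corresponds to time f × frame interval (0-based). A speed read
  spanning frames (f, f+1) is assigned to time windows by its midpoint
  time, window membership being half-open (start, end]; on a 5-min, 100-
  frame movie the "first 2 h" window covers exactly the first 24 steps.

## Inference

Both tests are two-sided. The Wilcoxon rank-sum statistic is the sum of
pooled mid-ranks of the first sample; for tie-free pooled samples of at
most 12 the null distribution is enumerated exactly, otherwise a normal
approximation with continuity correction and tie-corrected variance is
used (documented so p-values are reproducible). The Fligner–Killeen
statistic follows the normal-scores construction: jointly rank the
absolute deviations from group medians, map rank r to
Φ⁻¹(1/2 + r/(2(N+1))), and refer Σ n_g(ā_g − ā)²/V to χ²(k−1). Degenerate
inputs (both groups constant; all deviations tied) return p = 1 with a
flag rather than dividing by zero. No multiplicity adjustment is applied
to the two-frame variance-test schedule; Benjamini–Hochberg is available
behind a flag for dense schedules.

## Problem sizes

The validation suite runs the preset battery at 200 cells per group × 100
frames (ground-truth track tables), the Brownian closed-form check at 500
tracks × 99 steps, and the rendered tracking-recovery check at 30 cells ×
100 frames on a 1024² field — sizes at which the Monte-Carlo standard
errors are small relative to every asserted contrast.

## What passing tests do and do not show

The simulator establishes that the measurement chain is correct: geometry
recovers known shapes, tracking recovers known identities, statistics
recover known trends, and the two-sample tests are calibrated under the
null. It does not establish segmentation robustness to real microscopy
artifacts (uneven illumination, focus drift, debris, apoptotic
fragmentation), because the renderer does not model them; nor does it
validate against the proprietary surface/tracking implementations it
replaces — equivalence with those is not claimed, only functional
replacement. Mitosis and track merging are out of scope (the linker
neither splits nor merges), and the pipeline is strictly 2D + time.
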