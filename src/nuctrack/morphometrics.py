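"""Nuclear shape quantities.

The central shape descriptor is the object-oriented bounding box of a
nucleus: the box aligned with the principal axes of its pixel cloud.
``length_c_um`` is the extent along the first principal axis (the longest),
``length_b_um`` the extent along the second, and the C/B ratio is the
elongation measure used throughout the analysis (1 for a circle, larger for
elongated nuclei).

Area values imported from Imaris surface exports are doubled, because the
3D surface model counts both the bottom and the top face of a flat object;
:func:`correct_imaris_area` halves them.  Areas measured by this package's
own segmentation are already correct and must never pass through that
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientedBox",
    "oriented_bounding_box",
    "cb_ratio",
    "correct_imaris_area",
    "LOW_CONFIDENCE_CB",
]

#: C/B below this is treated as "effectively circular": the major-axis
#: orientation is still reported but flagged low-confidence, and alignment
#: angles built on it are masked downstream.
LOW_CONFIDENCE_CB = 1.05


@dataclass(frozen=True)
class OrientedBox:
    """Principal-axis-aligned bounding box of a 2D point cloud.

    Attributes
    ----------
    length_c_um : float
        Extent along the first principal axis (always the larger), µm.
    length_b_um : float
        Extent along the second principal axis, µm.
    orientation_deg : float
        Direction of the C axis in degrees, reported mod 180 (nuclear axes
        are undirected).
    low_confidence : bool
        True when C/B < 1.05; the orientation of a near-circular object is
        not meaningful.
    """

    length_c_um: float
    length_b_um: float
    orientation_deg: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.length_c_um >= self.length_b_um > 0):
            raise ValueError(
                f"invalid oriented box: C={self.length_c_um}, B={self.length_b_um} "
                "(need C >= B > 0)"
            )
        if not (0.0 <= self.orientation_deg < 180.0):
            raise ValueError(f"orientation {self.orientation_deg} not in [0, 180)")

    @property
    def cb_ratio(self) -> float:
        return self.length_c_um / self.length_b_um


def oriented_bounding_box(
    points: np.ndarray, pad: float = 0.0, label: object = None
) -> OrientedBox:
    """Compute the principal-axis oriented bounding box of a point set.

    The axes are the eigenvectors of the coordinate covariance matrix; the
    extents are max minus min of the projections onto each axis.  Axes are
    ordered so that C >= B.

    Parameters
    ----------
    points : (n, 2) array
        Point coordinates (x, y) in µm.  At least 3 non-collinear points.
    pad : float
        Added to both extents.  For rasterized objects pass the pixel size:
        pixel centers underestimate the footprint of the pixel squares by
        one pixel per axis.
    label : optional
        Identifier used in error messages for degenerate objects.

    Raises
    ------
    ValueError
        If the point set is degenerate (fewer than 3 points, or collinear).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) coordinates")
    name = f"object {label!r}" if label is not None else "point set"
    if pts.shape[0] < 3:
        raise ValueError(f"{name} is degenerate: need >= 3 points, got {pts.shape[0]}")

    centered = pts - pts.mean(axis=0)
    scale = float(np.max(np.abs(centered))) or 1.0
    if _is_collinear(centered, scale):
        raise ValueError(f"{name} is degenerate: points are collinear or coincident")
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending

    # major axis = eigenvector of the largest eigenvalue
    axes = evecs[:, ::-1]
    proj = centered @ axes
    extents = proj.max(axis=0) - proj.min(axis=0) + pad
    order = [0, 1] if extents[0] >= extents[1] else [1, 0]
    length_c = float(extents[order[0]])
    length_b = float(extents[order[1]])
    if length_b <= 0:
        raise ValueError(f"{name} is degenerate: zero extent along an axis")
    major = axes[:, order[0]]
    orientation = float(np.degrees(np.arctan2(major[1], major[0])) % 180.0)
    if orientation >= 180.0:  # guard against -0.0 wraparound
        orientation = 0.0
    return OrientedBox(
        length_c_um=length_c,
        length_b_um=length_b,
        orientation_deg=orientation,
        low_confidence=(length_c / length_b) < LOW_CONFIDENCE_CB,
    )


def _is_collinear(centered: np.ndarray, scale: float) -> bool:
    # rank of the centered cloud < 2 within a scale-relative tolerance
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] <= 1e-9 * max(s[0], scale))


def cb_ratio(box: OrientedBox) -> float:
    """Elongation ratio Length-C / Length-B (>= 1; 1 for a circle)."""
    return box.cb_ratio


def correct_imaris_area(raw_area_um2: float) -> float:
    """Halve a raw Imaris surface-export area.

    The Imaris surface model is a closed 3D surface, so its "Area" of a
    flat nucleus counts both the bottom and the top face; the planar
    nuclear footprint is half the exported value.  Apply only to areas read
    from Imaris CSV exports — internally segmented areas are already planar.
    """
    raw = np.asarray(raw_area_um2, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("raw Imaris area must be positive")
    out = raw / 2.0
    return float(out) if np.isscalar(raw_area_um2) else out
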