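"""Radius-of-curvature fitting of the central line and its thirds.

The whole midline and each of its three equal-arc-length segments (proximal,
middle, distal) are fitted with a circle; the fitted radii, converted to
millimetres through the pixel spacing, are the bowing measurements.

Circle fitting is an algebraic least-squares (Kåsa) fit followed by a
geometric (orthogonal-distance) refinement, so that all midline points
contribute — a three-point circle would be fragile to tracing noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .errors import ParameterError, StraightSegmentError
from .geometry import arc_length, as_xy, resample_uniform
from .territory import Midline

__all__ = [
    "CircleFit",
    "RadiusMeasurement",
    "fit_circle",
    "split_equal_thirds",
    "measure_radii",
    "NEAR_STRAIGHT_RADIUS_PX",
]

#: Fits with a radius above this are flagged near-straight rather than erroring.
NEAR_STRAIGHT_RADIUS_PX = 1e5

#: Number of uniform arc-length intervals the midline is resampled to before
#: fitting (robust to the non-uniform spacing of raster meeting points).
RESAMPLE_INTERVALS = 300


@dataclass(frozen=True)
class CircleFit:
    """A fitted circle with its root-mean-square orthogonal residual (px)."""

    center: np.ndarray
    radius: float
    rms_residual: float

    @property
    def near_straight(self) -> bool:
        return self.radius > NEAR_STRAIGHT_RADIUS_PX


@dataclass(frozen=True)
class RadiusMeasurement:
    """The four radii of one measurement, in millimetres.

    ``magnification`` divides the pixel radii: a radiograph enlarged by
    factor m projects a radius R as m*R on the detector.
    """

    whole: float
    proximal: float
    middle: float
    distal: float
    structure: Literal["outline", "canal"]
    pixel_spacing: float
    magnification: float = 1.0
    subject: str | None = None
    observer: str | None = None
    repeat: int | None = None
    rms_residuals: tuple[float, float, float, float] | None = None
    near_straight: tuple[bool, bool, bool, bool] | None = None

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "structure": self.structure,
            "observer": self.observer,
            "repeat": self.repeat,
            "whole_mm": self.whole,
            "proximal_mm": self.proximal,
            "middle_mm": self.middle,
            "distal_mm": self.distal,
        }


def _kasa(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic circle fit: linear least squares on x^2+y^2 = 2cx·x+2cy·y+k."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    # collinearity shows as a rank-deficient normal system
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[0] / max(sv[-1], np.finfo(float).tiny) > 1e14:
        span = float(arc_length(xy)) if len(xy) >= 2 else 0.0
        raise StraightSegmentError(
            f"points are collinear over a span of {span:.1f} px; no finite circle fits",
            span=span,
        )
    cx, cy, k = sol
    r2 = k + cx * cx + cy * cy
    if r2 <= 0:
        raise StraightSegmentError("degenerate algebraic circle fit")
    return np.array([cx, cy]), float(np.sqrt(r2))


def fit_circle(points) -> CircleFit:
    """Least-squares circle through an ordered point sequence.

    Algebraic (Kåsa) fit, then a geometric refinement minimizing the
    orthogonal distances.  Raises :class:`StraightSegmentError` on collinear
    input.
    """
    xy = as_xy(points)
    if len(xy) < 3:
        raise ParameterError("circle fitting needs at least 3 points")
    # center & scale for conditioning
    mu = xy.mean(axis=0)
    scale = float(np.max(np.abs(xy - mu)))
    if scale == 0:
        raise ParameterError("all points coincide")
    z = (xy - mu) / scale
    center0, r0 = _kasa(z)

    def resid(p):
        return np.hypot(z[:, 0] - p[0], z[:, 1] - p[1]) - p[2]

    fit = least_squares(resid, np.array([*center0, r0]), method="lm")
    cx, cy, r = fit.x
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2))) * scale
    return CircleFit(center=np.array([cx, cy]) * scale + mu, radius=float(abs(r)) * scale,
                     rms_residual=rms)


def split_equal_thirds(midline) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three contiguous sub-polylines of equal arc length.

    The midline is resampled to ``RESAMPLE_INTERVALS`` uniform arc-length
    intervals first; the two cut points are duplicated into both neighbors.
    """
    xy = midline.points.xy if isinstance(midline, Midline) else as_xy(midline)
    if arc_length(xy) <= 0:
        raise ParameterError("midline has zero arc length")
    n = RESAMPLE_INTERVALS  # divisible by 3 so the cuts land on samples
    pts = resample_uniform(xy, n + 1)
    k = n // 3
    return pts[: k + 1], pts[k : 2 * k + 1], pts[2 * k :]


def measure_radii(
    midline,
    pixel_spacing: float,
    magnification: float = 1.0,
    *,
    structure: Literal["outline", "canal"] | None = None,
    subject: str | None = None,
    observer: str | None = None,
    repeat: int | None = None,
) -> RadiusMeasurement:
    """Whole and per-third radii of a midline, in millimetres.

    mm radius = pixel radius × pixel_spacing / magnification.
    """
    if pixel_spacing <= 0:
        raise ParameterError("pixel_spacing must be positive (mm per pixel)")
    if magnification <= 0:
        raise ParameterError("magnification must be positive")
    xy = midline.points.xy if isinstance(midline, Midline) else as_xy(midline)
    if structure is None:
        structure = midline.source if isinstance(midline, Midline) else "outline"
    whole_pts = resample_uniform(xy, RESAMPLE_INTERVALS + 1)
    parts = {"whole": whole_pts}
    parts["proximal"], parts["middle"], parts["distal"] = split_equal_thirds(xy)
    fits: dict[str, CircleFit] = {}
    for name, pts in parts.items():
        try:
            fits[name] = fit_circle(pts)
        except StraightSegmentError as err:
            raise StraightSegmentError(f"{name} segment: {err}", span=err.span) from err
    to_mm = pixel_spacing / magnification
    return RadiusMeasurement(
        whole=fits["whole"].radius * to_mm,
        proximal=fits["proximal"].radius * to_mm,
        middle=fits["middle"].radius * to_mm,
        distal=fits["distal"].radius * to_mm,
        structure=structure,
        pixel_spacing=pixel_spacing,
        magnification=magnification,
        subject=subject,
        observer=observer,
        repeat=repeat,
        rms_residuals=tuple(fits[k].rms_residual for k in ("whole", "proximal", "middle", "distal")),
        near_straight=tuple(fits[k].near_straight for k in ("whole", "proximal", "middle", "distal")),
    )
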