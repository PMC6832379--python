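"""Planar geometry primitives shared by all measurement stages.

Coordinate convention: continuous pixel coordinates with the origin at the
top-left of the image, x rightward, y downward, 0-based.  All geometry is in
pixels; conversion to millimetres happens only at radius reporting.  Angles
are in degrees (0 = +x, counterclockwise positive in image axes); internal
math uses radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidPolylineError, ParameterError

__all__ = [
    "Polyline",
    "Line2D",
    "as_xy",
    "arc_length",
    "cumulative_arc_length",
    "resample_uniform",
    "point_at",
    "intersect_line_polyline",
    "local_tangent_angle",
    "project_point",
    "polyline_distance",
]


def as_xy(poly) -> np.ndarray:
    """Coerce a Polyline or (N, 2) array-like to a float (N, 2) array."""
    if isinstance(poly, Polyline):
        return poly.xy
    xy = np.asarray(poly, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InvalidPolylineError(f"expected (N, 2) coordinates, got shape {xy.shape}")
    return xy


@dataclass(frozen=True)
class Polyline:
    """An open, ordered piecewise-linear curve in pixel coordinates.

    Consecutive points must be distinct; no closure is assumed.
    """

    xy: np.ndarray

    def __post_init__(self):
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise InvalidPolylineError(f"expected (N, 2) coordinates, got shape {xy.shape}")
        if len(xy) < 2:
            raise InvalidPolylineError("a polyline needs at least 2 points")
        if not np.all(np.isfinite(xy)):
            raise InvalidPolylineError("polyline coordinates must be finite")
        if np.any(np.all(np.diff(xy, axis=0) == 0.0, axis=1)):
            raise InvalidPolylineError("consecutive polyline points must be distinct")
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def length(self) -> float:
        return arc_length(self.xy)


@dataclass(frozen=True)
class Line2D:
    """An infinite line given by an anchor point and a direction angle.

    ``angle_deg`` follows the image convention: 0 = +x, counterclockwise
    positive in image axes (which look clockwise on screen since y points
    down).
    """

    anchor: np.ndarray
    angle_deg: float

    def __post_init__(self):
        anchor = np.asarray(self.anchor, dtype=float).reshape(2)
        if not np.all(np.isfinite(anchor)) or not np.isfinite(self.angle_deg):
            raise ParameterError("line anchor and angle must be finite")
        object.__setattr__(self, "anchor", anchor)

    @property
    def direction(self) -> np.ndarray:
        t = np.deg2rad(self.angle_deg)
        return np.array([np.cos(t), np.sin(t)])

    @classmethod
    def through(cls, p: np.ndarray, q: np.ndarray) -> "Line2D":
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        d = q - p
        if np.hypot(*d) == 0.0:
            raise ParameterError("cannot build a line through two identical points")
        return cls(p, float(np.rad2deg(np.arctan2(d[1], d[0]))))

    def signed_distance(self, points) -> np.ndarray:
        """Perpendicular signed distance of points to the line.

        Positive on the side the direction's left normal points to.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.direction
        rel = pts - self.anchor
        return d[0] * rel[:, 1] - d[1] * rel[:, 0]

    def distance(self, points) -> np.ndarray:
        return np.abs(self.signed_distance(points))


def arc_length(poly) -> float:
    """Total length of a polyline: sum of consecutive Euclidean distances."""
    xy = as_xy(poly)
    if len(xy) < 2:
        raise InvalidPolylineError("arc_length needs at least 2 points")
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def cumulative_arc_length(poly) -> np.ndarray:
    """Arc-length position of every vertex; starts at 0."""
    xy = as_xy(poly)
    if len(xy) < 2:
        raise InvalidPolylineError("needs at least 2 points")
    seg = np.hypot(*np.diff(xy, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_uniform(poly, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    The first and last points are preserved exactly.
    """
    if n < 2:
        raise ParameterError(f"resample_uniform needs n >= 2, got {n}")
    xy = as_xy(poly)
    s = cumulative_arc_length(xy)
    t = np.linspace(0.0, s[-1], n)
    # iterate so the *output* chords are equal (fixed point: resampling an
    # already-uniform polyline leaves it unchanged)
    for _ in range(8):
        out = np.column_stack([np.interp(t, s, xy[:, 0]), np.interp(t, s, xy[:, 1])])
        chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(out, axis=0).T))])
        t_new = np.interp(np.linspace(0.0, chord[-1], n), chord, t)
        if np.max(np.abs(t_new - t)) < 1e-9 * max(s[-1], 1.0):
            t = t_new
            break
        t = t_new
    out = np.column_stack([np.interp(t, s, xy[:, 0]), np.interp(t, s, xy[:, 1])])
    out[0] = xy[0]
    out[-1] = xy[-1]
    return out


def point_at(poly, s: float) -> np.ndarray:
    """Point at arc-length position ``s`` along the polyline (clamped)."""
    xy = as_xy(poly)
    cs = cumulative_arc_length(xy)
    s = float(np.clip(s, 0.0, cs[-1]))
    return np.array([np.interp(s, cs, xy[:, 0]), np.interp(s, cs, xy[:, 1])])


def intersect_line_polyline(line: Line2D, poly, *, tol: float = 1e-9):
    """All crossings of an infinite line with a polyline.

    Returns a list of ``(point, segment_index, arc_length_position)`` ordered
    by arc-length position.  A vertex lying on the line (tangential touch) is
    counted once.
    """
    xy = as_xy(poly)
    cs = cumulative_arc_length(xy)
    scale = max(1.0, float(np.max(np.abs(xy - line.anchor))))
    d = line.signed_distance(xy)
    on = np.abs(d) <= tol * scale
    hits: list[tuple[np.ndarray, int, float]] = []
    # vertices exactly on the line (tangential touches), each counted once
    for i in np.flatnonzero(on):
        hits.append((xy[i].copy(), max(int(i) - 1, 0), float(cs[i])))
    # strict sign changes in segment interiors
    cross = (d[:-1] * d[1:] < 0.0) & ~on[:-1] & ~on[1:]
    idx = np.flatnonzero(cross)
    if idx.size:
        t = d[idx] / (d[idx] - d[idx + 1])
        pts = xy[idx] + t[:, None] * (xy[idx + 1] - xy[idx])
        pos = cs[idx] + t * (cs[idx + 1] - cs[idx])
        hits.extend((pts[k], int(idx[k]), float(pos[k])) for k in range(idx.size))
    hits.sort(key=lambda h: h[2])
    return hits


def local_tangent_angle(poly, s: float, window: float) -> float:
    """Direction angle (degrees, in (-90, 90]) of the border near position ``s``.

    Fits a total-least-squares line through every vertex within +-window/2 of
    arc length of ``s`` (plus the interpolated window endpoints); with fewer
    than 2 vertices in the window it falls back to the containing segment's
    direction.
    """
    if window <= 0:
        raise ParameterError("tangent window must be positive")
    xy = as_xy(poly)
    cs = cumulative_arc_length(xy)
    if not (0.0 <= s <= cs[-1] + 1e-9):
        raise ParameterError(f"position {s} outside [0, {cs[-1]}]")
    lo, hi = s - window / 2.0, s + window / 2.0
    mask = (cs >= lo) & (cs <= hi)
    pts = xy[mask]
    if len(pts) < 2:
        # containing segment's direction
        i = int(np.clip(np.searchsorted(cs, s, side="right") - 1, 0, len(xy) - 2))
        v = xy[i + 1] - xy[i]
    else:
        ends = [point_at(xy, np.clip(lo, 0, cs[-1])), point_at(xy, np.clip(hi, 0, cs[-1]))]
        pts = np.vstack([pts, ends])
        centered = pts - pts.mean(axis=0)
        # principal direction = dominant right singular vector
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        v = vt[0]
    ang = np.rad2deg(np.arctan2(v[1], v[0]))
    # fold into (-90, 90]
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def project_point(poly, p) -> tuple[float, float, np.ndarray]:
    """Orthogonal projection of a point onto a polyline.

    Returns ``(distance, arc_length_position, foot_point)`` for the nearest
    point of the polyline.
    """
    xy = as_xy(poly)
    p = np.asarray(p, dtype=float)
    a = xy[:-1]
    b = xy[1:]
    ab = b - a
    seglen2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(seglen2 == 0, 1, seglen2), 0, 1)
    foot = a + t[:, None] * ab
    dist = np.hypot(*(foot - p).T)
    i = int(np.argmin(dist))
    cs = cumulative_arc_length(xy)
    s = float(cs[i] + t[i] * np.sqrt(seglen2[i]))
    return float(dist[i]), s, foot[i]


def polyline_distance(poly, points, *, window: int = 12) -> np.ndarray:
    """Minimum distance from each query point to the polyline.

    Exact point-to-segment distance, restricted to the ``window`` segments on
    either side of each query's nearest vertex (found by a KD-tree).  For the
    smooth, densely sampled curves used here the true foot point always lies
    within a couple of vertices of the nearest one, so the window is a wide
    safety margin; ``window >= number of segments`` degrades gracefully to
    the brute-force answer.
    """
    from scipy.spatial import cKDTree

    xy = as_xy(poly)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    nseg = len(xy) - 1
    _, nearest = cKDTree(xy).query(pts)
    offs = np.arange(-window, window + 1)
    segs = np.clip(nearest[:, None] + offs[None, :], 0, nseg - 1)  # (M, W)
    a = xy[segs]  # (M, W, 2)
    ab = xy[segs + 1] - a
    seglen2 = np.einsum("mwj,mwj->mw", ab, ab)
    seglen2 = np.where(seglen2 == 0, 1.0, seglen2)
    ap = pts[:, None, :] - a
    t = np.clip(np.einsum("mwj,mwj->mw", ap, ab) / seglen2, 0.0, 1.0)
    diff = ap - t[..., None] * ab
    d = np.sqrt(np.einsum("mwj,mwj->mw", diff, diff))
    return d.min(axis=1)
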