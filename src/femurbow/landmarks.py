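"""Construction of the anatomical measurement endpoints.

The operator supplies three points on a lateral radiograph: the two
shaft/condyle junctions at the distal end of the cortical outline (points 1
and 2) and the bottom of the lesser trochanter on the lower cortical border
(point 3).  Everything else is derived:

* the distal end line joins points 1 and 2; its crossings with the medullary
  canal borders are the distal canal endpoints a and b;
* the proximal end line passes through point 3 and makes equal acute angles
  with the local directions of the lower and upper cortical borders; its
  crossing with the upper cortical border is point 4, and its crossings with
  the canal borders are the proximal canal endpoints c and d;
* each border is finally trimmed to the sub-curve between its two endpoints.

When the two cortical borders are locally parallel every direction through
point 3 satisfies the equal-angle condition; the perpendicular to the lower
border's local tangent is then chosen (a well-defined "cross-sectional" cut).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import LandmarkConstructionError, ParameterError
from .geometry import (
    Line2D,
    Polyline,
    as_xy,
    cumulative_arc_length,
    intersect_line_polyline,
    local_tangent_angle,
    project_point,
)

__all__ = [
    "BorderPair",
    "LandmarkSet",
    "distal_line_and_canal_ends",
    "equal_angle_proximal_line",
    "proximal_canal_ends",
    "trim_to_endpoints",
    "construct_landmarks",
    "trim_pair",
]

logger = logging.getLogger("femurbow")

ON_BORDER_TOL = 0.5  # px; how close a claimed on-border point must lie


@dataclass(frozen=True)
class BorderPair:
    """Upper (anterior) and lower (posterior) border of one structure.

    Both polylines are ordered proximal-to-distal and must not cross each
    other.  ``structure`` tags whether they outline the cortical bone
    ("outline") or the medullary canal ("canal").
    """

    upper: Polyline
    lower: Polyline
    structure: Literal["outline", "canal"]

    def __post_init__(self):
        if self.structure not in ("outline", "canal"):
            raise ParameterError(f"unknown structure tag {self.structure!r}")


@dataclass(frozen=True)
class LandmarkSet:
    """The eight measurement endpoints plus the two end lines.

    p1/p2: distal upper/lower cortical junctions (operator input).
    p3: bottom of the lesser trochanter on the lower cortical border
    (operator input).  p4: derived proximal upper cortical endpoint.
    a/b: distal canal endpoints; c/d: proximal canal endpoints.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray | None
    a: np.ndarray | None
    b: np.ndarray | None
    c: np.ndarray | None
    d: np.ndarray | None
    proximal_line: Line2D
    distal_line: Line2D


def _acute_between(angle_a_deg: float, angle_b_deg: float) -> float:
    """Acute angle in [0, 90] between two undirected directions."""
    d = abs(angle_a_deg - angle_b_deg) % 180.0
    return min(d, 180.0 - d)


def _default_window(poly) -> float:
    """Tangent-estimation window: 21 vertex spacings of the border."""
    xy = as_xy(poly)
    return 21.0 * float(cumulative_arc_length(xy)[-1]) / (len(xy) - 1)


def _pick_crossing(hits, *, mode: str):
    if not hits:
        return None
    if mode == "distal":  # borders run proximal->distal: largest arc length
        return hits[-1]
    if mode == "proximal":
        return hits[0]
    raise ValueError(mode)


def distal_line_and_canal_ends(p1, p2, canal: BorderPair):
    """Line through the distal cortical junctions and its canal crossings.

    Returns ``(line, a, b)`` where a/b are the most distal crossings with the
    canal's upper/lower border.
    """
    line = Line2D.through(p1, p2)
    ends = []
    for name, border in (("upper", canal.upper), ("lower", canal.lower)):
        hit = _pick_crossing(intersect_line_polyline(line, border), mode="distal")
        if hit is None:
            raise LandmarkConstructionError(
                f"distal end line does not cross the canal {name} border"
            )
        ends.append(hit[0])
    return line, ends[0], ends[1]


def equal_angle_proximal_line(
    p3,
    outline: BorderPair,
    search_range: float = 60.0,
    *,
    tangent_window: float | None = None,
    angle_tol: float = 0.05,
):
    """The proximal end line through point 3 and its upper-border crossing.

    Finds the direction through ``p3`` whose acute angle to the lower
    cortical border at p3 equals its acute angle to the upper cortical
    border at the crossing point, to within ``angle_tol`` degrees.  The root
    nearest the perpendicular of the lower border's tangent is taken; for
    locally parallel borders (every direction qualifies) the perpendicular
    itself is returned.
    """
    p3 = np.asarray(p3, dtype=float)
    dist, s3, foot = project_point(outline.lower, p3)
    if dist > ON_BORDER_TOL:
        raise LandmarkConstructionError(
            f"point 3 lies {dist:.2f} px from the lower cortical border (> {ON_BORDER_TOL})"
        )
    p3 = foot
    w_lower = tangent_window if tangent_window is not None else _default_window(outline.lower)
    w_upper = tangent_window if tangent_window is not None else _default_window(outline.upper)
    tau_lower = local_tangent_angle(outline.lower, s3, w_lower)
    phi_perp = tau_lower + 90.0

    def residual(phi: float) -> float | None:
        """Signed acute-angle difference (lower minus upper); None if the
        candidate line misses the upper border."""
        line = Line2D(p3, phi)
        hits = intersect_line_polyline(line, outline.upper)
        if not hits:
            return None
        # crossing nearest to p3: a steep proximal line meets the upper
        # border once near the cut; distant wiggle crossings are spurious
        pt, _, s_hit = min(hits, key=lambda h: float(np.hypot(*(h[0] - p3))))
        tau_upper = local_tangent_angle(outline.upper, s_hit, w_upper)
        return _acute_between(phi, tau_lower) - _acute_between(phi, tau_upper)

    step = 0.5
    phis = np.arange(phi_perp - search_range, phi_perp + search_range + step / 2, step)
    vals = [residual(p) for p in phis]
    defined = [(p, v) for p, v in zip(phis, vals) if v is not None]
    if not defined:
        raise LandmarkConstructionError("no direction through point 3 crosses the upper border")
    if max(abs(v) for _, v in defined) < 1e-9:
        phi_star = phi_perp  # parallel-border degeneracy
    else:
        roots = []
        for (pa, va), (pb, vb) in zip(defined[:-1], defined[1:]):
            if va == 0.0:
                roots.append(pa)
                continue
            if va * vb < 0.0:
                lo, hi, flo = pa, pb, va
                while hi - lo > 1e-4:
                    mid = 0.5 * (lo + hi)
                    fm = residual(mid)
                    if fm is None:
                        break
                    if abs(fm) <= angle_tol / 10.0:
                        lo = hi = mid
                        break
                    if flo * fm < 0.0:
                        hi = mid
                    else:
                        lo, flo = mid, fm
                roots.append(0.5 * (lo + hi))
        if defined[-1][1] == 0.0:
            roots.append(defined[-1][0])
        if not roots:
            raise LandmarkConstructionError(
                "equal-angle condition has no root in the search range"
            )
        phi_star = min(roots, key=lambda r: abs(r - phi_perp))

    line = Line2D(p3, phi_star)
    hits = intersect_line_polyline(line, outline.upper)
    if not hits:
        raise LandmarkConstructionError("proximal line does not cross the upper border")
    p4 = min(hits, key=lambda h: float(np.hypot(*(h[0] - p3))))[0]
    res = residual(phi_star)
    if res is not None and abs(res) > angle_tol:
        # the root was a sign change across a jump: on hand-traced (noisy)
        # borders the tangent estimates themselves fluctuate by more than the
        # solver tolerance, so the condition cannot be met exactly; keep the
        # nearest-perpendicular crossing and record the residual
        logger.info("equal-angle residual %.3f deg exceeds solver tolerance %s", res, angle_tol)
    return line, p4


def proximal_canal_ends(proximal_line: Line2D, canal: BorderPair):
    """Most proximal crossings of the proximal end line with the canal borders."""
    ends = []
    for name, border in (("upper", canal.upper), ("lower", canal.lower)):
        hit = _pick_crossing(intersect_line_polyline(proximal_line, border), mode="proximal")
        if hit is None:
            raise LandmarkConstructionError(
                f"proximal end line does not cross the canal {name} border"
            )
        ends.append(hit[0])
    return ends[0], ends[1]


def _clip(poly, start, end) -> Polyline:
    xy = as_xy(poly)
    d0, s0, f0 = project_point(xy, start)
    d1, s1, f1 = project_point(xy, end)
    for d, label in ((d0, "start"), (d1, "end")):
        if d > ON_BORDER_TOL:
            raise LandmarkConstructionError(
                f"trim {label} point lies {d:.2f} px off the border (> {ON_BORDER_TOL})"
            )
    if s0 > s1:
        (s0, f0), (s1, f1) = (s1, f1), (s0, f0)
    cs = cumulative_arc_length(xy)
    eps = 1e-9 * max(1.0, cs[-1])
    inside = xy[(cs > s0 + eps) & (cs < s1 - eps)]
    pts = [f0, *inside, f1]
    out = [pts[0]]
    for p in pts[1:]:
        if np.hypot(*(p - out[-1])) > 1e-12:
            out.append(p)
    if len(out) < 2:
        raise LandmarkConstructionError("trimmed border degenerates to a point")
    return Polyline(np.asarray(out))


def trim_to_endpoints(pair: BorderPair, start_upper, end_upper, start_lower, end_lower) -> BorderPair:
    """Clip both borders to the sub-curves between their endpoints.

    Endpoints must lie on their border (within 0.5 px) and are inserted as
    exact first/last vertices; output keeps the proximal-to-distal order.
    """
    return replace(
        pair,
        upper=_clip(pair.upper, start_upper, end_upper),
        lower=_clip(pair.lower, start_lower, end_lower),
    )


def construct_landmarks(
    p1,
    p2,
    p3,
    outline: BorderPair,
    canal: BorderPair | None = None,
    *,
    search_range: float = 60.0,
    tangent_window: float | None = None,
) -> LandmarkSet:
    """Derive the full landmark set from the three operator points."""
    distal_line = Line2D.through(p1, p2)
    a = b = c = d = None
    if canal is not None:
        distal_line, a, b = distal_line_and_canal_ends(p1, p2, canal)
    proximal_line, p4 = equal_angle_proximal_line(
        p3, outline, search_range, tangent_window=tangent_window
    )
    if canal is not None:
        c, d = proximal_canal_ends(proximal_line, canal)
    return LandmarkSet(
        p1=np.asarray(p1, dtype=float),
        p2=np.asarray(p2, dtype=float),
        p3=np.asarray(p3, dtype=float),
        p4=p4,
        a=a,
        b=b,
        c=c,
        d=d,
        proximal_line=proximal_line,
        distal_line=distal_line,
    )


def trim_pair(pair: BorderPair, lm: LandmarkSet) -> BorderPair:
    """Trim a border pair to its landmark endpoints for midline extraction."""
    if pair.structure == "outline":
        if lm.p4 is None:
            raise LandmarkConstructionError("outline trimming needs point 4")
        return trim_to_endpoints(pair, lm.p4, lm.p1, lm.p3, lm.p2)
    if any(v is None for v in (lm.a, lm.b, lm.c, lm.d)):
        raise LandmarkConstructionError("canal trimming needs endpoints a, b, c, d")
    return trim_to_endpoints(pair, lm.c, lm.a, lm.d, lm.b)
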