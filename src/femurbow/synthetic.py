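"""Phantom generators with known ground-truth geometry.

Every pipeline stage is testable without radiographs: the generators emit
border polylines whose true central line and radii are known in closed form.

* :func:`generate_annular_pair` — two concentric circular arcs at R +- w/2;
  the true midline is the circle of radius R.
* :func:`generate_three_arc_femur` — a "hockey-stick" shaft: a centerline of
  three tangent-continuous circular arcs of equal arc length (distinct
  proximal/middle/distal radii), with cortical-outline and medullary-canal
  borders offset by +- half-width along the normal.  Offsetting a circular
  arc along its normal yields a concentric arc, so each segment's true
  midline radius is exactly the requested one.
* :func:`generate_repeat_set` — re-jitters the annotation (borders and the
  three operator points) and pushes each repeat through the full pipeline,
  emulating observer re-tracing for reliability studies.

The noise model is isotropic Gaussian jitter on border vertices (hand
tracing); no image-intensity simulation — the method consumes polylines,
not pixels.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import Line2D, Polyline, project_point
from .landmarks import BorderPair, LandmarkSet
from .pipeline import measure_borders

__all__ = [
    "SyntheticTruth",
    "generate_annular_pair",
    "generate_three_arc_femur",
    "generate_repeat_set",
]

#: Default study-like phantom parameters: the reported per-segment radii of
#: an adult Asian femur, a ~330 mm measured shaft, mid-shaft outer diameter
#: ~27 mm and canal diameter ~13 mm, at the radiographs' 0.15 mm/px.
DEFAULT_RADII_MM = (752.0, 1379.0, 599.0)
DEFAULT_SEGMENT_LENGTH_MM = 110.0
DEFAULT_WIDTHS_MM = (27.0, 13.0)
DEFAULT_PIXEL_SPACING = 0.15


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters paired with the emitted borders.

    ``radii_mm`` holds (proximal, middle, distal) for the three-arc phantom
    or a single-element tuple for the annular one; widths/extents are in the
    units noted per field.  ``regenerate()``-style reuse goes through
    :func:`generate_repeat_set`, which rebuilds the noiseless phantom from
    these parameters.
    """

    kind: str  # "annular" | "three_arc"
    radii_mm: tuple[float, ...]
    pixel_spacing: float  # mm per px
    noise_sigma: float  # px
    seed: int
    width_px: float | None = None  # annular: border separation
    extent_deg: float | None = None  # annular: angular extent
    segment_length_mm: float | None = None  # three-arc
    widths_mm: tuple[float, float] | None = None  # three-arc: (outline, canal)
    extras: dict = field(default_factory=dict)


def _jitter(rng: np.random.Generator, xy: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return xy
    return xy + rng.normal(0.0, sigma, size=xy.shape)


def _snap(border: Polyline, p: np.ndarray) -> np.ndarray:
    """Foot point of p on the border (operator points lie on drawn curves)."""
    return project_point(border, p)[2]


def generate_annular_pair(
    radius: float,
    width: float,
    extent: float = 30.0,
    n: int = 400,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    structure: str = "outline",
    pad_deg: float = 3.0,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
) -> tuple[BorderPair, LandmarkSet, SyntheticTruth]:
    """Concentric-arc phantom: borders at radius +- width/2 (all in px).

    The arcs span ``extent`` degrees between the landmark end lines and are
    generated with ``pad_deg`` of overshoot on each side so the end lines
    cross them transversally.  Landmarks sit at the analytic arc ends.
    """
    if radius <= width:
        raise ParameterError(f"radius ({radius}) must exceed width ({width})")
    if extent <= 0 or n < 2:
        raise ParameterError("extent must be positive and n >= 2")
    rng = np.random.default_rng(seed)
    r_up = radius + width / 2.0  # upper = outer (anterior, convex) side
    r_lo = radius - width / 2.0
    # center below the arc so the bow opens downward like an anterior bow
    center = np.array([r_up + 10.0, r_up + 10.0])
    th_p = -90.0 - extent / 2.0  # proximal (left) end angle
    th_d = -90.0 + extent / 2.0
    thetas = np.union1d(np.linspace(th_p - pad_deg, th_d + pad_deg, n), [th_p, th_d])
    u = np.column_stack([np.cos(np.deg2rad(thetas)), np.sin(np.deg2rad(thetas))])

    def arc(r):  # ordered proximal -> distal (increasing theta)
        return center + r * u

    upper = Polyline(_jitter(rng, arc(r_up), noise_sigma))
    lower = Polyline(_jitter(rng, arc(r_lo), noise_sigma))
    pair = BorderPair(upper=upper, lower=lower, structure=structure)

    up_p, lo_p = center + r_up * _unit(th_p), center + r_lo * _unit(th_p)
    up_d, lo_d = center + r_up * _unit(th_d), center + r_lo * _unit(th_d)
    if noise_sigma > 0:  # keep endpoints on the (jittered) drawn borders
        up_p, up_d = _snap(upper, up_p), _snap(upper, up_d)
        lo_p, lo_d = _snap(lower, lo_p), _snap(lower, lo_d)
    lm = LandmarkSet(
        p1=up_d, p2=lo_d, p3=lo_p, p4=up_p,
        a=up_d, b=lo_d, c=up_p, d=lo_p,
        proximal_line=Line2D(center, th_p),
        distal_line=Line2D(center, th_d),
    )
    truth = SyntheticTruth(
        kind="annular",
        radii_mm=(radius * pixel_spacing,),
        pixel_spacing=pixel_spacing,
        noise_sigma=noise_sigma,
        seed=seed,
        width_px=width,
        extent_deg=extent,
        extras={"radius_px": radius, "n": n, "structure": structure},
    )
    return pair, lm, truth


def _unit(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([np.cos(t), np.sin(t)])


class _ThreeArcCenterline:
    """Arc-length-parameterized centerline of three tangent-continuous arcs."""

    def __init__(self, radii_px, seg_len_px):
        self.kappa = np.array([1.0 / r for r in radii_px])
        self.L = seg_len_px
        turns = self.kappa * seg_len_px
        self.psi0 = -float(np.sum(turns)) / 2.0  # symmetric overall bow
        # segment start states (position, tangent angle), s measured from 0
        self.starts = [(np.zeros(2), self.psi0)]
        for k in self.kappa:
            p, psi = self.starts[-1]
            self.starts.append((self._advance(p, psi, k, seg_len_px), psi + k * seg_len_px))

    @staticmethod
    def _advance(p0, psi0, kappa, s):
        return p0 + (1.0 / kappa) * np.array(
            [np.sin(psi0 + kappa * s) - np.sin(psi0), -np.cos(psi0 + kappa * s) + np.cos(psi0)]
        )

    def state(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Position(s) and tangent angle(s) at arc length ``s`` (scalar or
        array; overshoot extends the first/last arcs)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        i = np.clip(np.floor(s / self.L), 0, 2).astype(int)
        p0 = np.array([self.starts[j][0] for j in i])
        psi0 = np.array([self.starts[j][1] for j in i])
        k = self.kappa[i]
        ds = s - i * self.L
        psi = psi0 + k * ds
        pos = p0 + (1.0 / k)[:, None] * np.column_stack(
            [np.sin(psi) - np.sin(psi0), -np.cos(psi) + np.cos(psi0)]
        )
        return pos, psi

    def offset_point(self, s, offset: float) -> np.ndarray:
        """Point(s) displaced by ``offset`` along the normal (positive toward
        the centers of curvature, i.e. the concave/lower side)."""
        scalar = np.isscalar(s)
        p, psi = self.state(s)
        n = np.column_stack([-np.sin(psi), np.cos(psi)])
        out = p + offset * n
        return out[0] if scalar else out

    def normal_line(self, s: float) -> Line2D:
        p, psi = self.state(s)
        return Line2D(p[0], float(np.rad2deg(psi[0])) + 90.0)


def generate_three_arc_femur(
    radii_mm: tuple[float, float, float] = DEFAULT_RADII_MM,
    segment_length_mm: float = DEFAULT_SEGMENT_LENGTH_MM,
    widths_mm: tuple[float, float] = DEFAULT_WIDTHS_MM,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    point_spacing_px: float = 2.0,
    pad_mm: float = 10.0,
) -> tuple[BorderPair, BorderPair, LandmarkSet, SyntheticTruth]:
    """Hockey-stick femur phantom with known per-segment radii.

    Returns ``(outline, canal, landmarks, truth)``, all border coordinates
    in pixels.  The centerline is three tangent-continuous arcs of equal arc
    length with the given (proximal, middle, distal) radii; each border is a
    normal offset of the centerline, so the true midline of either structure
    is the centerline itself.
    """
    if any(r <= 0 for r in radii_mm) or segment_length_mm <= 0:
        raise ParameterError("radii and segment length must be positive")
    w_out, w_can = widths_mm
    if w_can >= w_out:
        raise ParameterError("canal width must be smaller than the outline width")
    if w_out / 2.0 >= min(radii_mm):
        raise ParameterError("half-width reaches the center of curvature: no inner border")
    rng = np.random.default_rng(seed)
    to_px = 1.0 / pixel_spacing
    radii_px = [r * to_px for r in radii_mm]
    seg_px = segment_length_mm * to_px
    pad_px = pad_mm * to_px
    cl = _ThreeArcCenterline(radii_px, seg_px)

    total = 3.0 * seg_px
    n_pts = max(int(np.ceil((total + 2 * pad_px) / point_spacing_px)) + 1, 8)
    ss = np.union1d(np.linspace(-pad_px, total + pad_px, n_pts), [0.0, total])

    def border(offset_px: float, sigma: float) -> Polyline:
        return Polyline(_jitter(rng, cl.offset_point(ss, offset_px), sigma))

    half_out, half_can = w_out * to_px / 2.0, w_can * to_px / 2.0
    outline = BorderPair(
        upper=border(-half_out, noise_sigma), lower=border(+half_out, noise_sigma),
        structure="outline",
    )
    canal = BorderPair(
        upper=border(-half_can, noise_sigma), lower=border(+half_can, noise_sigma),
        structure="canal",
    )
    p1 = cl.offset_point(total, -half_out)
    p2 = cl.offset_point(total, +half_out)
    p3 = cl.offset_point(0.0, +half_out)
    p4 = cl.offset_point(0.0, -half_out)
    a = cl.offset_point(total, -half_can)
    b = cl.offset_point(total, +half_can)
    c = cl.offset_point(0.0, -half_can)
    d = cl.offset_point(0.0, +half_can)
    if noise_sigma > 0:
        p1, p4 = _snap(outline.upper, p1), _snap(outline.upper, p4)
        p2, p3 = _snap(outline.lower, p2), _snap(outline.lower, p3)
        a, c = _snap(canal.upper, a), _snap(canal.upper, c)
        b, d = _snap(canal.lower, b), _snap(canal.lower, d)
    lm = LandmarkSet(
        p1=p1, p2=p2, p3=p3, p4=p4, a=a, b=b, c=c, d=d,
        proximal_line=cl.normal_line(0.0),
        distal_line=cl.normal_line(total),
    )
    truth = SyntheticTruth(
        kind="three_arc",
        radii_mm=tuple(radii_mm),
        pixel_spacing=pixel_spacing,
        noise_sigma=noise_sigma,
        seed=seed,
        segment_length_mm=segment_length_mm,
        widths_mm=tuple(widths_mm),
        extras={"pad_mm": pad_mm, "point_spacing_px": point_spacing_px},
    )
    return outline, canal, lm, truth


def generate_repeat_set(
    truth: SyntheticTruth,
    tracing_sigma: float = 1.0,
    repeats: int = 3,
    seed: int = 0,
    *,
    subject: str = "phantom",
    supersample: int = 2,
    structures: tuple[str, ...] = ("outline", "canal"),
) -> pd.DataFrame:
    """Repeat-measurement table from independently re-jittered annotations.

    Rebuilds the noiseless phantom described by ``truth``, then ``repeats``
    times jitters the borders and the three operator points (snapped back
    onto the drawn borders, as an observer clicks on the curve they traced)
    and runs the full pipeline.  Returns a long-format measurement table.
    """
    if repeats < 2:
        raise ParameterError("a repeat set needs at least 2 repeats")
    if truth.kind != "three_arc":
        raise ParameterError("repeat sets are generated from three-arc phantoms")
    rng = np.random.default_rng(seed)
    outline0, canal0, lm0, _ = generate_three_arc_femur(
        radii_mm=truth.radii_mm,  # type: ignore[arg-type]
        segment_length_mm=truth.segment_length_mm,
        widths_mm=truth.widths_mm,
        pixel_spacing=truth.pixel_spacing,
        noise_sigma=0.0,
        seed=truth.seed,
        point_spacing_px=truth.extras.get("point_spacing_px", 2.0),
        pad_mm=truth.extras.get("pad_mm", 10.0),
    )
    rows = []
    for rep in range(repeats):
        def retrace(b: Polyline) -> Polyline:
            return Polyline(_jitter(rng, b.xy, tracing_sigma))

        outline = BorderPair(retrace(outline0.upper), retrace(outline0.lower), "outline")
        canal = BorderPair(retrace(canal0.upper), retrace(canal0.lower), "canal")
        # operator clicks near the true junction points, on the traced curves
        p1 = _snap(outline.upper, _jitter(rng, lm0.p1[None], tracing_sigma)[0])
        p2 = _snap(outline.lower, _jitter(rng, lm0.p2[None], tracing_sigma)[0])
        p3 = _snap(outline.lower, _jitter(rng, lm0.p3[None], tracing_sigma)[0])
        res = measure_borders(
            outline,
            canal if "canal" in structures else None,
            p1, p2, p3,
            pixel_spacing=truth.pixel_spacing,
            supersample=supersample,
            subject=subject,
            observer="sim",
            repeat=rep,
        )
        for meas in (res.outline, res.canal):
            if meas is None or meas.structure not in structures:
                continue
            rows.append(meas.as_dict())
    return pd.DataFrame(rows)
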