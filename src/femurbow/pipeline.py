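"""End-to-end measurement: operator borders + three points -> four radii.

Chains the landmark construction, the two-seed territory midline and the
circle fitting for both structures (cortical outline and medullary canal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curvature import RadiusMeasurement, measure_radii
from .landmarks import BorderPair, LandmarkSet, construct_landmarks
from .territory import Midline, compute_midline

__all__ = ["MeasurementResult", "measure_borders"]


@dataclass(frozen=True)
class MeasurementResult:
    """Radii plus the intermediate geometry, for overlays and audits."""

    outline: RadiusMeasurement
    canal: RadiusMeasurement | None
    landmarks: LandmarkSet
    outline_midline: Midline
    canal_midline: Midline | None


def measure_borders(
    outline: BorderPair,
    canal: BorderPair | None,
    p1,
    p2,
    p3,
    *,
    pixel_spacing: float,
    magnification: float = 1.0,
    supersample: int = 2,
    subject: str | None = None,
    observer: str | None = None,
    repeat: int | None = None,
) -> MeasurementResult:
    """Measure the bowing radii of one annotated radiograph (or phantom).

    ``p1``/``p2`` are the distal shaft/condyle junctions on the upper/lower
    cortical border, ``p3`` the bottom of the lesser trochanter on the lower
    cortical border.  The canal is optional: without it only the cortical
    bow is measured.
    """
    lm = construct_landmarks(np.asarray(p1), np.asarray(p2), np.asarray(p3), outline, canal)
    mid_out = compute_midline(outline, lm, supersample=supersample)
    out_meas = measure_radii(
        mid_out,
        pixel_spacing,
        magnification,
        structure="outline",
        subject=subject,
        observer=observer,
        repeat=repeat,
    )
    mid_can = None
    can_meas = None
    if canal is not None:
        mid_can = compute_midline(canal, lm, supersample=supersample)
        can_meas = measure_radii(
            mid_can,
            pixel_spacing,
            magnification,
            structure="canal",
            subject=subject,
            observer=observer,
            repeat=repeat,
        )
    return MeasurementResult(
        outline=out_meas,
        canal=can_meas,
        landmarks=lm,
        outline_midline=mid_out,
        canal_midline=mid_can,
    )
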