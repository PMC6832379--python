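"""File formats: annotation JSON, DICOM images, measurement CSV.

The annotation document is the package's interchange format for operator
tracings: the four border polylines, the three operator landmark points and
the calibration metadata.  It is JSON (human-diffable, schema-checked by
pydantic) and versioned.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic
from pydantic import BaseModel, Field

from .errors import AnnotationError, FemurBowError
from .geometry import Polyline
from .landmarks import BorderPair

logger = logging.getLogger("femurbow")

__all__ = [
    "AnnotationDocument",
    "SubjectInfo",
    "read_annotation",
    "write_annotation",
    "read_dicom",
    "write_measurements_csv",
    "read_measurements_csv",
]

SCHEMA_VERSION = 1

_XY = list[tuple[float, float]]


class SubjectInfo(BaseModel):
    id: str = "anonymous"
    sex: str | None = None  # "F" / "M"
    age: float | None = None


class AnnotationDocument(BaseModel):
    """One operator tracing of one lateral femur radiograph (or phantom)."""

    schema_version: int = SCHEMA_VERSION
    image: str | None = None  # DICOM path; None for phantoms
    pixel_spacing: float = Field(gt=0, description="mm per pixel")
    magnification: float = Field(default=1.0, gt=0)
    outline_upper: _XY = Field(min_length=2)
    outline_lower: _XY = Field(min_length=2)
    canal_upper: _XY | None = None
    canal_lower: _XY | None = None
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    observer: str = "anonymous"
    repeat: int = 0
    subject: SubjectInfo = Field(default_factory=SubjectInfo)

    def outline_pair(self) -> BorderPair:
        return BorderPair(
            upper=Polyline(np.asarray(self.outline_upper)),
            lower=Polyline(np.asarray(self.outline_lower)),
            structure="outline",
        )

    def canal_pair(self) -> BorderPair | None:
        if self.canal_upper is None or self.canal_lower is None:
            return None
        return BorderPair(
            upper=Polyline(np.asarray(self.canal_upper)),
            lower=Polyline(np.asarray(self.canal_lower)),
            structure="canal",
        )


def read_annotation(path) -> AnnotationDocument:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as err:
        raise AnnotationError(f"cannot read annotation {path}: {err}") from err
    try:
        return AnnotationDocument.model_validate(payload)
    except pydantic.ValidationError as err:
        fields = ", ".join(".".join(map(str, e["loc"])) or "<root>" for e in err.errors())
        raise AnnotationError(f"invalid annotation {path}: bad field(s) {fields}") from err


def write_annotation(doc: AnnotationDocument, path) -> None:
    Path(path).write_text(doc.model_dump_json(indent=2))


def read_dicom(path, fallback_spacing: float | None = None):
    """Read a grayscale radiograph and its pixel spacing (mm/px).

    Spacing comes from the PixelSpacing / ImagerPixelSpacing attribute; when
    absent, ``fallback_spacing`` is used with a logged warning.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    try:
        ds = pydicom.dcmread(str(path))
        image = ds.pixel_array
    except (InvalidDicomError, OSError, AttributeError, ValueError) as err:
        raise FemurBowError(f"cannot read DICOM {path}: {err}") from err
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is not None:
        spacing = float(spacing[0])
    elif fallback_spacing is not None:
        logger.warning(
            "%s has no pixel-spacing attribute; falling back to %.4f mm/px",
            path,
            fallback_spacing,
        )
        spacing = float(fallback_spacing)
    else:
        raise FemurBowError(f"{path} has no pixel-spacing attribute and no fallback given")
    return np.asarray(image), spacing


MEASUREMENT_COLUMNS = [
    "subject",
    "structure",
    "observer",
    "repeat",
    "whole_mm",
    "proximal_mm",
    "middle_mm",
    "distal_mm",
]


def write_measurements_csv(rows, path, *, append: bool = False) -> None:
    """Write measurement rows (dicts or RadiusMeasurement) to CSV."""
    records = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in rows]
    df = pd.DataFrame(records)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    front = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    df = df[front + [c for c in df.columns if c not in front]]
    path = Path(path)
    mode = "a" if append and path.exists() else "w"
    df.to_csv(path, mode=mode, header=mode == "w", index=False)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise AnnotationError(f"measurement CSV {path} is empty")
    missing = [c for c in ("whole_mm", "proximal_mm", "middle_mm", "distal_mm") if c not in df]
    if missing:
        raise AnnotationError(f"measurement CSV {path} lacks columns: {missing}")
    return df
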