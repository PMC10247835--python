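"""Lesion file I/O: schema-validated JSON geometry, flat CSV tables.

A lesion file stores everything needed to recompute the analysis for one
lesion: metadata (id, burr diameter, slice spacing) and per-frame pre/post
geometry — lumen contour vertices in mm, catheter and wire circles,
calcium arc annotations and the post-procedure finding flags.  Contours
are validated on load (simple polygon, counter-clockwise; clockwise input
is re-oriented with a warning).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field, ValidationError
from shapely.geometry import Polygon

from .frames import FramePair, FramePre, FramePost
from .geometry import CalciumArc, DeviceCircle, GeometryError, Point2D
from .synthetic import SyntheticLesion

__all__ = ["SCHEMA_VERSION", "read_lesion", "write_lesion", "LesionFileError"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class LesionFileError(ValueError):
    """A lesion file violating the schema or geometric invariants."""


class _CircleModel(BaseModel):
    x: float
    y: float
    diameter: float = Field(gt=0)


class _ArcModel(BaseModel):
    start_deg: float
    end_deg: float
    min_depth_um: float = Field(ge=0, default=0.0)
    nodular: bool = False


class _PreModel(BaseModel):
    lumen: list[tuple[float, float]] = Field(min_length=3)
    catheter: _CircleModel
    wire: _CircleModel
    calcium: list[_ArcModel] = Field(default_factory=list)


class _PostModel(BaseModel):
    lumen: list[tuple[float, float]] = Field(min_length=3)
    deep_injury: bool = False
    flap_outside_P: bool = False


class _FrameModel(BaseModel):
    frame_index: int = Field(ge=0)
    z_mm: float
    pre: _PreModel
    post: _PostModel


class _LesionModel(BaseModel):
    schema_version: int
    lesion_id: str
    burr_diameter: float = Field(gt=0)
    spacing_mm: float = Field(gt=0)
    frames: list[_FrameModel] = Field(min_length=1)


def _contour(vertices: Sequence[tuple[float, float]], where: str) -> Polygon:
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise LesionFileError(f"{where}: self-intersecting contour")
    if not poly.exterior.is_ccw:
        logger.warning("%s: clockwise contour re-oriented", where)
    from .geometry import validate_contour
    try:
        return validate_contour(poly)
    except GeometryError as exc:
        raise LesionFileError(f"{where}: {exc}") from exc


def read_lesion(path: str | Path) -> SyntheticLesion:
    """Load and validate a lesion JSON file into frame pairs."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LesionFileError(f"{path}: not valid JSON ({exc})") from exc
    try:
        model = _LesionModel.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise LesionFileError(f"{path}: {loc}: {first['msg']}") from exc
    if model.schema_version != SCHEMA_VERSION:
        raise LesionFileError(
            f"{path}: unsupported schema_version {model.schema_version}")

    indices = [f.frame_index for f in model.frames]
    if indices != list(range(min(indices), min(indices) + len(indices))):
        raise LesionFileError(f"{path}: frame indices not contiguous")

    pairs: list[FramePair] = []
    for fm in model.frames:
        where = f"{path.name} frame {fm.frame_index}"
        try:
            pre = FramePre(
                frame_index=fm.frame_index,
                z_mm=fm.z_mm,
                lumen=_contour(fm.pre.lumen, where + " pre"),
                catheter=DeviceCircle(Point2D(fm.pre.catheter.x, fm.pre.catheter.y),
                                      fm.pre.catheter.diameter, "catheter"),
                wire=DeviceCircle(Point2D(fm.pre.wire.x, fm.pre.wire.y),
                                  fm.pre.wire.diameter, "wire"),
                calcium=[CalciumArc(a.start_deg, a.end_deg, a.min_depth_um,
                                    a.nodular) for a in fm.pre.calcium],
                burr_diameter=model.burr_diameter,
            )
            post = FramePost(
                frame_index=fm.frame_index,
                z_mm=fm.z_mm,
                lumen=_contour(fm.post.lumen, where + " post"),
                deep_injury=fm.post.deep_injury,
                flap_outside_p=fm.post.flap_outside_P,
            )
        except (ValueError, GeometryError) as exc:
            raise LesionFileError(f"{where}: {exc}") from exc
        pairs.append(FramePair(pre=pre, post=post))
    return SyntheticLesion(lesion_id=model.lesion_id,
                           burr_diameter=model.burr_diameter,
                           spacing_mm=model.spacing_mm,
                           pairs=pairs, truth=[])


def _ring(poly: Polygon) -> list[list[float]]:
    coords = list(poly.exterior.coords)[:-1]
    return [[float(x), float(y)] for x, y in coords]


def write_lesion(lesion: SyntheticLesion, path: str | Path) -> None:
    """Serialise a lesion to the JSON schema (round-trips with read_lesion)."""
    frames = []
    for pair in lesion.pairs:
        frames.append({
            "frame_index": pair.pre.frame_index,
            "z_mm": pair.pre.z_mm,
            "pre": {
                "lumen": _ring(pair.pre.lumen),
                "catheter": {"x": pair.pre.catheter.center.x,
                             "y": pair.pre.catheter.center.y,
                             "diameter": pair.pre.catheter.diameter},
                "wire": {"x": pair.pre.wire.center.x,
                         "y": pair.pre.wire.center.y,
                         "diameter": pair.pre.wire.diameter},
                "calcium": [{"start_deg": a.start_deg, "end_deg": a.end_deg,
                             "min_depth_um": a.min_depth_um,
                             "nodular": a.nodular} for a in pair.pre.calcium],
            },
            "post": {
                "lumen": _ring(pair.post.lumen),
                "deep_injury": pair.post.deep_injury,
                "flap_outside_P": pair.post.flap_outside_p,
            },
        })
    doc = {
        "schema_version": SCHEMA_VERSION,
        "lesion_id": lesion.lesion_id,
        "burr_diameter": lesion.burr_diameter,
        "spacing_mm": lesion.spacing_mm,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))
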