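"""Per-frame ablation metrics for both prediction modes.

A registered pre/post cross-section pair yields, for a given prediction
mode (burr circle centred at the imaging catheter or at the guidewire):
predicted/actual/overlap areas and angles, the %Correct and %Error
accuracy scores, device clearances, lumen and calcium measurements.

%Correct area = 100 * O / P   (how much of the prediction was ablated)
%Error  area = 100 * (A - O) / A  (how much ablation fell outside it)

Frames where the predicted or actual region essentially vanishes are
flagged as excluded rather than propagating undefined ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Sequence

from shapely.geometry import Polygon

from .geometry import (
    CalciumArc,
    DeviceCircle,
    GeometryError,
    Point2D,
    actual_region,
    angular_extent,
    lumen_diameters,
    lumen_loss_region,
    make_device_circle,
    min_clearance,
    overlap_region,
    predicted_region,
    region_area,
    validate_contour,
)

__all__ = [
    "FramePre",
    "FramePost",
    "FramePair",
    "AblationMetrics",
    "compute_frame_metrics",
    "classify_calcification",
    "burr_lumen_ratio",
    "AREA_EXCLUSION_EPS",
    "CONTACT_THRESHOLD_MM",
]

#: frames whose predicted or actual area falls below this are excluded (mm^2)
AREA_EXCLUSION_EPS = 1e-3
#: clearance at or below this counts as device contact (mm)
CONTACT_THRESHOLD_MM = 1e-6

Mode = Literal["catheter", "wire"]
CalcType = Literal["circumferential", "eccentric", "nodular"]


@dataclass
class FramePre:
    """Pre-procedure cross-section: lumen contour, devices, calcium."""

    frame_index: int
    z_mm: float
    lumen: Polygon
    catheter: DeviceCircle
    wire: DeviceCircle
    calcium: list[CalciumArc]
    burr_diameter: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.burr_diameter <= 0:
            raise ValueError("burr_diameter must be positive")
        self.lumen = validate_contour(self.lumen)
        from shapely.geometry import Point
        for dev in (self.catheter, self.wire):
            if not self.lumen.covers(Point(dev.center.x, dev.center.y)):
                raise ValueError(f"{dev.kind} center lies outside the lumen")


@dataclass
class FramePost:
    """Post-procedure cross-section with finding annotations."""

    frame_index: int
    z_mm: float
    lumen: Polygon
    deep_injury: bool = False
    flap_outside_p: bool = False

    def __post_init__(self) -> None:
        self.lumen = validate_contour(self.lumen)


@dataclass
class FramePair:
    """A registered pre/post pair for one longitudinal position."""

    pre: FramePre
    post: FramePost
    registered: bool = True

    def __post_init__(self) -> None:
        if self.pre.frame_index != self.post.frame_index:
            raise ValueError("pre/post frame_index mismatch")


@dataclass
class AblationMetrics:
    """All per-frame quantities for one prediction mode."""

    mode: Mode
    frame_index: int
    z_mm: float
    p_area: float
    a_area: float
    o_area: float
    p_angle: float
    a_angle: float
    o_angle: float
    pct_correct_area: Optional[float]
    pct_error_area: Optional[float]
    pct_correct_angle: Optional[float]
    pct_error_angle: Optional[float]
    d_catheter_intima: float
    d_wire_intima: float
    d_catheter_wire: float
    contact: bool
    min_lumen_diam: float
    mean_lumen_diam: float
    lumen_area_pre: float
    lumen_area_post: float
    burr_lumen_ratio: float
    calc_arc_deg: float
    calc_min_depth_um: Optional[float]
    calc_type: Optional[CalcType]
    lumen_loss_area: float
    deep_injury: bool
    flap_outside_p: bool
    excluded: bool
    exclusion_reason: Optional[str]

    def as_dict(self) -> dict:
        return asdict(self)


def burr_lumen_ratio(burr_diameter: float, mean_lumen_diameter: float) -> float:
    """Burr size over mean lumen diameter (per frame), unitless."""
    if mean_lumen_diameter <= 0:
        raise ValueError("mean lumen diameter must be positive")
    return burr_diameter / mean_lumen_diameter


def _merge_arc_coverage(arcs: Sequence[CalciumArc]) -> float:
    """Total non-overlapping angular coverage of calcium arcs, degrees."""
    import numpy as np
    from .geometry import _merge_circular
    intervals = np.array([[a.start_deg % 360.0, a.span_deg] for a in arcs])
    return _merge_circular(intervals)


def classify_calcification(arcs: Sequence[CalciumArc]) -> CalcType:
    """Classify frame calcification from annotated arcs.

    Nodular protrusion annotations take precedence; otherwise total arc
    coverage of at least 270 degrees is circumferential, below is eccentric.
    """
    if not arcs:
        raise ValueError("no calcium arcs to classify")
    if any(a.nodular for a in arcs):
        return "nodular"
    return "circumferential" if _merge_arc_coverage(arcs) >= 270.0 else "eccentric"


def compute_frame_metrics(pair: FramePair, mode: Mode,
                          n_vertices: int = 360,
                          area_eps: float = AREA_EXCLUSION_EPS,
                          contact_threshold: float = CONTACT_THRESHOLD_MM,
                          ) -> AblationMetrics:
    """Compute all per-frame metrics for one prediction mode.

    The prediction circle has the burr diameter and is centred at the
    imaging catheter (mode ``"catheter"``) or the guidewire (mode
    ``"wire"``).  Angles are measured around the centroid of the pre-
    procedural lumen for predicted, actual and overlap regions alike.
    """
    if mode not in ("catheter", "wire"):
        raise ValueError(f"unknown mode {mode!r}")
    if not pair.registered:
        raise ValueError("frame pair is not registered; metrics undefined")
    pre, post = pair.pre, pair.post

    center_dev = pre.catheter if mode == "catheter" else pre.wire
    burr = make_device_circle(center_dev.center, pre.burr_diameter, "burr")

    P = predicted_region(burr, pre.lumen, n_vertices=n_vertices)
    A = actual_region(pre.lumen, post.lumen)
    O = overlap_region(P, A)
    p_area, a_area, o_area = region_area(P), region_area(A), region_area(O)

    centroid = pre.lumen.centroid
    center = Point2D(centroid.x, centroid.y)
    p_angle = angular_extent(P, center)
    a_angle = angular_extent(A, center)
    o_angle = angular_extent(O, center)

    excluded, reason = False, None
    if p_area < area_eps:
        excluded, reason = True, "no predicted ablation (P-area below threshold)"
    if a_area < area_eps:
        excluded = True
        reason = "no actual ablation (A-area below threshold)" if reason is None \
            else "no predicted or actual ablation"

    if excluded:
        pct_ca = pct_ea = pct_cg = pct_eg = None
    else:
        pct_ca = 100.0 * o_area / p_area
        pct_ea = 100.0 * (a_area - o_area) / a_area
        pct_cg = 100.0 * o_angle / p_angle if p_angle > 0 else None
        pct_eg = 100.0 * (a_angle - o_angle) / a_angle if a_angle > 0 else None

    def _snap(d: float) -> float:
        return 0.0 if d <= contact_threshold else d

    d_ci = _snap(min_clearance(pre.catheter, pre.lumen))
    d_wi = _snap(min_clearance(pre.wire, pre.lumen))
    d_cw = _snap(min_clearance(pre.catheter, pre.wire))

    min_d, mean_d, lumen_area_pre = lumen_diameters(pre.lumen)
    lumen_area_post = region_area(post.lumen)

    if pre.calcium:
        calc_arc = _merge_arc_coverage(pre.calcium)
        calc_depth = min(a.min_depth_um for a in pre.calcium)
        calc_type = classify_calcification(pre.calcium)
    else:
        calc_arc, calc_depth, calc_type = 0.0, None, None

    return AblationMetrics(
        mode=mode,
        frame_index=pre.frame_index,
        z_mm=pre.z_mm,
        p_area=p_area,
        a_area=a_area,
        o_area=o_area,
        p_angle=p_angle,
        a_angle=a_angle,
        o_angle=o_angle,
        pct_correct_area=pct_ca,
        pct_error_area=pct_ea,
        pct_correct_angle=pct_cg,
        pct_error_angle=pct_eg,
        d_catheter_intima=d_ci,
        d_wire_intima=d_wi,
        d_catheter_wire=d_cw,
        contact=d_cw <= contact_threshold,
        min_lumen_diam=min_d,
        mean_lumen_diam=mean_d,
        lumen_area_pre=lumen_area_pre,
        lumen_area_post=lumen_area_post,
        burr_lumen_ratio=burr_lumen_ratio(pre.burr_diameter, mean_d),
        calc_arc_deg=calc_arc,
        calc_min_depth_um=calc_depth,
        calc_type=calc_type,
        lumen_loss_area=region_area(lumen_loss_region(pre.lumen, post.lumen)),
        deep_injury=post.deep_injury,
        flap_outside_p=post.flap_outside_p,
        excluded=excluded,
        exclusion_reason=reason,
    )
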