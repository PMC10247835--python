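"""Synthetic coronary cross-section cohort generator.

Real registered pre/post atherectomy image pairs are not publicly
available, so this module generates geometric phantoms carrying the
statistical structure the analysis pipeline assumes:

* lumen contours are Fourier-perturbed ellipses with a log-normal size
  distribution (cohort median area about 2.9 mm^2);
* the imaging catheter (0.9 mm) sits near or against the intima (median
  catheter-intima clearance 0 mm), the 0.009-inch guidewire touches the
  catheter in about 75 % of frames and is separated otherwise;
* burr diameters are drawn from the observed usage mix (1.5-2.25 mm);
* the post-procedure lumen is the pre-lumen united with a burr-sized
  disc placed at the *effective ablation centre* — the catheter centre
  when catheter and wire are in contact, the wire centre otherwise —
  plus positional jitter standing in for wire shift and burr orbiting;
* post-procedure finding flags (deep vessel injury, intimal flap outside
  the predicted area) are drawn with probabilities increasing with the
  fraction of ablation falling outside the catheter-based prediction.

Everything is driven by a single integer seed; per-lesion substreams are
derived deterministically so any lesion can be regenerated in isolation.
Ground truth (effective centre, true ablated region) is returned for
recovery tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from pydantic import BaseModel, Field, model_validator
from shapely.geometry import Point, Polygon

from .geometry import (
    CATHETER_DIAMETER_MM,
    WIRE_DIAMETER_MM,
    CalciumArc,
    DeviceCircle,
    Point2D,
    circle_polygon,
    validate_contour,
)
from .frames import FramePair, FramePre, FramePost

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticLesion",
    "generate_lesion",
    "generate_cohort",
    "simulate_distance_outcome",
]

logger = logging.getLogger(__name__)


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic cohort, with cohort-scale defaults."""

    seed: int = 0
    n_lesions: int = 55
    frames_per_lesion: tuple[int, int] = (5, 12)  # inclusive range, ~8.5 mean
    spacing_mm: float = 1.0

    # lumen shape
    lumen_area_median_mm2: float = 2.91
    lumen_area_log_sd: float = 0.31  # sd of log-radius (half of log-area sd)
    # imaged lumens must at least admit the 0.9-mm imaging catheter
    lumen_area_min_mm2: float = 1.3
    ellipticity_range: tuple[float, float] = (1.0, 1.35)
    boundary_noise_amplitude: float = 0.04
    boundary_harmonics: tuple[int, int] = (2, 5)
    lumen_vertices: int = 180

    # device placement
    catheter_diameter: float = CATHETER_DIAMETER_MM
    wire_diameter: float = WIRE_DIAMETER_MM
    catheter_wall_contact_prob: float = 0.6
    catheter_intima_exp_mean: float = 0.19
    wire_contact_fraction: float = 0.753
    catheter_wire_exp_mean: float = 0.30
    distance_grid_mm: float = 0.05  # non-contact clearances land on this grid

    # burr usage mix (diameter -> weight)
    burr_weights: dict[float, float] = Field(
        default_factory=lambda: {1.50: 19, 1.75: 26, 2.00: 8, 2.15: 1, 2.25: 1})

    # ablation model
    center_jitter_sd: float = 0.25
    depth_noise_sd: float = 0.10

    # calcium annotations
    calcium_arc_mean_deg: float = 238.0
    calcium_arc_sd_deg: float = 89.0
    calcium_depth_median_um: float = 430.0
    calcium_depth_log_sd: float = 0.45
    nodular_prob: float = 0.124

    # post-procedure finding model (logistic in the out-of-prediction fraction)
    deep_injury_intercept: float = -4.8
    deep_injury_slope: float = 3.5
    flap_intercept: float = -4.0
    flap_slope: float = 3.0

    max_retries: int = 50

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for p in (self.catheter_wall_contact_prob, self.wire_contact_fraction,
                  self.nodular_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.spacing_mm, self.lumen_area_median_mm2,
                  self.catheter_intima_exp_mean, self.catheter_wire_exp_mean,
                  self.distance_grid_mm):
            if s <= 0:
                raise ValueError("scale parameters must be positive")
        return self


@dataclass
class SyntheticTruth:
    """Per-frame generator ground truth for recovery tests."""

    frame_index: int
    effective_center: Point2D
    true_region: shapely.MultiPolygon | Polygon
    contact: bool
    tendency: str  # "catheter_centered" | "wire_centered"


@dataclass
class SyntheticLesion:
    lesion_id: str
    burr_diameter: float
    spacing_mm: float
    pairs: list[FramePair]
    truth: list[SyntheticTruth]


def _lesion_rng(seed: int, lesion_index: int) -> np.random.Generator:
    """Deterministic per-lesion substream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(lesion_index,)))


def _lumen_polygon(rng: np.random.Generator, cfg: GeneratorConfig,
                   area_mm2: float):
    """Star-shaped Fourier-perturbed ellipse with the requested area.

    Returns the polygon and its analytic polar radius function (about the
    construction origin), used for device placement.
    """
    ell = rng.uniform(*cfg.ellipticity_range)
    phi0 = rng.uniform(0, 2 * np.pi)
    k_lo, k_hi = cfg.boundary_harmonics
    ks = np.arange(k_lo, k_hi + 1)
    amps = cfg.boundary_noise_amplitude * rng.uniform(0.2, 1.0, len(ks)) / len(ks) * 2
    phases = rng.uniform(0, 2 * np.pi, len(ks))

    def radius(theta: np.ndarray) -> np.ndarray:
        t = theta - phi0
        base = 1.0 / np.sqrt(np.cos(t) ** 2 + (ell * np.sin(t)) ** 2)
        wave = 1.0 + np.sum(amps[:, None] * np.cos(ks[:, None] * theta
                                                   + phases[:, None]), axis=0)
        return base * np.maximum(wave, 0.5)

    theta = np.linspace(0, 2 * np.pi, cfg.lumen_vertices, endpoint=False)
    r = radius(theta)
    poly = Polygon(np.c_[r * np.cos(theta), r * np.sin(theta)])
    scale = math.sqrt(area_mm2 / poly.area)
    poly = shapely.affinity.scale(poly, scale, scale, origin=(0, 0))

    def scaled_radius(th: float) -> float:
        return float(radius(np.atleast_1d(np.asarray(th, float)))[0] * scale)

    return validate_contour(poly), scaled_radius


def _place_at_clearance(lumen: Polygon, radius_fn, direction: float,
                        device_radius: float, target_clearance: float,
                        ) -> Point2D:
    """Put a device centre along `direction` with a wall clearance target.

    Iteratively corrects for boundary waviness so that the signed clearance
    (distance from the device surface to the lumen contour) matches the
    target to ~1e-3 mm.
    """
    u = np.array([math.cos(direction), math.sin(direction)])
    d = float(radius_fn(direction)) - device_radius - target_clearance
    for _ in range(8):
        c = Point(d * u[0], d * u[1])
        signed = lumen.exterior.distance(c) - device_radius
        err = signed - target_clearance
        if abs(err) < 1e-3:
            break
        d += err
    d = max(d, 0.0)
    return Point2D(d * u[0], d * u[1])


def _place_wire(rng: np.random.Generator, cfg: GeneratorConfig,
                lumen: Polygon, catheter: Point2D, wall_dir: float,
                gap: float) -> Point2D | None:
    """Place the wire at surface gap `gap` from the catheter, inside the lumen."""
    sep = cfg.catheter_diameter / 2 + cfg.wire_diameter / 2 + gap
    for _ in range(cfg.max_retries):
        # mostly tangential to the wall so the wire also runs near the intima
        side = 1.0 if rng.random() < 0.5 else -1.0
        ang = wall_dir + math.pi + side * rng.uniform(0.8, 1.6)
        wx = catheter.x + sep * math.cos(ang)
        wy = catheter.y + sep * math.sin(ang)
        wire_pt = Point(wx, wy)
        if lumen.covers(wire_pt) and \
                lumen.exterior.distance(wire_pt) >= cfg.wire_diameter / 2:
            return Point2D(wx, wy)
    return None


def _quantize_up(x: float, step: float) -> float:
    """Snap a positive clearance onto the generator grid (>= one step)."""
    return max(step, round(x / step) * step)


def _calcium(rng: np.random.Generator, cfg: GeneratorConfig) -> list[CalciumArc]:
    span = float(np.clip(rng.normal(cfg.calcium_arc_mean_deg,
                                    cfg.calcium_arc_sd_deg), 30.0, 360.0))
    start = rng.uniform(0, 360)
    depth = cfg.calcium_depth_median_um * math.exp(
        rng.normal(0.0, cfg.calcium_depth_log_sd))
    nodular = bool(rng.random() < cfg.nodular_prob)
    return [CalciumArc(start_deg=start, end_deg=(start + span) % 360.0,
                       min_depth_um=depth, nodular=nodular)]


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_lesion(config: GeneratorConfig, lesion_index: int,
                    ) -> SyntheticLesion:
    """Generate one lesion: registered frame pairs plus ground truth."""
    rng = _lesion_rng(config.seed, lesion_index)
    lesion_id = f"L{lesion_index:03d}"

    burrs = sorted(config.burr_weights)
    w = np.array([config.burr_weights[b] for b in burrs], float)
    burr_diameter = float(rng.choice(burrs, p=w / w.sum()))
    lo, hi = config.frames_per_lesion
    n_frames = int(rng.integers(lo, hi + 1))
    floor = math.sqrt(config.lumen_area_min_mm2 / config.lumen_area_median_mm2)
    lesion_radius_factor = max(
        math.exp(rng.normal(0.0, config.lumen_area_log_sd)), 1.1 * floor)

    pairs: list[FramePair] = []
    truth: list[SyntheticTruth] = []
    for fi in range(n_frames):
        # contact status is drawn once per frame so that geometric retries
        # cannot bias the cohort contact fraction
        contact = bool(rng.random() < config.wire_contact_fraction)
        frame = None
        for attempt in range(config.max_retries):
            frame = _generate_frame(rng, config, fi, burr_diameter,
                                    lesion_radius_factor, contact)
            if frame is not None:
                break
            logger.debug("lesion %s frame %d: retry %d", lesion_id, fi, attempt)
        if frame is None and not contact:
            # lumen too small to separate catheter and wire: physically the
            # devices are then in contact
            logger.info("lesion %s frame %d: forcing contact (small lumen)",
                        lesion_id, fi)
            for attempt in range(config.max_retries):
                frame = _generate_frame(rng, config, fi, burr_diameter,
                                        lesion_radius_factor, True)
                if frame is not None:
                    break
        if frame is None:
            raise RuntimeError(f"could not generate frame {fi} of {lesion_id}")
        pair, tr = frame
        pairs.append(pair)
        truth.append(tr)
    return SyntheticLesion(lesion_id=lesion_id, burr_diameter=burr_diameter,
                           spacing_mm=config.spacing_mm, pairs=pairs, truth=truth)


def _generate_frame(rng: np.random.Generator, cfg: GeneratorConfig,
                    frame_index: int, burr_diameter: float,
                    lesion_radius_factor: float, contact: bool,
                    ) -> tuple[FramePair, SyntheticTruth] | None:
    # lumen size: lesion-level factor plus small frame-to-frame variation
    frame_factor = math.exp(rng.normal(0.0, 0.08))
    area = cfg.lumen_area_median_mm2 * (lesion_radius_factor * frame_factor) ** 2
    lumen, radius_fn = _lumen_polygon(rng, cfg, area)

    r_cath = cfg.catheter_diameter / 2
    r_wire = cfg.wire_diameter / 2
    # catheter against (or near) the intima along a random wall direction
    wall_dir = rng.uniform(0, 2 * np.pi)
    if rng.random() < cfg.catheter_wall_contact_prob:
        cath_clear = 0.0
    else:
        cath_clear = rng.exponential(cfg.catheter_intima_exp_mean)
    max_clear = float(radius_fn(wall_dir)) - r_cath
    if max_clear <= 0.02:  # lumen too small for the imaging catheter
        return None
    cath_clear = min(cath_clear, 0.8 * max_clear)
    catheter = _place_at_clearance(lumen, radius_fn, wall_dir, r_cath, cath_clear)

    if contact:
        gap = 0.0
    else:
        # cap the separation at what this lumen can accommodate
        verts = np.asarray(lumen.exterior.coords)
        far = float(np.hypot(verts[:, 0] - catheter.x,
                             verts[:, 1] - catheter.y).max())
        gap_cap = far - r_cath - 3.0 * r_wire - 0.05
        if gap_cap < cfg.distance_grid_mm:
            return None  # lumen too small for a separated wire; regenerate
        gap = _quantize_up(min(rng.exponential(cfg.catheter_wire_exp_mean),
                               gap_cap), cfg.distance_grid_mm)
    wire = _place_wire(rng, cfg, lumen, catheter, wall_dir, gap)
    if wire is None:
        if not contact:
            return None  # infeasible separation in this lumen; regenerate
        wire = Point2D(catheter.x - (r_cath + r_wire) * math.cos(wall_dir),
                       catheter.y - (r_cath + r_wire) * math.sin(wall_dir))
        if not lumen.covers(Point(wire.x, wire.y)):
            return None

    # effective ablation centre: catheter when in contact, wire otherwise,
    # with isotropic jitter plus extra radial (depth) noise toward the wall
    base = catheter if contact else wire
    u = np.array([math.cos(wall_dir), math.sin(wall_dir)])
    jitter = rng.normal(0.0, cfg.center_jitter_sd, 2)
    depth = rng.normal(0.0, cfg.depth_noise_sd)
    eff = np.array([base.x, base.y]) + jitter + depth * u

    burr_r = burr_diameter / 2
    post_lumen = None
    for _ in range(30):
        disc = circle_polygon((eff[0], eff[1]), burr_r)
        removed = disc.difference(lumen)
        if removed.area > 5e-3 and lumen.intersects(disc):
            post_lumen = lumen.union(disc)
            break
        eff = eff + 0.1 * u  # push toward the wall until the burr bites
    if post_lumen is None or not isinstance(post_lumen, Polygon):
        return None

    true_region = post_lumen.difference(lumen)
    err_frac = _catheter_error_fraction(lumen, catheter, burr_diameter,
                                        true_region)
    deep = rng.random() < _invlogit(cfg.deep_injury_intercept
                                    + cfg.deep_injury_slope * err_frac)
    flap = rng.random() < _invlogit(cfg.flap_intercept
                                    + cfg.flap_slope * err_frac)

    z = frame_index * cfg.spacing_mm
    pre = FramePre(
        frame_index=frame_index, z_mm=z, lumen=lumen,
        catheter=DeviceCircle(catheter, cfg.catheter_diameter, "catheter"),
        wire=DeviceCircle(wire, cfg.wire_diameter, "wire"),
        calcium=_calcium(rng, cfg), burr_diameter=burr_diameter)
    post = FramePost(frame_index=frame_index, z_mm=z,
                     lumen=validate_contour(post_lumen),
                     deep_injury=deep, flap_outside_p=flap)
    tr = SyntheticTruth(
        frame_index=frame_index,
        effective_center=Point2D(float(eff[0]), float(eff[1])),
        true_region=true_region, contact=contact,
        tendency="catheter_centered" if contact else "wire_centered")
    return FramePair(pre=pre, post=post), tr


def _catheter_error_fraction(lumen: Polygon, catheter: Point2D,
                             burr_diameter: float, true_region) -> float:
    """Fraction of true ablation outside the catheter-based prediction."""
    if true_region.area <= 0:
        return 0.0
    pred = circle_polygon(catheter, burr_diameter / 2, 90).difference(lumen)
    outside = true_region.difference(pred).area
    return float(outside / true_region.area)


def generate_cohort(config: GeneratorConfig) -> list[SyntheticLesion]:
    """Generate the full cohort of lesions."""
    if config.n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    return [generate_lesion(config, i) for i in range(config.n_lesions)]


def truth_table(lesions: list[SyntheticLesion]) -> pd.DataFrame:
    """Flatten ground truth into a DataFrame."""
    rows = []
    for les in lesions:
        for tr in les.truth:
            rows.append({
                "lesion_id": les.lesion_id,
                "frame_index": tr.frame_index,
                "effective_x": tr.effective_center.x,
                "effective_y": tr.effective_center.y,
                "true_ablated_area": float(tr.true_region.area),
                "contact": tr.contact,
                "tendency": tr.tendency,
            })
    return pd.DataFrame(rows)


def simulate_distance_outcome(n: int, seed: int,
                              or_per_step: float = 1.7,
                              baseline_prob: float = 0.25,
                              contact_fraction: float = 0.753,
                              exp_mean_mm: float = 0.30,
                              grid_mm: float = 0.05) -> pd.DataFrame:
    """Simulate (catheter-wire clearance, irrelevant-ablation) pairs.

    Clearance is 0 for contact frames and a grid-quantised exponential
    otherwise; the outcome is Bernoulli with log-odds increasing by
    ``log(or_per_step)`` per 0.1 mm of clearance from a baseline prevalence
    at contact.  Used for logistic/ROC recovery experiments.
    """
    rng = np.random.default_rng(seed)
    contact = rng.random(n) < contact_fraction
    d = np.where(contact, 0.0,
                 np.maximum(grid_mm,
                            np.round(rng.exponential(exp_mean_mm, n) / grid_mm)
                            * grid_mm))
    logit = math.log(baseline_prob / (1 - baseline_prob)) \
        + math.log(or_per_step) * d / 0.1
    p = 1.0 / (1.0 + np.exp(-logit))
    y = rng.random(n) < p
    return pd.DataFrame({"d_catheter_wire": d, "irrelevant": y})
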