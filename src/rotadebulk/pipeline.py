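"""End-to-end cohort pipeline: frame metrics -> lesion metrics -> statistics.

This is the programmatic counterpart of the command-line workflow: given a
list of lesions (synthetic or loaded from files), compute the per-frame
table for one or both prediction modes, aggregate per lesion, and run the
cohort analysis (median-split grouping, finding cross-tabulations, the
logistic screen/fit for good and irrelevant prediction, the ROC of the
catheter-wire clearance, and the contact-stratified comparison of the two
prediction modes).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frames import compute_frame_metrics
from .lesion import (
    LesionMetrics,
    crosstab_findings,
    frame_table,
    integrate_volumes,
    median_split_groups,
)
from .stats import (
    compare_prediction_modes,
    multivariable_logistic,
    roc_optimal_cutoff,
    univariable_screen,
)
from .synthetic import SyntheticLesion

__all__ = [
    "compute_cohort_frames",
    "compute_lesion_metrics",
    "analyze_cohort",
    "SCREEN_CANDIDATES",
    "DISTANCE_VARS",
]

logger = logging.getLogger(__name__)

#: candidate predictors entering the univariable screen
SCREEN_CANDIDATES = (
    "lumen_area_pre",
    "burr_lumen_ratio",
    "d_catheter_intima",
    "d_wire_intima",
    "d_catheter_wire",
    "calc_arc_deg",
)
#: predictors reported per 0.1-mm increase
DISTANCE_VARS = ("d_catheter_intima", "d_wire_intima", "d_catheter_wire")


def compute_cohort_frames(lesions: Sequence[SyntheticLesion],
                          modes: Sequence[str] = ("catheter", "wire"),
                          **metric_kwargs) -> pd.DataFrame:
    """Per-frame metrics for every lesion and mode, as one flat table.

    Extra keyword arguments (``area_eps``, ``contact_threshold``,
    ``n_vertices``) are forwarded to :func:`compute_frame_metrics`.
    """
    tables = []
    for les in lesions:
        for mode in modes:
            metrics = [compute_frame_metrics(pair, mode, **metric_kwargs)
                       for pair in les.pairs]
            tables.append(frame_table(metrics, lesion_id=les.lesion_id))
    return pd.concat(tables, ignore_index=True)


def compute_lesion_metrics(lesions: Sequence[SyntheticLesion],
                           modes: Sequence[str] = ("catheter", "wire"),
                           ) -> pd.DataFrame:
    """Lesion-level volumes and means, restricted to the debulked segment.

    The analysis region of a lesion is the longest contiguous run of frames
    with measurable actual ablation; frames outside it do not contribute.
    """
    rows = []
    for les in lesions:
        for mode in modes:
            metrics = [compute_frame_metrics(pair, mode) for pair in les.pairs]
            segment = _debulked_segment(metrics)
            if not segment:
                logger.info("lesion %s: no debulked segment", les.lesion_id)
                continue
            lm = integrate_volumes(segment, spacing=les.spacing_mm,
                                   lesion_id=les.lesion_id)
            rows.append(lm.as_dict())
    return pd.DataFrame(rows)


def _debulked_segment(metrics):
    """Longest contiguous run of frames with actual ablation present."""
    best, cur = [], []
    for m in metrics:
        if m.a_area >= 1e-3:
            cur.append(m)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    return best


def analyze_cohort(frames: pd.DataFrame,
                   group_mode: str = "catheter") -> dict:
    """Run the full cohort analysis on a both-modes frame table.

    Grouping, cross-tabulations, the logistic screen/fit and the ROC use
    the frames of `group_mode` (the catheter-based prediction by default);
    the mode comparison uses both modes.  Returns a JSON-serialisable
    report dictionary.
    """
    base = frames[(frames["mode"] == group_mode) & ~frames["excluded"]].copy()
    if len(base) < 4:
        raise ValueError("too few analysable frames for a cohort analysis")

    labels, med_c, med_e = median_split_groups(base)
    base["group"] = labels
    group_counts = labels.value_counts().to_dict()

    report: dict = {
        "n_frames_analyzed": int(len(base)),
        "n_frames_total": int((frames["mode"] == group_mode).sum()),
        "contact_fraction": float(base["contact"].mean()),
        "median_pct_correct_area": med_c,
        "median_pct_error_area": med_e,
        "median_pct_correct_angle": float(base["pct_correct_angle"].median()),
        "median_pct_error_angle": float(base["pct_error_angle"].median()),
        "group_counts": {g: int(group_counts.get(g, 0))
                         for g in ("good_prediction", "over_ablation",
                                   "insufficient_ablation",
                                   "irrelevant_ablation")},
    }

    findings = {}
    for col in ("deep_injury", "flap_outside_p"):
        tab, chi2, p, test = crosstab_findings(base["group"], base[col])
        findings[col] = {
            "table": {str(k): [int(v) for v in row]
                      for k, row in tab.iterrows()},
            "chi2": None if np.isnan(chi2) else chi2,
            "p_value": p,
            "test": test,
            "rate": float(base[col].mean()),
        }
    report["findings"] = findings

    regressions = {}
    for outcome_name, group in (("good_prediction", "good_prediction"),
                                ("irrelevant_ablation", "irrelevant_ablation")):
        base[outcome_name] = (base["group"] == group).astype(int)
        try:
            selected, uni = univariable_screen(
                base, outcome_name, SCREEN_CANDIDATES,
                distance_vars=DISTANCE_VARS)
            multi = multivariable_logistic(
                base, outcome_name, selected, distance_vars=DISTANCE_VARS)
            regressions[outcome_name] = {
                "univariable": [r.as_dict() for r in uni],
                "selected": selected,
                "multivariable": [r.as_dict() for r in multi],
            }
        except ValueError as exc:
            regressions[outcome_name] = {"status": f"not fitted: {exc}"}
    report["regressions"] = regressions

    irr = (base["group"] == "irrelevant_ablation").to_numpy()
    if irr.any() and not irr.all():
        roc = roc_optimal_cutoff(base["d_catheter_wire"].to_numpy(), irr)
        report["roc_catheter_wire_distance"] = roc.as_dict()
    else:
        report["roc_catheter_wire_distance"] = None

    both = frames[~frames["excluded"]]
    report["mode_comparison"] = [c.as_dict()
                                 for c in compare_prediction_modes(both)]
    return report
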