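"""Lesion-level aggregation and cohort four-group classification.

Volumes come from integrating per-frame areas over the pullback axis
(area x slice spacing, default 1 mm).  The cohort-level classification
splits all analysed frames at the cohort medians of %Correct and %Error
area into four groups — good prediction (high correct / low error), over
ablation (high/high), insufficient ablation (low/low) and irrelevant
ablation (low correct / high error) — and cross-tabulates post-procedure
findings against them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frames import AblationMetrics

__all__ = [
    "LesionMetrics",
    "GROUP_LABELS",
    "integrate_volumes",
    "median_split_groups",
    "crosstab_findings",
    "frame_table",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = (
    "good_prediction",
    "over_ablation",
    "insufficient_ablation",
    "irrelevant_ablation",
)


@dataclass
class LesionMetrics:
    """Integrated volumes and mean angles/percentages for one lesion."""

    lesion_id: str
    mode: str
    p_volume: float
    a_volume: float
    o_volume: float
    pct_correct_volume: Optional[float]
    pct_error_volume: Optional[float]
    mean_p_angle: float
    mean_a_angle: float
    mean_o_angle: float
    mean_pct_correct_angle: Optional[float]
    mean_pct_error_angle: Optional[float]
    n_frames: int

    def as_dict(self) -> dict:
        return asdict(self)


def frame_table(metrics: Sequence[AblationMetrics],
                lesion_id: str | None = None) -> pd.DataFrame:
    """Flatten per-frame metrics into a DataFrame (one row per frame/mode)."""
    df = pd.DataFrame([m.as_dict() for m in metrics])
    if lesion_id is not None:
        df.insert(0, "lesion_id", lesion_id)
    return df


def integrate_volumes(frames: Sequence[AblationMetrics], spacing: float = 1.0,
                      lesion_id: str = "lesion") -> LesionMetrics:
    """Integrate per-frame areas into lesion volumes (rectangle rule).

    Each volume is the sum of the per-frame areas times the uniform slice
    spacing.  Volume percentages are ratios of integrated volumes — a
    P-area-weighted quantity, not the mean of the per-frame percentages.
    Mean angles and mean percentages average over included frames only;
    excluded frames contribute nothing.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to integrate")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    zs = np.array([f.z_mm for f in frames])
    if len(zs) > 1:
        dz = np.diff(np.sort(zs))
        if not np.allclose(dz, dz[0], atol=1e-9):
            raise ValueError("non-uniform frame spacing")
    modes = {f.mode for f in frames}
    if len(modes) != 1:
        raise ValueError("frames mix prediction modes")

    included = [f for f in frames if not f.excluded]
    p_vol = sum(f.p_area for f in frames) * spacing
    a_vol = sum(f.a_area for f in frames) * spacing
    o_vol = sum(f.o_area for f in frames) * spacing

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return LesionMetrics(
        lesion_id=lesion_id,
        mode=modes.pop(),
        p_volume=p_vol,
        a_volume=a_vol,
        o_volume=o_vol,
        pct_correct_volume=100.0 * o_vol / p_vol if p_vol > 0 else None,
        pct_error_volume=100.0 * (a_vol - o_vol) / a_vol if a_vol > 0 else None,
        mean_p_angle=float(np.mean([f.p_angle for f in included])) if included else 0.0,
        mean_a_angle=float(np.mean([f.a_angle for f in included])) if included else 0.0,
        mean_o_angle=float(np.mean([f.o_angle for f in included])) if included else 0.0,
        mean_pct_correct_angle=_mean(f.pct_correct_angle for f in included),
        mean_pct_error_angle=_mean(f.pct_error_angle for f in included),
        n_frames=len(frames),
    )


def median_split_groups(table: pd.DataFrame,
                        correct_field: str = "pct_correct_area",
                        error_field: str = "pct_error_area",
                        ) -> tuple[pd.Series, float, float]:
    """Label every analysed frame by the cohort median split.

    "High" means at or above the cohort median of the respective metric.
    Returns the label Series (aligned to the table index) plus the two
    medians used.
    """
    vals_c = table[correct_field].astype(float)
    vals_e = table[error_field].astype(float)
    ok = vals_c.notna() & vals_e.notna()
    if ok.sum() < 2:
        raise ValueError("need at least 2 analysable frames for a median split")
    med_c = float(vals_c[ok].median())
    med_e = float(vals_e[ok].median())
    if vals_c[ok].nunique() == 1 or vals_e[ok].nunique() == 1:
        logger.warning("all-identical metric values: every frame labelled high")
    high_c = vals_c >= med_c
    high_e = vals_e >= med_e
    labels = pd.Series(pd.NA, index=table.index, dtype="object")
    labels[ok & high_c & ~high_e] = "good_prediction"
    labels[ok & high_c & high_e] = "over_ablation"
    labels[ok & ~high_c & ~high_e] = "insufficient_ablation"
    labels[ok & ~high_c & high_e] = "irrelevant_ablation"
    return labels, med_c, med_e


def crosstab_findings(labels: pd.Series, findings: pd.Series,
                      ) -> tuple[pd.DataFrame, float, float, str]:
    """Cross-tabulate a boolean post-procedure finding against group labels.

    Returns the 4x2 contingency table, the test statistic, the p-value and
    the test used.  A chi-square test is used by default; when any expected
    cell count falls below 5 and the table collapses to 2x2, Fisher's exact
    test replaces it (for larger sparse tables the chi-square result is kept
    and flagged in the test name).
    """
    if len(labels) != len(findings):
        raise ValueError("labels and findings must have equal length")
    if len(labels) == 0:
        raise ValueError("empty input")
    ok = labels.notna()
    tab = pd.crosstab(labels[ok], findings[ok].astype(bool))
    tab = tab.reindex(index=[g for g in GROUP_LABELS if g in tab.index],
                      columns=[False, True], fill_value=0)
    counts = tab.to_numpy()
    # degenerate: a finding column entirely absent -> no association testable
    if counts.sum(axis=0).min() == 0 or counts.shape[0] < 2:
        return tab, 0.0, 1.0, "degenerate"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2, p, dof, expected = sps.chi2_contingency(counts)
    test = "chi2"
    if (expected < 5).any():
        if counts.shape == (2, 2):
            _, p = sps.fisher_exact(counts)
            chi2, test = float("nan"), "fisher"
        else:
            test = "chi2_low_expected"
    return tab, float(chi2), float(p), test
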