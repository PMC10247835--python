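"""Cohort statistics for prediction-accuracy analysis.

Implements the statistical pipeline applied to the per-frame table:

* a univariable logistic screen (retain candidates with p < 0.15),
* a joint multivariable logistic fit reporting odds ratios with Wald
  95 % confidence intervals,
* an empirical ROC with Youden-index optimal cutoff (used for the
  catheter-wire clearance vs irrelevant-ablation question),
* Mann-Whitney comparison of catheter-based vs wire-based prediction
  accuracy, stratified by whether catheter and wire are in contact.

Frames are treated as independent observations.  An optional per-lesion
cluster-robust covariance is available for the logistic fits but is off
by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ORResult",
    "RocResult",
    "ModeComparison",
    "univariable_screen",
    "multivariable_logistic",
    "roc_optimal_cutoff",
    "compare_prediction_modes",
    "DISTANCE_SCALE_MM",
]

logger = logging.getLogger(__name__)

#: distance predictors are reported per 0.1-mm increase
DISTANCE_SCALE_MM = 0.1


@dataclass
class ORResult:
    """Odds ratio with Wald 95 % CI for one predictor."""

    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    scale_note: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RocResult:
    """Empirical ROC summary with Youden-optimal cutoff."""

    auc: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    p_value: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModeComparison:
    """Catheter-mode vs wire-mode medians and Mann-Whitney p for one metric."""

    stratum: str
    metric: str
    median_catheter: float
    median_wire: float
    p_value: float
    n_catheter: int
    n_wire: int

    def as_dict(self) -> dict:
        return asdict(self)


def _scaled(x: pd.Series, variable: str,
            distance_vars: Sequence[str]) -> tuple[np.ndarray, str]:
    if variable in distance_vars:
        return x.to_numpy(float) / DISTANCE_SCALE_MM, "per 0.1 mm increase"
    return x.to_numpy(float), ""


def _fit_logit(y: np.ndarray, X: np.ndarray, cluster: np.ndarray | None = None):
    model = sm.Logit(y, X)
    if cluster is not None:
        return model.fit(disp=0, maxiter=200,
                         cov_type="cluster", cov_kwds={"groups": cluster})
    return model.fit(disp=0, maxiter=200)


def univariable_screen(table: pd.DataFrame, outcome: str,
                       candidates: Sequence[str], alpha_in: float = 0.15,
                       distance_vars: Sequence[str] = (),
                       ) -> tuple[list[str], list[ORResult]]:
    """One-predictor logistic fit per candidate; keep those with p < alpha_in.

    Distance variables (names listed in `distance_vars`) are rescaled to
    0.1-mm units before fitting so their odds ratios read "per 0.1-mm
    increase".  Candidates with complete separation or failed fits are
    dropped with a warning.
    """
    y = table[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    selected: list[str] = []
    results: list[ORResult] = []
    for var in candidates:
        x, note = _scaled(table[var], var, distance_vars)
        X = sm.add_constant(x)
        try:
            with np.errstate(all="ignore"):
                fit = _fit_logit(y, X)
            if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
                raise sps.FitError("unstable fit (separation?)")
        except Exception as exc:  # separation, singularities
            logger.warning("screen: excluding %s (%s)", var, exc)
            continue
        beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        res = ORResult(
            variable=var,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            p_value=float(p),
            scale_note=note,
        )
        results.append(res)
        if p < alpha_in:
            selected.append(var)
    return selected, results


def multivariable_logistic(table: pd.DataFrame, outcome: str,
                           selected: Sequence[str],
                           distance_vars: Sequence[str] = (),
                           cluster_col: str | None = None,
                           ) -> list[ORResult]:
    """Joint logistic fit of the selected predictors; ORs with Wald 95 % CI.

    Returns an empty list (a no-op) when no variables were selected.  Set
    `cluster_col` to a lesion-id column for cluster-robust standard errors.
    """
    if not selected:
        logger.info("multivariable fit skipped: no variables selected")
        return []
    y = table[outcome].astype(float).to_numpy()
    cols, notes = [], []
    for var in selected:
        x, note = _scaled(table[var], var, distance_vars)
        cols.append(x)
        notes.append(note)
    X = sm.add_constant(np.column_stack(cols))
    n_per_var = len(y) / len(selected)
    if n_per_var <= 10:
        logger.warning("only %.1f observations per predictor", n_per_var)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        logger.warning("design matrix condition number %.1e (collinearity?)", cond)
    cluster = table[cluster_col].to_numpy() if cluster_col else None
    with np.errstate(all="ignore"):
        fit = _fit_logit(y, X, cluster)
    if not np.all(np.isfinite(fit.bse)):
        raise ValueError("singular multivariable logistic fit")
    out = []
    for i, (var, note) in enumerate(zip(selected, notes), start=1):
        beta, se = fit.params[i], fit.bse[i]
        out.append(ORResult(
            variable=var,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            p_value=float(fit.pvalues[i]),
            scale_note=note,
        ))
    return out


def roc_optimal_cutoff(scores: Sequence[float], labels: Sequence[bool],
                       ) -> RocResult:
    """Empirical ROC of `scores` against boolean `labels`.

    AUC is the trapezoidal area (equivalently the Mann-Whitney pair-count
    U/(n1*n0) with ties counted half).  The optimal cutoff c maximises the
    Youden index of the rule "positive if score > c", with ties broken
    toward the smaller cutoff; the associated sensitivity and specificity
    are returned in percent.  The p-value tests AUC != 0.5 via the normal
    approximation of the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC analysis")
    mw = sps.mannwhitneyu(scores[labels], scores[~labels],
                          alternative="two-sided", method="asymptotic")
    auc = float(mw.statistic) / (n1 * n0)
    # candidate cutoffs: each unique score value, rule = score > c
    uniq = np.unique(scores)
    best_j, best_c, best_sens, best_spec = -np.inf, uniq[0], 0.0, 0.0
    for c in uniq:
        pred = scores > c
        sens = (pred & labels).sum() / n1
        spec = (~pred & ~labels).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:  # strict improvement => ties keep smaller cutoff
            best_j, best_c, best_sens, best_spec = j, c, sens, spec
    return RocResult(
        auc=auc,
        cutoff=float(best_c),
        sensitivity=100.0 * best_sens,
        specificity=100.0 * best_spec,
        p_value=float(mw.pvalue),
    )


_COMPARE_METRICS = ("pct_correct_area", "pct_error_area",
                    "pct_correct_angle", "pct_error_angle")


def compare_prediction_modes(table: pd.DataFrame,
                             metrics: Sequence[str] = _COMPARE_METRICS,
                             ) -> list[ModeComparison]:
    """Compare catheter-based vs wire-based accuracy within contact strata.

    The frame table must hold both modes (column ``mode``) and the contact
    flag.  For each stratum (contact / non-contact) and each accuracy
    metric, reports the per-mode medians and a two-sided Mann-Whitney U
    p-value.  Empty strata are skipped.
    """
    out: list[ModeComparison] = []
    for stratum, sub in (("contact", table[table["contact"]]),
                         ("non_contact", table[~table["contact"]])):
        if sub.empty:
            logger.info("stratum %s empty: skipped", stratum)
            continue
        cat = sub[sub["mode"] == "catheter"]
        wire = sub[sub["mode"] == "wire"]
        for metric in metrics:
            a = cat[metric].dropna().to_numpy(float)
            b = wire[metric].dropna().to_numpy(float)
            if len(a) == 0 or len(b) == 0:
                continue
            if np.array_equal(np.sort(a), np.sort(b)):
                p = 1.0  # identical samples: no difference by construction
            else:
                p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            out.append(ModeComparison(
                stratum=stratum,
                metric=metric,
                median_catheter=float(np.median(a)),
                median_wire=float(np.median(b)),
                p_value=p,
                n_catheter=len(a),
                n_wire=len(b),
            ))
    return out
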