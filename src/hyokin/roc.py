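"""ROC screening of kinematic parameters for aspiration and stasis.

Impaired swallowing presents with *smaller* hyoid displacements and
velocities, so every parameter is scored with a lower-positive orientation:
a case is predicted positive when its value falls at or below the threshold.
Thresholds are placed at midpoints between consecutive distinct observed
values, with -inf/+inf sentinels so the curve runs from (0, 0) to (1, 1).
AUC is the trapezoidal area, which for this construction equals the
Mann-Whitney concordance probability P(positive < negative) + P(tie)/2.
The operating cutoff maximizes the Youden index J = sensitivity +
specificity - 1 (ties broken toward higher sensitivity, then lower
threshold); a parameter is flagged acceptable when AUC > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .grouping import CLASSIFIED_LABELS
from .kinematics import PARAMETERS

ORIENTATIONS = ("lower_positive", "higher_positive")
ACCEPTABLE_AUC = 0.7


def _check_classes(values: np.ndarray, labels: np.ndarray) -> None:
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(values)):
        raise ValidationError("values must be finite")
    if labels.all() or not labels.any():
        raise DegenerateDataError("both classes must be non-empty")


@dataclass(frozen=True)
class ROCCurve:
    """Curve points: parallel threshold/fpr/tpr arrays plus orientation."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str


def roc_curve(
    values: Sequence[float], labels: Sequence[bool], orientation: str = "lower_positive"
) -> ROCCurve:
    """Full ROC curve over midpoint thresholds plus sentinel endpoints."""
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(v, y)
    u = np.unique(v)
    mids = (u[:-1] + u[1:]) / 2.0
    pos = np.sort(v[y])
    neg = np.sort(v[~y])
    if orientation == "lower_positive":
        thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
        # predicted positive: value <= threshold
        tpr = np.searchsorted(pos, thresholds, side="right") / pos.size
        fpr = np.searchsorted(neg, thresholds, side="right") / neg.size
    else:
        thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
        # predicted positive: value >= threshold
        tpr = (pos.size - np.searchsorted(pos, thresholds, side="left")) / pos.size
        fpr = (neg.size - np.searchsorted(neg, thresholds, side="left")) / neg.size
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, orientation=orientation)


def auc(
    values: Sequence[float], labels: Sequence[bool], orientation: str = "lower_positive"
) -> float:
    """Trapezoidal area under the ROC curve."""
    curve = roc_curve(values, labels, orientation)
    return float(np.trapezoid(curve.tpr, curve.fpr))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def select_cutoff(curve: ROCCurve, criterion: str = "youden") -> CutoffResult:
    """Operating point maximizing Youden J; ties resolved toward higher
    sensitivity, then the lower threshold value."""
    if criterion != "youden":
        raise ValidationError(f"unknown cutoff criterion {criterion!r}")
    j = curve.tpr - curve.fpr
    best = np.flatnonzero(j == j.max())
    best = best[curve.tpr[best] == curve.tpr[best].max()]
    idx = int(best[np.argmin(curve.thresholds[best])])
    return CutoffResult(
        cutoff=float(curve.thresholds[idx]),
        sensitivity=float(curve.tpr[idx]),
        specificity=float(1.0 - curve.fpr[idx]),
        youden_j=float(j[idx]),
    )


def evaluate_cutoff(
    values: Sequence[float],
    labels: Sequence[bool],
    cutoff: float,
    orientation: str = "lower_positive",
) -> tuple[float, float]:
    """(sensitivity, specificity) of a fixed cutoff; ties at the cutoff count
    as positive predictions."""
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(v, y)
    predicted = v <= cutoff if orientation == "lower_positive" else v >= cutoff
    sensitivity = float(predicted[y].mean())
    specificity = float((~predicted[~y]).mean())
    return sensitivity, specificity


@dataclass(frozen=True)
class ROCResult:
    parameter: str
    target: str
    comparator: str
    orientation: str
    curve: ROCCurve
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    acceptable: bool


def run_roc_battery(
    table: pd.DataFrame,
    target: str = "aspiration",
    comparator: str = "rest",
    parameters: Sequence[str] = PARAMETERS,
    group_col: str = "group",
    criterion: str = "youden",
) -> list[ROCResult]:
    """One ROCResult per kinematic parameter for a target condition.

    ``target`` names the positive class ("aspiration" or "stasis").  With
    ``comparator="rest"`` the negatives are all other classified recordings;
    with ``"normal_only"`` they are the normal group alone.  Unclassified and
    doubly-affected recordings never enter.
    """
    classified = {label.value for label in CLASSIFIED_LABELS}
    if target not in classified:
        raise ValidationError(f"target must be one of {sorted(classified)}")
    if comparator not in ("rest", "normal_only"):
        raise ValidationError("comparator must be 'rest' or 'normal_only'")
    if group_col not in table.columns:
        raise ValidationError(f"table lacks group column {group_col!r}")
    groups = table[group_col].astype(str)
    pos_mask = groups == target
    if comparator == "rest":
        neg_mask = groups.isin(classified - {target})
    else:
        neg_mask = groups == "normal"
    if not pos_mask.any():
        raise DegenerateDataError(f"target class {target!r} is empty")
    if not neg_mask.any():
        raise DegenerateDataError(f"comparator class for {target!r} is empty")
    subset = table[pos_mask | neg_mask]
    labels = (subset[group_col] == target).to_numpy()
    results = []
    for param in parameters:
        if param not in table.columns:
            raise ValidationError(f"table lacks parameter column {param!r}")
        values = subset[param].to_numpy(dtype=float)
        curve = roc_curve(values, labels, orientation="lower_positive")
        area = float(np.trapezoid(curve.tpr, curve.fpr))
        cut = select_cutoff(curve, criterion=criterion)
        results.append(ROCResult(
            parameter=param, target=target, comparator=comparator,
            orientation="lower_positive", curve=curve, auc=area,
            cutoff=cut.cutoff, sensitivity=cut.sensitivity,
            specificity=cut.specificity, acceptable=area > ACCEPTABLE_AUC,
        ))
    return results


def battery_table(results: Sequence[ROCResult]) -> pd.DataFrame:
    """Flat report table (one row per parameter) for a ROC battery."""
    return pd.DataFrame([
        {
            "Measure": r.parameter, "target": r.target,
            "comparator": r.comparator, "cutoff": r.cutoff, "AUC": r.auc,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "acceptable": r.acceptable, "orientation": r.orientation,
        }
        for r in results
    ])


def curve_table(results: Sequence[ROCResult]) -> pd.DataFrame:
    """Curve points of a battery, long format, for plotting."""
    rows = []
    for r in results:
        for thr, fpr, tpr in zip(r.curve.thresholds, r.curve.fpr, r.curve.tpr):
            rows.append({
                "Measure": r.parameter, "target": r.target,
                "threshold": thr, "fpr": fpr, "tpr": tpr,
            })
    return pd.DataFrame(rows)
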