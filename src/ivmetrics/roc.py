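"""ROC curves, AUC and Youden-optimal thresholds for instability metrics.

The candidate cutoffs are the midpoints between consecutive distinct sorted
metric values, plus -inf and +inf sentinels; a case is called positive when
its value strictly exceeds the cutoff (or is strictly below, for metrics
where abnormality is low-valued).  This grid realizes every achievable
(sensitivity, specificity) pair.  The AUC is the trapezoidal integral of
the curve, which equals the pairwise concordance probability with ties
counted 1/2.  The operating threshold maximizes Youden's
J = sensitivity + specificity - 1; when several cutoffs tie, the smallest
is returned, favoring sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RocResult", "roc_curve", "auc", "youden_optimal", "sectioning_report"]


@dataclass
class RocResult:
    """A ROC curve with its summary operating point."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    optimal_threshold: float
    sensitivity: float
    specificity: float
    youden_j: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))


def _validate(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be matching 1-D arrays")
    if not np.isfinite(values).all():
        raise ValueError("metric values must be finite")
    if labels.all() or not labels.any():
        raise ValueError("ROC analysis needs at least one positive and one negative case")
    return values, labels


def roc_curve(values, labels, direction: str = "greater") -> RocResult:
    """Full ROC analysis of one metric against binary labels.

    ``labels`` are truthy for the positive (e.g. sectioned) class.
    ``direction='greater'`` treats high values as positive calls;
    ``'less'`` treats low values as positive.
    """
    values, labels = _validate(values, labels)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    work = values if direction == "greater" else -values

    distinct = np.unique(work)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))

    npos = int(labels.sum())
    nneg = labels.size - npos
    tpr = np.array([(work[labels] > t).sum() / npos for t in thresholds])
    fpr = np.array([(work[~labels] > t).sum() / nneg for t in thresholds])

    area = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    jmax = j.max()
    best = np.flatnonzero(j >= jmax - 1e-12)
    # smallest threshold among maximizers = most sensitive operating rule
    pick = best[np.argmin(thresholds[best])]
    opt = thresholds[pick] if direction == "greater" else -thresholds[pick]
    return RocResult(
        auc=area,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds if direction == "greater" else -thresholds,
        optimal_threshold=float(opt),
        sensitivity=float(tpr[pick]),
        specificity=float(1.0 - fpr[pick]),
        youden_j=float(jmax),
    )


def auc(values, labels, direction: str = "greater") -> float:
    """Area under the ROC curve (trapezoidal; equals concordance with ties 1/2)."""
    return roc_curve(values, labels, direction).auc


def youden_optimal(values, labels, direction: str = "greater") -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, J) at the Youden-optimal cutoff."""
    r = roc_curve(values, labels, direction)
    return r.optimal_threshold, r.sensitivity, r.specificity, r.youden_j


#: Default metric columns reported by :func:`sectioning_report`, with the
#: direction in which each indicates abnormality.
DEFAULT_REPORT_METRICS: dict[str, str] = {
    "avi": "greater",
    "pvi": "greater",
    "rotation_deg": "greater",
    "translation_pct_epw": "greater",
    "translation_mm": "greater",
    "segment_angle_diff_deg": "greater",
    "rotation_diff_deg": "greater",
}


def sectioning_report(
    scored: pd.DataFrame,
    metrics: dict[str, str] | list[str] | None = None,
    intact_label: str = "intact",
    per_stage: bool = False,
) -> pd.DataFrame:
    """Tabulate AUC / optimal threshold / sensitivity / specificity per metric.

    ``scored`` needs a ``condition`` column; every condition other than
    ``intact_label`` is a positive (injured) stage.  With ``per_stage`` each
    stage is contrasted against intact separately; otherwise all stages are
    pooled.  Metrics absent from the table are skipped with a warning.
    """
    if isinstance(metrics, list):
        metrics = {m: DEFAULT_REPORT_METRICS.get(m, "greater") for m in metrics}
    metrics = metrics or DEFAULT_REPORT_METRICS
    if "condition" not in scored.columns:
        raise ValueError("sectioning_report requires a 'condition' column")
    cond = scored["condition"].astype(str)
    stages = sorted(set(cond) - {intact_label})
    if not stages:
        raise ValueError("no sectioned stages present")
    contrasts = [(s, cond.isin([intact_label, s])) for s in stages] if per_stage else [
        ("pooled", pd.Series(True, index=scored.index))
    ]

    rows = []
    for stage, mask in contrasts:
        sub = scored.loc[mask]
        labels = (sub["condition"].astype(str) != intact_label).to_numpy()
        for name, direction in metrics.items():
            if name not in sub.columns:
                logger.warning("metric %r not in scores table; row skipped", name)
                continue
            vals = pd.to_numeric(sub[name], errors="coerce")
            ok = vals.notna().to_numpy()
            try:
                r = roc_curve(vals.to_numpy()[ok], labels[ok], direction)
            except ValueError as exc:
                logger.warning("metric %r (%s): %s; row skipped", name, stage, exc)
                continue
            row = {
                "metric": name,
                "auc": r.auc,
                "optimal_threshold": r.optimal_threshold,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            if per_stage:
                row = {"stage": stage, **row}
            rows.append(row)
    return pd.DataFrame(rows)
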