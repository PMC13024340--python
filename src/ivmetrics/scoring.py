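"""Instability indices, abnormality flags, effort filtering and prevalence.

The three regression-based indices share one form: the observed quantity
minus its rotation-predicted value, divided by the standard error of the
forecast at that rotation,

    TI  = (translation - RDT(rotation))   / SEF_RDT(rotation)      per-level model
    AVI = ((ADH_ext - ADH_flex) - RDDW_a(rotation)) / SEF_a(rotation)   pooled
    PVI = ((PDH_flex - PDH_ext) - RDDW_p(rotation)) / SEF_p(rotation)   pooled

so each index is a rotation-adjusted z-score: values in [-2, +2] are within
normal limits regardless of level, vertebral size, or how far the patient
flexed.  Standardized disc height (SDH) is the plain z-score of the
segment's average disc height against the per-level reference; SDH < -2
indicates an abnormally collapsed disc.

Classical criteria are evaluated alongside: adjacent-level rotation
difference > 11 deg, flexion segment-angle difference > 11 deg, and
|translation| > 20 %EPW.  All comparisons are strict.  Segments rotating
less than the minimum (default 5 deg) are marked excluded and carry no
flags, since an under-stressed segment cannot demonstrate instability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import SEGMENTS
from .reference import NormativeReference, standardized_disc_height

logger = logging.getLogger(__name__)

__all__ = [
    "InstabilityScores",
    "ti_index",
    "avi_index",
    "pvi_index",
    "classify_segment",
    "score_records",
    "effort_filter",
    "prevalence",
    "CRITERIA",
]

#: Criterion name -> flag column, in report order.
CRITERIA: dict[str, str] = {
    "TI > 2": "flag_ti",
    "AVI > 2": "flag_avi",
    "PVI > 2": "flag_pvi",
    "SDH < -2": "flag_sdh",
    "Rot Diff > 11": "flag_rotation_diff",
    "Angle Diff > 11": "flag_angle_diff",
    "Trans > 20% EPW": "flag_translation",
}

MM_CRITERION = "Trans > 3.5 mm"


def _index(observed: float, rotation: float, model) -> float:
    s = float(model.sef(rotation))
    if s <= 0:
        raise ValueError("degenerate reference: SEF is zero")
    return (observed - float(model.predict(rotation))) / s


def ti_index(
    translation_pct_epw: float, rotation_deg: float, ref: NormativeReference, segment: str
) -> float:
    """Translational instability index (per-level RDT model)."""
    if segment not in ref.rdt:
        raise ValueError(f"no RDT model for segment {segment}")
    return _index(translation_pct_epw, rotation_deg, ref.rdt[segment])


def avi_index(
    adh_ext: float, adh_flex: float, rotation_deg: float, ref: NormativeReference
) -> float:
    """Anterior vertical instability index (pooled anterior RDDW model)."""
    return _index(adh_ext - adh_flex, rotation_deg, ref.rddw_anterior)


def pvi_index(
    pdh_flex: float, pdh_ext: float, rotation_deg: float, ref: NormativeReference
) -> float:
    """Posterior vertical instability index (pooled posterior RDDW model)."""
    return _index(pdh_flex - pdh_ext, rotation_deg, ref.rddw_posterior)


@dataclass
class InstabilityScores:
    """Index values and abnormality flags for one segment."""

    segment: str
    excluded: bool = False
    exclusion_reason: str | None = None
    ti: float | None = None
    avi: float | None = None
    pvi: float | None = None
    sdh: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)


def classify_segment(row: dict, ref: NormativeReference) -> InstabilityScores:
    """Score one segment (a metric-table row as a mapping) against a reference.

    Missing inputs leave the corresponding index/flag absent (logged);
    they never default to "normal" silently in prevalence denominators.
    """
    thr = ref.thresholds
    seg = row["segment"]
    out = InstabilityScores(segment=seg)

    rotation = row.get("rotation_deg")
    if rotation is None or not np.isfinite(rotation):
        out.excluded, out.exclusion_reason = True, "missing rotation"
        return out
    if rotation < thr.min_rotation_deg:
        out.excluded, out.exclusion_reason = True, f"rotation < {thr.min_rotation_deg} deg"
        return out

    def has(*names: str) -> bool:
        return all(row.get(n) is not None and np.isfinite(row[n]) for n in names)

    if has("translation_pct_epw") and seg in ref.rdt:
        out.ti = ti_index(row["translation_pct_epw"], rotation, ref, seg)
        out.flags["flag_ti"] = out.ti > thr.index_limit
        out.flags["flag_translation"] = abs(row["translation_pct_epw"]) > thr.translation_limit_pct_epw
    else:
        logger.info("%s/%s: translation inputs missing", row.get("exam_id"), seg)
    if has("adh_ext", "adh_flex"):
        out.avi = avi_index(row["adh_ext"], row["adh_flex"], rotation, ref)
        out.flags["flag_avi"] = out.avi > thr.index_limit
    if has("pdh_flex", "pdh_ext"):
        out.pvi = pvi_index(row["pdh_flex"], row["pdh_ext"], rotation, ref)
        out.flags["flag_pvi"] = out.pvi > thr.index_limit
    if has("avg_dh") and seg in ref.avg_dh_ref and ref.avg_dh_ref[seg].sd > 0:
        s = ref.avg_dh_ref[seg]
        out.sdh = standardized_disc_height(row["avg_dh"], s.mean, s.sd)
        out.flags["flag_sdh"] = out.sdh < -thr.index_limit
    if has("rotation_diff_deg"):
        out.flags["flag_rotation_diff"] = row["rotation_diff_deg"] > thr.rotation_diff_limit_deg
    if has("segment_angle_diff_deg"):
        out.flags["flag_angle_diff"] = row["segment_angle_diff_deg"] > thr.angle_diff_limit_deg
    if thr.apply_mm_criterion and has("translation_mm"):
        out.flags["flag_translation_mm"] = abs(row["translation_mm"]) > thr.translation_limit_mm
    return out


def score_records(records: pd.DataFrame, ref: NormativeReference) -> pd.DataFrame:
    """Score every segment of a metric table; returns metrics + scores/flags.

    Output columns add ``ti``, ``avi``, ``pvi``, ``sdh``, one boolean-ish
    column per criterion (NaN where that criterion's inputs are missing),
    and ``excluded``/``exclusion_reason``.
    """
    flag_cols = list(CRITERIA.values()) + (
        ["flag_translation_mm"] if ref.thresholds.apply_mm_criterion else []
    )
    rows = []
    for _, rec in records.iterrows():
        row = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        scores = classify_segment(row, ref)
        out = dict(rec)
        out.update(
            ti=scores.ti,
            avi=scores.avi,
            pvi=scores.pvi,
            sdh=scores.sdh,
            excluded=scores.excluded,
            exclusion_reason=scores.exclusion_reason,
        )
        for col in flag_cols:
            out[col] = scores.flags.get(col)
        rows.append(out)
    frame = pd.DataFrame(rows)
    for col in flag_cols:
        frame[col] = frame[col].astype("boolean")
    return frame


def effort_filter(
    records: pd.DataFrame, min_total_rotation: float = 60.0, active: bool = True
) -> pd.DataFrame:
    """Keep exams demonstrating adequate global motion.

    An exam passes when its total C2-C7 rotation strictly exceeds
    ``min_total_rotation`` (deg).  Exams without a computable total are
    dropped while the filter is active, since effort cannot be verified.
    """
    if min_total_rotation < 0:
        raise ValueError("min_total_rotation must be >= 0")
    if not active:
        return records.copy()
    total = records["total_c2c7_rotation_deg"]
    keep = total.notna() & (total > min_total_rotation)
    out = records.loc[keep].copy()
    if out.empty:
        logger.warning("effort filter removed every exam (no totals > %.1f deg)", min_total_rotation)
    return out


def prevalence(scored: pd.DataFrame, criteria: dict[str, str] | None = None) -> pd.DataFrame:
    """Percent abnormal per level and criterion, over analyzable segments.

    ``n`` counts non-excluded segments at the level; each criterion's
    denominator additionally drops segments whose inputs for that criterion
    were unavailable (its flag is NA).
    """
    criteria = criteria or {
        name: col for name, col in CRITERIA.items() if col in scored.columns
    }
    analyzable = scored.loc[~scored["excluded"].astype(bool)]
    rows = []
    for segment in SEGMENTS:
        group = analyzable.loc[analyzable["segment"] == segment]
        row: dict = {"segment": segment, "n": int(len(group))}
        for name, col in criteria.items():
            flags = group[col].dropna() if col in group.columns else pd.Series(dtype="boolean")
            row[name] = 100.0 * flags.astype(bool).mean() if len(flags) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
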