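"""Normative reference model for cervical intervertebral motion.

The reference is built from a cohort of asymptomatic flexion-extension
exams.  Levels with definite radiographic degeneration and levels moving
less than a minimum rotation (default 5 deg, below which the intrinsic
restraints are not meaningfully stressed) are excluded.  The model stores:

* per-level means/SDs with 95% upper limits (mean + 1.96 SD) for rotation,
  translation (%EPW and mm), adjacent-level rotation and segment-angle
  differences, and the per-segment share of total C2-C7 rotation;
* rotation-dependent translation (RDT): one ordinary least-squares line of
  translation on rotation per level (slopes differ across levels);
* rotation-dependent disc widening (RDDW): pooled lines of anterior and
  posterior disc opening on rotation (slopes are similar across levels);
* the per-level average-disc-height reference used for standardized disc
  height (SDH);
* the mean/SD of total C2-C7 rotation, and all decision thresholds.

Each regression carries the sufficient statistics (n, x mean, Sxx, residual
SD) needed for the standard error of the forecast

    SEF(x0) = s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx),

the rotation-specific prediction uncertainty used to standardize the
instability indices.  Unlike a constant SD band, the SEF widens away from
the cohort's mean rotation, so an index value of +/-2 always corresponds to
the ~95% prediction band at the observed rotation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import SEGMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "LevelStats",
    "LinearModel",
    "Thresholds",
    "NormativeReference",
    "filter_reference_levels",
    "fit_level_stats",
    "fit_linear",
    "sef",
    "standardized_disc_height",
    "fit_reference",
    "save_reference",
    "load_reference",
]

REFERENCE_FORMAT_VERSION = "1"

#: Metric-table columns summarized per level in the reference.
STAT_METRICS: tuple[str, ...] = (
    "rotation_deg",
    "translation_pct_epw",
    "translation_mm",
    "rotation_diff_deg",
    "segment_angle_diff_deg",
    "rotation_pct_c2c7",
)


@dataclass(frozen=True)
class LevelStats:
    """Sample mean/SD of one metric at one level, with the 95% upper limit."""

    metric: str
    segment: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.metric}/{self.segment}: negative SD")

    @property
    def upper95(self) -> float:
        """Upper limit of the 95% reference interval, mean + 1.96 SD."""
        return self.mean + 1.96 * self.sd


@dataclass(frozen=True)
class LinearModel:
    """A fitted simple regression with the statistics needed for the SEF."""

    slope: float
    intercept: float
    n: int
    x_mean: float
    sxx: float
    residual_sd: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("LinearModel requires n >= 3")
        if self.sxx <= 0:
            raise ValueError("LinearModel requires non-degenerate x (sxx > 0)")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError(f"r_squared out of range: {self.r_squared}")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def sef(self, x):
        """Standard error of the forecast at x (same units as y)."""
        x = np.asarray(x, dtype=float)
        return self.residual_sd * np.sqrt(1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)


def sef(model: LinearModel, x0) -> float | np.ndarray:
    """Functional form of :meth:`LinearModel.sef`."""
    out = model.sef(x0)
    return float(out) if np.ndim(x0) == 0 else out


def fit_linear(x, y) -> LinearModel:
    """Ordinary least squares of y on x with forecast statistics.

    Requires n >= 3 and non-constant x.  The residual SD uses the usual
    n - 2 denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"fit_linear requires n >= 3, got {n}")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 0:
        raise ValueError("fit_linear requires non-constant x")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    residual_sd = math.sqrt(float((resid ** 2).sum()) / (n - 2))
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
        x_mean=float(x.mean()),
        sxx=sxx,
        residual_sd=residual_sd,
        r_squared=float(res.rvalue) ** 2,
    )


def filter_reference_levels(
    records: pd.DataFrame,
    min_rotation: float = 5.0,
    degeneration_cutoff: int = 2,
) -> pd.DataFrame:
    """Restrict a metric table to reference-quality segments.

    Keeps segments with rotation >= ``min_rotation`` (the exclusion drops
    levels moving *less than* the minimum, so the boundary value is
    retained) and, where a degeneration grade is recorded, grade
    strictly below ``degeneration_cutoff`` (Kellgren-Lawrence >= 2 is
    treated as definite degeneration).  Ungraded segments are retained.
    """
    if min_rotation < 0:
        raise ValueError("min_rotation must be >= 0")
    keep = records["rotation_deg"] >= min_rotation
    if "grade" in records.columns:
        grades = pd.to_numeric(records["grade"], errors="coerce")
        keep &= grades.isna() | (grades < degeneration_cutoff)
    return records.loc[keep].copy()


def fit_level_stats(records: pd.DataFrame, metric: str) -> dict[str, LevelStats]:
    """Per-level sample mean/SD (n-1 denominator) of one metric column.

    Levels with fewer than two finite values are omitted with a warning.
    """
    out: dict[str, LevelStats] = {}
    for segment, group in records.groupby("segment"):
        vals = pd.to_numeric(group[metric], errors="coerce").dropna().to_numpy()
        if vals.size < 2:
            logger.warning("%s/%s: <2 records, level omitted from stats", metric, segment)
            continue
        out[segment] = LevelStats(
            metric=metric,
            segment=str(segment),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            n=int(vals.size),
        )
    return out


def standardized_disc_height(avg_dh: float, ref_mean: float, ref_sd: float) -> float:
    """SDH: z-score of a segment's average disc height against the reference."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (avg_dh - ref_mean) / ref_sd


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; defaults are the published criteria.

    All comparisons downstream are strict ("exceeds"), so boundary values
    are normal.  The legacy 3.5 mm translation criterion is carried but
    disabled by default: it presumes ~30% radiographic magnification, which
    magnification-free measurements do not have.
    """

    index_limit: float = 2.0
    rotation_diff_limit_deg: float = 11.0
    angle_diff_limit_deg: float = 11.0
    translation_limit_pct_epw: float = 20.0
    translation_limit_mm: float = 3.5
    apply_mm_criterion: bool = False
    min_rotation_deg: float = 5.0
    min_total_rotation_deg: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "index_limit",
            "rotation_diff_limit_deg",
            "angle_diff_limit_deg",
            "translation_limit_pct_epw",
            "translation_limit_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class NormativeReference:
    """Serializable bundle of everything needed to score a new exam."""

    level_stats: dict[str, dict[str, LevelStats]]
    rdt: dict[str, LinearModel]
    rddw_anterior: LinearModel
    rddw_posterior: LinearModel
    avg_dh_ref: dict[str, LevelStats]
    c2c7_rotation: tuple[float, float, int] | None
    thresholds: Thresholds = field(default_factory=Thresholds)
    version: str = REFERENCE_FORMAT_VERSION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.rdt]
        if missing:
            raise ValueError(f"RDT model missing for segments {missing}")


def fit_reference(
    records: pd.DataFrame,
    min_rotation: float = 5.0,
    degeneration_cutoff: int = 2,
    thresholds: Thresholds | None = None,
    provenance: Mapping | None = None,
) -> NormativeReference:
    """Fit the full normative model from a long-form metric table.

    ``records`` must carry the columns produced by
    :func:`ivmetrics.geometry.metrics_frame` (a ``grade`` column is
    optional).  Filtering, per-level statistics, per-level RDT regressions,
    pooled RDDW regressions and the disc-height reference are all derived
    from the same filtered cohort.
    """
    ref_records = filter_reference_levels(records, min_rotation, degeneration_cutoff)
    if ref_records.empty:
        raise ValueError("no reference-quality segments after filtering")

    level_stats = {
        metric: fit_level_stats(ref_records, metric)
        for metric in STAT_METRICS
        if metric in ref_records.columns
    }

    rdt = {}
    for segment, group in ref_records.groupby("segment"):
        try:
            rdt[str(segment)] = fit_linear(group["rotation_deg"], group["translation_pct_epw"])
        except ValueError as exc:
            logger.warning("RDT fit failed at %s: %s", segment, exc)

    rddw_anterior = fit_linear(ref_records["rotation_deg"], ref_records["d_adh"])
    rddw_posterior = fit_linear(ref_records["rotation_deg"], ref_records["d_pdh"])

    avg_dh_ref = fit_level_stats(ref_records, "avg_dh")

    c2c7 = None
    if "total_c2c7_rotation_deg" in records.columns:
        totals = (
            records.dropna(subset=["total_c2c7_rotation_deg"])
            .groupby("exam_id")["total_c2c7_rotation_deg"]
            .first()
            .to_numpy()
        )
        if totals.size >= 2:
            c2c7 = (float(totals.mean()), float(totals.std(ddof=1)), int(totals.size))

    thr = thresholds or Thresholds(min_rotation_deg=min_rotation)
    prov = dict(provenance or {})
    prov.setdefault("n_segments", int(len(ref_records)))
    prov.setdefault("n_per_level", {s: int(m.n) for s, m in level_stats["rotation_deg"].items()})
    return NormativeReference(
        level_stats=level_stats,
        rdt=rdt,
        rddw_anterior=rddw_anterior,
        rddw_posterior=rddw_posterior,
        avg_dh_ref=avg_dh_ref,
        c2c7_rotation=c2c7,
        thresholds=thr,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _stats_to_dict(s: LevelStats) -> dict:
    return {"mean": s.mean, "sd": s.sd, "n": s.n, "upper95": s.upper95}


def _model_to_dict(m: LinearModel) -> dict:
    return {
        "M": m.slope,
        "B": m.intercept,
        "n": m.n,
        "x_mean": m.x_mean,
        "sxx": m.sxx,
        "s": m.residual_sd,
        "r2": m.r_squared,
    }


def _model_from_dict(d: Mapping) -> LinearModel:
    return LinearModel(
        slope=d["M"],
        intercept=d["B"],
        n=d["n"],
        x_mean=d["x_mean"],
        sxx=d["sxx"],
        residual_sd=d["s"],
        r_squared=d["r2"],
    )


def save_reference(ref: NormativeReference, path: str | Path) -> None:
    """Write a reference model as canonical JSON."""
    payload = {
        "version": ref.version,
        "levels": {
            metric: {seg: _stats_to_dict(s) for seg, s in sorted(per_level.items())}
            for metric, per_level in sorted(ref.level_stats.items())
        },
        "rdt": {seg: _model_to_dict(m) for seg, m in sorted(ref.rdt.items())},
        "rddw_a": _model_to_dict(ref.rddw_anterior),
        "rddw_p": _model_to_dict(ref.rddw_posterior),
        "avg_dh_ref": {seg: _stats_to_dict(s) for seg, s in sorted(ref.avg_dh_ref.items())},
        "c2c7": (
            None
            if ref.c2c7_rotation is None
            else {"mean": ref.c2c7_rotation[0], "sd": ref.c2c7_rotation[1], "n": ref.c2c7_rotation[2]}
        ),
        "thresholds": {
            "index_limit": ref.thresholds.index_limit,
            "rotation_diff_limit_deg": ref.thresholds.rotation_diff_limit_deg,
            "angle_diff_limit_deg": ref.thresholds.angle_diff_limit_deg,
            "translation_limit_pct_epw": ref.thresholds.translation_limit_pct_epw,
            "translation_limit_mm": ref.thresholds.translation_limit_mm,
            "apply_mm_criterion": ref.thresholds.apply_mm_criterion,
            "min_rotation_deg": ref.thresholds.min_rotation_deg,
            "min_total_rotation_deg": ref.thresholds.min_total_rotation_deg,
        },
        "provenance": ref.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")


def load_reference(path: str | Path) -> NormativeReference:
    """Load a reference model written by :func:`save_reference`."""
    raw = json.loads(Path(path).read_text())
    try:
        level_stats = {
            metric: {
                seg: LevelStats(metric=metric, segment=seg, mean=d["mean"], sd=d["sd"], n=d["n"])
                for seg, d in per_level.items()
            }
            for metric, per_level in raw["levels"].items()
        }
        for metric, per_level in raw["levels"].items():
            for seg, d in per_level.items():
                stored = d["upper95"]
                if abs(stored - level_stats[metric][seg].upper95) > 1e-9:
                    raise ValueError(
                        f"{metric}/{seg}: stored upper95 {stored} inconsistent with mean/sd"
                    )
        ref = NormativeReference(
            level_stats=level_stats,
            rdt={seg: _model_from_dict(d) for seg, d in raw["rdt"].items()},
            rddw_anterior=_model_from_dict(raw["rddw_a"]),
            rddw_posterior=_model_from_dict(raw["rddw_p"]),
            avg_dh_ref={
                seg: LevelStats(metric="avg_dh", segment=seg, mean=d["mean"], sd=d["sd"], n=d["n"])
                for seg, d in raw["avg_dh_ref"].items()
            },
            c2c7_rotation=(
                None
                if raw["c2c7"] is None
                else (raw["c2c7"]["mean"], raw["c2c7"]["sd"], raw["c2c7"]["n"])
            ),
            thresholds=Thresholds(**raw["thresholds"]),
            version=raw["version"],
            provenance=raw.get("provenance", {}),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: malformed reference file (missing {exc})") from exc
    return ref
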