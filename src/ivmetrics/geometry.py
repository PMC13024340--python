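"""Per-segment sagittal kinematics from corner landmarks.

All measurements are made in an *anatomical frame* derived from the image
coordinates: anterior is +X (resolved through the radiograph's ``facing``
flag) and cranial is +Y.  Angles are reported in degrees with anterior disc
opening (extension) positive.  Linear measures are normalized to the width
of the inferior vertebra's superior endplate (%EPW), which removes both
radiographic magnification and inter-individual size differences; the one
millimetric output (translation in mm) is obtained by assigning each level a
population-average endplate width.

Definitions
-----------
disc angle
    Signed angle between the inferior endplate of the superior vertebra and
    the superior endplate of the inferior vertebra.
intervertebral rotation
    Extension disc angle minus flexion disc angle, so that normal
    flexion-extension motion is positive.
intervertebral translation
    After registering the inferior vertebra's landmarks between phases by a
    least-squares similarity transform, the displacement of the superior
    vertebra's posterior-inferior corner, projected on the (flexion)
    inferior superior-endplate direction; anterior displacement from
    extension to flexion is positive; reported in %EPW.
disc heights
    Euclidean corner-to-corner distances: anterior-inferior corner of the
    superior vertebra to anterior-superior corner of the inferior vertebra
    (dh_A), and the posterior analogue (dh_P), in %EPW.
segment angle
    Signed angle between the *inferior* endplates of the two vertebrae (the
    convention used by impairment-rating guides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .landmarks import (
    CORNERS,
    LEVELS,
    SEGMENTS,
    ExamLandmarks,
    VertebraLandmarks,
    segment_levels,
)

__all__ = [
    "DEFAULT_EPW_MM",
    "EndplateLine",
    "SegmentMetrics",
    "ExamMetrics",
    "endplate",
    "disc_angle",
    "segment_angle",
    "intervertebral_rotation",
    "intervertebral_translation",
    "disc_heights",
    "similarity_transform",
    "vertebra_rotation",
    "adjacent_level_difference",
    "exam_metrics",
    "metrics_frame",
]

#: Average endplate widths (mm) assigned per level for the mm translation
#: output; each value is the population ratio of millimetric to %EPW
#: translation at that level (the normalizer is the superior endplate of the
#: inferior vertebra).  User-overridable in :func:`exam_metrics`.
DEFAULT_EPW_MM: dict[str, float] = {
    "C2-C3": 14.9,
    "C3-C4": 14.9,
    "C4-C5": 14.9,
    "C5-C6": 15.8,
    "C6-C7": 16.7,
}


def _to_anatomical(points: np.ndarray, facing: str) -> np.ndarray:
    """Map image coordinates (x right, y down) to anatomical (X anterior, Y up)."""
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    out[..., 0] = pts[..., 0] if facing == "right" else -pts[..., 0]
    out[..., 1] = -pts[..., 1]
    return out


def _wrap_deg(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class EndplateLine:
    """An endplate as a directed line in the anatomical frame.

    ``origin`` is the posterior corner, ``direction`` the unit vector
    pointing anteriorly, ``width`` the posterior-to-anterior corner distance
    in the coordinate units of the landmarks.
    """

    origin: np.ndarray
    direction: np.ndarray
    width: float

    @property
    def angle_deg(self) -> float:
        """Orientation vs. the anatomical horizontal, positive tilting up anteriorly."""
        return math.degrees(math.atan2(self.direction[1], self.direction[0]))


def endplate(vertebra: VertebraLandmarks, side: str, facing: str) -> EndplateLine:
    """The superior or inferior endplate line of a vertebra, anatomical frame."""
    if side not in ("superior", "inferior"):
        raise ValueError(f"side must be 'superior' or 'inferior', got {side!r}")
    ant, post = ("AS", "PS") if side == "superior" else ("AI", "PI")
    p = _to_anatomical(vertebra.corners[post].as_array(), facing)
    a = _to_anatomical(vertebra.corners[ant].as_array(), facing)
    vec = a - p
    width = float(np.linalg.norm(vec))
    if width <= 0:
        raise ValueError(f"{vertebra.level}: zero-width {side} endplate")
    return EndplateLine(origin=p, direction=vec / width, width=width)


def disc_angle(superior: VertebraLandmarks, inferior: VertebraLandmarks, facing: str) -> float:
    """Signed disc angle (deg); anterior opening positive."""
    _check_adjacent(superior, inferior)
    upper = endplate(superior, "inferior", facing)
    lower = endplate(inferior, "superior", facing)
    return _wrap_deg(upper.angle_deg - lower.angle_deg)


def segment_angle(superior: VertebraLandmarks, inferior: VertebraLandmarks, facing: str) -> float:
    """Signed angle between the two inferior endplates (deg), same sign convention."""
    _check_adjacent(superior, inferior)
    upper = endplate(superior, "inferior", facing)
    lower = endplate(inferior, "inferior", facing)
    return _wrap_deg(upper.angle_deg - lower.angle_deg)


def intervertebral_rotation(flex_angle: float, ext_angle: float) -> float:
    """Sagittal rotation: extension minus flexion disc angle (deg)."""
    return _wrap_deg(ext_angle - flex_angle)


def _check_adjacent(superior: VertebraLandmarks, inferior: VertebraLandmarks) -> None:
    si, ii = LEVELS.index(superior.level), LEVELS.index(inferior.level)
    if ii - si != 1:
        raise ValueError(f"{superior.level} and {inferior.level} are not adjacent levels")


def similarity_transform(source: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity (uniform scale + rotation + translation).

    Returns ``(s, R, t)`` minimizing ``sum ||s R x + t - y||^2`` over
    corresponding rows of ``source`` and ``target``.  Reflections are not
    allowed.  Raises for degenerate (collinear or coincident) point sets.
    """
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise ValueError("similarity_transform requires matching (n>=3, 2) arrays")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    var_x = (xc ** 2).sum()
    cov = yc.T @ xc
    u, d, vt = np.linalg.svd(cov)
    if d[-1] < 1e-9 * max(d[0], 1.0) or var_x <= 0:
        raise ValueError("degenerate registration: landmarks are collinear or coincident")
    sign = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, sign])
    rot = u @ corr @ vt
    scale = float(np.trace(np.diag(d) @ corr) / var_x)
    if scale <= 0:
        raise ValueError("degenerate registration: non-positive scale")
    trans = my - scale * rot @ mx
    return scale, rot, trans


def vertebra_rotation(flex: VertebraLandmarks, ext: VertebraLandmarks, facing: str) -> float:
    """Rigid-body orientation change of one vertebra, extension minus flexion (deg)."""
    src = _to_anatomical(flex.corner_array(), facing)
    dst = _to_anatomical(ext.corner_array(), facing)
    _, rot, _ = similarity_transform(src, dst)
    return math.degrees(math.atan2(rot[1, 0], rot[0, 0]))


def intervertebral_translation(
    superior_flex: VertebraLandmarks,
    superior_ext: VertebraLandmarks,
    inferior_flex: VertebraLandmarks,
    inferior_ext: VertebraLandmarks,
    facing: str,
) -> float:
    """Sagittal translation in %EPW; anterior displacement from extension to flexion positive."""
    src = _to_anatomical(inferior_ext.corner_array(), facing)
    dst = _to_anatomical(inferior_flex.corner_array(), facing)
    s, rot, t = similarity_transform(src, dst)
    pi_ext = _to_anatomical(superior_ext.corners["PI"].as_array(), facing)
    pi_flex = _to_anatomical(superior_flex.corners["PI"].as_array(), facing)
    displacement = pi_flex - (s * rot @ pi_ext + t)
    ref = endplate(inferior_flex, "superior", facing)
    return float(displacement @ ref.direction) / ref.width * 100.0


def disc_heights(
    superior: VertebraLandmarks, inferior: VertebraLandmarks, facing: str
) -> tuple[float, float]:
    """(dh_A, dh_P) corner-to-corner disc heights in %EPW."""
    _check_adjacent(superior, inferior)
    width = endplate(inferior, "superior", facing).width
    dh_a = math.dist(
        (superior.corners["AI"].x, superior.corners["AI"].y),
        (inferior.corners["AS"].x, inferior.corners["AS"].y),
    )
    dh_p = math.dist(
        (superior.corners["PI"].x, superior.corners["PI"].y),
        (inferior.corners["PS"].x, inferior.corners["PS"].y),
    )
    return dh_a / width * 100.0, dh_p / width * 100.0


def adjacent_level_difference(values: Mapping[str, float], segment: str) -> float | None:
    """Maximum absolute difference between a segment's value and its neighbors'.

    Neighbors are the adjacent segments (C2-C3 and C6-C7 each have one).
    Returns ``None`` when the segment or every neighbor is unavailable;
    missing neighbors never count as zero difference.
    """
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    if segment not in values or values[segment] is None:
        return None
    i = SEGMENTS.index(segment)
    diffs = [
        abs(values[segment] - values[n])
        for n in SEGMENTS[max(i - 1, 0) : i + 2]
        if n != segment and n in values and values[n] is not None
    ]
    return max(diffs) if diffs else None


@dataclass
class SegmentMetrics:
    """Every basic measurement for one motion segment of one exam."""

    segment: str
    rotation_deg: float
    translation_pct_epw: float
    translation_mm: float
    adh_flex: float
    adh_ext: float
    pdh_flex: float
    pdh_ext: float
    disc_angle_flex: float
    disc_angle_ext: float
    segment_angle_flex: float
    segment_angle_ext: float
    rotation_pct_c2c7: float | None = None

    @property
    def avg_dh(self) -> float:
        """Mean of the four disc heights (%EPW); the subject value for SDH."""
        return (self.adh_flex + self.adh_ext + self.pdh_flex + self.pdh_ext) / 4.0

    @property
    def d_adh(self) -> float:
        """Anterior disc opening: extension minus flexion anterior height (%EPW)."""
        return self.adh_ext - self.adh_flex

    @property
    def d_pdh(self) -> float:
        """Posterior disc opening: flexion minus extension posterior height (%EPW)."""
        return self.pdh_flex - self.pdh_ext


@dataclass
class ExamMetrics:
    """All segment metrics plus exam-level quantities for one exam."""

    exam_id: str
    segments: dict[str, SegmentMetrics] = field(default_factory=dict)
    total_c2c7_rotation_deg: float | None = None
    rotation_diff_deg: dict[str, float] = field(default_factory=dict)
    segment_angle_diff_deg: dict[str, float] = field(default_factory=dict)
    degeneration_grades: dict[str, int] = field(default_factory=dict)
    condition: str | None = None

    def to_records(self) -> list[dict]:
        rows = []
        for seg in SEGMENTS:
            if seg not in self.segments:
                continue
            m = self.segments[seg]
            row = asdict(m)
            row.update(
                exam_id=self.exam_id,
                segment=seg,
                avg_dh=m.avg_dh,
                d_adh=m.d_adh,
                d_pdh=m.d_pdh,
                rotation_diff_deg=self.rotation_diff_deg.get(seg),
                segment_angle_diff_deg=self.segment_angle_diff_deg.get(seg),
                total_c2c7_rotation_deg=self.total_c2c7_rotation_deg,
                grade=self.degeneration_grades.get(seg),
                condition=self.condition,
            )
            rows.append(row)
        return rows


def exam_metrics(
    exam: ExamLandmarks, epw_mm_table: Mapping[str, float] | None = None
) -> ExamMetrics:
    """Compute every per-segment and exam-level metric for one exam.

    Segments are computed iff both vertebrae are present in both phases;
    everything else is left absent rather than guessed.  The total C2-C7
    rotation (present iff C2 and C7 are analyzable in both phases) is the
    relative rigid-body rotation of C2 vs C7 between phases, which equals
    the sum of the five segmental rotations when all are available.
    """
    epw_mm = dict(DEFAULT_EPW_MM)
    if epw_mm_table:
        epw_mm.update(epw_mm_table)
    facing = exam.facing
    out = ExamMetrics(
        exam_id=exam.exam_id,
        degeneration_grades=dict(exam.degeneration_grades),
        condition=exam.condition,
    )

    total = None
    if all(lv in rad for rad in (exam.flexion, exam.extension) for lv in ("C2", "C7")):
        total = _wrap_deg(
            vertebra_rotation(exam.flexion["C2"], exam.extension["C2"], facing)
            - vertebra_rotation(exam.flexion["C7"], exam.extension["C7"], facing)
        )
    out.total_c2c7_rotation_deg = total

    for seg in exam.available_segments():
        sup, inf = segment_levels(seg)
        sup_f, inf_f = exam.flexion[sup], exam.flexion[inf]
        sup_e, inf_e = exam.extension[sup], exam.extension[inf]
        da_f = disc_angle(sup_f, inf_f, facing)
        da_e = disc_angle(sup_e, inf_e, facing)
        rotation = intervertebral_rotation(da_f, da_e)
        translation = intervertebral_translation(sup_f, sup_e, inf_f, inf_e, facing)
        adh_f, pdh_f = disc_heights(sup_f, inf_f, facing)
        adh_e, pdh_e = disc_heights(sup_e, inf_e, facing)
        out.segments[seg] = SegmentMetrics(
            segment=seg,
            rotation_deg=rotation,
            translation_pct_epw=translation,
            translation_mm=translation / 100.0 * epw_mm[seg],
            adh_flex=adh_f,
            adh_ext=adh_e,
            pdh_flex=pdh_f,
            pdh_ext=pdh_e,
            disc_angle_flex=da_f,
            disc_angle_ext=da_e,
            segment_angle_flex=segment_angle(sup_f, inf_f, facing),
            segment_angle_ext=segment_angle(sup_e, inf_e, facing),
            rotation_pct_c2c7=(100.0 * rotation / total) if total else None,
        )

    rotations = {s: m.rotation_deg for s, m in out.segments.items()}
    angles_flex = {s: m.segment_angle_flex for s, m in out.segments.items()}
    for seg in out.segments:
        rd = adjacent_level_difference(rotations, seg)
        ad = adjacent_level_difference(angles_flex, seg)
        if rd is not None:
            out.rotation_diff_deg[seg] = rd
        if ad is not None:
            out.segment_angle_diff_deg[seg] = ad
    return out


#: Fixed column order of the long-form metric table.
METRIC_COLUMNS: tuple[str, ...] = (
    "exam_id",
    "segment",
    "rotation_deg",
    "translation_pct_epw",
    "translation_mm",
    "adh_flex",
    "adh_ext",
    "pdh_flex",
    "pdh_ext",
    "avg_dh",
    "d_adh",
    "d_pdh",
    "disc_angle_flex",
    "disc_angle_ext",
    "segment_angle_flex",
    "segment_angle_ext",
    "rotation_diff_deg",
    "segment_angle_diff_deg",
    "rotation_pct_c2c7",
    "total_c2c7_rotation_deg",
    "grade",
    "condition",
)


def metrics_frame(exams: list[ExamMetrics]) -> pd.DataFrame:
    """Stack exam metrics into one long-form DataFrame (one row per segment)."""
    rows = [row for exam in exams for row in exam.to_records()]
    frame = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    return frame
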