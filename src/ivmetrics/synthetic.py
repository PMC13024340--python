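"""Synthetic cohorts with the statistical structure the method assumes.

The generator emulates three study designs without any imaging data:

* **Asymptomatic reference cohorts** — per-level intervertebral rotations
  drawn from normative means/SDs; translation generated from a per-level
  linear rotation-dependent-translation (RDT) model; anterior/posterior
  disc opening generated from pooled rotation-dependent-disc-widening
  (RDDW) models; disc-height baselines chosen so %EPW values stay in a
  plausible 10-25% band.  The default rotation/translation moments and RDT
  R-squared targets are the published normative values for radiographically
  normal levels; RDT slopes/intercepts/noise are derived from them
  (``M = sd_y*sqrt(R2)/sd_x`` etc.) so a refit on generated data
  reproduces the configured table.
* **Low-effort patient cohorts** — the ``effort`` multiplier scales every
  per-level mean rotation, emulating under-stressed flexion-extension exams.
* **Ligament-sectioning experiments** — paired intact/sectioned arms where
  each stage adds a rotation increase and a disc-opening excess at one
  target level while leaving translation at its intact value (sectioning
  destabilizes vertical motion long before translation).

Metric-level records are drawn exactly from the configured model.  Landmark
exams are *posed*: vertebral outlines are stacked so that the measurement
pipeline recovers each prescribed rotation, translation and corner disc
height to numerical precision, then arbitrary per-radiograph similarity
transforms (magnification, rotation, offset) are applied, which the %EPW
and angle metrics must ignore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .landmarks import (
    CORNERS,
    LEVELS,
    SEGMENTS,
    ExamLandmarks,
    Point2D,
    RadiographLandmarks,
    VertebraLandmarks,
    segment_levels,
)
from .geometry import DEFAULT_EPW_MM, METRIC_COLUMNS, adjacent_level_difference

__all__ = [
    "NORMATIVE_ROTATION",
    "NORMATIVE_TRANSLATION_PCT",
    "RDT_R_SQUARED",
    "InjuryEffect",
    "GeneratorConfig",
    "PoseError",
    "generate_metric_cohort",
    "pose_landmarks",
    "generate_landmark_cohort",
    "generate_sectioning_experiment",
]

#: Normative per-level rotation (mean, SD) in degrees for radiographically
#: normal segments of asymptomatic adults at full voluntary effort.
NORMATIVE_ROTATION: dict[str, tuple[float, float]] = {
    "C2-C3": (8.7, 2.8),
    "C3-C4": (14.1, 3.4),
    "C4-C5": (17.9, 3.2),
    "C5-C6": (19.1, 4.5),
    "C6-C7": (16.5, 4.7),
}

#: Normative per-level translation (mean, SD) in %EPW.
NORMATIVE_TRANSLATION_PCT: dict[str, tuple[float, float]] = {
    "C2-C3": (12.1, 4.7),
    "C3-C4": (15.4, 4.7),
    "C4-C5": (18.1, 4.5),
    "C5-C6": (15.2, 4.5),
    "C6-C7": (9.0, 3.1),
}

#: Normative per-level R-squared of the translation-on-rotation regression.
RDT_R_SQUARED: dict[str, float] = {
    "C2-C3": 0.56,
    "C3-C4": 0.48,
    "C4-C5": 0.30,
    "C5-C6": 0.48,
    "C6-C7": 0.56,
}


def _derived_rdt() -> dict[str, tuple[float, float, float]]:
    """Per-level (slope, intercept, noise SD) reproducing the normative moments.

    For y = M x + B + e with x ~ N(mx, sx^2):  M = sy*sqrt(R2)/sx,
    B = my - M*mx, sd(e) = sy*sqrt(1 - R2); refitting on a large generated
    sample recovers the configured means, SDs and R-squared.
    """
    out = {}
    for seg in SEGMENTS:
        mx, sx = NORMATIVE_ROTATION[seg]
        my, sy = NORMATIVE_TRANSLATION_PCT[seg]
        r2 = RDT_R_SQUARED[seg]
        slope = sy * math.sqrt(r2) / sx
        out[seg] = (slope, my - slope * mx, sy * math.sqrt(1.0 - r2))
    return out


#: Flexion segment-angle (mean, SD) in degrees per level; only adjacent-level
#: differences of these enter any criterion.
_SEGMENT_ANGLE_FLEX: dict[str, tuple[float, float]] = {
    "C2-C3": (-8.0, 3.0),
    "C3-C4": (-9.0, 3.0),
    "C4-C5": (-10.0, 3.0),
    "C5-C6": (-9.0, 3.0),
    "C6-C7": (-7.0, 3.0),
}


@dataclass(frozen=True)
class InjuryEffect:
    """Additive shifts a sectioning stage applies at the target level."""

    rotation_deg: float = 0.0
    translation_pct_epw: float = 0.0
    d_adh: float = 0.0
    d_pdh: float = 0.0


def _default_stages() -> dict[str, InjuryEffect]:
    # Anterior-to-posterior sequential sectioning: disc opening departs from
    # the rotation-predicted value by far more than the RDDW noise SD at the
    # first stage already; rotation increases moderately; translation not at all.
    return {
        "section-1": InjuryEffect(rotation_deg=3.0, d_adh=8.0, d_pdh=6.0),
        "section-2": InjuryEffect(rotation_deg=4.5, d_adh=11.0, d_pdh=8.0),
        "section-3": InjuryEffect(rotation_deg=6.0, d_adh=14.0, d_pdh=10.0),
    }


@dataclass
class GeneratorConfig:
    """Everything the synthetic cohorts are drawn from.

    The defaults are the generator's emulation targets: normative rotation
    and translation moments, regression structure, and a cadaver-style
    sectioning arm of 12 specimens.  ``effort`` multiplies every per-level
    mean rotation (1.0 = full voluntary effort).
    """

    n_subjects: int = 341
    seed: int = 0
    effort: float = 1.0
    rotation: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NORMATIVE_ROTATION)
    )
    rdt: dict[str, tuple[float, float, float]] = field(default_factory=_derived_rdt)
    #: pooled anterior disc opening on rotation: (slope %EPW/deg, intercept, noise SD)
    rddw_anterior: tuple[float, float, float] = (1.0, 0.0, 1.35)
    #: pooled posterior disc opening on rotation
    rddw_posterior: tuple[float, float, float] = (0.75, 0.0, 1.25)
    #: per-segment mid-motion anterior/posterior disc-height baseline (mean, SD), %EPW
    disc_baseline_anterior: tuple[float, float] = (15.0, 1.5)
    disc_baseline_posterior: tuple[float, float] = (12.0, 1.5)
    segment_angle_flex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_SEGMENT_ANGLE_FLEX)
    )
    target_level: str = "C4-C5"
    n_per_arm: int = 12
    injury_stages: dict[str, InjuryEffect] = field(default_factory=_default_stages)

    def __post_init__(self) -> None:
        for seg in SEGMENTS:
            if self.rotation[seg][1] < 0 or self.rdt[seg][2] < 0:
                raise ValueError(f"{seg}: negative SD in config")
        for triple in (self.rddw_anterior, self.rddw_posterior):
            if triple[2] < 0:
                raise ValueError("negative RDDW noise SD")
        if self.effort < 0:
            raise ValueError("effort must be >= 0")
        segment_levels(self.target_level)


# ---------------------------------------------------------------------------
# metric-level cohorts
# ---------------------------------------------------------------------------


def _adjacent_max_abs_diff(values: np.ndarray) -> np.ndarray:
    """Row-wise max |level - neighbor| over the (n, 5) segment axis."""
    n, k = values.shape
    diffs = np.abs(np.diff(values, axis=1))
    out = np.empty_like(values)
    out[:, 0] = diffs[:, 0]
    out[:, -1] = diffs[:, -1]
    for j in range(1, k - 1):
        out[:, j] = np.maximum(diffs[:, j - 1], diffs[:, j])
    return out


def _draw_exam_arrays(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Draw (n, 5) arrays of every metric for n full-chain exams."""
    k = len(SEGMENTS)
    rot_mean = np.array([cfg.rotation[s][0] for s in SEGMENTS]) * cfg.effort
    rot_sd = np.array([cfg.rotation[s][1] for s in SEGMENTS])
    rot = rng.normal(rot_mean, rot_sd, size=(n, k))

    slope = np.array([cfg.rdt[s][0] for s in SEGMENTS])
    intercept = np.array([cfg.rdt[s][1] for s in SEGMENTS])
    noise = np.array([cfg.rdt[s][2] for s in SEGMENTS])
    trans = slope * rot + intercept + rng.normal(0.0, 1.0, size=(n, k)) * noise

    ma, ba, sa = cfg.rddw_anterior
    mp, bp, sp = cfg.rddw_posterior
    d_adh = ma * rot + ba + rng.normal(0.0, sa, size=(n, k))
    d_pdh = mp * rot + bp + rng.normal(0.0, sp, size=(n, k))

    base_a = rng.normal(*cfg.disc_baseline_anterior, size=(n, k))
    base_p = rng.normal(*cfg.disc_baseline_posterior, size=(n, k))

    ang_mean = np.array([cfg.segment_angle_flex[s][0] for s in SEGMENTS])
    ang_sd = np.array([cfg.segment_angle_flex[s][1] for s in SEGMENTS])
    ang_flex = rng.normal(ang_mean, ang_sd, size=(n, k))

    return {
        "rotation_deg": rot,
        "translation_pct_epw": trans,
        "d_adh": d_adh,
        "d_pdh": d_pdh,
        "base_a": base_a,
        "base_p": base_p,
        "segment_angle_flex": ang_flex,
    }


def _arrays_to_frame(
    arrays: Mapping[str, np.ndarray], exam_ids: list[str], condition: str | None = None
) -> pd.DataFrame:
    """Assemble drawn arrays into the long-form metric table."""
    rot = arrays["rotation_deg"]
    trans = arrays["translation_pct_epw"]
    d_adh, d_pdh = arrays["d_adh"], arrays["d_pdh"]
    base_a, base_p = arrays["base_a"], arrays["base_p"]
    ang_flex = arrays["segment_angle_flex"]
    n, k = rot.shape

    adh_flex = base_a - d_adh / 2.0
    adh_ext = base_a + d_adh / 2.0
    pdh_flex = base_p + d_pdh / 2.0
    pdh_ext = base_p - d_pdh / 2.0
    total = rot.sum(axis=1)
    epw = np.array([DEFAULT_EPW_MM[s] for s in SEGMENTS])

    frame = pd.DataFrame(
        {
            "exam_id": np.repeat(exam_ids, k),
            "segment": np.tile(SEGMENTS, n),
            "rotation_deg": rot.ravel(),
            "translation_pct_epw": trans.ravel(),
            "translation_mm": (trans * epw / 100.0).ravel(),
            "adh_flex": adh_flex.ravel(),
            "adh_ext": adh_ext.ravel(),
            "pdh_flex": pdh_flex.ravel(),
            "pdh_ext": pdh_ext.ravel(),
            "avg_dh": ((adh_flex + adh_ext + pdh_flex + pdh_ext) / 4.0).ravel(),
            "d_adh": d_adh.ravel(),
            "d_pdh": d_pdh.ravel(),
            "disc_angle_flex": (-0.45 * rot).ravel(),
            "disc_angle_ext": (0.55 * rot).ravel(),
            "segment_angle_flex": ang_flex.ravel(),
            "segment_angle_ext": (ang_flex + rot).ravel(),
            "rotation_diff_deg": _adjacent_max_abs_diff(rot).ravel(),
            "segment_angle_diff_deg": _adjacent_max_abs_diff(ang_flex).ravel(),
            "rotation_pct_c2c7": (100.0 * rot / total[:, None]).ravel(),
            "total_c2c7_rotation_deg": np.repeat(total, k),
            "grade": np.nan,
            "condition": condition,
        },
        columns=list(METRIC_COLUMNS),
    )
    return frame


def generate_metric_cohort(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw a metric-level cohort; one row per segment, full chains.

    The returned table is simultaneously the ground truth: every column is
    the exact drawn value, suitable for reference fitting, scoring and
    parameter-recovery tests.  Fixing the seed fixes the output.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    arrays = _draw_exam_arrays(cfg, rng, cfg.n_subjects)
    ids = [f"S{i:05d}" for i in range(cfg.n_subjects)]
    return _arrays_to_frame(arrays, ids)


# ---------------------------------------------------------------------------
# landmark posing
# ---------------------------------------------------------------------------


class PoseError(ValueError):
    """Raised when prescribed segment parameters admit no vertebral pose."""


#: Superior endplate width per vertebra (the %EPW normalizer of the segment
#: above it matches the level-average mm widths).
_VERTEBRA_WIDTH: dict[str, float] = {
    "C2": 15.0,
    "C3": 14.9,
    "C4": 14.9,
    "C5": 14.9,
    "C6": 15.8,
    "C7": 16.7,
}
#: Sagittal wedge of each vertebral body (inferior endplate tilted anteriorly
#: down by this many degrees relative to the superior endplate).
_VERTEBRA_WEDGE_DEG: dict[str, float] = {
    "C2": 2.5,
    "C3": 2.0,
    "C4": 1.5,
    "C5": 1.0,
    "C6": 1.5,
    "C7": 3.0,
}
_TAPER = 0.88  # inferior / superior endplate width ratio
_HEIGHT_RATIO = 0.55  # body height / superior width
_OFFSET_RATIO = 0.04  # posterior offset of the inferior endplate


def _body_corners(level: str) -> dict[str, np.ndarray]:
    """Corner coordinates of one vertebra in its body frame (anterior +X, up +Y).

    The superior endplate runs from PS=(0,0) to AS=(w,0); the inferior
    endplate is narrower, posteriorly offset and wedged by the level's body
    wedge angle.
    """
    w = _VERTEBRA_WIDTH[level]
    h = _HEIGHT_RATIO * w
    off = _OFFSET_RATIO * w
    gamma = math.radians(_VERTEBRA_WEDGE_DEG[level])
    d = np.array([math.cos(-gamma), math.sin(-gamma)])
    pi = np.array([off, -h])
    return {
        "PS": np.array([0.0, 0.0]),
        "AS": np.array([w, 0.0]),
        "PI": pi,
        "AI": pi + _TAPER * w * d,
    }


def _rot2(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def _circle_intersections(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Both intersection points of two circles (upper first), or None."""
    delta = c2 - c1
    d = float(np.hypot(*delta))
    if d < 1e-12 or d > r1 + r2 or d < abs(r1 - r2):
        return None
    a = (r1 * r1 - r2 * r2 + d * d) / (2.0 * d)
    h = math.sqrt(max(r1 * r1 - a * a, 0.0))
    mid = c1 + a * delta / d
    perp = np.array([-delta[1], delta[0]]) / d
    p, q = mid + h * perp, mid - h * perp
    return (p, q) if p[1] >= q[1] else (q, p)


def _segment_pose(
    segment: str,
    rotation_deg: float,
    translation_pct: float,
    adh_flex: float,
    pdh_flex: float,
    adh_ext: float,
    pdh_ext: float,
) -> tuple[tuple[np.ndarray, float], tuple[np.ndarray, float]]:
    """Solve the superior vertebra's pose in both phases.

    Works in the frame of the inferior vertebra's superior endplate (origin
    at its posterior corner, +X anterior along the endplate).  For a given
    inferior-endplate direction angle ``phi`` of the superior vertebra, the
    two corner disc heights pin its posterior-inferior corner to the upper
    intersection of two circles; the flexion/extension split of the disc
    angle is the one remaining degree of freedom and is solved so the
    registered anterior translation matches its target.  Returns
    ``((q_flex, phi_flex), (q_ext, phi_ext))`` with q the posterior-inferior
    corner position.  Raises :class:`PoseError` when the prescription is
    geometrically infeasible.
    """
    sup_level, inf_level = segment_levels(segment)
    if min(adh_flex, pdh_flex, adh_ext, pdh_ext) <= 0:
        raise PoseError(f"{segment}: disc heights must be positive in both phases")
    w = _VERTEBRA_WIDTH[inf_level]
    w_u = _TAPER * _VERTEBRA_WIDTH[sup_level]
    r = math.radians(rotation_deg)
    heights = {
        "flex": (adh_flex / 100.0 * w, pdh_flex / 100.0 * w),
        "ext": (adh_ext / 100.0 * w, pdh_ext / 100.0 * w),
    }
    a_s = np.array([w, 0.0])

    def q_of(phi: float, phase: str, branch: int) -> np.ndarray | None:
        da, dp = heights[phase]
        c2 = a_s - w_u * np.array([math.cos(phi), math.sin(phi)])
        pts = _circle_intersections(np.zeros(2), dp, c2, da)
        return None if pts is None else pts[branch]

    def q_grid(phis: np.ndarray, phase: str) -> np.ndarray:
        """Both branch intersections over an angle grid; NaN where infeasible."""
        da, dp = heights[phase]
        c2 = a_s[None, :] - w_u * np.stack([np.cos(phis), np.sin(phis)], axis=1)
        d = np.hypot(c2[:, 0], c2[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            a = (dp * dp - da * da + d * d) / (2.0 * d)
            h = np.sqrt(np.maximum(dp * dp - a * a, 0.0))
            mid = a[:, None] * c2 / d[:, None]
            perp = np.stack([-c2[:, 1], c2[:, 0]], axis=1) / d[:, None]
        out = np.stack([mid + h[:, None] * perp, mid - h[:, None] * perp], axis=1)
        bad = (d < 1e-12) | (d > dp + da) | (d < abs(dp - da))
        out[bad] = np.nan
        upper_first = out[:, 0, 1] >= out[:, 1, 1]
        out[~upper_first] = out[~upper_first][:, ::-1]
        return out

    # The flexion/extension angle split is the one free parameter; each
    # phase's posterior-inferior corner additionally has two circle branches.
    # Branch pairs are tried in a fixed order (upper/upper first), so the
    # solve is deterministic.
    grid = np.linspace(-0.9, 0.7, 321)
    gf = q_grid(grid, "flex")
    ge = q_grid(grid + r, "ext")
    for bf in (0, 1):
        for be in (0, 1):
            f = (gf[:, bf, 0] - ge[:, be, 0]) / w * 100.0 - translation_pct

            def trans_of(phi_f: float) -> float | None:
                qf = q_of(phi_f, "flex", bf)
                qe = q_of(phi_f + r, "ext", be)
                if qf is None or qe is None:
                    return None
                return (qf[0] - qe[0]) / w * 100.0

            ok = np.isfinite(f)
            sign_change = ok[:-1] & ok[1:] & (f[:-1] * f[1:] <= 0)
            idx = np.flatnonzero(sign_change)
            if idx.size == 0:
                continue
            i = int(idx[0])
            if f[i] == 0.0:
                phi_f = float(grid[i])
            else:
                phi_f = brentq(
                    lambda p: trans_of(p) - translation_pct,
                    float(grid[i]),
                    float(grid[i + 1]),
                    xtol=1e-13,
                    rtol=8.9e-16,
                )
            qf = q_of(phi_f, "flex", bf)
            qe = q_of(phi_f + r, "ext", be)
            if qf is None or qe is None:
                continue
            return (qf, phi_f), (qe, phi_f + r)
    raise PoseError(
        f"{segment}: no pose reaches translation {translation_pct:.1f} %EPW "
        f"with the prescribed rotation and disc heights"
    )


def _to_image(points: np.ndarray, facing: str) -> np.ndarray:
    """Anatomical (X anterior, Y up) to image coordinates under a facing."""
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    out[..., 0] = pts[..., 0] if facing == "right" else -pts[..., 0]
    out[..., 1] = -pts[..., 1]
    return out


def pose_landmarks(
    truth: Mapping[str, Mapping[str, float]],
    exam_id: str = "synthetic",
    facing: str = "right",
    rng: np.random.Generator | None = None,
    jitter: bool = True,
    condition: str | None = None,
    return_angles: bool = False,
) -> ExamLandmarks | tuple[ExamLandmarks, dict[str, dict[str, float]]]:
    """Build a landmark exam realizing prescribed per-segment parameters.

    ``truth`` maps segments to dicts with ``rotation_deg``,
    ``translation_pct_epw``, ``adh_flex``, ``adh_ext``, ``pdh_flex`` and
    ``pdh_ext`` (%EPW).  Vertebrae are stacked caudal to cranial; with
    ``jitter`` each radiograph then receives an arbitrary global similarity
    transform (magnification 0.85-1.25, rotation within +/-12 deg, offset),
    which every %EPW/angle metric is invariant to.  Raises
    :class:`PoseError` for geometrically infeasible prescriptions.

    The flexion/extension split of the disc angle is an outcome of the
    solve, not a prescription; with ``return_angles`` the achieved disc and
    segment angles per phase are returned alongside the exam.
    """
    rng = rng or np.random.default_rng()
    segs = [s for s in SEGMENTS if s in truth]
    if not segs:
        raise ValueError("truth must prescribe at least one segment")
    needed = {lv for s in segs for lv in segment_levels(s)}

    # global pose (angle, translation) per vertebra per phase, anatomical frame
    poses: dict[str, dict[str, tuple[float, np.ndarray]]] = {}
    for phase in ("flexion", "extension"):
        poses[phase] = {}
    # seed the caudal-most vertebra of each contiguous run at a neutral pose,
    # stacking runs with a vertical gap so they cannot overlap
    run_offset = 0.0
    placed: set[str] = set()
    achieved: dict[str, dict[str, float]] = {}
    for seg in reversed(segs):  # caudal to cranial
        sup, inf = segment_levels(seg)
        if inf not in placed:
            for phase in ("flexion", "extension"):
                poses[phase][inf] = (0.0, np.array([0.0, run_offset]))
            placed.add(inf)
            run_offset += 2.5 * _VERTEBRA_WIDTH[inf]
        t = truth[seg]
        (qf, phif), (qe, phie) = _segment_pose(
            seg,
            float(t["rotation_deg"]),
            float(t["translation_pct_epw"]),
            float(t["adh_flex"]),
            float(t["pdh_flex"]),
            float(t["adh_ext"]),
            float(t["pdh_ext"]),
        )
        gamma_inf = _VERTEBRA_WEDGE_DEG[inf]
        achieved[seg] = {
            "disc_angle_flex": math.degrees(phif),
            "disc_angle_ext": math.degrees(phie),
            "segment_angle_flex": math.degrees(phif) + gamma_inf,
            "segment_angle_ext": math.degrees(phie) + gamma_inf,
        }
        gamma_sup = math.radians(_VERTEBRA_WEDGE_DEG[sup])
        pi_body = _body_corners(sup)["PI"]
        for phase, (q, phi) in (("flexion", (qf, phif)), ("extension", (qe, phie))):
            alpha_inf, p_inf = poses[phase][inf]
            alpha_sup = alpha_inf + phi + gamma_sup
            ps_global = p_inf  # inferior vertebra's PS is its body-frame origin
            pi_global = ps_global + _rot2(alpha_inf) @ q
            p_sup = pi_global - _rot2(alpha_sup) @ pi_body
            poses[phase][sup] = (alpha_sup, p_sup)
        placed.add(sup)

    radiographs = {}
    for phase in ("flexion", "extension"):
        if jitter:
            theta = rng.uniform(-0.21, 0.21)
            scale = rng.uniform(0.85, 1.25)
            offset = rng.uniform(-30.0, 30.0, size=2)
        else:
            theta, scale, offset = 0.0, 1.0, np.zeros(2)
        g_rot = _rot2(theta)
        vertebrae = {}
        for level in sorted(needed, key=LEVELS.index):
            alpha, p = poses[phase][level]
            body = _body_corners(level)
            corners = {}
            for name in CORNERS:
                pt = scale * g_rot @ (_rot2(alpha) @ body[name] + p) + offset
                img = _to_image(pt, facing)
                corners[name] = Point2D(float(img[0]), float(img[1]))
            vertebrae[level] = VertebraLandmarks(level=level, corners=corners)
        radiographs[phase] = RadiographLandmarks(phase=phase, vertebrae=vertebrae, facing=facing)

    exam = ExamLandmarks(
        exam_id=exam_id,
        flexion=radiographs["flexion"],
        extension=radiographs["extension"],
        condition=condition,
    )
    return (exam, achieved) if return_angles else exam


def generate_landmark_cohort(
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
    n_exams: int | None = None,
    facing: str = "right",
    max_tries: int = 80,
) -> tuple[list[ExamLandmarks], pd.DataFrame]:
    """Draw metric truths and pose them as landmark exams.

    Returns ``(exams, truth)`` where ``truth`` is the metric table the
    measurement pipeline must recover.  Individual draws whose disc
    heights/rotation/translation admit no corner geometry are redrawn
    (bounded rejection sampling); the accepted draw is recorded as truth.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects if n_exams is None else n_exams
    exams: list[ExamLandmarks] = []
    truth_rows = []
    for i in range(n):
        exam_id = f"S{i:05d}"
        for attempt in range(max_tries):
            arrays = _draw_exam_arrays(cfg, rng, 1)
            frame = _arrays_to_frame(arrays, [exam_id])
            truth = {
                row["segment"]: row for row in frame.to_dict("records")
            }
            try:
                exam, angles = pose_landmarks(
                    truth, exam_id=exam_id, facing=facing, rng=rng, return_angles=True
                )
            except PoseError:
                continue
            # the angle split is an outcome of the pose, not a draw: record
            # the achieved angles (and their adjacent-level differences)
            for col in (
                "disc_angle_flex", "disc_angle_ext",
                "segment_angle_flex", "segment_angle_ext",
            ):
                frame[col] = [angles[s][col] for s in frame["segment"]]
            ang = dict(zip(frame["segment"], frame["segment_angle_flex"]))
            frame["segment_angle_diff_deg"] = [
                adjacent_level_difference(ang, s) for s in frame["segment"]
            ]
            exams.append(exam)
            truth_rows.append(frame)
            break
        else:
            raise PoseError(
                f"{exam_id}: no feasible pose in {max_tries} draws; "
                "the configured metric distributions are geometrically inconsistent"
            )
    return exams, pd.concat(truth_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# sectioning experiments
# ---------------------------------------------------------------------------


def generate_sectioning_experiment(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Paired intact/sectioned metric cohort for ROC validation.

    Each of ``n_per_arm`` specimens is 'imaged' intact and after every
    configured sectioning stage (same baseline noise draws, so arms are
    paired as in repeated imaging of one specimen).  A stage adds its
    configured shifts at ``target_level`` only: rotation increases,
    disc opening exceeds the rotation-predicted value, and translation
    stays at the intact value (the translational restraints are untouched).
    The ``condition`` column carries ``"intact"`` or the stage name.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if not cfg.injury_stages:
        raise ValueError("at least one sectioning stage is required")
    # specimen anatomy (baseline rotations, disc baselines, alignment) is
    # shared across arms; every imaging session redraws the residual noise
    base = _draw_exam_arrays(cfg, rng, cfg.n_per_arm)
    n, k = base["rotation_deg"].shape
    j = SEGMENTS.index(cfg.target_level)
    ma, ba, sa = cfg.rddw_anterior
    mp, bp, sp = cfg.rddw_posterior
    slope = np.array([cfg.rdt[s][0] for s in SEGMENTS])
    intercept = np.array([cfg.rdt[s][1] for s in SEGMENTS])
    noise = np.array([cfg.rdt[s][2] for s in SEGMENTS])
    rot0 = base["rotation_deg"].copy()

    frames = []
    arms: list[tuple[str, InjuryEffect]] = [("intact", InjuryEffect())] + list(
        cfg.injury_stages.items()
    )
    for stage, eff in arms:
        arrays = {key: val.copy() for key, val in base.items()}
        rot = rot0.copy()
        rot[:, j] += eff.rotation_deg
        arrays["rotation_deg"] = rot
        # Translation follows the RDT line at the *baseline* rotation: the
        # sectioned segment rotates further without recruiting the normal
        # rotation-translation coupling (translational restraints untouched).
        arrays["translation_pct_epw"] = (
            slope * rot0 + intercept + rng.normal(0.0, 1.0, size=(n, k)) * noise
        )
        arrays["translation_pct_epw"][:, j] += eff.translation_pct_epw
        # Disc opening departs from the value predicted at the achieved
        # rotation by the configured stage excess.
        arrays["d_adh"] = ma * rot + ba + rng.normal(0.0, sa, size=(n, k))
        arrays["d_adh"][:, j] += eff.d_adh
        arrays["d_pdh"] = mp * rot + bp + rng.normal(0.0, sp, size=(n, k))
        arrays["d_pdh"][:, j] += eff.d_pdh
        ids = [f"CAD{i:02d}-{stage}" for i in range(cfg.n_per_arm)]
        frames.append(_arrays_to_frame(arrays, ids, condition=stage))
    return pd.concat(frames, ignore_index=True)
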