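"""Containers and file formats for vertebral corner-landmark exams.

A flexion-extension exam consists of two lateral cervical radiographs.  On
each radiograph every analyzable vertebra from C2 to C7 is summarized by four
corner landmarks in the midsagittal plane:

* ``AS`` anterior-superior, ``AI`` anterior-inferior,
* ``PS`` posterior-superior, ``PI`` posterior-inferior.

Coordinates follow the image convention (x grows rightward, y grows
downward) and may be in pixels of unknown magnification; every metric
derived downstream is either an angle or normalized to endplate width, so
absolute scale never matters.  The ``facing`` flag records which screen
direction is anatomically anterior (the direction the patient faces).

Vertebrae may be missing from either radiograph (obscured by shoulders,
limited field of view, ...).  Missingness is handled per level: a motion
segment is computable iff both of its vertebrae are present in both phases.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Cervical vertebral levels handled by the pipeline, cranial to caudal.
LEVELS: tuple[str, ...] = ("C2", "C3", "C4", "C5", "C6", "C7")

#: Motion segments (adjacent level pairs), cranial to caudal.
SEGMENTS: tuple[str, ...] = ("C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7")

#: Canonical corner-key order used in files and arrays.
CORNERS: tuple[str, ...] = ("AS", "AI", "PS", "PI")

PHASES: tuple[str, ...] = ("flexion", "extension")
FACINGS: tuple[str, ...] = ("left", "right")


class SchemaError(ValueError):
    """Raised when a landmark file violates the exam schema."""


def segment_levels(segment: str) -> tuple[str, str]:
    """Return (superior, inferior) vertebra labels of a segment like 'C4-C5'."""
    try:
        sup, inf = segment.split("-")
    except ValueError as exc:
        raise ValueError(f"malformed segment label {segment!r}") from exc
    if sup not in LEVELS or inf not in LEVELS or LEVELS.index(inf) - LEVELS.index(sup) != 1:
        raise ValueError(f"{segment!r} is not an adjacent cervical level pair")
    return sup, inf


@dataclass(frozen=True)
class Point2D:
    """A finite image-plane coordinate."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class VertebraLandmarks:
    """Four labeled corner landmarks of one vertebra on one radiograph."""

    level: str
    corners: Mapping[str, Point2D]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown vertebral level {self.level!r}")
        missing = [c for c in CORNERS if c not in self.corners]
        if missing:
            raise ValueError(f"{self.level}: missing corners {missing}")
        pts = [self.corners[c] for c in CORNERS]
        for i in range(4):
            for j in range(i + 1, 4):
                if pts[i].x == pts[j].x and pts[i].y == pts[j].y:
                    raise ValueError(
                        f"{self.level}: corners {CORNERS[i]} and {CORNERS[j]} coincide"
                    )
        for a, b, side in (("AS", "PS", "superior"), ("AI", "PI", "inferior")):
            if math.dist(
                (self.corners[a].x, self.corners[a].y),
                (self.corners[b].x, self.corners[b].y),
            ) <= 0:
                raise ValueError(f"{self.level}: zero-width {side} endplate")

    def corner_array(self, order: tuple[str, ...] = CORNERS) -> np.ndarray:
        """Corners stacked as a (4, 2) float array in the given order."""
        return np.array([[self.corners[c].x, self.corners[c].y] for c in order])


@dataclass
class RadiographLandmarks:
    """All analyzable vertebrae on one radiograph (one phase)."""

    phase: str
    vertebrae: dict[str, VertebraLandmarks] = field(default_factory=dict)
    facing: str = "right"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.facing not in FACINGS:
            raise ValueError(f"facing must be one of {FACINGS}, got {self.facing!r}")
        for level, vert in self.vertebrae.items():
            if vert.level != level:
                raise ValueError(f"vertebra keyed {level} carries level {vert.level}")

    def __contains__(self, level: str) -> bool:
        return level in self.vertebrae

    def __getitem__(self, level: str) -> VertebraLandmarks:
        return self.vertebrae[level]


@dataclass
class ExamLandmarks:
    """One flexion-extension exam: paired radiographs plus optional annotations.

    ``degeneration_grades`` maps segments (e.g. ``"C5-C6"``) to ordinal
    radiographic degeneration grades (Kellgren-Lawrence, 0-4); it is consumed
    only when building normative references.  ``condition`` is a free-form
    label (e.g. ``"intact"`` or a ligament-sectioning stage) used by ROC
    analyses.
    """

    exam_id: str
    flexion: RadiographLandmarks
    extension: RadiographLandmarks
    degeneration_grades: dict[str, int] = field(default_factory=dict)
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.flexion.phase != "flexion":
            raise ValueError(f"{self.exam_id}: flexion radiograph has phase {self.flexion.phase!r}")
        if self.extension.phase != "extension":
            raise ValueError(
                f"{self.exam_id}: extension radiograph has phase {self.extension.phase!r}"
            )
        if not self.flexion.vertebrae or not self.extension.vertebrae:
            raise ValueError(f"{self.exam_id}: both phases must contain at least one vertebra")
        if self.flexion.facing != self.extension.facing:
            raise ValueError(f"{self.exam_id}: facing differs between phases")
        for seg in self.degeneration_grades:
            segment_levels(seg)

    @property
    def facing(self) -> str:
        return self.flexion.facing

    def available_segments(self) -> list[str]:
        """Segments whose two vertebrae are present in both phases."""
        out = []
        for seg in SEGMENTS:
            sup, inf = segment_levels(seg)
            if all(lv in rad for rad in (self.flexion, self.extension) for lv in (sup, inf)):
                out.append(seg)
        return out


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------


def _phase_from_raw(exam_id: str, phase: str, raw: Mapping, facing: str) -> RadiographLandmarks:
    vertebrae: dict[str, VertebraLandmarks] = {}
    seen: set[str] = set()
    for level in raw:
        if level in seen:
            raise SchemaError(f"{exam_id}/{phase}: duplicate level {level}")
        seen.add(level)
    for level, corners_raw in raw.items():
        if level not in LEVELS:
            raise SchemaError(f"{exam_id}/{phase}: unknown level {level!r}")
        if not isinstance(corners_raw, Mapping) or any(c not in corners_raw for c in CORNERS):
            raise SchemaError(f"{exam_id}/{phase}/{level}: all four corners {CORNERS} required")
        try:
            corners = {
                c: Point2D(float(corners_raw[c][0]), float(corners_raw[c][1])) for c in CORNERS
            }
            vertebrae[level] = VertebraLandmarks(level=level, corners=corners)
        except (TypeError, ValueError, IndexError) as exc:
            # Geometrically degenerate or unparseable vertebra: drop it, keep the exam.
            logger.warning("%s/%s/%s: dropping vertebra (%s)", exam_id, phase, level, exc)
    return RadiographLandmarks(phase=phase, vertebrae=vertebrae, facing=facing)


def read_exam(path: str | Path) -> ExamLandmarks:
    """Read one exam from a JSON landmark file.

    Schema::

        {"exam_id": str, "facing": "left"|"right",
         "flexion":   {"C2": {"AS": [x, y], "AI": ..., "PS": ..., "PI": ...}, ...},
         "extension": {...},
         "degeneration": {"C2-C3": int, ...},    # optional
         "condition": str | null}                 # optional

    Vertebrae that fail geometric validation are dropped with a logged
    warning; structural schema violations raise :class:`SchemaError`.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    exam_id = raw.get("exam_id")
    if not isinstance(exam_id, str) or not exam_id:
        raise SchemaError(f"{path}: missing exam_id")
    facing = raw.get("facing", "right")
    if facing not in FACINGS:
        raise SchemaError(f"{exam_id}: facing must be one of {FACINGS}")
    phases = {}
    for phase in PHASES:
        if phase not in raw or not isinstance(raw[phase], Mapping):
            raise SchemaError(f"{exam_id}: missing phase {phase!r}")
        phases[phase] = _phase_from_raw(exam_id, phase, raw[phase], facing)
    grades_raw = raw.get("degeneration") or {}
    try:
        grades = {seg: int(g) for seg, g in grades_raw.items()}
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{exam_id}: malformed degeneration grades ({exc})") from exc
    condition = raw.get("condition")
    if condition is not None and not isinstance(condition, str):
        raise SchemaError(f"{exam_id}: condition must be a string or null")
    try:
        return ExamLandmarks(
            exam_id=exam_id,
            flexion=phases["flexion"],
            extension=phases["extension"],
            degeneration_grades=grades,
            condition=condition,
        )
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def exam_to_dict(exam: ExamLandmarks) -> dict:
    """Canonical plain-dict form of an exam (sorted levels, fixed corner order)."""
    def phase_dict(rad: RadiographLandmarks) -> dict:
        return {
            level: {c: [rad[level].corners[c].x, rad[level].corners[c].y] for c in CORNERS}
            for level in sorted(rad.vertebrae, key=LEVELS.index)
        }

    return {
        "exam_id": exam.exam_id,
        "facing": exam.facing,
        "flexion": phase_dict(exam.flexion),
        "extension": phase_dict(exam.extension),
        "degeneration": {
            seg: exam.degeneration_grades[seg]
            for seg in sorted(exam.degeneration_grades, key=SEGMENTS.index)
        },
        "condition": exam.condition,
    }


def write_exam(exam: ExamLandmarks, path: str | Path) -> None:
    """Write an exam as canonical JSON (byte-identical for identical exams)."""
    path = Path(path)
    payload = json.dumps(exam_to_dict(exam), indent=1, sort_keys=False)
    path.write_text(payload + "\n")


def read_exam_dir(directory: str | Path, pattern: str = "*.json") -> Iterator[ExamLandmarks]:
    """Yield exams from every matching JSON file in a directory (sorted)."""
    for p in sorted(Path(directory).glob(pattern)):
        yield read_exam(p)


# ---------------------------------------------------------------------------
# CSV (long form)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("exam_id", "phase", "level", "corner", "x", "y")


def read_exams_csv(
    path: str | Path,
    annotations: str | Path | None = None,
    facing: str = "right",
) -> list[ExamLandmarks]:
    """Read exams from a long-form CSV with columns exam_id,phase,level,corner,x,y.

    ``annotations`` optionally points to a second CSV with columns
    ``exam_id,segment,grade`` and/or ``exam_id,condition`` supplying
    degeneration grades and condition labels.
    """
    rows: dict[str, dict[str, dict[str, dict[str, list[float]]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(f not in reader.fieldnames for f in _CSV_FIELDS):
            raise SchemaError(f"{path}: expected columns {_CSV_FIELDS}")
        for rec in reader:
            exam = rows.setdefault(rec["exam_id"], {p: {} for p in PHASES})
            phase = rec["phase"]
            if phase not in PHASES:
                raise SchemaError(f"{rec['exam_id']}: unknown phase {phase!r}")
            corners = exam[phase].setdefault(rec["level"], {})
            if rec["corner"] in corners:
                raise SchemaError(
                    f"{rec['exam_id']}/{phase}/{rec['level']}: duplicate corner {rec['corner']}"
                )
            corners[rec["corner"]] = [float(rec["x"]), float(rec["y"])]

    grades: dict[str, dict[str, int]] = {}
    conditions: dict[str, str] = {}
    if annotations is not None:
        with open(annotations, newline="") as fh:
            for rec in csv.DictReader(fh):
                if rec.get("segment") and rec.get("grade") not in (None, ""):
                    grades.setdefault(rec["exam_id"], {})[rec["segment"]] = int(rec["grade"])
                if rec.get("condition"):
                    conditions[rec["exam_id"]] = rec["condition"]

    exams = []
    for exam_id, phases_raw in rows.items():
        exams.append(
            ExamLandmarks(
                exam_id=exam_id,
                flexion=_phase_from_raw(exam_id, "flexion", phases_raw["flexion"], facing),
                extension=_phase_from_raw(exam_id, "extension", phases_raw["extension"], facing),
                degeneration_grades=grades.get(exam_id, {}),
                condition=conditions.get(exam_id),
            )
        )
    return exams


def write_exams_csv(exams: list[ExamLandmarks], path: str | Path) -> None:
    """Write exams in the long-form CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for exam in exams:
            for phase in PHASES:
                rad = getattr(exam, phase)
                for level in sorted(rad.vertebrae, key=LEVELS.index):
                    for corner in CORNERS:
                        pt = rad[level].corners[corner]
                        writer.writerow([exam.exam_id, phase, level, corner, pt.x, pt.y])
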