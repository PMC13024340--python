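import numpy as np
import pytest

import ivmetrics as ivm
from ivmetrics.landmarks import Point2D, RadiographLandmarks, VertebraLandmarks


def rect_vertebra(
    level: str,
    x0: float = 0.0,
    y0: float = 0.0,
    width: float = 15.0,
    height: float = 9.0,
    facing: str = "right",
    angle_deg: float = 0.0,
) -> VertebraLandmarks:
    """An axis-aligned (optionally rotated) rectangular vertebra in image coords.

    ``(x0, y0)`` is the posterior-superior corner; with ``facing='right'``
    anterior is +x and superior is -y (image y grows downward).
    """
    sx = 1.0 if facing == "right" else -1.0
    corners = {
        "PS": (0.0, 0.0),
        "AS": (sx * width, 0.0),
        "PI": (0.0, height),
        "AI": (sx * width, height),
    }
    th = np.radians(angle_deg)
    # positive angle = anterior edge up (anatomically), i.e. image y decreases
    rot = np.array([[np.cos(th), sx * np.sin(th)], [-sx * np.sin(th), np.cos(th)]])
    out = {}
    for name, (dx, dy) in corners.items():
        vx, vy = rot @ np.array([dx, dy])
        out[name] = Point2D(x0 + vx, y0 + vy)
    return VertebraLandmarks(level=level, corners=out)


def two_vertebra_exam(sup, inf, sup_ext=None, inf_ext=None, facing="right", exam_id="t"):
    """Assemble a one-segment exam; extension defaults to the flexion pose."""
    sup_ext = sup_ext or sup
    inf_ext = inf_ext or inf
    return ivm.ExamLandmarks(
        exam_id=exam_id,
        flexion=RadiographLandmarks(
            phase="flexion", vertebrae={sup.level: sup, inf.level: inf}, facing=facing
        ),
        extension=RadiographLandmarks(
            phase="extension", vertebrae={sup_ext.level: sup_ext, inf_ext.level: inf_ext},
            facing=facing,
        ),
    )


@pytest.fixture(scope="session")
def metric_cohort():
    """A moderate asymptomatic metric cohort (2000 segments, fixed seed)."""
    return ivm.generate_metric_cohort(ivm.GeneratorConfig(n_subjects=400, seed=11))


@pytest.fixture(scope="session")
def reference(metric_cohort):
    """Normative reference fitted on the session cohort."""
    return ivm.fit_reference(metric_cohort)


@pytest.fixture(scope="session")
def landmark_cohort_small():
    """Twenty posed landmark exams with their ground-truth metric table."""
    return ivm.generate_landmark_cohort(ivm.GeneratorConfig(n_subjects=20, seed=5))
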