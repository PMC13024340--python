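"""Geometric oracles: endplates, angles, translation, disc heights, invariances."""

import math

import numpy as np
import pytest

import ivmetrics as ivm
from ivmetrics.geometry import _to_anatomical, adjacent_level_difference
from ivmetrics.landmarks import Point2D, RadiographLandmarks, VertebraLandmarks

from conftest import rect_vertebra, two_vertebra_exam


class TestEndplate:
    def test_axis_aligned_rectangle(self):
        v = rect_vertebra("C4", width=15.0)
        line = ivm.endplate(v, "superior", "right")
        assert line.width == pytest.approx(15.0)
        assert line.direction == pytest.approx([1.0, 0.0])

    def test_facing_flip_negates_direction(self):
        v = rect_vertebra("C4", width=15.0)
        right = ivm.endplate(v, "superior", "right")
        left = ivm.endplate(v, "superior", "left")
        assert left.direction == pytest.approx(-right.direction)

    @pytest.mark.parametrize("angle", [10.0, -25.0, 40.0])
    def test_rotated_rectangle_direction(self, angle):
        v = rect_vertebra("C4", angle_deg=angle)
        line = ivm.endplate(v, "inferior", "right")
        assert line.angle_deg == pytest.approx(angle, abs=1e-9)


class TestDiscAngle:
    def test_parallel_endplates_zero(self):
        sup = rect_vertebra("C4", y0=-12.0)
        inf = rect_vertebra("C5")
        assert ivm.disc_angle(sup, inf, "right") == pytest.approx(0.0, abs=1e-12)

    def test_constructed_ten_degree_wedge(self):
        # inferior vertebra superior endplate (0,0)->(15,0); superior
        # vertebra inferior endplate (0,-5)->(15, -5-15*tan10); anterior +x
        t = 15.0 * math.tan(math.radians(10.0))
        sup = VertebraLandmarks(
            level="C4",
            corners={
                "PI": Point2D(0, -5), "AI": Point2D(15, -5 - t),
                "PS": Point2D(0, -14), "AS": Point2D(15, -14 - t),
            },
        )
        inf = rect_vertebra("C5")
        assert ivm.disc_angle(sup, inf, "right") == pytest.approx(10.0, abs=1e-9)

    def test_pose_intrinsic_same_for_either_phase_label(self):
        sup = rect_vertebra("C4", y0=-12.0, angle_deg=7.0)
        inf = rect_vertebra("C5")
        a = ivm.disc_angle(sup, inf, "right")
        exam = two_vertebra_exam(sup, inf)
        m = ivm.exam_metrics(exam)
        assert m.segments["C4-C5"].disc_angle_flex == pytest.approx(a)
        assert m.segments["C4-C5"].disc_angle_ext == pytest.approx(a)

    def test_mirror_symmetry_under_facing_flip(self):
        sup = rect_vertebra("C4", y0=-12.0, angle_deg=9.0)
        inf = rect_vertebra("C5", angle_deg=-3.0)
        m_sup, m_inf = (
            VertebraLandmarks(
                level=lv.level,
                corners={c: Point2D(-p.x, p.y) for c, p in lv.corners.items()},
            )
            for lv in (sup, inf)
        )
        assert ivm.disc_angle(sup, inf, "right") == pytest.approx(
            ivm.disc_angle(m_sup, m_inf, "left"), abs=1e-9
        )


class TestRotation:
    def test_extension_minus_flexion(self):
        assert ivm.intervertebral_rotation(-5.0, 12.0) == pytest.approx(17.0)

    def test_identical_poses_zero(self):
        assert ivm.intervertebral_rotation(4.2, 4.2) == 0.0

    def test_antisymmetry_under_phase_swap(self):
        assert ivm.intervertebral_rotation(12.0, -5.0) == pytest.approx(-17.0)


class TestSegmentAngle:
    def test_parallel_inferior_endplates_zero(self):
        sup = rect_vertebra("C4", y0=-12.0)
        inf = rect_vertebra("C5")
        assert ivm.segment_angle(sup, inf, "right") == pytest.approx(0.0, abs=1e-12)

    def test_seven_degree_tilt(self):
        sup = rect_vertebra("C4", y0=-12.0, angle_deg=7.0)
        inf = rect_vertebra("C5")
        assert ivm.segment_angle(sup, inf, "right") == pytest.approx(7.0, abs=1e-9)

    def test_independent_of_superior_endplates(self):
        sup = rect_vertebra("C4", y0=-12.0, angle_deg=7.0)
        inf = rect_vertebra("C5")
        base = ivm.segment_angle(sup, inf, "right")
        # shove the superior endplates somewhere else entirely
        moved = VertebraLandmarks(
            level="C4",
            corners={
                "AS": Point2D(sup.corners["AS"].x + 4, sup.corners["AS"].y - 11),
                "PS": Point2D(sup.corners["PS"].x - 2, sup.corners["PS"].y - 3),
                "AI": sup.corners["AI"],
                "PI": sup.corners["PI"],
            },
        )
        assert ivm.segment_angle(moved, inf, "right") == pytest.approx(base, abs=1e-12)


class TestTranslation:
    def test_pure_anterior_slide_is_twenty_percent(self):
        inf = rect_vertebra("C5", width=15.0)
        sup_ext = rect_vertebra("C4", x0=0.0, y0=-12.0)
        sup_flex = rect_vertebra("C4", x0=3.0, y0=-12.0)  # 3 units anterior
        assert ivm.intervertebral_translation(
            sup_flex, sup_ext, inf, inf, "right"
        ) == pytest.approx(20.0, abs=1e-9)

    def test_rotation_about_pi_corner_is_zero(self):
        inf = rect_vertebra("C5", width=15.0)
        sup_ext = rect_vertebra("C4", x0=0.0, y0=-3.0)
        # rotate the superior vertebra 8 deg about its own PI corner
        pivot = sup_ext.corners["PI"].as_array()
        th = math.radians(8.0)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        sup_flex = VertebraLandmarks(
            level="C4",
            corners={
                c: Point2D(*(rot @ (p.as_array() - pivot) + pivot))
                for c, p in sup_ext.corners.items()
            },
        )
        assert ivm.intervertebral_translation(
            sup_flex, sup_ext, inf, inf, "right"
        ) == pytest.approx(0.0, abs=1e-9)

    def test_collinear_landmarks_degenerate(self):
        inf = rect_vertebra("C5")
        flat = VertebraLandmarks(
            level="C5",
            corners={
                "AS": Point2D(15, 0), "PS": Point2D(0, 0),
                "AI": Point2D(10, 0), "PI": Point2D(5, 0),
            },
        )
        sup = rect_vertebra("C4", y0=-12.0)
        with pytest.raises(ValueError, match="degenerate"):
            ivm.intervertebral_translation(sup, sup, flat, flat, "right")


class TestDiscHeights:
    def test_touching_corners_zero(self):
        inf = rect_vertebra("C5")
        sup = rect_vertebra("C4", y0=-9.0)  # inferior corners meet superior corners
        assert ivm.disc_heights(sup, inf, "right") == pytest.approx((0.0, 0.0))

    def test_parallel_gap_twenty_percent(self):
        inf = rect_vertebra("C5", width=15.0)
        sup = rect_vertebra("C4", y0=-12.0)  # 3-unit gap below a 9-tall body
        assert ivm.disc_heights(sup, inf, "right") == pytest.approx((20.0, 20.0))


class TestSimilarityInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_metrics_invariant_under_global_similarity(self, seed):
        rng = np.random.default_rng(seed)
        exams, _ = ivm.generate_landmark_cohort(
            ivm.GeneratorConfig(n_subjects=1, seed=seed), n_exams=1
        )
        exam = exams[0]
        base = ivm.exam_metrics(exam)

        th = rng.uniform(-0.5, 0.5)
        scale = rng.uniform(0.7, 1.3)
        offset = rng.uniform(-50, 50, size=2)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

        def transform(rad):
            return RadiographLandmarks(
                phase=rad.phase,
                vertebrae={
                    lv: VertebraLandmarks(
                        level=lv,
                        corners={
                            c: Point2D(*(scale * rot @ p.as_array() + offset))
                            for c, p in v.corners.items()
                        },
                    )
                    for lv, v in rad.vertebrae.items()
                },
                facing=rad.facing,
            )

        moved = ivm.ExamLandmarks(
            exam_id=exam.exam_id,
            flexion=transform(exam.flexion),
            extension=transform(exam.extension),
        )
        after = ivm.exam_metrics(moved)
        for seg, m0 in base.segments.items():
            m1 = after.segments[seg]
            for attr in (
                "rotation_deg", "translation_pct_epw", "adh_flex", "adh_ext",
                "pdh_flex", "pdh_ext", "disc_angle_flex", "disc_angle_ext",
                "segment_angle_flex", "segment_angle_ext",
            ):
                assert getattr(m1, attr) == pytest.approx(getattr(m0, attr), abs=1e-9)
        assert after.total_c2c7_rotation_deg == pytest.approx(
            base.total_c2c7_rotation_deg, abs=1e-9
        )


class TestAdjacentDifference:
    def test_interior_segment_brute_force(self):
        vals = {"C3-C4": 14.0, "C4-C5": 18.0, "C5-C6": 21.0}
        assert adjacent_level_difference(vals, "C4-C5") == pytest.approx(4.0)

    def test_equal_values_zero(self):
        vals = {s: 7.0 for s in ivm.SEGMENTS}
        assert all(adjacent_level_difference(vals, s) == 0.0 for s in ivm.SEGMENTS)

    def test_single_segment_undefined(self):
        assert adjacent_level_difference({"C4-C5": 18.0}, "C4-C5") is None

    def test_edge_segments_have_one_neighbor(self):
        vals = {"C2-C3": 5.0, "C3-C4": 9.0, "C6-C7": 3.0}
        assert adjacent_level_difference(vals, "C2-C3") == pytest.approx(4.0)
        assert adjacent_level_difference(vals, "C6-C7") is None


class TestExamMetrics:
    def test_round_trip_recovers_ground_truth(self, landmark_cohort_small):
        exams, truth = landmark_cohort_small
        measured = ivm.metrics_frame([ivm.exam_metrics(e) for e in exams])
        m = measured.set_index(["exam_id", "segment"]).sort_index()
        t = truth.set_index(["exam_id", "segment"]).sort_index()
        for col in (
            "rotation_deg", "translation_pct_epw",
            "adh_flex", "adh_ext", "pdh_flex", "pdh_ext",
        ):
            assert (m[col] - t[col]).abs().max() < 1e-6

    def test_rotation_share_sums_to_hundred(self, landmark_cohort_small):
        exams, _ = landmark_cohort_small
        m = ivm.exam_metrics(exams[0])
        shares = [m.segments[s].rotation_pct_c2c7 for s in ivm.SEGMENTS]
        assert sum(shares) == pytest.approx(100.0, abs=1e-9)

    def test_translation_mm_uses_level_width(self):
        inf = rect_vertebra("C3", width=15.0)
        sup_ext = rect_vertebra("C2", x0=0.0, y0=-12.0)
        sup_flex = rect_vertebra("C2", x0=15.0 * 0.121, y0=-12.0)
        exam = two_vertebra_exam(sup_flex, inf, sup_ext=sup_ext, inf_ext=inf)
        m = ivm.exam_metrics(exam).segments["C2-C3"]
        assert m.translation_pct_epw == pytest.approx(12.1, abs=1e-9)
        # 12.1 %EPW at the 14.9 mm level-average width -> 1.80 mm
        assert m.translation_mm == pytest.approx(1.80, abs=0.005)

    def test_total_requires_c2_and_c7(self, landmark_cohort_small):
        exams, _ = landmark_cohort_small
        exam = exams[0]
        clipped = ivm.ExamLandmarks(
            exam_id=exam.exam_id,
            flexion=exam.flexion,
            extension=RadiographLandmarks(
                phase="extension",
                vertebrae={lv: v for lv, v in exam.extension.vertebrae.items() if lv != "C7"},
                facing=exam.facing,
            ),
        )
        m = ivm.exam_metrics(clipped)
        assert m.total_c2c7_rotation_deg is None
        assert "C6-C7" not in m.segments
        assert all(s.rotation_pct_c2c7 is None for s in m.segments.values())
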