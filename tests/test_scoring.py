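"""Instability indices, abnormality flags, effort filter and prevalence tables."""

import numpy as np
import pandas as pd
import pytest

import ivmetrics as ivm
from ivmetrics.reference import LinearModel
from ivmetrics.scoring import CRITERIA, classify_segment, effort_filter, prevalence


def make_row(segment="C4-C5", rotation=15.0, **overrides):
    row = {
        "exam_id": "e",
        "segment": segment,
        "rotation_deg": rotation,
        "translation_pct_epw": 14.0,
        "adh_flex": 8.0,
        "adh_ext": 22.0,
        "pdh_flex": 17.0,
        "pdh_ext": 6.0,
        "avg_dh": 13.0,
        "rotation_diff_deg": 3.0,
        "segment_angle_diff_deg": 3.0,
        "translation_mm": 2.0,
    }
    row.update(overrides)
    return row


class TestIndices:
    def test_ti_observed_minus_predicted_over_sef(self, reference):
        model = reference.rdt["C4-C5"]
        rot = 10.0
        predicted = float(model.predict(rot))
        s = float(model.sef(rot))
        assert ivm.ti_index(predicted, rot, reference, "C4-C5") == pytest.approx(0.0)
        assert ivm.ti_index(predicted + 2 * s, rot, reference, "C4-C5") == pytest.approx(2.0)
        assert ivm.ti_index(16.0, rot, reference, "C4-C5") == pytest.approx(
            (16.0 - predicted) / s
        )

    def test_avi_on_the_line_and_at_cadaver_threshold(self, reference):
        model = reference.rddw_anterior
        rot = 18.0
        predicted = float(model.predict(rot))
        s = float(model.sef(rot))
        assert ivm.avi_index(predicted + 5.0, 5.0, rot, reference) == pytest.approx(0.0)
        # opening 3.2 SEF beyond predicted: the cadaver-optimal threshold magnitude
        assert ivm.avi_index(predicted + 3.2 * s + 5.0, 5.0, rot, reference) == pytest.approx(3.2)

    def test_avi_negative_when_opening_below_predicted(self, reference):
        model = reference.rddw_anterior
        rot = 18.0
        predicted = float(model.predict(rot))
        assert ivm.avi_index(predicted - 1.0 + 5.0, 5.0, rot, reference) < 0

    def test_pvi_mirrors_avi_with_posterior_model(self, reference):
        model = reference.rddw_posterior
        rot = 12.0
        predicted = float(model.predict(rot))
        s = float(model.sef(rot))
        assert ivm.pvi_index(predicted + 9.0, 9.0, rot, reference) == pytest.approx(0.0)
        assert ivm.pvi_index(predicted + 1.5 * s + 9.0, 9.0, rot, reference) == pytest.approx(1.5)

    def test_degenerate_sef_rejected(self, reference):
        bad = ivm.NormativeReference(
            level_stats=reference.level_stats,
            rdt={
                s: LinearModel(
                    slope=m.slope, intercept=m.intercept, n=m.n, x_mean=m.x_mean,
                    sxx=m.sxx, residual_sd=0.0, r_squared=m.r_squared,
                )
                for s, m in reference.rdt.items()
            },
            rddw_anterior=reference.rddw_anterior,
            rddw_posterior=reference.rddw_posterior,
            avg_dh_ref=reference.avg_dh_ref,
            c2c7_rotation=None,
        )
        with pytest.raises(ValueError, match="SEF"):
            ivm.ti_index(10.0, 12.0, bad, "C4-C5")

    def test_unknown_segment_rejected(self, reference):
        with pytest.raises(ValueError, match="RDT"):
            ivm.ti_index(10.0, 12.0, reference, "C7-T1")


class TestClassifySegment:
    def test_low_rotation_excluded_without_flags(self, reference):
        scores = classify_segment(make_row(rotation=4.2), reference)
        assert scores.excluded
        assert "5.0 deg" in scores.exclusion_reason
        assert scores.flags == {}
        assert scores.ti is None

    def test_boundary_translation_not_abnormal(self, reference):
        scores = classify_segment(make_row(translation_pct_epw=20.0), reference)
        assert scores.flags["flag_translation"] is False
        scores = classify_segment(make_row(translation_pct_epw=20.0001), reference)
        assert scores.flags["flag_translation"] is True

    def test_retrolisthesis_counts_via_absolute_value(self, reference):
        scores = classify_segment(make_row(translation_pct_epw=-21.0), reference)
        assert scores.flags["flag_translation"] is True

    def test_rotation_difference_threshold(self, reference):
        assert classify_segment(make_row(rotation_diff_deg=11.5), reference).flags[
            "flag_rotation_diff"
        ]
        assert not classify_segment(make_row(rotation_diff_deg=11.0), reference).flags[
            "flag_rotation_diff"
        ]

    def test_missing_input_leaves_flag_absent(self, reference):
        scores = classify_segment(make_row(rotation_diff_deg=None), reference)
        assert "flag_rotation_diff" not in scores.flags

    def test_mm_criterion_disabled_by_default(self, reference):
        scores = classify_segment(make_row(translation_mm=9.0), reference)
        assert "flag_translation_mm" not in scores.flags

    def test_flags_monotone_in_underlying_value(self, reference):
        for col, flag in [
            ("translation_pct_epw", "flag_translation"),
            ("rotation_diff_deg", "flag_rotation_diff"),
            ("segment_angle_diff_deg", "flag_angle_diff"),
        ]:
            flagged_at = None
            for v in np.linspace(0.0, 40.0, 41):
                scores = classify_segment(make_row(**{col: v}), reference)
                if scores.flags.get(flag):
                    flagged_at = v
                elif flagged_at is not None:
                    pytest.fail(f"{flag} cleared at {v} after set at {flagged_at}")


class TestEffortFilter:
    @pytest.fixture()
    def records(self):
        return pd.DataFrame(
            {
                "exam_id": ["a", "b", "c"],
                "segment": ["C4-C5"] * 3,
                "total_c2c7_rotation_deg": [59.0, 61.0, np.nan],
            }
        )

    def test_threshold_is_strict(self, records):
        kept = effort_filter(records, 60.0)
        assert list(kept["exam_id"]) == ["b"]

    def test_missing_total_dropped_while_active(self, records):
        assert "c" not in effort_filter(records, 0.0)["exam_id"].values

    def test_inactive_is_identity(self, records):
        pd.testing.assert_frame_equal(effort_filter(records, 60.0, active=False), records)

    def test_never_decreases_mean_total(self, metric_cohort, reference):
        scored = ivm.score_records(metric_cohort, reference)
        before = scored["total_c2c7_rotation_deg"].mean()
        after = effort_filter(scored, 60.0)["total_c2c7_rotation_deg"].mean()
        assert after >= before

    def test_empty_result_warns(self, records, caplog):
        with caplog.at_level("WARNING"):
            out = effort_filter(records, 1000.0)
        assert out.empty
        assert any("effort filter" in r.message for r in caplog.records)


class TestPrevalence:
    def test_simple_fraction(self, reference):
        rows = [make_row() for _ in range(10)]
        rows[0]["translation_pct_epw"] = 25.0
        scored = ivm.score_records(pd.DataFrame(rows), reference)
        table = prevalence(scored).set_index("segment")
        assert table.loc["C4-C5", "n"] == 10
        assert table.loc["C4-C5", "Trans > 20% EPW"] == pytest.approx(10.0)

    def test_brute_force_recount_on_synthetic_cohort(self, metric_cohort, reference):
        scored = ivm.score_records(metric_cohort.head(250), reference)
        table = prevalence(scored).set_index("segment")
        analyzable = scored.loc[~scored["excluded"]]
        for seg in ivm.SEGMENTS:
            seg_rows = analyzable.loc[analyzable["segment"] == seg]
            assert table.loc[seg, "n"] == len(seg_rows)
            for name, col in CRITERIA.items():
                flags = [f for f in seg_rows[col].tolist() if f is not pd.NA]
                expected = 100.0 * sum(bool(f) for f in flags) / len(flags)
                assert table.loc[seg, name] == pytest.approx(expected)

    def test_invariant_to_ordering_and_duplication(self, metric_cohort, reference):
        scored = ivm.score_records(metric_cohort.head(100), reference)
        base = prevalence(scored)
        shuffled = prevalence(scored.sample(frac=1.0, random_state=0))
        doubled = prevalence(pd.concat([scored, scored], ignore_index=True))
        pd.testing.assert_frame_equal(base, shuffled)
        for name in CRITERIA:
            assert doubled[name].tolist() == pytest.approx(base[name].tolist(), nan_ok=True)

    def test_all_excluded_gives_empty_rows(self, reference):
        rows = [make_row(rotation=2.0, segment=s) for s in ivm.SEGMENTS]
        scored = ivm.score_records(pd.DataFrame(rows), reference)
        table = prevalence(scored)
        assert (table["n"] == 0).all()


class TestIndexCalibration:
    def test_indices_standardized_on_independent_cohort(self, reference):
        cohort = ivm.generate_metric_cohort(ivm.GeneratorConfig(n_subjects=600, seed=77))
        scored = ivm.score_records(cohort, reference)
        ok = scored.loc[~scored["excluded"]]
        for idx in ("ti", "avi", "pvi"):
            vals = ok[idx].dropna()
            assert abs(vals.mean()) < 0.1
            assert 0.9 < vals.std() < 1.1
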