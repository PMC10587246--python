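"""Fractional frequency/area metrics: conservation, summaries, exclusions."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from oracles import mc_field_fractions

from retquant.geometry import InvalidGeometryError, polygon_area_mm2
from retquant.lesions import EyeRecord, LesionAnnotation
from retquant.quantify import (
    apply_exclusions,
    quantify_eye,
    summarize_by_severity,
    totals_frame,
)


def _eye(lesions, eye_id="e1"):
    return EyeRecord(
        eye_id=eye_id, laterality="OD", disc_center=(-15.5, 1.5), lesions=lesions
    )


class TestQuantifyEye:
    def test_lesion_free_eye_all_zero(self, od_layout):
        m = quantify_eye(_eye([]), od_layout)
        assert m.table["frequency"].sum() == 0.0
        assert m.table["area_mm2"].sum() == 0.0

    def test_single_contained_microaneurysm(self, od_layout):
        ma = Point(0, 0).buffer(0.194, quad_segs=64)  # ~0.01 mm^2 in field 2
        m = quantify_eye(_eye([LesionAnnotation("MA", ma)]), od_layout)
        assert m.total("MA", "frequency") == pytest.approx(1.0, abs=1e-9)
        assert m.cell(2, "MA", "frequency") == pytest.approx(1.0, abs=1e-9)
        assert m.total("MA", "area_mm2") == pytest.approx(0.01, rel=0.02)

    def test_straddling_hemorrhage_matches_oracle(self, od_layout):
        h = Point(7.5, 0).buffer(5, quad_segs=32)
        m = quantify_eye(_eye([LesionAnnotation("H", h)]), od_layout)
        mc, mc_out = mc_field_fractions(h, od_layout, n=100_000, seed=5)
        assert m.cell(2, "H") == pytest.approx(mc[1], abs=0.01)
        assert m.cell(3, "H") == pytest.approx(mc[2], abs=0.01)
        assert m.total("H") + float(m.outside.loc["H", "frequency"]) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_conservation_over_synthetic_eyes(self, small_cohort, od_layout):
        """Per-type field totals plus outside mass recover the raw counts."""
        from retquant.geometry import build_field_layout

        _, eyes, _ = small_cohort
        for eye in eyes[::3]:
            layout = build_field_layout(eye.disc_center, eye.fovea_center, eye.laterality)
            m = quantify_eye(eye, layout)
            for t, n in m.raw_counts.items():
                mass = m.total(t, "frequency") + float(m.outside.loc[t, "frequency"])
                assert mass == pytest.approx(n, abs=1e-6)

    def test_adding_a_lesion_never_decreases_totals(self, od_layout):
        base = [LesionAnnotation("H", Point(3, 3).buffer(1))]
        extra = base + [LesionAnnotation("H", Point(-4, 2).buffer(1.5))]
        m0 = quantify_eye(_eye(base), od_layout)
        m1 = quantify_eye(_eye(extra), od_layout)
        assert m1.total("H", "frequency") >= m0.total("H", "frequency")
        assert m1.total("H", "area_mm2") >= m0.total("H", "area_mm2")

    def test_excluded_eye_rejected(self, od_layout):
        eye = _eye([])
        eye.excluded_reason = "rvo"
        with pytest.raises(ValueError):
            quantify_eye(eye, od_layout)

    def test_invalid_polygon_dropped_with_warning(self, od_layout):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        eye = _eye([LesionAnnotation("H", bowtie), LesionAnnotation("H", Point(1, 1).buffer(1))])
        with pytest.warns(UserWarning):
            m = quantify_eye(eye, od_layout)
        assert m.dropped_lesions == 1
        assert m.raw_counts["H"] == 1

    def test_invalid_polygon_raises_with_identifiers_when_strict(self, od_layout):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        eye = _eye([LesionAnnotation("H", bowtie)], eye_id="bad_eye")
        with pytest.raises(InvalidGeometryError, match="bad_eye"):
            quantify_eye(eye, od_layout, on_invalid="raise")


class _Grade:
    def __init__(self, eye_id, icdr, aa="20"):
        self.eye_id = eye_id
        self.icdr = icdr
        self.aa_level = aa


class TestSummaries:
    def _metrics(self, od_layout, eye_id, n_ma):
        lesions = [
            LesionAnnotation("MA", Point(0.5 * k, 1).buffer(0.3)) for k in range(n_ma)
        ]
        return quantify_eye(_eye(lesions, eye_id), od_layout)

    def test_singleton_groups_mean_equals_value_sd_zero(self, od_layout):
        metrics = [self._metrics(od_layout, f"e{i}", i + 1) for i in range(3)]
        grades = [_Grade(f"e{i}", i + 1) for i in range(3)]
        s = summarize_by_severity(metrics, grades, scale="icdr")
        ma_freq = s[(s.lesion_type == "MA") & (s.metric == "frequency")]
        assert (ma_freq["sd"] == 0.0).all()
        assert (ma_freq["n"] == 1).all()
        assert sorted(ma_freq["mean"]) == pytest.approx([1.0, 2.0, 3.0], abs=1e-9)

    def test_duplication_invariance_of_mean_and_median(self, od_layout):
        metrics = [self._metrics(od_layout, f"e{i}", 2 + i) for i in range(4)]
        grades = [_Grade(f"e{i}", 2) for i in range(4)]
        doubled = metrics + [
            self._metrics(od_layout, f"d{i}", 2 + i) for i in range(4)
        ]
        grades2 = grades + [_Grade(f"d{i}", 2) for i in range(4)]
        s1 = summarize_by_severity(metrics, grades, scale="icdr")
        s2 = summarize_by_severity(doubled, grades2, scale="icdr")
        for metric in ("frequency", "area_mm2"):
            a = s1[(s1.lesion_type == "MA") & (s1.metric == metric)]
            b = s2[(s2.lesion_type == "MA") & (s2.metric == metric)]
            assert a["mean"].iloc[0] == pytest.approx(b["mean"].iloc[0])
            assert a["median"].iloc[0] == pytest.approx(b["median"].iloc[0])

    def test_fibrous_proliferation_rows_omitted(self, od_layout):
        lesions = [LesionAnnotation("PFD", Point(-15, 1).buffer(1))]
        metrics = [quantify_eye(_eye(lesions, "e0"), od_layout)]
        s = summarize_by_severity(metrics, [_Grade("e0", 4)], scale="icdr")
        assert not set(s["lesion_type"]) & {"PFD", "PFE"}
        s_all = summarize_by_severity(
            metrics, [_Grade("e0", 4)], scale="icdr", include_nonreportable=True
        )
        assert "PFD" in set(s_all["lesion_type"])

    def test_missing_grade_rejected(self, od_layout):
        metrics = [self._metrics(od_layout, "e0", 1)]
        with pytest.raises(ValueError):
            summarize_by_severity(metrics, [], scale="icdr")


class TestApplyExclusions:
    def _cohort(self, n):
        return [_eye([], eye_id=f"e{i}") for i in range(n)]

    def test_no_flags_identity(self):
        cohort = self._cohort(5)
        included, acc = apply_exclusions(cohort)
        assert len(included) == 5
        assert acc["retained"] == 5 and acc["assessed"] == 5

    def test_all_flagged_empties_cohort(self):
        cohort = self._cohort(3)
        for eye, reason in zip(cohort, ("poor_quality", "rvo", "interfering")):
            eye.excluded_reason = reason
        included, acc = apply_exclusions(cohort)
        assert included == []
        assert (
            acc["excluded_poor_quality"] + acc["excluded_rvo"] + acc["excluded_interfering"]
            == acc["assessed"]
        )

    def test_accounting_conserves_cohort_size(self, rng):
        cohort = self._cohort(20)
        for eye in rng.choice(cohort, size=6, replace=False):
            eye.excluded_reason = "poor_quality"
        included, acc = apply_exclusions(cohort)
        assert acc["assessed"] == acc["retained"] + 6

    def test_ungradable_grades_counted_as_interfering(self):
        cohort = self._cohort(2)

        class G:
            def __init__(self, eye_id, gradable):
                self.eye_id = eye_id
                self.gradable = gradable

        included, acc = apply_exclusions(cohort, [G("e0", False), G("e1", True)])
        assert acc["excluded_interfering"] == 1 and acc["retained"] == 1
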