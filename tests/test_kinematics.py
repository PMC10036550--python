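"""Landmark geometry: angles, phase timing, shoe-width distances, suggestions."""

from __future__ import annotations

import math
import numpy as np
import pytest
from hypothesis import given, strategies as st

import wgskit as w
from wgskit.errors import GeometryError, MissingLandmarkError, TimelineError

FPS30 = dict(fps=30.0, shoe_width_px=30.0)


def sagittal_cal(**kw):
    return w.CalibrationInfo(
        progression_direction=np.array([1.0, 0.0]), view="sagittal", **{**FPS30, **kw}
    )


def frontal_cal(**kw):
    return w.CalibrationInfo(
        progression_direction=np.array([0.0, -1.0]), view="frontal", **{**FPS30, **kw}
    )


def leg_frame(phi_deg: float, psi_deg: float, side="affected", origin=(0.0, 0.0)):
    """Thigh at ``phi`` and shank at ``psi`` degrees from vertical-down."""
    o = np.asarray(origin, float)
    phi, psi = math.radians(phi_deg), math.radians(psi_deg)
    thigh = np.array([math.sin(phi), math.cos(phi)])
    shank = np.array([math.sin(psi), math.cos(psi)])
    condyle = o + 100 * thigh
    return w.LandmarkFrame(
        0,
        {
            ("trochanter", side): o,
            ("lateral_femoral_condyle", side): condyle,
            ("fibula_head", side): condyle + 8 * shank,
            ("lateral_malleolus", side): condyle + 100 * shank,
        },
    )


class TestAnglePrimitives:
    @pytest.mark.parametrize(
        "a1, a2, b1, b2, expected",
        [
            ((0, 0), (2, 0), (5, 5), (9, 5), 0.0),       # parallel / collinear
            ((0, 0), (0, 1), (0, 0), (1, 0), 90.0),       # perpendicular
            ((0, 0), (1, 0), (0, 0), (1, 1), 45.0),       # unit diagonal
        ],
    )
    def test_line_angles(self, a1, a2, b1, b2, expected):
        assert w.angle_between_lines(a1, a2, b1, b2) == pytest.approx(expected)

    def test_undirected_folds_into_quarter_turn(self):
        # opposite directions: 180 as vectors, 0 as lines
        assert w.angle_between_lines((0, 0), (1, 0), (0, 0), (-1, 0)) == pytest.approx(0.0)
        assert w.angle_between_lines(
            (0, 0), (1, 0), (0, 0), (-1, 0), directed=True
        ) == pytest.approx(180.0)

    def test_coincident_endpoints_raise(self):
        with pytest.raises(GeometryError):
            w.angle_between_lines((1, 1), (1, 1), (0, 0), (1, 0))


class TestKneeFlexion:
    def test_straight_leg_is_zero(self):
        assert w.knee_flexion(leg_frame(0, 0), "affected") == pytest.approx(0.0)

    def test_right_angle_bend(self):
        # thigh vertical down, shank horizontal (bent backwards)
        assert w.knee_flexion(leg_frame(0, -90), "affected") == pytest.approx(90.0)

    def test_missing_landmark_named(self):
        f = leg_frame(0, -30)
        del f.points[("fibula_head", "affected")]
        with pytest.raises(MissingLandmarkError, match="fibula_head"):
            w.knee_flexion(f, "affected")

    @given(
        phi=st.floats(-60, 60),
        knee=st.floats(0, 120),
        rot=st.floats(0, 2 * math.pi),
        scale=st.floats(0.1, 10),
        tx=st.floats(-1e3, 1e3),
        ty=st.floats(-1e3, 1e3),
    )
    def test_invariant_under_similarity_transform(self, phi, knee, rot, scale, tx, ty):
        f = leg_frame(phi, phi - knee)
        base = w.knee_flexion(f, "affected")
        c, s = math.cos(rot), math.sin(rot)
        R = np.array([[c, -s], [s, c]]) * scale
        t = np.array([tx, ty])
        g = w.LandmarkFrame(0, {k: R @ v + t for k, v in f.points.items()})
        assert abs(w.knee_flexion(g, "affected") - base) < 1e-9
        assert base == pytest.approx(knee, abs=1e-6)


class TestCompareKneeFlexion:
    def trial(self, **kw):
        return w.simulate_gait(w.GaitProfile(seed=7, **kw))

    def test_symmetric_gait_is_equal(self):
        ann = self.trial()
        res = w.compare_knee_flexion(ann.series, ann.timeline)
        assert res.category == "equal" and res.code == "1"
        assert res.affected_peak_deg == pytest.approx(res.unaffected_peak_deg, abs=1e-9)

    def test_sixty_percent_peak_is_less(self):
        ann = self.trial(flexion_deficit_fraction=0.4)
        res = w.compare_knee_flexion(ann.series, ann.timeline)
        assert res.category == "less" and res.code == "2a"

    def test_two_degree_peak_with_five_degree_floor_is_minimal(self):
        ann = self.trial(flexion_deficit_fraction=1 - 2.0 / 60.0)  # peak 2 degrees
        res = w.compare_knee_flexion(ann.series, ann.timeline, minimal_floor_deg=5.0)
        assert res.category == "minimal" and res.code == "3a"

    def test_extended_knee_is_none(self):
        ann = self.trial(flexion_deficit_fraction=1.0, knee_stance_deg=0.0)
        res = w.compare_knee_flexion(ann.series, ann.timeline)
        assert res.category == "none" and res.code == "4"

    def test_empty_window_errors(self):
        ann = self.trial()
        empty = w.GaitEventTimeline({"affected": {}, "unaffected": {}})
        with pytest.raises(TimelineError):
            w.compare_knee_flexion(ann.series, empty)


class TestStanceTime:
    def test_thirty_frames_at_30fps(self):
        tl = w.GaitEventTimeline({"affected": {"heel_strike": (0,), "toe_off": (30,)}})
        assert w.stance_time(tl, sagittal_cal(), "affected") == pytest.approx(1.0)

    def test_missing_interval_errors(self):
        tl = w.GaitEventTimeline({"affected": {"heel_strike": (10,), "toe_off": (5,)}})
        with pytest.raises(TimelineError):
            w.stance_time(tl, sagittal_cal(), "affected")


class TestStanceWidth:
    def frame(self, sep_px: float):
        return w.LandmarkFrame(
            0,
            {
                ("heel", "affected"): np.array([100.0 + sep_px, 500.0]),
                ("heel", "unaffected"): np.array([100.0, 500.0]),
            },
        )

    @pytest.mark.parametrize("sep_sw", [0.8, 2.0, 2.5])
    def test_separation_in_shoe_widths(self, sep_sw):
        cal = frontal_cal()
        got = w.stance_width(self.frame(sep_sw * cal.shoe_width_px), cal)
        assert got == pytest.approx(sep_sw)

    def test_scales_inversely_with_calibration(self):
        f = self.frame(60.0)
        assert w.stance_width(f, frontal_cal(shoe_width_px=60.0)) == pytest.approx(
            w.stance_width(f, frontal_cal(shoe_width_px=30.0)) / 2
        )

    def test_requires_frontal_view(self):
        with pytest.raises(GeometryError, match="frontal"):
            w.stance_width(self.frame(30.0), sagittal_cal())

    def test_invariant_to_progression_sign(self):
        f = self.frame(45.0)
        flipped = w.CalibrationInfo(
            progression_direction=np.array([0.0, 1.0]), view="frontal", **FPS30
        )
        assert w.stance_width(f, frontal_cal()) == pytest.approx(
            w.stance_width(f, flipped)
        )


class TestCircumductionAndRotation:
    @pytest.mark.parametrize("planted", [0.0, 0.7, 1.4])
    def test_planted_arc_recovered(self, planted):
        ann = w.simulate_gait(
            w.GaitProfile(seed=9, view="frontal", circumduction_sw=planted)
        )
        got = w.circumduction(ann.series, ann.timeline, ann.calibration)
        assert got == pytest.approx(planted, abs=0.05)

    def test_no_swing_frames_errors(self):
        ann = w.simulate_gait(w.GaitProfile(seed=9, view="frontal"))
        tl = w.GaitEventTimeline({"affected": {}, "unaffected": {}})
        with pytest.raises(TimelineError):
            w.circumduction(ann.series, tl, ann.calibration)

    def test_foot_axis_angles(self):
        cal = frontal_cal()
        heel = np.array([50.0, 400.0])
        for deg in (0.0, 30.0, 60.0):
            r = math.radians(deg)
            f = w.LandmarkFrame(
                0,
                {
                    ("heel", "affected"): heel,
                    ("toe", "affected"): heel + 90 * np.array([math.sin(r), -math.cos(r)]),
                },
            )
            assert w.external_rotation(f, cal) == pytest.approx(deg, abs=1e-9)

    def test_degenerate_foot_errors(self):
        f = w.LandmarkFrame(
            0, {("heel", "affected"): np.zeros(2), ("toe", "affected"): np.zeros(2)}
        )
        with pytest.raises(GeometryError):
            w.external_rotation(f, frontal_cal())


class TestSuggestions:
    def test_symmetric_gait_all_comparative_items_code_1(self, symmetric_trial):
        m = w.measure_trial(
            sagittal=symmetric_trial["sagittal"], frontal=symmetric_trial["frontal"]
        )
        by_item = {s.item_id: s for s in w.suggest_ratings(m)}
        assert by_item[1].status == "manual"
        assert by_item[13].status == "manual"  # transverse plane: not measurable here
        for i in set(range(2, 15)) - {13}:
            assert by_item[i].code == "1", f"item {i}: {by_item[i]}"
            assert by_item[i].evidence  # numeric evidence attached

    def test_rotation_sixty_suggests_item8_code3(self):
        m = w.MeasurementSet(
            external_rotation_affected_deg=60.0, external_rotation_unaffected_deg=7.0
        )
        by_item = {s.item_id: s for s in w.suggest_ratings(m)}
        assert by_item[8].code == "3"

    def test_empty_measurements_all_manual(self):
        for s in w.suggest_ratings(w.MeasurementSet()):
            assert s.status == "manual" and s.code is None

    def test_pelvic_rotation_supplied_directly(self):
        by_item = {
            s.item_id: s
            for s in w.suggest_ratings(w.MeasurementSet(pelvic_rotation_deg=-8.0))
        }
        assert by_item[13].code == "3"

    def test_removing_landmark_degrades_only_dependent_items(self, symmetric_trial):
        sag = symmetric_trial["sagittal"]
        stripped = w.LandmarkSeries(
            [
                w.LandmarkFrame(
                    f.frame_index,
                    {k: v for k, v in f.points.items() if k[0] != "fibula_head"},
                )
                for f in sag.series.frames
            ]
        )
        ann = w.Annotation(stripped, sag.timeline, sag.calibration)
        m = w.measure_trial(sagittal=ann, frontal=symmetric_trial["frontal"])
        by_item = {s.item_id: s for s in w.suggest_ratings(m)}
        assert by_item[11].status == "manual"  # knee flexion needs the shank line
        for i in (2, 3, 5, 6, 8, 9, 10, 12, 14):
            assert by_item[i].status == "suggested", f"item {i}"

    def test_shoe_width_boundaries_inclusive(self):
        cfg = w.DEFAULT_CONFIG
        exactly_one = {s.item_id: s for s in w.suggest_ratings(w.MeasurementSet(stance_width_sw=1.0), cfg)}
        exactly_two = {s.item_id: s for s in w.suggest_ratings(w.MeasurementSet(stance_width_sw=2.0), cfg)}
        assert exactly_one[5].code == "1"  # "up to one shoe width" is inclusive
        assert exactly_two[5].code == "2"


def test_measure_trial_rejects_swapped_views(symmetric_trial):
    with pytest.raises(w.SchemaError):
        w.measure_trial(sagittal=symmetric_trial["frontal"])
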