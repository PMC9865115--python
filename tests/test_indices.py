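"""Gait indices: constructed-geometry oracles, cutoff flags, simulator behavior."""

from __future__ import annotations

import numpy as np
import pytest

from gaitplane import (
    CutoffConfig,
    GaitIndexSet,
    IndexValue,
    compute_indices,
    fit_ellipse,
    flags_from_indices,
    foot_angle,
    heel_vertical_amplitude,
    hip_angle_range,
    knee_angle_range,
    major_axis_endpoints,
    outward_shifts,
    preset,
    project_recording,
    simulate_recording,
    y_width,
)
from gaitplane.body_frame import ProjectedTracks, SegmentLengths

from conftest import mirror_recording, symmetric_cloud


def _tracks(sagittal=None, axial=None) -> ProjectedTracks:
    points = {"sagittal": sagittal or {}, "coronal": {}, "axial": axial or {}}
    frames = {kp: np.arange(len(pts))
              for plane in points.values() for kp, pts in plane.items()}
    return ProjectedTracks(points=points, frames=frames,
                           lengths=SegmentLengths(1.0, 1.0),
                           n_frames=50, n_frames_used=50)


def _cloud_with_vertical_major_axis(cx, cy, half_extent, n=4):
    """Four points whose fitted ellipse has major-axis endpoints (cx, cy±half_extent)."""
    from gaitplane.ellipse import ellipse_radius
    r = ellipse_radius(0.75, n)
    s = half_extent / r * np.sqrt(3.0 / 2.0)  # var_y = 2 s^2 / 3 over 4 points
    eps = s / 100.0
    return np.array([[cx, cy + s], [cx, cy - s], [cx + eps, cy], [cx - eps, cy]])


def _angle_oracle(apex, p1, p2):
    """Independent vector-angle routine: difference of atan2 headings."""
    a1 = np.arctan2(p1[1] - apex[1], p1[0] - apex[0])
    a2 = np.arctan2(p2[1] - apex[1], p2[0] - apex[0])
    d = abs(a1 - a2) % (2 * np.pi)
    return np.degrees(min(d, 2 * np.pi - d))


class TestJointAngleRanges:
    def test_symmetric_endpoints_give_right_angle(self):
        sag = {}
        for s in ("r", "l"):
            sag[f"hip_{s}"] = symmetric_cloud(0.0, 0.0, spread=1e-4)
            sag[f"knee_{s}"] = _cloud_with_vertical_major_axis(1.0, 0.0, 1.0)
        iv = hip_angle_range(_tracks(sagittal=sag))
        assert iv.value == pytest.approx(90.0, abs=1e-6)
        assert iv.right == pytest.approx(iv.left, abs=1e-9)

    def test_coincident_centers_give_straight_angle(self):
        sag = {}
        for s in ("r", "l"):
            sag[f"hip_{s}"] = symmetric_cloud(0.5, -0.5, spread=1e-4)
            sag[f"knee_{s}"] = _cloud_with_vertical_major_axis(0.5, -0.5, 0.8)
        iv = hip_angle_range(_tracks(sagittal=sag))
        assert iv.value == pytest.approx(180.0, abs=1e-6)

    def test_collinear_distal_endpoints_give_zero_knee_angle(self):
        sag = {}
        for s in ("r", "l"):
            sag[f"knee_{s}"] = symmetric_cloud(0.0, 0.0, spread=1e-4)
            # heel major axis along +x, centered at (2, 0), semi-axis < 2:
            pts = _cloud_with_vertical_major_axis(0.0, 2.0, 0.5)
            sag[f"heel_{s}"] = pts[:, ::-1]  # swap axes -> horizontal major axis
        iv = knee_angle_range(_tracks(sagittal=sag))
        assert iv.value == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_configuration_matches_arccos_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sag = {}
        for s in ("r", "l"):
            sag[f"hip_{s}"] = rng.normal(size=(30, 2))
            sag[f"knee_{s}"] = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 2)) + 2
        tracks = _tracks(sagittal=sag)
        iv = hip_angle_range(tracks)
        for side, got in (("r", iv.right), ("l", iv.left)):
            apex = fit_ellipse(sag[f"hip_{side}"], 0.75).center
            p1, p2 = major_axis_endpoints(fit_ellipse(sag[f"knee_{side}"], 0.75))
            assert got == pytest.approx(_angle_oracle(apex, p1, p2), abs=1e-9)


class TestHeelAmplitude:
    def test_flat_heel_track_has_zero_raw_amplitude(self):
        sag = {f"heel_{s}": np.column_stack([np.linspace(0, 1, 20), np.full(20, -0.8)])
               for s in ("r", "l")}
        iv = heel_vertical_amplitude(_tracks(sagittal=sag), mode="raw")
        assert iv.value == pytest.approx(0.0, abs=1e-12)

    def test_ellipse_mode_equals_ellipse_y_width(self):
        rng = np.random.default_rng(5)
        sag = {f"heel_{s}": rng.normal(size=(40, 2)) for s in ("r", "l")}
        tracks = _tracks(sagittal=sag)
        iv = heel_vertical_amplitude(tracks, mode="ellipse")
        expected = np.mean([y_width(fit_ellipse(sag[f"heel_{s}"], 0.75))
                            for s in ("r", "l")])
        assert iv.value == pytest.approx(expected, rel=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            heel_vertical_amplitude(_tracks(), mode="median")


class TestFootAngle:
    def _axial(self, vec_r, vec_l):
        ax = {
            "heel_r": symmetric_cloud(0.1, 0.0, 1e-4),
            "toe_r": symmetric_cloud(0.1 + vec_r[0], vec_r[1], 1e-4),
            "heel_l": symmetric_cloud(-0.1, 0.0, 1e-4),
            "toe_l": symmetric_cloud(-0.1 + vec_l[0], vec_l[1], 1e-4),
        }
        return _tracks(axial=ax)

    def test_parallel_feet_give_zero(self):
        iv = foot_angle(self._axial((0, 1), (0, 1)))
        assert iv.value == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_heel_toe_vectors(self):
        iv = foot_angle(self._axial((1, 1), (-1, 1)))
        assert iv.value == pytest.approx(90.0, abs=1e-6)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(9)
        vr, vl = rng.normal(size=2), rng.normal(size=2)
        iv = foot_angle(self._axial(vr, vl))
        assert iv.value == pytest.approx(_angle_oracle((0, 0), vr, vl), abs=1e-4)


class TestOutwardShifts:
    def _axial_stance(self, hip=0.10, heel=0.05, toe=0.12):
        ax = {}
        for s, sgn in (("r", 1.0), ("l", -1.0)):
            ax[f"hip_{s}"] = symmetric_cloud(sgn * hip, 0.0, 1e-4)
            ax[f"heel_{s}"] = symmetric_cloud(sgn * heel, 0.0, 1e-4)
            ax[f"toe_{s}"] = symmetric_cloud(sgn * toe, 0.0, 1e-4)
        return _tracks(axial=ax)

    def test_constructed_stance_shifts(self):
        heel, toe, leg = outward_shifts(self._axial_stance())
        assert heel.value == pytest.approx(-0.05, abs=1e-9)   # heels inside hips
        assert toe.value == pytest.approx(0.07, abs=1e-9)     # toes outside heels
        assert leg.value == pytest.approx(0.02, abs=1e-9)

    def test_toe_shift_independent_of_stance_width(self):
        _, toe_narrow, _ = outward_shifts(self._axial_stance(heel=0.05, toe=0.10))
        _, toe_wide, _ = outward_shifts(self._axial_stance(hip=0.2, heel=0.15, toe=0.20))
        assert toe_narrow.value == pytest.approx(toe_wide.value, abs=1e-9)

    def test_heels_below_hips_give_zero_heel_shift(self):
        heel, _, _ = outward_shifts(self._axial_stance(hip=0.08, heel=0.08))
        assert heel.value == pytest.approx(0.0, abs=1e-9)

    def test_leg_shift_identity_exact(self, normal_tracks):
        heel, toe, leg = outward_shifts(normal_tracks)
        assert leg.value == heel.value + toe.value  # identity by construction
        assert leg.right == heel.right + toe.right
        assert leg.left == heel.left + toe.left


class TestFlags:
    def _index_set(self, **over):
        base = dict(hip_angle_range=60.0, knee_angle_range=80.0,
                    heel_vertical_amplitude=0.2, foot_angle=20.0,
                    heel_outward_shift=-0.12, toe_outward_shift=0.05,
                    leg_outward_shift=-0.07)
        base.update(over)
        return GaitIndexSet(**{k: IndexValue(v) for k, v in base.items()})

    def test_strict_below_cutoff_flags(self):
        flags = flags_from_indices(self._index_set(hip_angle_range=29.9))
        assert flags["hip_angle_range"] is True
        flags = flags_from_indices(self._index_set(hip_angle_range=30.0))
        assert flags["hip_angle_range"] is False  # boundary = no flag

    def test_strict_above_cutoff_flags(self):
        flags = flags_from_indices(self._index_set(leg_outward_shift=0.100001))
        assert flags["leg_outward_shift"] is True
        flags = flags_from_indices(self._index_set(leg_outward_shift=0.1))
        assert flags["leg_outward_shift"] is False

    def test_undefined_index_flag_absent_not_false(self):
        flags = flags_from_indices(self._index_set(heel_outward_shift=float("nan")))
        assert "heel_outward_shift" not in flags

    def test_custom_cutoffs_respected(self):
        cfg = CutoffConfig(hip_angle=70.0)
        flags = flags_from_indices(self._index_set(), cfg)
        assert flags["hip_angle_range"] is True


class TestSimulatedGaits:
    def test_normal_gait_raises_no_flags(self, normal_tracks):
        report = compute_indices(normal_tracks)
        assert not any(report.flags.values())

    def test_shuffling_has_smaller_heel_amplitude_than_normal(self, preset_tracks):
        amp = {k: compute_indices(v).indices.heel_vertical_amplitude.value
               for k, v in preset_tracks.items()}
        assert amp["shuffling"] < amp["normal"]
        assert amp["shuffling"] < 0.1 < amp["normal"]

    def test_short_stepped_has_smaller_knee_angle_than_normal(self, preset_tracks):
        knee = {k: compute_indices(v).indices.knee_angle_range.value
                for k, v in preset_tracks.items()}
        assert knee["short_stepped"] < knee["normal"]
        assert knee["short_stepped"] < 45.0 < knee["normal"]

    def test_wide_based_has_larger_leg_shift_than_normal(self, preset_tracks):
        leg = {k: compute_indices(v).indices.leg_outward_shift.value
               for k, v in preset_tracks.items()}
        assert leg["wide_based"] > leg["normal"]
        assert leg["wide_based"] > 0.1 > leg["normal"]

    @pytest.mark.parametrize("field,levels,index_name", [
        ("step_height", (0.015, 0.05, 0.15), "heel_vertical_amplitude"),
        ("step_length", (0.24, 0.42, 0.60), "knee_angle_range"),
        ("stance_width", (0.07, 0.14, 0.21), "leg_outward_shift"),
    ])
    def test_monotone_response_to_kinematic_parameter(self, field, levels, index_name):
        values = []
        for level in levels:
            params = preset("normal", seed=3, **{field: level})
            tracks = project_recording(simulate_recording(params))
            values.append(getattr(compute_indices(tracks).indices, index_name).value)
        assert values[0] < values[1] < values[2]

    def test_mirrored_recording_swaps_side_values(self, normal_recording):
        tracks = project_recording(normal_recording)
        mirrored = project_recording(mirror_recording(normal_recording))
        for fn in (hip_angle_range, knee_angle_range):
            orig, mirr = fn(tracks), fn(mirrored)
            assert orig.right == pytest.approx(mirr.left, abs=1e-9)
            assert orig.left == pytest.approx(mirr.right, abs=1e-9)
        h0, t0, _ = outward_shifts(tracks)
        h1, t1, _ = outward_shifts(mirrored)
        assert h0.right == pytest.approx(h1.left, abs=1e-9)
        assert t0.left == pytest.approx(t1.right, abs=1e-9)
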