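"""Amplitude-time parameters, normative verdicts, 21-feature vector."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulsecontour import features as feat
from pulsecontour import synthwave as syn
from pulsecontour.errors import MissingFiducialError
from pulsecontour.fiducials import FiducialPoints, Point
from pulsecontour.preprocess import Beat
from pulsecontour.signal_io import SubjectMetadata

FS = 512.0


def _subject(**kw):
    base = dict(subject_id="s", age=30.0, gender="female", height_cm=170.0,
                weight_kg=65.0, waist_cm=80.0, arm_cm=28.0)
    base.update(kw)
    return SubjectMetadata(**base)


def _worked_beat():
    """The worked single-beat configuration: baseline 0, B=10, C=6, D=7 at
    t = 0 / 0.15 / 0.30 / 0.38 / 0.80 s."""
    points = FiducialPoints(
        a=Point(0.0, 0.0), b=Point(0.15, 10.0), e=Point(0.80, 0.0),
        c=Point(0.30, 6.0), d=Point(0.38, 7.0),
    )
    t = np.arange(int(0.8 * FS)) / FS
    # a simple rising/decaying stand-in carrying the right rising limb
    x = np.interp(t, [0, 0.15, 0.30, 0.38, 0.80], [0, 10, 6, 7, 0])
    return Beat(x, FS), points


class TestDicroticWaveIndex:
    def test_stiff_vessel_worked_ratio(self):
        """5 mmHg dicrotic surge on a 22 mmHg wave: 22.7 % (one decimal)."""
        assert round(feat.dicrotic_wave_index(5, 22), 1) == 22.7

    def test_elastic_vessel_worked_ratio(self):
        """3.5 mmHg surge on an 8 mmHg wave: 44 % (nearest integer)."""
        assert round(feat.dicrotic_wave_index(3.5, 8)) == 44

    def test_zero_dicrotic_amplitude(self):
        assert feat.dicrotic_wave_index(0, 10) == 0.0

    def test_nonpositive_pulse_amplitude_errors(self):
        with pytest.raises(ValueError):
            feat.dicrotic_wave_index(5, 0)


class TestComputeBeatFeatures:
    def test_worked_beat_arithmetic(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        assert f.systole_duration == pytest.approx(0.30)
        assert f.reflection_time == pytest.approx(0.08)
        assert f.heart_rate == pytest.approx(75.0)
        assert f.dicrotic_wave_index == pytest.approx(70.0)
        assert f.anacrotic_duration == pytest.approx(0.15)
        assert f.rising_wave_index == pytest.approx(100 * 0.15 / 0.8)
        assert f.incision_height == pytest.approx(6.0)

    def test_partial_beat_absent_fields(self):
        beat, points = _worked_beat()
        partial = dataclasses.replace(points, c=None, d=None)
        f = feat.compute_beat_features(beat, partial)
        assert f.dicrotic_wave_index is None
        assert f.reflection_time is None
        assert f.systole_duration is None and f.diastole_duration is None
        assert f.pulse_duration == pytest.approx(0.8)
        assert f.heart_rate == pytest.approx(75.0)

    def test_missing_mandatory_fiducial_errors(self):
        beat, points = _worked_beat()
        bad = FiducialPoints(a=points.a, b=points.b, e=Point(0.0, 0.0))
        with pytest.raises(MissingFiducialError):
            feat.compute_beat_features(beat, bad)
        with pytest.raises(MissingFiducialError):
            feat.compute_beat_features(
                beat, dataclasses.replace(points, e=None))

    def test_filling_time_on_linear_rise(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        # linear rise 0 -> 10 over 0.15 s: 90 % reached at 0.135 s
        assert f.filling_time == pytest.approx(0.135, abs=1.5 / FS)

    def test_complementarity_exact(self, beat_sweep):
        for _, _, _, _, f in beat_sweep:
            assert f.vessel_time_fraction + f.heart_time_fraction == 100.0

    def test_parameter_recovery_over_sweep(self, beat_sweep):
        """DWI within 2 points and HR within 1 bpm of generator truth."""
        for params, _, _, _, f in beat_sweep:
            assert abs(f.dicrotic_wave_index - 100 * params.dicrotic_ratio) <= 2.0
            assert abs(f.heart_rate - 60.0 / params.beat_duration) <= 1.0

    def test_scale_invariance_of_indices_and_durations(self):
        beat, truth = syn.generate_beat(syn.BeatParams())
        from pulsecontour import fiducials as fid
        f1 = feat.compute_beat_features(
            beat, fid.detect_fiducials(beat, fid.compute_derivatives(beat)))
        scaled = Beat(beat.samples * 7.0, FS)
        f2 = feat.compute_beat_features(
            scaled, fid.detect_fiducials(scaled, fid.compute_derivatives(scaled)))
        for name in ("dicrotic_wave_index", "rising_wave_index",
                     "vessel_time_fraction", "anacrotic_duration",
                     "pulse_duration", "systole_duration", "heart_rate"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name), rel=1e-6)


class TestCheckNormative:
    def _features(self, dwi):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        return dataclasses.replace(f, dicrotic_wave_index=dwi)

    def test_normal_band(self):
        verdicts = {v.parameter: v.status
                    for v in feat.check_normative(self._features(70.0))}
        assert verdicts["dicrotic_wave_index"] == "normal"

    def test_stiff_vessel_below_band(self):
        verdicts = {v.parameter: v.status
                    for v in feat.check_normative(self._features(22.7))}
        assert verdicts["dicrotic_wave_index"] == "below"

    def test_absent_value(self):
        verdicts = {v.parameter: v.status
                    for v in feat.check_normative(self._features(None))}
        assert verdicts["dicrotic_wave_index"] == "absent"

    @pytest.mark.parametrize("value,status", [
        (62.999, "below"), (63.0, "normal"), (73.0, "normal"), (73.001, "above"),
    ])
    def test_boundaries_inclusive(self, value, status):
        verdicts = {v.parameter: v.status
                    for v in feat.check_normative(self._features(value))}
        assert verdicts["dicrotic_wave_index"] == status

    @given(st.floats(min_value=-10, max_value=200, allow_nan=False))
    def test_exhaustive_and_mutually_exclusive(self, dwi):
        """Every parameter gets exactly one verdict from the four states."""
        verdicts = feat.check_normative(self._features(dwi))
        names = [v.parameter for v in verdicts]
        assert len(names) == len(set(names)) == 6
        for v in verdicts:
            assert v.status in ("below", "normal", "above", "absent")


class TestAssembleFeatureVector:
    def test_complete_inputs_give_21(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        vec = feat.assemble_feature_vector(_subject(), f)
        assert len(vec.values) == 21
        assert vec.names == feat.FEATURE_VECTOR_NAMES
        assert vec.schema_version == feat.FEATURE_SCHEMA_VERSION

    def test_gender_encoding(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        v_f = feat.assemble_feature_vector(_subject(gender="female"), f)
        v_m = feat.assemble_feature_vector(_subject(gender="male"), f)
        i = list(v_f.names).index("gender")
        assert v_f.values[i] == 0.0 and v_m.values[i] == 1.0

    def test_absent_reflection_time_imputed_with_band_midpoint(self):
        beat, points = _worked_beat()
        f = dataclasses.replace(
            feat.compute_beat_features(beat, points), reflection_time=None
        )
        vec = feat.assemble_feature_vector(_subject(), f)
        i = list(vec.names).index("reflection_time")
        assert vec.values[i] == pytest.approx(0.035)
        assert "reflection_time" in vec.imputed

    def test_missing_age_errors(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        with pytest.raises(ValueError, match="age"):
            feat.assemble_feature_vector(_subject(age=None), f)

    def test_bmi_consistent_with_height_weight(self):
        beat, points = _worked_beat()
        f = feat.compute_beat_features(beat, points)
        vec = feat.assemble_feature_vector(_subject(), f)
        names = list(vec.names)
        h = vec.values[names.index("height_cm")] / 100.0
        w = vec.values[names.index("weight_kg")]
        assert vec.values[names.index("bmi")] == pytest.approx(w / h**2)
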