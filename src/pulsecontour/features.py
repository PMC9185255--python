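"""Amplitude–time hemodynamic parameters and the 21-feature vector.

The contour of one cardiac cycle, reduced to its fiducial points, yields a
standard set of amplitude and duration parameters: pulse amplitude, dicrotic
wave amplitude and index, incision (notch) height, anacrotic/dicrotic phase
durations, systole/diastole split, filling and reflection times, and heart
rate.  Together with seven anthropometric values they form the 21-element
multiparametric feature vector used by the classifier.

Amplitude conventions: the beat-local baseline is the amplitude at cycle
onset (point A); pulse_amplitude = amp(B) − amp(A), incision_height =
amp(C) − amp(A), dicrotic_amplitude = amp(D) − amp(E).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import MissingFiducialError
from .fiducials import FiducialPoints
from .preprocess import Beat
from .signal_io import SubjectMetadata

FEATURE_SCHEMA_VERSION = "1"

#: Fraction of pulse amplitude the rising limb must reach to end the
#: filling phase (the normative filling-time band is 0.06–0.12 s).
DEFAULT_FILLING_THRESHOLD = 0.90


@dataclass(frozen=True)
class BeatFeatures:
    """Amplitude–time parameters of one pulse wave.

    Amplitudes are mmHg on the stabilized (relative) scale, durations are
    seconds, indices and fractions are percent, heart rate is bpm.  Fields
    depending on absent fiducials (C, D or B') are ``None`` — never NaN.
    """

    pulse_amplitude: Optional[float] = None
    dicrotic_amplitude: Optional[float] = None
    incision_height: Optional[float] = None
    dicrotic_wave_index: Optional[float] = None
    rising_wave_index: Optional[float] = None
    anacrotic_duration: Optional[float] = None
    dicrotic_phase_duration: Optional[float] = None
    ejection_duration: Optional[float] = None
    pulse_duration: Optional[float] = None
    filling_time: Optional[float] = None
    systole_duration: Optional[float] = None
    diastole_duration: Optional[float] = None
    reflection_time: Optional[float] = None
    heart_rate: Optional[float] = None
    vessel_time_fraction: Optional[float] = None
    heart_time_fraction: Optional[float] = None


@dataclass(frozen=True)
class NormativeRanges:
    """Normative bands and point values for contour parameters.

    Defaults: dicrotic wave index 63–73 %, rising wave index 15–24 %,
    filling time 0.06–0.12 s, reflection time 0.03–0.04 s; point norms:
    dicrotic amplitude = 1/2 and incision height = 2/3 of pulse amplitude.
    """

    dicrotic_wave_index: tuple[float, float] = (63.0, 73.0)
    rising_wave_index: tuple[float, float] = (15.0, 24.0)
    filling_time: tuple[float, float] = (0.06, 0.12)
    reflection_time: tuple[float, float] = (0.03, 0.04)
    dicrotic_amplitude_ratio: float = 0.5
    incision_height_ratio: float = 2.0 / 3.0
    #: relative half-width of the acceptance band around the point norms
    point_tolerance: float = 0.10

    def __post_init__(self) -> None:
        for name in ("dicrotic_wave_index", "rising_wave_index",
                     "filling_time", "reflection_time"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")


DEFAULT_NORMATIVE = NormativeRanges()


@dataclass(frozen=True)
class NormativeVerdict:
    parameter: str
    value: Optional[float]
    status: str  # below | normal | above | absent


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 21-element input row for the classifier.

    Schema v1: 7 anthropometric values (age, gender 0=female/1=male,
    height, weight, waist, arm, BMI) followed by 14 beat-derived
    parameters.  ``imputed`` names the features that were absent and filled
    with their normative midpoint.
    """

    values: np.ndarray
    names: tuple[str, ...]
    imputed: tuple[str, ...] = ()
    schema_version: str = FEATURE_SCHEMA_VERSION

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size != len(self.names):
            raise ValueError("values and names length mismatch")


ANTHROPOMETRIC_NAMES: tuple[str, ...] = (
    "age", "gender", "height_cm", "weight_kg", "waist_cm", "arm_cm", "bmi",
)

BEAT_FEATURE_NAMES: tuple[str, ...] = (
    "pulse_amplitude", "dicrotic_amplitude", "incision_height",
    "dicrotic_wave_index", "rising_wave_index", "anacrotic_duration",
    "dicrotic_phase_duration", "ejection_duration", "pulse_duration",
    "filling_time", "systole_duration", "diastole_duration",
    "reflection_time", "heart_rate",
)

FEATURE_VECTOR_NAMES: tuple[str, ...] = ANTHROPOMETRIC_NAMES + BEAT_FEATURE_NAMES
assert len(FEATURE_VECTOR_NAMES) == 21


def dicrotic_wave_index(dicrotic_amplitude: float, pulse_amplitude: float) -> float:
    """Dicrotic wave amplitude as a percentage of pulse amplitude.

    Low values indicate reduced elasticity of the vascular bed: an elastic
    young vessel shows ~44 % while a stiff 60-year-old vessel can drop to
    ~22.7 %.
    """
    if not pulse_amplitude > 0:
        raise ValueError(f"pulse_amplitude must be positive, got {pulse_amplitude}")
    if dicrotic_amplitude < 0:
        raise ValueError(f"dicrotic_amplitude must be >= 0, got {dicrotic_amplitude}")
    return 100.0 * dicrotic_amplitude / pulse_amplitude


def _filling_time(beat: Beat, points: FiducialPoints, threshold: float) -> Optional[float]:
    """Time from onset for the rising limb to reach ``threshold`` of the
    pulse amplitude (linear interpolation between samples)."""
    fs = beat.sampling_rate
    a_i = int(round(points.a.time * fs))
    b_i = int(round(points.b.time * fs))
    if b_i <= a_i:
        return None
    x = beat.samples[a_i : b_i + 1]
    target = points.a.amplitude + threshold * (points.b.amplitude - points.a.amplitude)
    above = np.flatnonzero(x >= target)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return 0.0
    # linear interpolation across the crossing sample
    frac = (target - x[i - 1]) / (x[i] - x[i - 1]) if x[i] != x[i - 1] else 0.0
    return (i - 1 + frac) / fs


def compute_beat_features(
    beat: Beat,
    points: FiducialPoints,
    filling_threshold: float = DEFAULT_FILLING_THRESHOLD,
) -> BeatFeatures:
    """Compute all amplitude–time parameters for one beat.

    A, B and E are mandatory; with C/D absent the dependent parameters
    (notch/dicrotic amplitudes and indices, systole/diastole split,
    reflection time) come back ``None``.  ``heart_time_fraction`` is
    computed as ``100 − vessel_time_fraction`` so the two always sum to
    exactly 100.
    """
    if points.a is None or points.b is None or points.e is None:
        raise MissingFiducialError("A, B and E are required to compute features")

    t_a, t_b, t_e = points.a.time, points.b.time, points.e.time
    pulse_duration = t_e - t_a
    if not pulse_duration > 0:
        raise MissingFiducialError("nonpositive pulse duration")

    pulse_amplitude = points.b.amplitude - points.a.amplitude
    anacrotic = t_b - t_a
    dicrotic_phase = t_e - t_b
    heart_rate = 60.0 / pulse_duration
    rising_index = 100.0 * anacrotic / pulse_duration
    fill = _filling_time(beat, points, filling_threshold)

    ejection = None
    if points.b_prime is not None:
        ejection = points.b_prime.time - t_a

    dic_amp = inc_height = dwi = systole = diastole = reflection = None
    vessel_frac = heart_frac = None
    if points.c is not None and points.d is not None:
        t_c, t_d = points.c.time, points.d.time
        dic_amp = points.d.amplitude - points.e.amplitude
        inc_height = points.c.amplitude - points.a.amplitude
        if pulse_amplitude > 0 and dic_amp >= 0:
            dwi = dicrotic_wave_index(dic_amp, pulse_amplitude)
        systole = t_c - t_a
        diastole = t_e - t_c
        reflection = t_d - t_c
        vessel_frac = 100.0 * diastole / pulse_duration
        heart_frac = 100.0 - vessel_frac

    return BeatFeatures(
        pulse_amplitude=pulse_amplitude,
        dicrotic_amplitude=dic_amp,
        incision_height=inc_height,
        dicrotic_wave_index=dwi,
        rising_wave_index=rising_index,
        anacrotic_duration=anacrotic,
        dicrotic_phase_duration=dicrotic_phase,
        ejection_duration=ejection,
        pulse_duration=pulse_duration,
        filling_time=fill,
        systole_duration=systole,
        diastole_duration=diastole,
        reflection_time=reflection,
        heart_rate=heart_rate,
        vessel_time_fraction=vessel_frac,
        heart_time_fraction=heart_frac,
    )


def _band_status(value: Optional[float], lo: float, hi: float) -> str:
    if value is None:
        return "absent"
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "normal"  # boundaries inclusive


def check_normative(
    features: BeatFeatures, ranges: NormativeRanges = DEFAULT_NORMATIVE
) -> list[NormativeVerdict]:
    """Classify each range-bearing parameter as below / normal / above.

    Band boundaries are inclusive; point norms (dicrotic amplitude 1/2 and
    incision height 2/3 of pulse amplitude) use a symmetric relative band of
    ``ranges.point_tolerance``.  Parameters whose inputs are absent come
    back ``absent``; every verdict is exactly one of the four states.
    """
    out = []
    for name in ("dicrotic_wave_index", "rising_wave_index",
                 "filling_time", "reflection_time"):
        lo, hi = getattr(ranges, name)
        out.append(NormativeVerdict(name, getattr(features, name),
                                    _band_status(getattr(features, name), lo, hi)))

    for name, ratio in (
        ("dicrotic_amplitude", ranges.dicrotic_amplitude_ratio),
        ("incision_height", ranges.incision_height_ratio),
    ):
        value = getattr(features, name)
        pa = features.pulse_amplitude
        if value is None or pa is None or not pa > 0:
            out.append(NormativeVerdict(name, value, "absent"))
            continue
        target = ratio * pa
        lo = target * (1 - ranges.point_tolerance)
        hi = target * (1 + ranges.point_tolerance)
        out.append(NormativeVerdict(name, value, _band_status(value, lo, hi)))
    return out


#: Imputation values for absent optional beat features: the midpoint of the
#: normative band where one exists; otherwise a documented fallback.
def _imputation_value(name: str, features: BeatFeatures,
                      ranges: NormativeRanges) -> float:
    banded = {
        "dicrotic_wave_index": ranges.dicrotic_wave_index,
        "rising_wave_index": ranges.rising_wave_index,
        "filling_time": ranges.filling_time,
        "reflection_time": ranges.reflection_time,
    }
    if name in banded:
        lo, hi = banded[name]
        return 0.5 * (lo + hi)
    pa = features.pulse_amplitude or 0.0
    pd_ = features.pulse_duration or 0.0
    if name == "dicrotic_amplitude":
        return ranges.dicrotic_amplitude_ratio * pa
    if name == "incision_height":
        return ranges.incision_height_ratio * pa
    if name == "ejection_duration":
        # B' -> B limit: ejection collapses onto the anacrotic rise
        return features.anacrotic_duration or 0.0
    if name == "systole_duration":
        return 0.36 * pd_  # healthy 36/64 systole/diastole split
    if name == "diastole_duration":
        return 0.64 * pd_
    raise KeyError(name)


def assemble_feature_vector(
    subject: SubjectMetadata,
    features: BeatFeatures,
    ranges: NormativeRanges = DEFAULT_NORMATIVE,
) -> FeatureVector:
    """Build the ordered 21-element classifier input.

    Seven anthropometric values (gender encoded female=0 / male=1) are
    followed by the 14 beat parameters (the two redundant time fractions
    are excluded).  Absent optional beat features are imputed with their
    normative midpoint and listed in ``imputed``; a missing mandatory
    anthropometric raises ``ValueError``.
    """
    anthro = {
        "age": subject.age,
        "gender": {"female": 0.0, "male": 1.0}.get(subject.gender),
        "height_cm": subject.height_cm,
        "weight_kg": subject.weight_kg,
        "waist_cm": subject.waist_cm,
        "arm_cm": subject.arm_cm,
        "bmi": subject.bmi,
    }
    for name, v in anthro.items():
        if v is None:
            raise ValueError(f"missing mandatory anthropometric: {name}")

    values = [float(anthro[n]) for n in ANTHROPOMETRIC_NAMES]
    imputed = []
    for name in BEAT_FEATURE_NAMES:
        v = getattr(features, name)
        if v is None:
            if name in ("pulse_amplitude", "anacrotic_duration",
                        "dicrotic_phase_duration", "pulse_duration",
                        "heart_rate"):
                raise MissingFiducialError(f"mandatory beat feature absent: {name}")
            v = _imputation_value(name, features, ranges)
            imputed.append(name)
        values.append(float(v))
    return FeatureVector(
        values=np.asarray(values), names=FEATURE_VECTOR_NAMES,
        imputed=tuple(imputed),
    )
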