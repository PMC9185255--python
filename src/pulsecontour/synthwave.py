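"""Seeded synthetic pulse-wave generator with analytic ground truth.

Replaces the acquisition hardware for all tests.  A single beat is modelled
as a baseline plus a sum of smooth positive components: an asymmetric
systolic bump, an optional narrow B' shoulder bump on the descent, and an
asymmetric dicrotic bump.  The two inner widths and the two component
amplitudes are calibrated numerically so the continuous composite attains
*exactly* the requested systolic height, dicrotic-wave height, notch depth
and notch time; the returned ground truth holds the extrema of the
continuous model resolved to 1e-8 s, so sampled-signal detectors can be
judged against it at sub-sample precision.

Recordings concatenate jittered beats, multiply each beat's deviation from
baseline by a respiratory factor ``1 + depth*sin(2*pi*f_resp*t_peak)``, and
add slow sinusoidal drift plus white noise.  Everything is reproducible
from a single seed consumed in documented order (drift phase, then per-beat
period jitter, then noise).
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CalibrationError
from .fiducials import FiducialPoints, Point
from .preprocess import Beat
from .signal_io import PulseRecording, SubjectMetadata

# Fixed shape constants of the generator (not exposed as science knobs):
_SIGMA_RISE_FACTOR = 3.5      # systolic left width = t_sys / 3.5 (small onset tail)
_SIGMA_DICROTIC_DECAY = 0.07  # s, dicrotic right-tail decay
_BPRIME_WIDTH = 0.018         # s, B' shoulder bump width
_BPRIME_GAIN = 0.10           # B' bump amplitude = gain * saliency * pulse amp
_BPRIME_POSITION = 0.45       # fraction of the B->C interval
_DRIFT_RATE = 0.05            # Hz, baseline drift frequency


@dataclass(frozen=True)
class BeatParams:
    """Morphology of one synthetic beat.

    Heights are measured above ``baseline``: the systolic peak reaches
    ``pulse_amplitude``, the dicrotic wave ``dicrotic_ratio *
    pulse_amplitude`` and the notch ``notch_depth_ratio * pulse_amplitude``
    (so the measured dicrotic wave index is ``100*dicrotic_ratio`` by
    construction).  ``bprime_saliency`` in [0, 1] scales the B' shoulder;
    0 disables it.
    """

    pulse_amplitude: float = 10.0
    dicrotic_ratio: float = 0.70
    notch_depth_ratio: float = 0.60
    systolic_peak_time: float = 0.15
    notch_time: float = 0.30
    dicrotic_peak_time: float = 0.38
    bprime_saliency: float = 0.0
    beat_duration: float = 0.80
    baseline: float = 80.0

    def __post_init__(self) -> None:
        if not self.pulse_amplitude > 0:
            raise ValueError("pulse_amplitude must be positive")
        if not 0 <= self.dicrotic_ratio < 1:
            raise ValueError("dicrotic_ratio must be in [0, 1)")
        if not (self.systolic_peak_time < self.notch_time
                < self.dicrotic_peak_time < self.beat_duration):
            raise ValueError(
                "times must satisfy systolic_peak < notch < dicrotic_peak < duration"
            )
        if self.dicrotic_ratio > 0:
            if not 0.02 <= self.notch_depth_ratio < self.dicrotic_ratio:
                raise ValueError(
                    "notch_depth_ratio must be in [0.02, dicrotic_ratio)"
                )
        if not 0 <= self.bprime_saliency <= 1:
            raise ValueError("bprime_saliency must be in [0, 1]")


@dataclass(frozen=True)
class RecordingParams:
    """Statistical structure of a synthetic recording."""

    heart_rate: float = 75.0         # bpm
    hr_jitter: float = 0.02          # fractional sd of the beat period
    respiration_rate: float = 0.25   # Hz
    respiration_depth: float = 0.20  # fractional amplitude modulation
    drift_amplitude: float = 1.0     # mmHg
    noise_sd: float = 0.05           # mmHg
    duration: float = 30.0           # s
    sampling_rate: float = 512.0     # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.respiration_depth <= 0.5:
            raise ValueError("respiration_depth must be in [0, 0.5]")
        for name in ("heart_rate", "respiration_rate", "sampling_rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.hr_jitter < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("jitter, noise and drift must be nonnegative")


def _asym_gauss(t: np.ndarray, mu: float, sl: float, sr: float) -> np.ndarray:
    """Asymmetric Gaussian-like bump with unit height exactly at ``mu``.

    The width blends smoothly (logistically) from ``sl`` left of the centre
    to ``sr`` right of it, so the bump is infinitely differentiable — a
    hard piecewise width would put a curvature jump at every peak, which
    both the local-polynomial smoother and the spline refiner would turn
    into a systematic sub-sample bias.
    """
    t = np.asarray(t, dtype=float)
    w = 0.15 * min(sl, sr) + 1e-9
    blend = 1.0 / (1.0 + np.exp(-np.clip((t - mu) / w, -60, 60)))
    sigma = sl + (sr - sl) * blend
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


class BeatShape:
    """Continuous calibrated beat model with exact extremum queries."""

    def __init__(self, params: BeatParams):
        self.params = params
        p = params
        self.t_sys = p.systolic_peak_time
        self.sl_sys = p.systolic_peak_time / _SIGMA_RISE_FACTOR
        self.t_dic = p.dicrotic_peak_time
        self.sr_dic = _SIGMA_DICROTIC_DECAY
        self.t_bp = p.systolic_peak_time + _BPRIME_POSITION * (
            p.notch_time - p.systolic_peak_time
        )
        self.s_bp = _BPRIME_WIDTH
        self.a_bp = _BPRIME_GAIN * p.bprime_saliency * p.pulse_amplitude
        self._calibrate()

    # -- continuous model -------------------------------------------------
    def eval_rel(self, t) -> np.ndarray:
        """Composite above baseline, vectorized."""
        out = self.a_sys * _asym_gauss(t, self.t_sys, self.sl_sys, self.sr_sys)
        if self.a_bp > 0:
            out = out + self.a_bp * _asym_gauss(t, self.t_bp, self.s_bp, self.s_bp)
        if self.a_dic > 0:
            out = out + self.a_dic * _asym_gauss(t, self.t_dic, self.sl_dic, self.sr_dic)
        return out

    def eval(self, t) -> np.ndarray:
        return self.params.baseline + self.eval_rel(t)

    def _extremum(self, lo: float, hi: float, kind: str) -> tuple[float, float]:
        sign = -1.0 if kind == "max" else 1.0
        res = optimize.minimize_scalar(
            lambda t: sign * float(self.eval_rel(t)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x), float(self.eval_rel(res.x))

    # -- calibration ------------------------------------------------------
    def _fit_amplitudes(self) -> tuple[float, float, float, float]:
        """Fixed point on component amplitudes so the composite peaks hit
        the target systolic and dicrotic heights exactly."""
        p = self.params
        h_b_target = p.pulse_amplitude
        h_d_target = p.dicrotic_ratio * p.pulse_amplitude
        for _ in range(60):
            t_b, h_b = self._extremum(0.5 * self.t_sys,
                                      0.5 * (self.t_sys + self.t_dic), "max")
            err_b = h_b_target / h_b
            self.a_sys *= err_b
            if self.a_dic > 0:
                t_d, h_d = self._extremum(0.5 * (self.t_sys + self.t_dic),
                                          self.t_dic + 3 * self.sr_dic, "max")
                err_d = h_d_target / h_d
                self.a_dic *= err_d
            else:
                err_d = 1.0
            if abs(err_b - 1) < 1e-12 and abs(err_d - 1) < 1e-12:
                break
        t_b, h_b = self._extremum(0.5 * self.t_sys,
                                  0.5 * (self.t_sys + self.t_dic), "max")
        if self.a_dic > 0:
            t_d, h_d = self._extremum(0.5 * (self.t_sys + self.t_dic),
                                      self.t_dic + 3 * self.sr_dic, "max")
        else:
            t_d, h_d = np.nan, np.nan
        return t_b, h_b, t_d, h_d

    def _calibrate(self) -> None:
        p = self.params
        self.a_sys = p.pulse_amplitude
        self.a_dic = p.dicrotic_ratio * p.pulse_amplitude

        if p.dicrotic_ratio == 0:
            # Single decaying wave; the right width just sets a smooth descent.
            self.sr_sys = 0.45 * (p.notch_time - p.systolic_peak_time)
            self.sl_dic = 0.05
            self._fit_amplitudes()
            return

        h_c_target = p.notch_depth_ratio * p.pulse_amplitude
        t_c_target = p.notch_time
        span_l = p.notch_time - p.systolic_peak_time
        span_r = p.dicrotic_peak_time - p.notch_time

        def residual(logs: np.ndarray) -> np.ndarray:
            self.sr_sys = float(np.exp(logs[0]))
            self.sl_dic = float(np.exp(logs[1]))
            self._fit_amplitudes()
            t_c, h_c = self._extremum(self.t_sys + 1e-4, self.t_dic - 1e-4, "min")
            return np.array([
                (h_c - h_c_target) / p.pulse_amplitude,
                (t_c - t_c_target) / (self.t_dic - self.t_sys),
            ])

        bounds = (np.log([0.006, 0.006]), np.log([0.6, 0.6]))
        res = None
        for f in (0.55, 0.35, 0.8):
            x0 = np.log([f * span_l, f * span_r])
            sol = optimize.least_squares(
                residual, x0, bounds=bounds, method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            res = residual(sol.x)
            if np.all(np.abs(res) < 1e-6):
                break
        if not np.all(np.abs(res) < 1e-6):
            raise CalibrationError(
                f"could not calibrate beat shape to notch depth "
                f"{p.notch_depth_ratio} at t={p.notch_time}: residual {res}"
            )

    # -- ground truth ------------------------------------------------------
    def truth(self, duration: float, sampling_rate: float) -> FiducialPoints:
        """Fiducial ground truth of the continuous composite on a sampled
        beat of ``duration`` seconds.

        A sits at t=0 and E at the beat's final sample; B, C, D are the
        numerically resolved extrema of the continuous model.  B' (when
        enabled) is logged at the shoulder-bump centre.
        """
        base = self.params.baseline
        n = int(round(duration * sampling_rate))
        t_e = (n - 1) / sampling_rate
        t_b, h_b = self._extremum(0.5 * self.t_sys,
                                  0.5 * (self.t_sys + self.t_dic), "max")
        a = Point(0.0, base + float(self.eval_rel(0.0)))
        b = Point(t_b, base + h_b)
        e = Point(t_e, base + float(self.eval_rel(t_e)))
        c = d = None
        if self.a_dic > 0:
            t_c, h_c = self._extremum(self.t_sys + 1e-4, self.t_dic - 1e-4, "min")
            t_d, h_d = self._extremum(t_c + 1e-4, self.t_dic + 3 * self.sr_dic, "max")
            c = Point(t_c, base + h_c)
            d = Point(t_d, base + h_d)
        bp = None
        if self.a_bp > 0:
            bp = Point(self.t_bp, base + float(self.eval_rel(self.t_bp)))
        return FiducialPoints(a=a, b=b, e=e, b_prime=bp, c=c, d=d)


@functools.lru_cache(maxsize=512)
def _shape_for(params: BeatParams) -> BeatShape:
    """Calibration is deterministic and moderately expensive; memoize it."""
    return BeatShape(params)


def sample_beat_params(
    rng: np.random.Generator,
    amplitude_range: tuple[float, float] = (6.0, 24.0),
    bprime_probability: float = 0.5,
) -> BeatParams:
    """Draw one random plausible beat morphology (seeded via ``rng``).

    Timing and ratio ranges span the morphologies seen across age groups:
    systolic peak 0.10-0.18 s, notch 0.10-0.26 s later, dicrotic peak
    55-110 ms after the notch, dicrotic ratio 0.20-0.75 with the notch at
    45-80 % of the dicrotic height, amplitudes within the cuff's 6-24 mmHg
    oscillation band.  A small fraction of random combinations ask for a
    notch the two-bump composite cannot place (too deep and too far from
    both bumps); those raise :class:`CalibrationError` inside the shape
    calibration and are redrawn, so every returned parameter set is
    realizable.
    """
    for _ in range(50):
        t_s = rng.uniform(0.10, 0.18)
        t_c = rng.uniform(t_s + 0.10, t_s + 0.26)
        t_d = rng.uniform(t_c + 0.055, t_c + 0.11)
        dur = rng.uniform(max(0.7, t_d + 0.25), 1.1)
        ratio = rng.uniform(0.20, 0.75)
        notch = max(0.05, rng.uniform(0.45, 0.80) * ratio)
        amp = rng.uniform(*amplitude_range)
        sal = float(rng.uniform(0, 1)) if rng.random() < bprime_probability else 0.0
        params = BeatParams(
            pulse_amplitude=amp, dicrotic_ratio=ratio, notch_depth_ratio=notch,
            systolic_peak_time=t_s, notch_time=t_c, dicrotic_peak_time=t_d,
            bprime_saliency=sal, beat_duration=dur,
        )
        try:
            _shape_for(params)
        except CalibrationError:
            continue
        return params
    raise CalibrationError("could not draw a realizable morphology in 50 tries")


def generate_beat(
    params: BeatParams, sampling_rate: float = 512.0
) -> tuple[Beat, FiducialPoints]:
    """Generate one noiseless beat and its ground-truth fiducials."""
    shape = _shape_for(params)
    n = int(round(params.beat_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    samples = shape.eval(t)
    beat = Beat(samples=samples, sampling_rate=sampling_rate, start_index=0,
                subject_id="synthetic")
    return beat, shape.truth(params.beat_duration, sampling_rate)


def generate_recording(
    beat_params: BeatParams, rec_params: RecordingParams
) -> tuple[PulseRecording, pd.DataFrame]:
    """Generate a quasi-periodic recording and its per-beat truth log.

    Beats are concatenated with per-beat period jitter; each beat's
    above-baseline pressure is multiplied by the respiratory factor
    evaluated at that beat's systolic-peak time; a slow sinusoidal drift
    and white noise are added on top.  The truth log records every beat's
    onset, absolute fiducial times, applied modulation factor and the
    construction dicrotic-wave index.
    """
    rp = rec_params
    fs = rp.sampling_rate
    period0 = 60.0 / rp.heart_rate
    if rp.duration < 3 * period0:
        raise ValueError("recording must be at least 3 beats long")

    shape = _shape_for(beat_params)
    rng = np.random.default_rng(rp.seed)
    drift_phase = rng.uniform(0, 2 * np.pi)  # stream order: 1) drift phase

    min_period = shape.t_dic + 3 * shape.sr_dic + 0.02
    chunks: list[np.ndarray] = []
    rows = []
    onset = 0
    k = 0
    while True:
        jit = rng.standard_normal() if rp.hr_jitter > 0 else 0.0  # 2) per-beat jitter
        period = period0 * (1.0 + rp.hr_jitter * float(np.clip(jit, -3, 3)))
        period = max(period, min_period)
        n_k = int(round(period * fs))
        if (onset + n_k) / fs > rp.duration:
            break
        tt = np.arange(n_k) / fs
        rel = shape.eval_rel(tt)
        t_onset = onset / fs
        truth = shape.truth(n_k / fs, fs)
        m_k = 1.0 + rp.respiration_depth * np.sin(
            2 * np.pi * rp.respiration_rate * (t_onset + truth.b.time)
        )
        chunks.append(m_k * rel)
        rows.append(
            dict(
                beat=k,
                onset_index=onset,
                onset_time=t_onset,
                duration_s=n_k / fs,
                heart_rate_bpm=60.0 * fs / n_k,
                modulation=m_k,
                amplitude=m_k * beat_params.pulse_amplitude,
                t_a=t_onset + truth.a.time,
                t_b=t_onset + truth.b.time,
                t_bprime=(t_onset + truth.b_prime.time) if truth.b_prime else np.nan,
                t_c=(t_onset + truth.c.time) if truth.c else np.nan,
                t_d=(t_onset + truth.d.time) if truth.d else np.nan,
                t_e=t_onset + truth.e.time,
                dwi_truth=100.0 * beat_params.dicrotic_ratio
                if beat_params.dicrotic_ratio > 0 else np.nan,
            )
        )
        onset += n_k
        k += 1

    if not chunks:
        raise ValueError("duration too short to fit a single beat")
    x = beat_params.baseline + np.concatenate(chunks)
    t_all = np.arange(x.size) / fs
    if rp.drift_amplitude > 0:
        x = x + rp.drift_amplitude * np.sin(
            2 * np.pi * _DRIFT_RATE * t_all + drift_phase
        )
    if rp.noise_sd > 0:
        x = x + rng.normal(0.0, rp.noise_sd, x.size)  # 3) additive noise

    rec = PulseRecording(samples=x, sampling_rate=fs, subject_id="synthetic")
    return rec, pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

#: Named morphology presets.  "young-normal" is the textbook elastic-vessel
#: contour whose dicrotic wave index sits inside the 63-73 % normative band.
#: The three "age*" presets reproduce the printed single-subject exemplars:
#: amplitudes 8 / 12 / 22 mmHg, dicrotic indices 44 / 41.6 / 22.7 % and
#: vessel-time fractions 64 / 64 / 49.4 %.
PRESETS: dict[str, dict] = {
    "young-normal": dict(
        beat=BeatParams(
            pulse_amplitude=10.0, dicrotic_ratio=0.70, notch_depth_ratio=0.60,
            systolic_peak_time=0.15, notch_time=0.30, dicrotic_peak_time=0.38,
            bprime_saliency=0.5, beat_duration=0.80, baseline=80.0,
        ),
        heart_rate=75.0, age=22.0,
    ),
    "age20": dict(
        beat=BeatParams(
            pulse_amplitude=8.0, dicrotic_ratio=0.44, notch_depth_ratio=0.33,
            systolic_peak_time=0.14, notch_time=0.3086, dicrotic_peak_time=0.385,
            bprime_saliency=0.6, beat_duration=60.0 / 70.0, baseline=80.0,
        ),
        heart_rate=70.0, age=20.0,
    ),
    "age30": dict(
        beat=BeatParams(
            pulse_amplitude=12.0, dicrotic_ratio=0.416, notch_depth_ratio=0.32,
            systolic_peak_time=0.13, notch_time=0.288, dicrotic_peak_time=0.360,
            bprime_saliency=0.2, beat_duration=0.80, baseline=80.0,
        ),
        heart_rate=75.0, age=30.0,
    ),
    "age60": dict(
        beat=BeatParams(
            pulse_amplitude=22.0, dicrotic_ratio=0.227, notch_depth_ratio=0.15,
            systolic_peak_time=0.16, notch_time=0.4048, dicrotic_peak_time=0.495,
            bprime_saliency=0.0, beat_duration=0.80, baseline=80.0,
        ),
        heart_rate=75.0, age=60.0,
    ),
}


@dataclass(frozen=True)
class CohortSubject:
    """One labeled cohort member."""

    label: str
    subject: SubjectMetadata
    recording: PulseRecording
    beat_params: BeatParams
    truth_log: pd.DataFrame


def _draw_subject(rng: np.random.Generator, subject_id: str,
                  age_mean: float) -> SubjectMetadata:
    gender = "male" if rng.random() < 0.5 else "female"
    height = float(np.clip(rng.normal(176 if gender == "male" else 165, 6), 150, 200))
    bmi = float(np.clip(rng.normal(24, 2.5), 18, 33))
    weight = bmi * (height / 100) ** 2
    return SubjectMetadata(
        subject_id=subject_id,
        age=float(np.clip(rng.normal(age_mean, 2.0), 18, 90)),
        gender=gender,
        height_cm=height,
        weight_kg=weight,
        waist_cm=float(np.clip(rng.normal(84, 8), 60, 120)),
        arm_cm=float(np.clip(rng.normal(29, 3), 20, 45)),
    )


def _draw_beat_params(rng: np.random.Generator, base: BeatParams) -> BeatParams:
    """Subject-level morphology variation around a preset.

    Some presets sit close to the realizable boundary of the two-bump
    composite; a variant the calibrator rejects is simply redrawn.
    """
    for _ in range(30):
        ratio = float(base.dicrotic_ratio * np.clip(rng.normal(1.0, 0.03), 0.9, 1.1))
        notch = float(base.notch_depth_ratio * np.clip(rng.normal(1.0, 0.03), 0.9, 1.1))
        notch = min(notch, 0.85 * ratio) if ratio > 0 else notch
        params = replace(
            base,
            pulse_amplitude=float(
                base.pulse_amplitude * np.clip(rng.normal(1.0, 0.08), 0.7, 1.3)
            ),
            dicrotic_ratio=ratio,
            notch_depth_ratio=max(notch, 0.02),
        )
        try:
            _shape_for(params)
        except CalibrationError:
            continue
        return params
    raise CalibrationError(f"no realizable variant of preset morphology {base}")


def generate_cohort(
    n_subjects: int,
    class_spec: dict[str, str],
    seed: int = 0,
    duration: float = 12.0,
    respiration_depth: float = 0.2,
    noise_fraction: float = 0.005,
) -> list[CohortSubject]:
    """Generate a labeled cohort, classes split as evenly as possible.

    ``class_spec`` maps a class label to a preset name (see :data:`PRESETS`).
    Each subject gets drawn anthropometrics matched to the preset's age
    group, per-subject morphology variation, and an independent recording
    (noise sd = ``noise_fraction`` of the subject's pulse amplitude).
    Identical seeds give identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not class_spec:
        raise ValueError("class_spec must be non-empty")
    for preset in class_spec.values():
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}")

    rng = np.random.default_rng(seed)
    labels = sorted(class_spec)
    out: list[CohortSubject] = []
    for i in range(n_subjects):
        label = labels[i % len(labels)]
        preset = PRESETS[class_spec[label]]
        subject = _draw_subject(rng, f"{label}-{i:03d}", preset["age"])
        bp = _draw_beat_params(rng, preset["beat"])
        hr = float(preset["heart_rate"] * np.clip(rng.normal(1.0, 0.05), 0.8, 1.2))
        rp = RecordingParams(
            heart_rate=hr,
            hr_jitter=0.02,
            respiration_rate=float(rng.uniform(0.18, 0.30)),
            respiration_depth=respiration_depth,
            drift_amplitude=0.3,
            noise_sd=noise_fraction * bp.pulse_amplitude,
            duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, log = generate_recording(bp, rp)
        rec = rec.replace(subject_id=subject.subject_id)
        out.append(CohortSubject(label=label, subject=subject, recording=rec,
                                 beat_params=bp, truth_log=log))
    return out
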