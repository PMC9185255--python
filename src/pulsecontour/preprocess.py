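"""Respiratory amplitude stabilization and beat segmentation.

Cuff-pressure pulse trains carry a slow amplitude modulation at the breathing
frequency.  Before contour analysis the per-beat oscillation amplitude is
estimated at every systolic peak, interpolated into a smooth envelope, and
divided out so that every cycle has the same working amplitude.  The
recording is then cut into single cardiac cycles at the pre-systolic minima
(point A candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .errors import EnvelopeError, OnsetDetectionError
from .signal_io import PulseRecording

logger = logging.getLogger(__name__)

#: Plausibility band for a single cardiac cycle, seconds (30–240 bpm).
MIN_BEAT_DURATION = 0.25
MAX_BEAT_DURATION = 2.0


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle cut from a parent recording.

    ``samples`` spans ``[start_index, start_index + len)`` of the parent;
    times inside a beat are seconds relative to its first sample.
    """

    samples: np.ndarray
    sampling_rate: float
    start_index: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def start_time(self) -> float:
        """Offset of the beat's first sample in the parent recording, s."""
        return self.start_index / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class RespiratoryEnvelope:
    """Per-beat oscillation amplitude interpolated to every sample.

    Anchors sit at the systolic-peak time of each complete beat and carry
    that beat's peak-to-trough amplitude; between anchors the envelope is a
    shape-preserving (monotone-segment) piecewise cubic, held constant
    beyond the first/last anchor.
    """

    anchor_times: np.ndarray
    anchor_amplitudes: np.ndarray
    interpolated: np.ndarray
    onsets: np.ndarray  # beat boundaries the anchors were computed from

    def modulation_depth(self) -> float:
        """Fractional modulation depth ``(max - min) / (max + min)`` of the
        per-beat amplitude anchors."""
        hi = float(np.max(self.anchor_amplitudes))
        lo = float(np.min(self.anchor_amplitudes))
        return (hi - lo) / (hi + lo)


def detect_onsets(
    recording: PulseRecording,
    min_rate: float = 40.0,
    max_rate: float = 180.0,
    prominence_fraction: float = 0.25,
) -> np.ndarray:
    """Locate cardiac-cycle onsets (point A candidates).

    The signal is band-limited to 0.5–10 Hz, systolic peaks are found by
    prominence (at least ``prominence_fraction`` of the median beat
    amplitude), and each onset is the local minimum of the raw signal
    preceding its systolic upstroke.  Inter-onset intervals outside
    ``[60/max_rate, 60/min_rate]`` seconds are rejected.

    Returns sorted, unique sample indices; raises
    :class:`OnsetDetectionError` when the signal is flat or no plausible
    cycle structure exists.
    """
    x = recording.samples
    fs = recording.sampling_rate
    if np.ptp(x) == 0:
        raise OnsetDetectionError("no onsets: signal is constant")

    # Band-limit for peak picking only; onsets are read off the raw signal.
    nyq = fs / 2.0
    hi = min(10.0, 0.9 * nyq)
    sos = sps.butter(2, [0.5, hi], btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)

    min_dist = max(1, int(round(fs * 60.0 / max_rate)))
    peaks, props = sps.find_peaks(xb, distance=min_dist, prominence=1e-12)
    if peaks.size == 0:
        raise OnsetDetectionError("no onsets: no oscillation peaks found")
    # Estimate the typical systolic prominence from the upper part of the
    # prominence population: the candidate list can contain dicrotic waves,
    # whose small prominences would otherwise drag a plain median down and
    # let them pass the threshold as false "beats".
    prom = props["prominences"]
    med_amp = float(np.percentile(prom, 75))
    keep = prom >= prominence_fraction * med_amp
    peaks, prom = peaks[keep], prom[keep]
    if peaks.size == 0:
        raise OnsetDetectionError("no onsets: all peaks below prominence threshold")
    # Dedupe peaks closer than 60% of the typical spacing (keep the more
    # prominent of the pair).
    if peaks.size >= 3:
        min_sep = 0.6 * float(np.median(np.diff(peaks)))
        kept: list[int] = []
        for i, p in enumerate(peaks):
            if kept and p - peaks[kept[-1]] < min_sep:
                if prom[i] > prom[kept[-1]]:
                    kept[-1] = i
            else:
                kept.append(i)
        peaks, prom = peaks[kept], prom[kept]

    if peaks.size >= 2:
        med_period = int(np.median(np.diff(peaks)))
    else:
        med_period = int(round(fs * 60.0 / min_rate))

    # Smooth for the foot search and estimate the noise floor: on a flat
    # diastolic tail the literal argmin wanders with noise, so the onset is
    # the LAST sample still within a noise-scaled tolerance of the segment
    # minimum — the foot of the systolic upstroke.
    smooth_win = max(5, int(round(0.025 * fs)) | 1)
    xs = sps.savgol_filter(x, smooth_win, 2) if x.size > smooth_win else x
    sigma = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    pr_med = float(np.median(prom))  # one tolerance for all beats
    onsets = []
    prev_peak = None
    for p, pr in zip(peaks, prom):
        lo = int(prev_peak) if prev_peak is not None else max(0, p - med_period)
        lo = max(lo, p - int(round(fs * 60.0 / min_rate)))
        if lo >= p:
            prev_peak = p
            continue
        seg = xs[lo:p]
        tol = max(4.0 * sigma / np.sqrt(smooth_win), 0.005 * pr_med, 1e-12)
        near = np.flatnonzero(seg <= np.min(seg) + tol)
        onset = lo + int(near[-1])
        onsets.append(onset)
        prev_peak = p

    # The first beat has no preceding diastolic tail, so its detected foot
    # sits slightly late.  When the train is essentially periodic, place
    # the first onset one median period before the second one instead.
    if len(onsets) >= 4:
        sp = np.diff(onsets[1:])
        med_sp = float(np.median(sp))
        if med_sp > 0 and float(np.std(sp)) / med_sp < 0.005:
            cand = int(round(onsets[1] - med_sp))
            if 0 <= cand and abs(cand - onsets[0]) <= max(2.0, 0.05 * med_sp):
                onsets[0] = cand

    onsets = np.unique(np.asarray(onsets, dtype=int))
    if onsets.size == 0:
        raise OnsetDetectionError("no onsets found")

    # Enforce the inter-onset plausibility band.
    filtered = [int(onsets[0])]
    lo_iv, hi_iv = 60.0 / max_rate, 60.0 / min_rate
    for o in onsets[1:]:
        iv = (o - filtered[-1]) / fs
        if iv < lo_iv:
            continue  # too close: keep the earlier onset
        if iv > hi_iv:
            logger.debug("onset at %d starts a gap of %.3f s", o, iv)
        filtered.append(int(o))
    return np.asarray(filtered, dtype=int)


def estimate_respiratory_envelope(
    recording: PulseRecording, onsets: Sequence[int]
) -> RespiratoryEnvelope:
    """Estimate the respiration-induced amplitude envelope.

    Each complete beat ``[onset_k, onset_{k+1})`` contributes one anchor:
    its peak-to-trough amplitude, placed at its systolic-peak time.  The
    anchors are interpolated with a shape-preserving piecewise cubic
    (PCHIP), which cannot overshoot and therefore cannot drive the envelope
    negative; beyond the first/last anchor the end value is held.

    Requires at least 3 complete beats.
    """
    onsets = np.asarray(onsets, dtype=int)
    n_beats = onsets.size - 1
    if n_beats < 3:
        raise EnvelopeError(f"need at least 3 complete beats, got {n_beats}")

    x = recording.samples
    fs = recording.sampling_rate
    anchor_t = np.empty(n_beats)
    anchor_a = np.empty(n_beats)
    for k in range(n_beats):
        seg = x[onsets[k] : onsets[k + 1]]
        anchor_a[k] = float(np.max(seg) - np.min(seg))
        anchor_t[k] = (onsets[k] + int(np.argmax(seg))) / fs
    if not np.all(np.diff(anchor_t) > 0):
        raise EnvelopeError("anchor times not strictly increasing")

    t = np.arange(x.size) / fs
    interp = PchipInterpolator(anchor_t, anchor_a, extrapolate=False)
    env = interp(t)
    env[t <= anchor_t[0]] = anchor_a[0]
    env[t >= anchor_t[-1]] = anchor_a[-1]
    return RespiratoryEnvelope(
        anchor_times=anchor_t,
        anchor_amplitudes=anchor_a,
        interpolated=env,
        onsets=onsets,
    )


def stabilize_amplitudes(
    recording: PulseRecording,
    envelope: RespiratoryEnvelope,
    target_amplitude: Optional[float] = None,
) -> PulseRecording:
    """Rescale each beat so its oscillation amplitude equals ``target_amplitude``.

    Within every beat, the deviation of each sample from the beat-local
    baseline (the beat minimum) is multiplied by
    ``target_amplitude / envelope``; the head before the first onset and the
    tail after the last use the nearest beat's baseline.  When
    ``target_amplitude`` is omitted, the median anchor amplitude is used so
    the overall signal scale is preserved.
    """
    env = envelope.interpolated
    if np.any(env <= 0):
        raise EnvelopeError("envelope contains nonpositive values")
    if target_amplitude is None:
        target_amplitude = float(np.median(envelope.anchor_amplitudes))
    if not target_amplitude > 0:
        raise ValueError("target_amplitude must be positive")

    x = recording.samples
    onsets = envelope.onsets
    out = np.array(x, dtype=float)
    gain = target_amplitude / env

    bounds = [0] + [int(o) for o in onsets[1:-1]] + [x.size]
    # Beat-local baselines from the interior segmentation; head/tail merge
    # into the first/last beat respectively.
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = x[lo:hi]
        base = float(np.min(seg))
        out[lo:hi] = base + (seg - base) * gain[lo:hi]
    return recording.replace(samples=out)


def segment_beats(
    recording: PulseRecording,
    onsets: Sequence[int],
    min_duration: float = MIN_BEAT_DURATION,
    max_duration: float = MAX_BEAT_DURATION,
) -> list[Beat]:
    """Cut the recording into single cycles ``[onset_k, onset_{k+1})``.

    The final partial beat (after the last onset) is dropped.  Beats whose
    duration falls outside the plausibility band are discarded with a logged
    reason.  May return an empty list.
    """
    onsets = np.asarray(onsets, dtype=int)
    fs = recording.sampling_rate
    beats: list[Beat] = []
    for k in range(onsets.size - 1):
        lo, hi = int(onsets[k]), int(onsets[k + 1])
        dur = (hi - lo) / fs
        if not (min_duration <= dur <= max_duration):
            logger.info(
                "discarding beat %d at sample %d: duration %.3f s outside "
                "[%.2f, %.2f] s",
                k, lo, dur, min_duration, max_duration,
            )
            continue
        beats.append(
            Beat(
                samples=recording.samples[lo:hi],
                sampling_rate=fs,
                start_index=lo,
                subject_id=recording.subject_id,
            )
        )
    return beats
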