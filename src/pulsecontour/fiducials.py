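"""Fiducial-point delineation on a single pulse wave.

A cardiac cycle carries six characteristic points: A (cycle onset), B
(systolic peak), B' (an often-invisible shoulder on the descent where left
ventricular ejection stops), C (dicrotic notch / incisura, end of systole),
D (dicrotic wave peak, aortic valve closure) and E (end of diastole).  They
are located on a locally-polynomial-smoothed copy of the beat via its first
and second derivatives, then refined to sub-sample resolution with a cubic
spline fit around each extremum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .preprocess import Beat

#: Presentation-only gain applied to derivative exports (steepness of the
#: derivative curves in normalized plots); never used in detection.
DISPLAY_SCALE_D1 = 5.0
DISPLAY_SCALE_D2 = 50.0

DEFAULT_SMOOTH_WINDOW = 0.025  # s
DEFAULT_POLY_ORDER = 3
DEFAULT_BPRIME_THRESHOLD = 0.10  # fraction of the global |d2| peak
DEFAULT_REBOUND_WINDOW = 0.25  # s, window for the dicrotic rebound after C


class Point(NamedTuple):
    """A fiducial landmark: time (s, relative to beat start) and amplitude
    (mmHg)."""

    time: float
    amplitude: float


@dataclass(frozen=True)
class DerivativeSet:
    """Smoothed beat and its first/second analytic derivatives.

    ``d0``/``d1``/``d2`` share the beat's length and grid.  The display
    scales only affect :meth:`display_arrays` exports.
    """

    d0: np.ndarray  # mmHg
    d1: np.ndarray  # mmHg/s
    d2: np.ndarray  # mmHg/s^2
    sampling_rate: float
    display_scale_d1: float = DISPLAY_SCALE_D1
    display_scale_d2: float = DISPLAY_SCALE_D2

    def display_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Derivatives normalized to the signal's scale and multiplied by the
        display coefficients, for plotting/export only."""
        span = np.ptp(self.d0) or 1.0

        def norm(a, k):
            s = np.max(np.abs(a)) or 1.0
            return k * a / s * span / self.display_scale_d2

        return (
            self.d0,
            norm(self.d1, self.display_scale_d1),
            norm(self.d2, self.display_scale_d2),
        )


@dataclass(frozen=True)
class FiducialPoints:
    """Times and amplitudes of A, B, B', C, D, E within one beat.

    ``b_prime``, ``c`` and ``d`` may be absent (``None``) on beats without a
    visible shoulder or dicrotic structure; ``flags`` records why.  Times
    are seconds relative to the beat start.
    """

    a: Point
    b: Point
    e: Point
    b_prime: Optional[Point] = None
    c: Optional[Point] = None
    d: Optional[Point] = None
    flags: tuple[str, ...] = ()

    def complete(self) -> bool:
        """True when the dicrotic structure (C and D) was found."""
        return self.c is not None and self.d is not None

    def ordering_ok(self) -> bool:
        """Check t_A < t_B <= t_B' (if present) < t_C < t_D < t_E over the
        points that are present."""
        if not self.a.time < self.b.time:
            return False
        if self.b_prime is not None and self.b_prime.time < self.b.time:
            return False
        # strictly increasing across B' (if present) and the later points
        seq = [self.b_prime.time if self.b_prime is not None else self.b.time]
        for p in (self.c, self.d, self.e):
            if p is not None:
                seq.append(p.time)
        return all(t1 < t2 for t1, t2 in zip(seq, seq[1:]))

    def with_flag(self, flag: str) -> "FiducialPoints":
        return dataclasses.replace(self, flags=self.flags + (flag,))

    def absolute(self, beat: Beat) -> "FiducialPoints":
        """Shift all times by the beat's offset in its parent recording."""
        dt = beat.start_time

        def sh(p: Optional[Point]) -> Optional[Point]:
            return None if p is None else Point(p.time + dt, p.amplitude)

        return dataclasses.replace(
            self, a=sh(self.a), b=sh(self.b), e=sh(self.e),
            b_prime=sh(self.b_prime), c=sh(self.c), d=sh(self.d),
        )


def compute_derivatives(
    beat: Beat,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> DerivativeSet:
    """Smooth the beat and differentiate it analytically.

    A Savitzky–Golay local polynomial fit (default 25 ms window, order 3)
    yields the smoothed signal and its first and second derivatives on the
    sample grid.  The window must be shorter than the beat and hold at least
    ``poly_order + 2`` samples.
    """
    fs = beat.sampling_rate
    win = int(round(smooth_window * fs))
    if win % 2 == 0:
        win += 1
    if win < poly_order + 2:
        win = poly_order + 2 + ((poly_order + 1) % 2)  # next odd >= order+2
    if win > len(beat):
        raise ValueError(
            f"smoothing window of {win} samples exceeds beat length {len(beat)}"
        )
    x = beat.samples
    delta = 1.0 / fs
    d0 = savgol_filter(x, win, poly_order, deriv=0, delta=delta, mode="interp")
    d1 = savgol_filter(x, win, poly_order, deriv=1, delta=delta, mode="interp")
    d2 = savgol_filter(x, win, poly_order, deriv=2, delta=delta, mode="interp")
    return DerivativeSet(d0=d0, d1=d1, d2=d2, sampling_rate=fs)


def _local_minima(x: np.ndarray) -> np.ndarray:
    idx, _ = find_peaks(-x)
    return idx


def detect_fiducials(
    beat: Beat,
    derivs: DerivativeSet,
    bprime_threshold: float = DEFAULT_BPRIME_THRESHOLD,
    rebound_window: float = DEFAULT_REBOUND_WINDOW,
) -> FiducialPoints:
    """Locate A, B, B', C, D, E on one beat.

    * A is the beat onset (first sample: the segmentation cut at the
      pre-systolic minimum).
    * B is the global maximum.
    * C is the post-B local minimum followed by the largest rebound within
      ``rebound_window`` seconds (the dicrotic wave); ties break to the
      earliest candidate.
    * D is the highest interior local maximum after C.
    * E is the end-of-beat minimum.
    * B' is the most salient local maximum of the second derivative on the
      B→C descent, reported only when its height exceeds
      ``bprime_threshold`` of the global |d2| peak; it is frequently absent
      on real contours.

    Beats without any post-B minimum come back with C and D absent and a
    ``no_dicrotic_structure`` flag; callers must handle partially-filled
    results.
    """
    d0 = derivs.d0
    d2 = derivs.d2
    fs = beat.sampling_rate
    n = d0.size
    flags: list[str] = []

    a_idx = 0
    b_idx = int(np.argmax(d0))
    if b_idx == 0:
        # Degenerate: monotone-decreasing beat; keep B at the first interior max.
        b_idx = 1
        flags.append("b_at_edge")

    # --- C: dicrotic notch ---------------------------------------------
    interior = slice(b_idx + 1, n - 1)
    minima = _local_minima(d0[interior]) + b_idx + 1
    c_idx: Optional[int] = None
    if minima.size:
        w = max(1, int(round(rebound_window * fs)))
        rebounds = np.array(
            [np.max(d0[m : min(n, m + w)]) - d0[m] for m in minima]
        )
        best = float(np.max(rebounds))
        # A real dicrotic wave rebounds by a visible fraction of the beat
        # amplitude; anything smaller is smoothing/float ripple.
        if best >= 0.005 * (np.ptp(d0) or 1.0):
            # earliest candidate within numerical tie of the best rebound
            tie = np.flatnonzero(rebounds >= best * (1 - 1e-9))
            c_idx = int(minima[tie[0]])

    # --- D: dicrotic wave peak ------------------------------------------
    d_idx: Optional[int] = None
    if c_idx is not None:
        maxima, _ = find_peaks(d0[c_idx:n - 1])
        if maxima.size:
            cand = maxima + c_idx
            d_idx = int(cand[np.argmax(d0[cand])])
    if c_idx is None or d_idx is None:
        c_idx = d_idx = None
        flags.append("no_dicrotic_structure")

    # --- E: end-of-diastole minimum -------------------------------------
    # Beats are cut at consecutive cycle-onset minima, so the end of
    # diastole is the beat's final sample.  Searching the (often nearly
    # flat, noisy) diastolic tail for a literal minimum would let noise
    # ripple drag E into the tail and bias every duration feature.
    e_idx = n - 1

    # --- B': shoulder on the descent -------------------------------------
    # Search only the interior of the B->C descent: curvature immediately
    # after B belongs to the systolic peak and curvature just before C to
    # the notch itself, and both would otherwise masquerade as a shoulder.
    bp: Optional[Point] = None
    c_stop = c_idx if c_idx is not None else e_idx
    span = c_stop - b_idx
    lo_bp = b_idx + max(1, int(round(0.15 * span)))
    hi_bp = b_idx + int(round(0.75 * span))
    if hi_bp - lo_bp > 2:
        seg = d2[lo_bp:hi_bp]
        peaks, _ = find_peaks(seg)
        scale = float(np.max(np.abs(d2))) or 1.0
        if peaks.size:
            heights = seg[peaks]
            best = int(peaks[np.argmax(heights)])
            if heights.max() >= bprime_threshold * scale and seg[best] > 0:
                i = best + lo_bp
                bp = Point(i / fs, float(d0[i]))

    def pt(i: int) -> Point:
        return Point(i / fs, float(d0[i]))

    return FiducialPoints(
        a=pt(a_idx),
        b=pt(b_idx),
        e=pt(e_idx),
        b_prime=bp,
        c=pt(c_idx) if c_idx is not None else None,
        d=pt(d_idx) if d_idx is not None else None,
        flags=tuple(flags),
    )


def _refine_extremum(
    beat: Beat, p: Point, kind: str, window: float,
    lo_bound: float, hi_bound: float,
) -> tuple[Optional[Point], bool]:
    """Fit a cubic spline to ±window around the point and move it to the
    spline extremum.  Returns (point or None, refined?)."""
    fs = beat.sampling_rate
    n = len(beat)
    idx = int(round(p.time * fs))
    w = max(2, int(round(window * fs)))
    lo, hi = idx - w, idx + w
    if lo < 0 or hi >= n:
        return None, False
    tt = np.arange(lo, hi + 1) / fs
    spline = CubicSpline(tt, beat.samples[lo : hi + 1])
    crit = spline.derivative().roots(extrapolate=False)
    crit = crit[(crit >= tt[0]) & (crit <= tt[-1])]
    if crit.size == 0:
        return None, False
    vals = spline(crit)
    t_new = float(crit[np.argmax(vals)] if kind == "max" else crit[np.argmin(vals)])
    # never move more than one sample, never cross a neighboring fiducial
    t_new = float(np.clip(t_new, p.time - 1.0 / fs, p.time + 1.0 / fs))
    eps = 0.25 / fs
    t_new = float(np.clip(t_new, lo_bound + eps, hi_bound - eps))
    return Point(t_new, float(spline(t_new))), True


def refine_with_spline(
    beat: Beat, points: FiducialPoints, window: float = 0.010
) -> FiducialPoints:
    """Refine fiducial times/amplitudes to sub-sample resolution.

    Each interior extremum (B, C, D) is replaced by the extremum of a cubic
    spline fit to ``±window`` seconds around its grid sample; the refined
    time never moves by more than one sample nor across a neighboring
    fiducial.  Points too close to the beat edge (always A and E) are left
    unrefined and flagged ``unrefined_edge``.  B' is a curvature landmark,
    not an extremum, and is left untouched.
    """
    flags = list(points.flags)
    out = {}
    fs = beat.sampling_rate

    seq: list[tuple[str, Optional[Point], str]] = [
        ("b", points.b, "max"),
        ("c", points.c, "min"),
        ("d", points.d, "max"),
    ]
    # ordered neighbor times for crossing protection
    times = {
        "a": points.a.time,
        "b": points.b.time,
        "c": points.c.time if points.c else None,
        "d": points.d.time if points.d else None,
        "e": points.e.time,
    }

    def neighbor(name: str, side: int) -> float:
        order = ["a", "b", "c", "d", "e"]
        i = order.index(name) + side
        while 0 <= i < len(order):
            t = times[order[i]]
            if t is not None:
                return t
            i += side
        return -np.inf if side < 0 else np.inf

    for name, p, kind in seq:
        if p is None:
            out[name] = None
            continue
        refined, ok = _refine_extremum(
            beat, p, kind, window, neighbor(name, -1), neighbor(name, +1)
        )
        if ok and refined is not None:
            out[name] = refined
            times[name] = refined.time
        else:
            out[name] = p
            flags.append(f"unrefined_{name}")

    # Edge points are never refinable with a symmetric window.
    for name in ("a", "e"):
        idx = int(round(times[name] * fs))
        w = max(2, int(round(window * fs)))
        if idx - w < 0 or idx + w >= len(beat):
            flags.append("unrefined_edge")

    return dataclasses.replace(
        points,
        b=out["b"],
        c=out["c"],
        d=out["d"],
        flags=tuple(dict.fromkeys(flags)),
    )
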