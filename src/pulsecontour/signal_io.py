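"""Reading and writing pulse recordings, subject metadata and feature tables.

A recording is a uniformly sampled single-channel cuff-pressure signal
(mmHg).  Two plain-text dialects are supported: one numeric sample per line,
and a two-column ``time,value`` CSV whose sampling rate is inferred from the
median time step.  Sample ``i`` of a recording occurs at ``t0 + i / sampling_rate``
seconds; all times reported by this package are in seconds.
"""

from __future__ import annotations

import dataclasses
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: Default sampling rate of the acquisition hardware, Hz.
DEFAULT_SAMPLING_RATE = 512.0

FEATURE_TABLE_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PulseRecording:
    """A uniformly sampled arterial pressure pulsation signal.

    Parameters
    ----------
    samples:
        Pressure values in mmHg.
    sampling_rate:
        Sampling frequency in Hz (default 512).
    subject_id:
        Opaque subject label.
    t0:
        Start-time offset in seconds.
    units:
        Pressure unit tag; recorded, never converted.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    subject_id: str = ""
    t0: float = 0.0
    units: str = "mmHg"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a recording needs at least 2 samples in one channel")
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (``t0 + i / sampling_rate``)."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def replace(self, **kw) -> "PulseRecording":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SubjectMetadata:
    """Anthropometric subject record.

    Body-mass index is derived (``weight / (height/100)**2``) and never
    stored independently.  ``gender`` is one of ``"female"`` / ``"male"``.
    """

    subject_id: str = ""
    age: Optional[float] = None
    gender: Optional[str] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    waist_cm: Optional[float] = None
    arm_cm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("age", "height_cm", "weight_kg"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.gender is not None and self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")

    @property
    def bmi(self) -> Optional[float]:
        """Body-mass index in kg/m², or None when height/weight is missing."""
        if self.height_cm is None or self.weight_kg is None:
            return None
        return self.weight_kg / (self.height_cm / 100.0) ** 2


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(token: str) -> bool:
    return bool(_NUMBER_RE.match(token.strip()))


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [t for t in line.split(",")]
    if "\t" in line:
        return [t for t in line.split("\t")]
    return line.split()


def read_recording(
    path,
    sampling_rate: Optional[float] = None,
    units: str = "mmHg",
    subject_id: Optional[str] = None,
) -> PulseRecording:
    """Read a pulse recording from a plain-text file.

    Two dialects are auto-detected: a single numeric column (one sample per
    line; ``sampling_rate`` defaults to 512 Hz), and a two-column
    ``time,value`` file whose rate, when not given, is inferred as
    ``1 / median(Δt)``.  One non-numeric header line is tolerated; comment
    lines starting with ``#`` are skipped.  Any other non-numeric row raises
    :class:`FormatError` with its line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")

    values: list[float] = []
    times: list[float] = []
    ncols: Optional[int] = None
    header_seen = False
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _split_row(line)
            numeric = all(_is_number(t) for t in tokens)
            if not numeric:
                if not header_seen and not values:
                    header_seen = True  # single optional header line
                    continue
                raise FormatError(f"{path}: line {lineno}: non-numeric row {line!r}")
            if ncols is None:
                ncols = len(tokens)
                if ncols not in (1, 2):
                    raise FormatError(
                        f"{path}: line {lineno}: expected 1 or 2 columns, got {ncols}"
                    )
            elif len(tokens) != ncols:
                raise FormatError(
                    f"{path}: line {lineno}: inconsistent column count "
                    f"({len(tokens)} vs {ncols})"
                )
            if ncols == 1:
                values.append(float(tokens[0]))
            else:
                times.append(float(tokens[0]))
                values.append(float(tokens[1]))

    if len(values) == 0:
        raise FormatError(f"{path}: no samples")
    if len(values) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")

    t0 = 0.0
    if ncols == 2:
        dt = np.diff(np.asarray(times, dtype=float))
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2
            raise FormatError(f"{path}: time column not strictly increasing near row {bad}")
        if sampling_rate is None:
            sampling_rate = 1.0 / float(np.median(dt))
        t0 = float(times[0])
    elif sampling_rate is None:
        sampling_rate = DEFAULT_SAMPLING_RATE

    return PulseRecording(
        samples=np.asarray(values, dtype=float),
        sampling_rate=float(sampling_rate),
        subject_id=subject_id or path.stem,
        t0=t0,
        units=units,
    )


def write_recording(recording: PulseRecording, path) -> None:
    """Write a recording as a two-column ``time,value`` CSV."""
    t = recording.times()
    with open(path, "w") as fh:
        fh.write("time,value\n")
        for ti, vi in zip(t, recording.samples):
            fh.write(f"{ti:.9f},{vi:.6f}\n")


def _feature_columns(features) -> list[str]:
    return [f.name for f in dataclasses.fields(features)]


def write_feature_table(rows: Sequence[tuple], path) -> None:
    """Write per-beat features as CSV, one row per beat.

    ``rows`` is a non-empty sequence of ``(subject_id, BeatFeatures)`` pairs.
    The column order is the declared field order of the features dataclass;
    units and schema version go in ``#``-prefixed header comments.  Absent
    (optional) features are written as empty cells.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("write_feature_table: no rows")
    cols = _feature_columns(rows[0][1])
    records = []
    for subject_id, feats in rows:
        rec = {"subject_id": subject_id}
        rec.update(dataclasses.asdict(feats))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=["subject_id"] + cols)
    with open(path, "w") as fh:
        fh.write(f"# pulsecontour feature table, schema v{FEATURE_TABLE_SCHEMA_VERSION}\n")
        fh.write("# amplitudes: mmHg (relative units); durations: s; indices/fractions: %; heart_rate: bpm\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, comment="#")


def read_subject_table(path) -> list[SubjectMetadata]:
    """Read subject metadata from CSV with columns
    ``subject_id,age,gender,height_cm,weight_kg,waist_cm,arm_cm``."""
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        kw = {}
        for col in ("subject_id", "gender"):
            if col in df.columns and not pd.isna(row[col]):
                kw[col] = str(row[col])
        for col in ("age", "height_cm", "weight_kg", "waist_cm", "arm_cm"):
            if col in df.columns and not pd.isna(row[col]):
                kw[col] = float(row[col])
        out.append(SubjectMetadata(**kw))
    return out


def write_subject_table(subjects: Sequence[SubjectMetadata], path) -> None:
    records = []
    for s in subjects:
        records.append(
            dict(
                subject_id=s.subject_id,
                age=s.age,
                gender=s.gender,
                height_cm=s.height_cm,
                weight_kg=s.weight_kg,
                waist_cm=s.waist_cm,
                arm_cm=s.arm_cm,
            )
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
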