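"""Domain types and I/O for binocular gaze recordings under alternate occlusion.

A recording is a :class:`GazeTrace` — timestamped horizontal gaze positions
(millimetres, one shared axis where positive is rightward in the headset
frame) for the left and right eye, each sample carrying a tracker-validity
flag — together with an :class:`OcclusionSchedule` saying which eye was
covered when.  The trace CSV format carries both in one file::

    t_s,left_x_mm,right_x_mm,left_valid,right_valid,covered_eye

with floats in decimal notation, validity as 0/1 and ``covered_eye`` one of
``left``, ``right`` or ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, SchemaError, UnusableEyeError

LEFT = "left"
RIGHT = "right"
NONE = "none"

_CSV_COLUMNS = ["t_s", "left_x_mm", "right_x_mm", "left_valid", "right_valid",
                "covered_eye"]


@dataclass(frozen=True)
class GazeSample:
    """One binocular gaze sample.

    Attributes
    ----------
    t : float
        Time since recording start, in seconds.
    x_left, x_right : float
        Horizontal gaze position of each eye, in millimetres (positive =
        rightward for both eyes).
    valid_left, valid_right : bool
        Tracker validity flags; positions are only meaningful when True.
    """

    t: float
    x_left: float
    x_right: float
    valid_left: bool = True
    valid_right: bool = True


@dataclass
class GazeTrace:
    """Array-backed sequence of gaze samples.

    Parameters
    ----------
    t : array of float
        Strictly increasing sample times (s), starting at or after 0.
    x_left, x_right : array of float
        Per-eye horizontal positions (mm).
    valid_left, valid_right : array of bool
        Validity flags.
    nominal_rate : float
        Nominal sampling rate of the tracker (Hz).
    duration : float, optional
        Recording duration (s); defaults to the last sample time.
    gaps : list of (float, float)
        Gap log written by :func:`clean_trace`: (start time, missing span).
    """

    t: np.ndarray
    x_left: np.ndarray
    x_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    nominal_rate: float = 120.0
    duration: float | None = None
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_left = np.asarray(self.x_left, dtype=float)
        self.x_right = np.asarray(self.x_right, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        n = self.t.size
        for name in ("x_left", "x_right", "valid_left", "valid_right"):
            if getattr(self, name).size != n:
                raise DataError(f"column {name!r} has length "
                                f"{getattr(self, name).size}, expected {n}")
        if n == 0:
            raise DataError("empty trace")
        if self.t[0] < 0:
            raise DataError("negative timestamps")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("sample times are not strictly increasing")
        if self.nominal_rate <= 0:
            raise DataError("nominal_rate must be positive")
        for x, valid, eye in ((self.x_left, self.valid_left, LEFT),
                              (self.x_right, self.valid_right, RIGHT)):
            if not np.all(np.isfinite(x[valid])):
                raise DataError(f"non-finite {eye}-eye position flagged valid")
        if self.duration is None:
            self.duration = float(self.t[-1])
        elif self.duration < self.t[-1]:
            raise DataError("duration is shorter than the last sample time")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def samples(self) -> Iterator[GazeSample]:
        """Iterate over samples as :class:`GazeSample` records."""
        for i in range(len(self)):
            yield GazeSample(float(self.t[i]), float(self.x_left[i]),
                             float(self.x_right[i]), bool(self.valid_left[i]),
                             bool(self.valid_right[i]))


@dataclass(frozen=True)
class Segment:
    """One occlusion segment: ``covered_eye`` is covered on [t_start, t_end)."""

    t_start: float
    t_end: float
    covered_eye: str

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise DataError("segment must have positive length")
        if self.covered_eye not in (LEFT, RIGHT, NONE):
            raise DataError(f"unknown covered_eye {self.covered_eye!r}")


@dataclass
class OcclusionSchedule:
    """Contiguous, non-overlapping occlusion segments.

    Alternate occlusion of each eye for ``occlusion_duration`` seconds gives a
    refixation cycle of ``cycle_period = 2 * occlusion_duration`` seconds —
    the fixed period of the downstream sine fit.
    """

    segments: list[Segment]
    cycle_period: float = 2.0
    occlusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise DataError("schedule has no segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise DataError("schedule segments are not contiguous")
        if not np.isclose(self.cycle_period, 2.0 * self.occlusion_duration):
            raise DataError("cycle_period must equal 2 x occlusion_duration")

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    def covered_at(self, t: np.ndarray | float) -> np.ndarray:
        """Covered eye at each time in `t` (``'none'`` outside the schedule)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, NONE, dtype=object)
        edges = np.array([s.t_start for s in self.segments] +
                         [self.segments[-1].t_end])
        idx = np.searchsorted(edges, t, side="right") - 1
        inside = (idx >= 0) & (idx < len(self.segments)) & (t < edges[-1])
        labels = np.array([s.covered_eye for s in self.segments], dtype=object)
        out[inside] = labels[idx[inside]]
        return out


def read_trace(path: str | Path) -> tuple[GazeTrace, OcclusionSchedule]:
    """Read a trace CSV, returning the gaze trace and the occlusion schedule.

    Malformed input is rejected: missing columns raise :class:`SchemaError`;
    empty files and non-monotone timestamps raise :class:`DataError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    for col in ("t_s", "left_x_mm", "right_x_mm"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataError(f"{path}: column {col!r} is not numeric")
    trace = GazeTrace(
        t=df["t_s"].to_numpy(float),
        x_left=df["left_x_mm"].to_numpy(float),
        x_right=df["right_x_mm"].to_numpy(float),
        valid_left=df["left_valid"].to_numpy() != 0,
        valid_right=df["right_valid"].to_numpy() != 0,
    )
    schedule = _schedule_from_labels(trace.t, df["covered_eye"].astype(str),
                                     trace.duration)
    return trace, schedule


def write_trace(path: str | Path, trace: GazeTrace,
                schedule: OcclusionSchedule) -> None:
    """Write a trace and schedule to the trace CSV format (lossless floats)."""
    covered = schedule.covered_at(trace.t)
    df = pd.DataFrame({
        "t_s": trace.t,
        "left_x_mm": trace.x_left,
        "right_x_mm": trace.x_right,
        "left_valid": trace.valid_left.astype(int),
        "right_valid": trace.valid_right.astype(int),
        "covered_eye": covered,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def _schedule_from_labels(t: np.ndarray, labels: Sequence[str],
                          duration: float) -> OcclusionSchedule:
    """Reconstruct segments from per-sample covered-eye labels.

    A segment starts at the first sample carrying its label and ends where
    the next label begins (the final segment ends at `duration`, half-open).
    """
    labels = np.asarray(labels, dtype=object)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    segs = []
    for i, s in enumerate(starts):
        t_start = float(t[s])
        t_end = float(t[starts[i + 1]]) if i + 1 < len(starts) else float(
            max(duration, t[-1]) or t[-1])
        if t_end <= t_start:  # single trailing sample
            t_end = t_start + (t[1] - t[0] if len(t) > 1 else 1.0)
        segs.append(Segment(t_start, t_end, str(labels[s])))
    occ = next((s.t_end - s.t_start for s in segs if s.covered_eye != NONE),
               1.0)
    return OcclusionSchedule(segs, cycle_period=2.0 * occ,
                             occlusion_duration=occ)


def clean_trace(trace: GazeTrace, max_gap: float = 0.2) -> GazeTrace:
    """Drop invalid samples and log the gaps this (or dropout) leaves behind.

    Samples flagged invalid for either eye are removed rather than
    interpolated — the fixed-period sine fit tolerates irregular sampling,
    and interpolation would fabricate data during blinks.  Whenever the span
    between consecutive retained samples exceeds one nominal sample interval
    by more than `max_gap` seconds, a ``(start_time, missing_span)`` entry is
    appended to the result's gap log.  Retained sample values are unchanged.
    """
    if not trace.valid_left.any():
        raise UnusableEyeError("left eye has no valid samples")
    if not trace.valid_right.any():
        raise UnusableEyeError("right eye has no valid samples")
    keep = trace.valid_left & trace.valid_right
    if not keep.any():
        raise UnusableEyeError("no sample is valid for both eyes")
    cleaned = GazeTrace(
        t=trace.t[keep],
        x_left=trace.x_left[keep],
        x_right=trace.x_right[keep],
        valid_left=trace.valid_left[keep],
        valid_right=trace.valid_right[keep],
        nominal_rate=trace.nominal_rate,
        duration=trace.duration,
    )
    dt_nominal = 1.0 / trace.nominal_rate
    dts = np.diff(cleaned.t)
    for i in np.flatnonzero(dts - dt_nominal > max_gap):
        cleaned.gaps.append((float(cleaned.t[i]),
                             float(dts[i] - dt_nominal)))
    return cleaned
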