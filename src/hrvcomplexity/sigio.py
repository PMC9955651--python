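"""Core signal containers and plain-text I/O.

Two containers are used throughout the package:

``UniformSignal``
    An evenly sampled waveform (respiration, EDA, resampled tachogram)
    with an explicit sampling rate in Hz.

``EventSeries``
    A physiologically timed interval series: RR intervals in milliseconds,
    or breath intervals (inbreath / outbreath / peak-to-peak) in seconds.
    Event times are seconds from the start of the recording, each event
    stamped at the *end* of its interval.

Interval files are unitless numbers, one per line (an optional single
header line is tolerated); the declared ``kind`` assigns units — RRi in
ms, breath intervals in s.  Long-format results travel as a
``TrialTable`` and round-trip through CSV losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UniformSignal",
    "EventSeries",
    "MeasureResult",
    "TrialTable",
    "read_series",
    "write_results",
    "read_results",
    "INTERVAL_KINDS",
    "WAVEFORM_KINDS",
    "TRIAL_LABELS",
]

#: Interval series kinds and the unit each implies.
INTERVAL_KINDS = {"RRi": "ms", "IN": "s", "OUT": "s", "PP": "s"}
#: Waveform kinds (require a sampling rate on read).
WAVEFORM_KINDS = ("RSP", "EDA", "waveform")
#: The fixed trial labels of the paced-breathing protocol.
TRIAL_LABELS = ("Baseline", "Self", "5", "5.5", "6", "6.5", "7", "RBR")


@dataclass(frozen=True)
class UniformSignal:
    """Evenly sampled signal: ``values`` at rate ``fs`` Hz starting at ``t0`` s."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Length of the sampled span in seconds."""
        return self.values.size / self.fs

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EventSeries:
    """Interval series with event times at the end of each interval.

    ``times`` are strictly increasing seconds; ``intervals[i]`` is the
    duration ending at ``times[i]`` in the unit implied by ``kind``
    (ms for RRi, s for breath intervals).
    """

    times: np.ndarray
    intervals: np.ndarray
    kind: str = "RRi"
    #: when True, times must be the running sum of the intervals; breath
    #: interval series (IN/OUT stamped at peaks/troughs) set this False.
    strict: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intervals", intervals)
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if times.shape != intervals.shape or times.ndim != 1:
            raise ValueError("times and intervals must be 1-D and equal length")
        if np.any(intervals <= 0):
            bad = int(np.argmax(intervals <= 0))
            raise ValueError(f"non-positive interval at index {bad}")
        if times.size > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("event times must be strictly increasing")
            if self.strict:
                # consistency: times[i+1]-times[i] == intervals[i+1] in s
                expected = intervals[1:] * self.unit_scale
                if not np.allclose(dt, expected, rtol=1e-9, atol=1e-9):
                    raise ValueError("times/intervals inconsistent for kind "
                                     f"{self.kind!r}")

    @property
    def unit_scale(self) -> float:
        """Seconds per interval unit (1e-3 for ms, 1 for s)."""
        return 1e-3 if INTERVAL_KINDS[self.kind] == "ms" else 1.0

    @classmethod
    def from_intervals(cls, intervals: Sequence[float], kind: str = "RRi",
                       t0: float = 0.0) -> "EventSeries":
        """Build a series with times as cumulative interval sums from ``t0``."""
        intervals = np.asarray(intervals, dtype=float)
        scale = 1e-3 if INTERVAL_KINDS.get(kind) == "ms" else 1.0
        times = t0 + np.cumsum(intervals) * scale
        return cls(times=times, intervals=intervals, kind=kind)

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class MeasureResult:
    """A single measure evaluation with its parameters and fit diagnostics."""

    measure_id: str
    value: float
    params: Mapping[str, object] = field(default_factory=dict)
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


_TRIAL_COLUMNS = ["participant", "trial", "duration", "measure_id", "value"]


class TrialTable:
    """Long-format results table: one row per (participant, trial, duration, measure).

    ``duration`` is the analysed segment length in minutes; ``trial`` must be
    one of the protocol labels.  The four key columns are unique.
    """

    columns = tuple(_TRIAL_COLUMNS)

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_TRIAL_COLUMNS)
        df = df.loc[:, _TRIAL_COLUMNS].copy()
        df["trial"] = df["trial"].astype(str)
        if len(df):
            df["duration"] = df["duration"].astype(float)
            df["value"] = df["value"].astype(float)
        bad = set(df["trial"]) - set(TRIAL_LABELS)
        if bad:
            raise ValueError(f"unknown trial labels: {sorted(bad)}")
        keys = df[["participant", "trial", "duration", "measure_id"]]
        dup = keys.duplicated()
        if dup.any():
            first = keys[dup].iloc[0].tolist()
            raise ValueError(f"duplicate key row: {first}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[Mapping[str, object]]) -> "TrialTable":
        return cls(pd.DataFrame.from_records(records, columns=_TRIAL_COLUMNS))

    def add_row(self, participant, trial, duration, measure_id, value) -> None:
        row = pd.DataFrame([[participant, str(trial), duration, measure_id, value]],
                           columns=_TRIAL_COLUMNS)
        self.df = TrialTable(pd.concat([self.df, row], ignore_index=True)).df

    def pivot(self, measure_id: str, duration=None) -> pd.DataFrame:
        """Participant x trial matrix for one measure (Friedman-ready)."""
        sel = self.df[self.df["measure_id"] == measure_id]
        if duration is not None:
            sel = sel[sel["duration"] == duration]
        wide = sel.pivot(index="participant", columns="trial", values="value")
        order = [t for t in TRIAL_LABELS if t in wide.columns]
        return wide[order]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        a = _sorted_df(self.df)
        b = _sorted_df(other.df)
        return a.equals(b)


def _sorted_df(df: pd.DataFrame) -> pd.DataFrame:
    return (df.sort_values(["participant", "trial", "duration", "measure_id"])
              .reset_index(drop=True))


def _parse_numeric_lines(path: str) -> np.ndarray:
    """One numeric column per line; tolerate a single non-numeric header line."""
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().split(",")[0].strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise ValueError(
                    f"{path}: non-numeric value {text!r} at line {lineno}")
    return np.asarray(values, dtype=float)


def read_series(path: str, kind: str, fs: float | None = None):
    """Read a one-column text/CSV file as an :class:`EventSeries` or
    :class:`UniformSignal`.

    ``kind`` decides the container and units: interval kinds (``RRi``,
    ``IN``, ``OUT``, ``PP``) produce an EventSeries whose times are the
    cumulative interval sums starting at t0 = 0; waveform kinds require
    ``fs``.
    """
    values = _parse_numeric_lines(path)
    if kind in INTERVAL_KINDS:
        if np.any(values <= 0):
            bad = int(np.argmax(values <= 0)) + 1
            raise ValueError(f"{path}: non-positive interval at line {bad}")
        return EventSeries.from_intervals(values, kind=kind)
    if kind in WAVEFORM_KINDS:
        if fs is None:
            raise ValueError("fs is required for waveform kinds")
        return UniformSignal(values=values, fs=fs)
    raise ValueError(f"unknown series kind {kind!r}")


def write_results(table: TrialTable, path: str) -> None:
    """Write a TrialTable as CSV with fixed column order and deterministic
    row ordering (participant, trial, duration, measure_id)."""
    out = _sorted_df(table.df)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        out.to_csv(fh, index=False, float_format="%.12g")


def read_results(path: str) -> TrialTable:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path, dtype={"trial": str})
    if list(df.columns) != _TRIAL_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    return TrialTable(df)
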