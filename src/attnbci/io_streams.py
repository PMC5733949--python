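"""Recording/marker data model, the simple columnar file format, and streaming.

This module plays the role of the acquisition/communication layer of an
online EEG system, reduced to an in-process model: a continuous multichannel
recording with per-sample timestamps, a stream of labelled event markers,
a marker-triggered ring buffer that emits fixed trial windows only once all
their samples have arrived, and a chunked replay driver that feeds a
recording through any stream consumer as if it were arriving live.

Timestamps are authoritative throughout; sample indices are derived.  The
marker-to-sample rule is causal and deterministic: the onset sample of a
marker is the first sample whose timestamp is >= the marker time.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_MONTAGE",
    "ContinuousRecording",
    "EventMarker",
    "MarkerStream",
    "StreamChunk",
    "StreamBuffer",
    "ReplayReport",
    "FormatError",
    "read_recording",
    "write_recording",
    "replay",
    "onset_sample",
]

#: 24-channel 10/20 montage used by the wireless amplifier this pipeline targets
#: (reference FCz, ground AFz; neither carried as a data row).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "Fz", "F8", "FC1", "FC2", "C3", "Cz", "C4",
    "T7", "T8", "TP9", "TP10", "CP5", "CP1", "CPz", "CP2", "CP6",
    "P3", "Pz", "P4", "O1", "O2",
)


class FormatError(ValueError):
    """Raised when a recording file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class EventMarker:
    """A labelled, time-stamped discrete event (stimulus onset, cue, feedback)."""

    label: str
    time: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError(f"marker time must be finite, got {self.time!r}")


@dataclass
class MarkerStream:
    """Time-ordered sequence of event markers."""

    markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [m.time for m in self.markers]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("marker times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i):
        return self.markers[i]

    def select(self, labels: Iterable[str]) -> "MarkerStream":
        """Markers whose label is in *labels*, preserving order."""
        wanted = set(labels)
        return MarkerStream([m for m in self.markers if m.label in wanted])

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.markers:
            out[m.label] = out.get(m.label, 0) + 1
        return out


@dataclass
class ContinuousRecording:
    """Multichannel voltage time series in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in µV.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per data row.
    start_time
        Timestamp of the first sample, in seconds.  Per-sample timestamps
        are derived as ``start_time + i / fs``.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str] = DEFAULT_MONTAGE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; available: {', '.join(self.channel_labels)}"
            ) from None


def onset_sample(marker_time: float, start_time: float, fs: float) -> int:
    """Index of the first sample whose timestamp is >= ``marker_time``.

    A marker exactly on the grid maps to its own sample; a small numerical
    guard keeps grid-aligned times from rounding up to the next sample.
    May be negative for markers preceding the recording start.
    """
    return int(math.ceil((marker_time - start_time) * fs - 1e-9))


# ---------------------------------------------------------------------------
# Simple columnar format
#
# A single diffable CSV-based text file:
#
#   # attnbci-recording 1
#   # fs: 250.0
#   # start_time: 0.0
#   time,Fp1,Fp2,...          <- channels as columns
#   0.0,1.25,-0.5,...
#   ...
#   # markers
#   label,time
#   left,1.5
#
# Floats are written with repr(), which round-trips bit-exactly.
# ---------------------------------------------------------------------------

_MAGIC = "# attnbci-recording 1"


def write_recording(recording: ContinuousRecording, markers: MarkerStream,
                    path, format: str = "simple"):
    """Write a recording plus markers; the simple format round-trips bit-exactly."""
    if format != "simple":
        raise NotImplementedError(
            f"unsupported write format {format!r}; only 'simple' is supported"
        )
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"# fs: {recording.fs!r}\n")
    buf.write(f"# start_time: {recording.start_time!r}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["time", *recording.channel_labels])
    ts = recording.timestamps
    for i in range(recording.n_samples):
        w.writerow([repr(float(ts[i])), *(repr(float(v)) for v in recording.data[:, i])])
    buf.write("# markers\n")
    w.writerow(["label", "time"])
    for m in markers:
        w.writerow([m.label, repr(float(m.time))])
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())
    return path


def read_recording(path, format: str = "simple"):
    """Read ``(ContinuousRecording, MarkerStream)`` written by :func:`write_recording`.

    Returns a third element, a list of warnings (e.g. markers before the
    recording start are accepted but flagged).
    """
    if format == "xdf":
        raise NotImplementedError(
            "XDF reading is not available in this build; convert to the "
            "simple columnar format (see write_recording)"
        )
    if format != "simple":
        raise NotImplementedError(f"unknown format {format!r}")

    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise FormatError(f"{path}: not a simple-format recording (bad magic line)")

    header: dict[str, str] = {}
    idx = 1
    while idx < len(lines) and lines[idx].startswith("# ") and ":" in lines[idx]:
        key, _, val = lines[idx][2:].partition(":")
        header[key.strip()] = val.strip()
        idx += 1
    try:
        fs = float(header["fs"])
        start_time = float(header["start_time"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from None

    if idx >= len(lines):
        raise FormatError(f"{path}: truncated file, no data table")
    cols = next(csv.reader([lines[idx]]))
    if not cols or cols[0] != "time":
        raise FormatError(f"{path}: data table must start with a 'time' column")
    labels = cols[1:]
    idx += 1

    rows: list[list[float]] = []
    times: list[float] = []
    while idx < len(lines) and lines[idx] != "# markers":
        rec = next(csv.reader([lines[idx]]))
        if len(rec) != len(cols):
            raise FormatError(
                f"{path}: line {idx + 1}: expected {len(cols)} fields, got {len(rec)}"
            )
        try:
            vals = [float(v) for v in rec]
        except ValueError:
            raise FormatError(f"{path}: line {idx + 1}: non-numeric sample") from None
        times.append(vals[0])
        rows.append(vals[1:])
        idx += 1
    if idx >= len(lines):
        raise FormatError(f"{path}: truncated file, missing marker section")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise FormatError(f"{path}: timestamps not strictly increasing")

    idx += 1  # skip "# markers"
    if idx >= len(lines) or next(csv.reader([lines[idx]])) != ["label", "time"]:
        raise FormatError(f"{path}: marker table header missing")
    idx += 1
    markers: list[EventMarker] = []
    for lineno in range(idx, len(lines)):
        if not lines[lineno]:
            continue
        rec = next(csv.reader([lines[lineno]]))
        if len(rec) != 2:
            raise FormatError(f"{path}: line {lineno + 1}: bad marker record {rec!r}")
        try:
            markers.append(EventMarker(rec[0], float(rec[1])))
        except ValueError:
            raise FormatError(f"{path}: line {lineno + 1}: bad marker time") from None

    data = np.array(rows, dtype=np.float64).T if rows else np.empty((len(labels), 0))
    recording = ContinuousRecording(data, fs=fs, channel_labels=labels,
                                    start_time=start_time)
    warnings = [
        f"marker {m.label!r} at t={m.time} precedes recording start ({start_time})"
        for m in markers if m.time < start_time
    ]
    return recording, MarkerStream(markers), warnings


# ---------------------------------------------------------------------------
# Marker-triggered stream buffer and chunked replay
# ---------------------------------------------------------------------------


@dataclass
class StreamChunk:
    """A block of consecutive samples with the timestamp of its first sample."""

    samples: np.ndarray  # channels x k
    first_timestamp: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[1] < 1:
            raise ValueError("chunk must contain at least one sample")


@dataclass
class CompletedTrial:
    """Trial window emitted by the buffer: ``data`` is channels x n_win."""

    marker: EventMarker
    data: np.ndarray
    window: tuple[float, float]


class WindowUnrecoverableError(RuntimeError):
    """The requested trial window extends before the buffered history."""


class StreamBuffer:
    """Ring buffer that emits marker-locked trial windows exactly once.

    Mirrors the communication layer of an online BCI: data stream in
    continuously, but a fixed window ``[marker + t_min, marker + t_max)``
    is cut out and handed downstream only when an event marker of interest
    arrives *and* every sample of its window has been received.  Markers may
    arrive before or after their window's data; samples are selected by
    timestamp, never by arrival order.

    Parameters
    ----------
    fs
        Sampling rate of the incoming stream.
    window
        ``(t_min, t_max)`` seconds relative to the marker, half-open.
    capacity
        Seconds of history retained; must exceed ``|t_min| + t_max``.
    """

    def __init__(self, fs: float, window: tuple[float, float],
                 capacity: float = 10.0):
        t_min, t_max = window
        if not t_min < t_max:
            raise ValueError("window must satisfy t_min < t_max")
        if capacity <= abs(t_min) + abs(t_max):
            raise ValueError(
                f"capacity {capacity} s must exceed |t_min| + t_max = "
                f"{abs(t_min) + abs(t_max)} s"
            )
        self.fs = float(fs)
        self.window = (float(t_min), float(t_max))
        self.n_win = int(round((t_max - t_min) * fs))
        self.capacity_samples = int(round(capacity * fs))
        self._data: np.ndarray | None = None  # channels x buffered
        self._first_ts: float | None = None   # timestamp of _data[:, 0]
        self._dropped_samples = 0
        self._pending: list[EventMarker] = []

    # -- internal -----------------------------------------------------------

    def _trial_bounds(self, marker: EventMarker) -> tuple[int, int]:
        # onset index relative to the first *buffered* sample
        onset = onset_sample(marker.time, self._first_ts, self.fs)
        s0 = onset + int(round(self.window[0] * self.fs))
        return s0, s0 + self.n_win

    def _drain(self) -> list[CompletedTrial]:
        done: list[CompletedTrial] = []
        if self._data is None:
            return done
        still: list[EventMarker] = []
        n_buf = self._data.shape[1]
        for m in self._pending:
            s0, s1 = self._trial_bounds(m)
            if s0 < 0:
                raise WindowUnrecoverableError(
                    f"window for marker {m.label!r} at t={m.time} starts before "
                    f"buffered history (capacity {self.capacity_samples / self.fs} s)"
                )
            if s1 <= n_buf:
                done.append(CompletedTrial(m, self._data[:, s0:s1].copy(), self.window))
            else:
                still.append(m)
        self._pending = still
        return done

    # -- public -------------------------------------------------------------

    def push_chunk(self, chunk: StreamChunk) -> list[CompletedTrial]:
        """Append a chunk of samples; return any trials completed by it."""
        if self._data is None:
            self._data = chunk.samples.copy()
            self._first_ts = float(chunk.first_timestamp)
            self._dropped_samples = 0
        else:
            if chunk.samples.shape[0] != self._data.shape[0]:
                raise ValueError("inconsistent channel count within session")
            expected = self._first_ts + self._data.shape[1] / self.fs
            if abs(chunk.first_timestamp - expected) > 0.5 / self.fs:
                raise ValueError(
                    f"non-contiguous chunk: expected first timestamp ~{expected}, "
                    f"got {chunk.first_timestamp}"
                )
            self._data = np.concatenate([self._data, chunk.samples], axis=1)
        # trim history beyond capacity
        excess = self._data.shape[1] - self.capacity_samples
        if excess > 0:
            self._data = self._data[:, excess:]
            self._first_ts += excess / self.fs
            self._dropped_samples += excess
        return self._drain()

    def push_marker(self, marker: EventMarker) -> list[CompletedTrial]:
        """Register a marker; return its trial immediately if already buffered."""
        self._pending.append(marker)
        return self._drain()

    @property
    def pending(self) -> tuple[EventMarker, ...]:
        return tuple(self._pending)


@dataclass
class ReplayReport:
    """Completion report of a chunked replay."""

    n_samples: int
    n_chunks: int
    n_markers: int
    failure_position: int | None = None


def replay(recording: ContinuousRecording, markers: MarkerStream,
           chunk_size: int,
           sink: Callable[[StreamChunk | EventMarker], None]) -> ReplayReport:
    """Stream a recording through *sink* in chunks, markers interleaved by time.

    Every sample is delivered exactly once and in order; each marker is
    delivered immediately before the first chunk whose first timestamp
    exceeds the marker time (markers beyond the recording end are delivered
    after the last chunk).  With ``chunk_size`` equal to the recording
    length this degenerates to a single batch hand-off.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    ts = recording.timestamps
    mlist = list(markers)
    mi = 0
    n_chunks = 0
    delivered = 0
    for s0 in range(0, recording.n_samples, chunk_size):
        first_ts = float(ts[s0])
        while mi < len(mlist) and mlist[mi].time < first_ts:
            try:
                sink(mlist[mi])
            except Exception as exc:
                raise RuntimeError(
                    f"sink failed on marker {mi} at sample {delivered}"
                ) from exc
            mi += 1
        chunk = StreamChunk(recording.data[:, s0:s0 + chunk_size], first_ts)
        try:
            sink(chunk)
        except Exception as exc:
            raise RuntimeError(f"sink failed at sample {delivered}") from exc
        delivered += chunk.samples.shape[1]
        n_chunks += 1
    while mi < len(mlist):
        sink(mlist[mi])
        mi += 1
    return ReplayReport(n_samples=delivered, n_chunks=n_chunks, n_markers=mi)
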