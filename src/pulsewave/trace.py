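"""Shared signal/event data model and CSV I/O.

Conventions used throughout the package: sample indices are 0-based,
times are in seconds (``t = index / sample_rate_hz``), amplitudes in
millivolts.  Traces are uniformly sampled and gap-free — a missing or
non-numeric cell in an input file is a parse error, never a NaN, because
the downstream detector state machine assumes contiguity.

The on-disk trace format is a plain UTF-8 CSV with one comment line::

    # sample_rate_hz=5000
    ch1,ch2
    0.0,0.0
    ...

Values are written with 17 significant digits so a write/read round trip
is bit-exact for float64 samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SignalTrace",
    "DetectionEvent",
    "BeatAnnotation",
    "EVENT_KINDS",
    "BEAT_LABELS",
    "TraceFormatError",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "write_annotations",
    "index_to_seconds",
]

EVENT_KINDS = ("rise_onset", "peak", "fall_onset", "trough")
BEAT_LABELS = ("normal", "ectopic")

_HEADER_KEY = "sample_rate_hz"


class TraceFormatError(ValueError):
    """The file does not follow the trace CSV layout (e.g. missing header)."""


class TraceParseError(ValueError):
    """A data cell could not be parsed; the message carries the row number."""


def index_to_seconds(index: float, sample_rate_hz: float) -> float:
    """Convert a sample index to seconds (``index / sample_rate_hz``)."""
    return index / sample_rate_hz


@dataclass
class SignalTrace:
    """One channel of uniformly sampled voltage.

    Parameters
    ----------
    samples
        Voltage values in mV; stored as a float64 array.
    sample_rate_hz
        Sampling rate, strictly positive.
    channel_id
        Free-text channel label (becomes the CSV column name).
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_id: str = "ch1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def time_of(self, index: int) -> float:
        """Time in seconds of a sample index."""
        return index_to_seconds(index, self.sample_rate_hz)


@dataclass(frozen=True)
class DetectionEvent:
    """A single landmark emitted by the beat detector."""

    kind: str
    index: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.index < 0:
            raise ValueError("event index must be >= 0")


@dataclass(frozen=True)
class BeatAnnotation:
    """Per-beat annotation: first-peak position and normal/ectopic label.

    ``interval_prev_s`` is the time since the previous beat's first peak;
    it is ``None`` for the first beat of a record.
    """

    peak_index: int
    label: str
    interval_prev_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in BEAT_LABELS:
            raise ValueError(f"unknown beat label {self.label!r}")
        if self.interval_prev_s is not None and not self.interval_prev_s > 0:
            raise ValueError("interval_prev_s must be > 0 when present")


def read_trace(path: str | Path) -> tuple[SignalTrace, ...]:
    """Read one or two channels from a trace CSV.

    Returns one :class:`SignalTrace` per data column, with ``channel_id``
    taken from the column-name row.

    Raises
    ------
    TraceFormatError
        If the ``# sample_rate_hz=...`` header line is missing or malformed.
    TraceParseError
        If a data cell is non-numeric; the message names the 1-based file
        row of the offending cell.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.startswith("#") or _HEADER_KEY not in first:
            raise TraceFormatError(
                f"{path}: missing '# {_HEADER_KEY}=<value>' header line"
            )
        try:
            rate = float(first.split("=", 1)[1].strip())
        except (IndexError, ValueError) as exc:
            raise TraceFormatError(f"{path}: unreadable {_HEADER_KEY} value") from exc
        reader = csv.reader(fh)
        try:
            names = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: missing column-name row") from None
        names = [n.strip() for n in names]
        if not 1 <= len(names) <= 2:
            raise TraceFormatError(
                f"{path}: expected 1 or 2 columns, found {len(names)}"
            )
        columns: list[list[float]] = [[] for _ in names]
        for rownum, row in enumerate(reader, start=3):  # header is rows 1-2
            if not row:
                continue
            if len(row) != len(names):
                raise TraceParseError(
                    f"{path}: row {rownum}: expected {len(names)} cells, got {len(row)}"
                )
            for col, cell in zip(columns, row):
                try:
                    col.append(float(cell))
                except ValueError:
                    raise TraceParseError(
                        f"{path}: row {rownum}: non-numeric cell {cell!r}"
                    ) from None
    return tuple(
        SignalTrace(np.array(col, dtype=np.float64), rate, name)
        for name, col in zip(names, columns)
    )


def write_trace(traces: Sequence[SignalTrace], path: str | Path) -> None:
    """Write one or two traces to the CSV trace format.

    All traces must share the sample rate and length.
    """
    traces = list(traces)
    if not 1 <= len(traces) <= 2:
        raise ValueError(f"expected 1 or 2 traces, got {len(traces)}")
    rate = traces[0].sample_rate_hz
    n = len(traces[0])
    for t in traces[1:]:
        if t.sample_rate_hz != rate:
            raise ValueError(
                f"sample-rate mismatch: {t.sample_rate_hz} != {rate}"
            )
        if len(t) != n:
            raise ValueError(f"length mismatch: {len(t)} != {n}")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_HEADER_KEY}={rate:.17g}\n")
        fh.write(",".join(t.channel_id for t in traces) + "\n")
        data = np.column_stack([t.samples for t in traces])
        for row in data:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def write_annotations(
    annotations: Iterable[BeatAnnotation], sample_rate_hz: float, path: str | Path
) -> None:
    """Export beat annotations as a 3-column CSV (peak_index, time_s, label)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("peak_index,time_s,label\n")
        for a in annotations:
            t = index_to_seconds(a.peak_index, sample_rate_hz)
            fh.write(f"{a.peak_index},{t:.17g},{a.label}\n")
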