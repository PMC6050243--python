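"""Reading, validating, windowing and writing pulse-timestamp trains.

A pulse train is the sequence of times at which a fish emitted an electric
organ discharge (EOD).  Timestamps are stored in seconds from recording
start; all interval analytics convert to milliseconds at the IPI boundary.

File format: plain text, one timestamp (seconds) per row, with optional
``# key=value`` metadata header lines (UTF-8).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "PulseTrain",
    "read_pulse_times",
    "write_pulse_times",
    "extract_window",
    "MIN_EVENT_SPACING_S",
]

#: Events closer than this are treated as duplicates.  The recordings the
#: pipeline targets are digitized at 100 kHz, so 10 µs is the smallest
#: resolvable separation between two distinct pulses.
MIN_EVENT_SPACING_S = 1e-5

_SEXES = frozenset({"M", "F", "unknown"})
_PHASES = frozenset({"resting", "active", "synthetic"})


@dataclass
class PulseTrain:
    """Ordered EOD event times plus recording metadata.

    Parameters
    ----------
    timestamps
        Event times in seconds from recording start, strictly increasing.
    species_label, sex, phase, individual_id
        Free-form provenance metadata; ``sex`` is one of ``M``/``F``/
        ``unknown`` and ``phase`` one of ``resting``/``active``/``synthetic``.
    duration_s
        Recording span in seconds.  Defaults to the last timestamp.
    """

    timestamps: np.ndarray
    species_label: str = ""
    sex: str = "unknown"
    phase: str = "synthetic"
    individual_id: str = ""
    duration_s: float | None = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be a 1-D array")
        if ts.size and ts[0] < 0:
            raise ValueError("timestamps must be non-negative (row 0)")
        diffs = np.diff(ts)
        bad = np.flatnonzero(diffs < MIN_EVENT_SPACING_S)
        if bad.size:
            i = int(bad[0]) + 1
            if diffs[bad[0]] <= 0:
                raise ValueError(
                    f"timestamps not strictly increasing at row {i}: "
                    f"{ts[i - 1]!r} followed by {ts[i]!r}"
                )
            raise ValueError(
                f"timestamps at rows {i - 1} and {i} are closer than "
                f"{MIN_EVENT_SPACING_S} s and count as duplicates"
            )
        self.timestamps = ts
        if self.duration_s is None:
            self.duration_s = float(ts[-1]) if ts.size else 0.0
        elif ts.size and ts[-1] > self.duration_s + 1e-9:
            raise ValueError(
                f"last timestamp {ts[-1]} exceeds duration_s {self.duration_s}"
            )
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")
        if self.phase not in _PHASES:
            raise ValueError(
                f"phase must be one of {sorted(_PHASES)}, got {self.phase!r}"
            )

    @property
    def n_events(self) -> int:
        return int(self.timestamps.size)

    @property
    def span_s(self) -> float:
        """Time between first and last event, in seconds."""
        if self.n_events < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def metadata(self) -> dict[str, str]:
        return {
            "species_label": self.species_label,
            "sex": self.sex,
            "phase": self.phase,
            "individual_id": self.individual_id,
            "duration_s": repr(float(self.duration_s)),
        }


def _parse_metadata(raw: Mapping[str, str]) -> dict:
    meta: dict = {}
    for key in ("species_label", "sex", "phase", "individual_id"):
        if key in raw:
            meta[key] = str(raw[key])
    if "duration_s" in raw:
        meta["duration_s"] = float(raw["duration_s"])
    return meta


def read_pulse_times(path, metadata: Mapping[str, str] | None = None) -> PulseTrain:
    """Read a pulse train from a one-timestamp-per-row text file.

    Lines beginning with ``#`` are metadata headers of the form
    ``# key=value``; explicit ``metadata`` overrides take precedence.
    Raises ``ValueError`` on an empty file or non-monotone timestamps
    (the error names the first offending row).
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            try:
                times.append(float(line.split(",")[0]))
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable timestamp at line {lineno}") from exc
    if not times:
        raise ValueError(f"{path}: no timestamps found")
    meta = _parse_metadata(header)
    if metadata:
        meta.update(_parse_metadata(metadata))
    return PulseTrain(np.asarray(times), **meta)


def write_pulse_times(train: PulseTrain, path) -> None:
    """Write a train to text with microsecond timestamp precision.

    The output is byte-stable: identical trains serialize identically.
    """
    path = Path(path)
    if str(path) == "":
        raise OSError("empty output path")
    buf = io.StringIO()
    for key, value in train.metadata().items():
        buf.write(f"# {key}={value}\n")
    for t in train.timestamps:
        buf.write(f"{t:.6f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def extract_window(train: PulseTrain, start_s: float, length_s: float) -> PulseTrain:
    """Return the events with ``start_s <= t < start_s + length_s``, re-zeroed.

    The half-open convention means adjacent windows never share an event.
    """
    if start_s < 0:
        raise ValueError("window start must be non-negative")
    if length_s <= 0:
        raise ValueError("window length must be positive")
    if start_s + length_s > train.duration_s + 1e-9:
        raise ValueError(
            f"window [{start_s}, {start_s + length_s}) outside recording of "
            f"duration {train.duration_s} s"
        )
    ts = train.timestamps
    sel = ts[(ts >= start_s) & (ts < start_s + length_s)]
    return replace(train, timestamps=sel - start_s, duration_s=float(length_s))
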