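"""Domain types for pulse trains and RR-interval series.

The raw observable a wearable or Holter monitor provides is a train of pulse
(heartbeat) times; all variability metrics are computed on the derived
RR-interval series.  Pulse times are kept in seconds, intervals in
milliseconds — the scales on which recording devices and the noise model
naturally operate.  Conversions between the two are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "DISORDERS",
    "InsufficientDataError",
    "InvalidIntervalError",
    "PulseTrain",
    "RRSeries",
    "SubjectRecord",
    "pulses_to_intervals",
    "intervals_to_pulses",
]

#: Cardiac disorders the screening method targets: premature ventricular
#: contraction, premature atrial contraction, atrial fibrillation.
DISORDERS = ("PVC", "PAC", "AF")


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested computation."""


class InvalidIntervalError(ValueError):
    """Raised when an RR interval is zero or negative."""


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing heartbeat times, in seconds."""

    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or times.size < 2:
            raise InsufficientDataError(
                "insufficient data: a pulse train needs at least 2 pulse times"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError("pulse times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RRSeries:
    """Ordered positive RR intervals, in milliseconds.

    ``start_time`` (seconds) anchors the series on the recording timeline so
    that windowing and reconstruction of pulse times are possible.
    """

    intervals: np.ndarray
    subject_id: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1:
            raise ValueError("intervals must be a 1-D sequence")
        if intervals.size and not np.all(intervals > 0):
            raise InvalidIntervalError("invalid interval: all RR intervals must be > 0")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        """Total covered time span in seconds."""
        return float(self.intervals.sum()) / 1000.0


@dataclass(frozen=True)
class SubjectRecord:
    """An RR series together with per-disorder anomaly fractions.

    ``disorder_ratios`` maps each disorder to the fraction of beats (PVC,
    PAC) or of recording time (AF) affected.  ``dichotomized`` flags a
    subject positive when the fraction exceeds ``threshold`` (default 0.1).
    """

    rr: RRSeries
    disorder_ratios: Mapping[str, float] = field(default_factory=dict)
    threshold: float = 0.1

    def __post_init__(self) -> None:
        for d, r in self.disorder_ratios.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"disorder ratio for {d} must be in [0, 1], got {r}")

    @property
    def dichotomized(self) -> dict[str, int]:
        return {
            d: int(self.disorder_ratios.get(d, 0.0) > self.threshold)
            for d in DISORDERS
        }

    @property
    def subject_id(self) -> str:
        return self.rr.subject_id


def pulses_to_intervals(pulses: PulseTrain) -> RRSeries:
    """Convert pulse times (s) to RR intervals (ms).

    The i-th interval is ``times[i+1] - times[i]``; the series is anchored at
    the first pulse time so the conversion is invertible.
    """
    if len(pulses) < 2:
        raise InsufficientDataError("insufficient data: need at least 2 pulses")
    intervals_ms = np.diff(pulses.times) * 1000.0
    return RRSeries(
        intervals=intervals_ms,
        subject_id=pulses.subject_id,
        start_time=float(pulses.times[0]),
    )


def intervals_to_pulses(rr: RRSeries) -> PulseTrain:
    """Reconstruct pulse times (s) by cumulative summation of intervals (ms).

    Inverse of :func:`pulses_to_intervals` up to floating-point precision.
    """
    if len(rr) < 1:
        raise InsufficientDataError("insufficient data: need at least 1 interval")
    if not np.all(rr.intervals > 0):
        raise InvalidIntervalError("invalid interval: all RR intervals must be > 0")
    times = rr.start_time + np.concatenate(([0.0], np.cumsum(rr.intervals) / 1000.0))
    return PulseTrain(times=times, subject_id=rr.subject_id)
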