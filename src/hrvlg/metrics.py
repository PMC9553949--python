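"""Heart-rate-variability metrics: Hr, Cv, Lv and the ratio Lg = Lv/Cv².

Cv (coefficient of variation) is the global variability of a series — the
standard deviation of RR intervals over their mean — and is sensitive to slow
heart-rate modulation.  Lv (local variation),

    Lv = 3/(n-1) * sum_i ((I_i - I_{i+1}) / (I_i + I_{i+1}))^2,

contrasts each interval only with its neighbour and therefore discounts slow
modulation.  Their ratio Lg = Lv/Cv² depends purely on how intervals are
*arranged*: it is ≪ 1 for a locally regular train whose rate drifts slowly,
1 for a Poisson train, 3/2 for similar intervals in random order, and up to 3
when long and short intervals strictly alternate.  Both Cv and Lv are 0 for a
perfectly regular train, where Lg is undefined.

Conventions (matching the screening protocol this package implements):
standard deviations are population (divide by n); per-subject statistics are
computed in consecutive 10-minute windows after a 10-minute transient and
summarised as the mean of log₁₀ of the per-window values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "VariabilityMetrics",
    "WindowSpec",
    "SubjectSummary",
    "DURATION_MODES",
    "compute_hr",
    "compute_cv",
    "compute_lv",
    "compute_lg",
    "windowed_metrics",
    "aggregate_subject",
    "subject_summary",
]

#: Recording-duration modes and the analysis span (s) each one covers
#: after the transient.
DURATION_MODES = {"1min": 60.0, "10min": 600.0, "1h": 3600.0, "18h": 64800.0}


def _log10_or_none(x: float | None) -> float | None:
    if x is None or x <= 0:
        return None
    return math.log10(x)


@dataclass(frozen=True)
class VariabilityMetrics:
    """Per-window metric values; ``None`` marks an undefined quantity.

    ``lg`` is undefined (None) when ``cv`` is 0; a log₁₀ field is None when
    the underlying metric is 0 or undefined, never −inf.
    """

    hr: float | None
    cv: float | None
    lv: float | None
    lg: float | None
    n_intervals: int

    @property
    def log10_cv(self) -> float | None:
        return _log10_or_none(self.cv)

    @property
    def log10_lv(self) -> float | None:
        return _log10_or_none(self.lv)

    @property
    def log10_lg(self) -> float | None:
        if self.log10_lv is None or self.log10_cv is None:
            return None
        return self.log10_lv - 2.0 * self.log10_cv

    @property
    def defined(self) -> bool:
        """True when the window supports log-scale aggregation of Cv and Lv."""
        return self.log10_cv is not None and self.log10_lv is not None

    @classmethod
    def from_intervals(cls, intervals: np.ndarray) -> "VariabilityMetrics":
        intervals = np.asarray(intervals, dtype=float)
        n = intervals.size
        if n < 2:
            hr = 60000.0 / intervals.mean() if n == 1 else None
            return cls(hr=hr, cv=None, lv=None, lg=None, n_intervals=n)
        hr = 60000.0 / float(intervals.mean())
        cv = _cv(intervals)
        lv = _lv(intervals)
        lg = lv / cv**2 if cv > 0 else None
        return cls(hr=hr, cv=cv, lv=lv, lg=lg, n_intervals=n)


@dataclass(frozen=True)
class WindowSpec:
    """Windowing convention: skip ``transient`` seconds, then cut the next
    ``total_duration`` seconds into consecutive windows of ``window_length``."""

    window_length: float = 600.0
    total_duration: float = 64800.0
    transient: float = 600.0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if self.total_duration < self.window_length:
            raise ValueError("total_duration must be >= window_length")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")


def _require(rr: RRSeries, n_min: int) -> np.ndarray:
    x = np.asarray(rr.intervals, dtype=float)
    if x.size < n_min:
        raise InsufficientDataError(
            f"insufficient data: need at least {n_min} intervals, got {x.size}"
        )
    return x


def _cv(x: np.ndarray) -> float:
    return float(x.std(ddof=0) / x.mean())


def _lv(x: np.ndarray) -> float:
    d = (x[:-1] - x[1:]) / (x[:-1] + x[1:])
    return float(3.0 * np.mean(d**2))


def compute_hr(rr: RRSeries) -> float:
    """Average heart rate in beats per minute: 60000 / mean interval (ms)."""
    x = _require(rr, 1)
    return 60000.0 / float(x.mean())


def compute_cv(rr: RRSeries) -> float:
    """Coefficient of variation: population SD of intervals over their mean."""
    x = _require(rr, 2)
    return _cv(x)


def compute_lv(rr: RRSeries) -> float:
    """Local variation of consecutive intervals (1 for Poisson, 0 if regular)."""
    x = _require(rr, 2)
    return _lv(x)


def compute_lg(rr: RRSeries) -> float | None:
    """Local-global variation ratio Lv/Cv²; ``None`` when Cv = 0 (regular)."""
    x = _require(rr, 2)
    cv = _cv(x)
    if cv == 0:
        return None
    return _lv(x) / cv**2


def windowed_metrics(rr: RRSeries, spec: WindowSpec) -> list[VariabilityMetrics]:
    """Compute metrics in consecutive non-overlapping windows.

    An interval belongs (for Hr and Cv) to the window containing its
    terminal heartbeat.  An adjacent interval pair contributes to Lv in the
    window containing the heartbeat the two intervals share — the first
    interval's terminal beat — so a pair straddling a window edge still
    counts once, in the earlier window.  Windows with fewer than 2 intervals
    are kept in the output but flagged undefined.
    """
    x = _require(rr, 2)
    # beat times (s); beat j terminates interval j-1
    beats = rr.start_time + np.concatenate(([0.0], np.cumsum(x) / 1000.0))
    t0 = rr.start_time + spec.transient
    t_end = min(beats[-1], t0 + spec.total_duration)
    n_windows = int(math.floor((t_end - t0) / spec.window_length + 1e-9))
    if n_windows < 1:
        raise InsufficientDataError(
            "insufficient data: series does not span transient plus one window"
        )
    # terminal beat of interval i (0-based) is beats[i+1]
    terminal = beats[1:]
    win_index = np.floor((terminal - t0) / spec.window_length).astype(int)
    out: list[VariabilityMetrics] = []
    for k in range(n_windows):
        idx = np.flatnonzero(win_index == k)
        nk = idx.size
        if nk < 2:
            hr = 60000.0 / float(x[idx].mean()) if nk else None
            out.append(
                VariabilityMetrics(hr=hr, cv=None, lv=None, lg=None, n_intervals=nk)
            )
            continue
        xk = x[idx]
        hr = 60000.0 / float(xk.mean())
        cv = _cv(xk)
        pair = idx[idx + 1 < x.size]  # pairs sharing a beat inside this window
        d = (x[pair] - x[pair + 1]) / (x[pair] + x[pair + 1])
        lv = float(3.0 * np.mean(d**2))
        lg = lv / cv**2 if cv > 0 else None
        out.append(
            VariabilityMetrics(hr=hr, cv=cv, lv=lv, lg=lg, n_intervals=nk)
        )
    return out


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject metric summary on the log scale, ready for classification."""

    log10_cv: float
    log10_lv: float
    log10_lg: float
    hr: float
    n_windows: int
    subject_id: str = ""
    duration_mode: str = "18h"


# number of leading 10-minute windows each mode aggregates; None = all
_MODE_N_WINDOWS = {"1min": 1, "10min": 1, "1h": 6, "18h": None}


def aggregate_subject(
    metrics: list[VariabilityMetrics],
    duration_mode: str = "18h",
    subject_id: str = "",
) -> SubjectSummary:
    """Summarise per-window metrics for one subject.

    18h/1h modes: mean over windows of log₁₀ of the per-window value (1h uses
    the first six 10-minute windows).  10min/1min modes: the single leading
    window, log-transformed.  The Lg summary is derived as
    summary(log₁₀Lv) − 2·summary(log₁₀Cv).  Windows where Cv or Lv is 0 (log
    undefined) are dropped from every mean so all three summaries refer to
    the same window set.
    """
    if duration_mode not in _MODE_N_WINDOWS:
        raise ValueError(f"unknown duration mode {duration_mode!r}")
    k = _MODE_N_WINDOWS[duration_mode]
    selected = metrics if k is None else metrics[:k]
    valid = [m for m in selected if m.defined]
    n_dropped = len(selected) - len(valid)
    if n_dropped:
        logger.warning(
            "dropping %d window(s) with undefined log metrics for subject %r",
            n_dropped,
            subject_id,
        )
    if not valid:
        raise InsufficientDataError("no valid windows")
    log_cv = float(np.mean([m.log10_cv for m in valid]))
    log_lv = float(np.mean([m.log10_lv for m in valid]))
    return SubjectSummary(
        log10_cv=log_cv,
        log10_lv=log_lv,
        log10_lg=log_lv - 2.0 * log_cv,
        hr=float(np.mean([m.hr for m in valid])),
        n_windows=len(valid),
        subject_id=subject_id,
        duration_mode=duration_mode,
    )


def subject_summary(
    rr: RRSeries,
    duration_mode: str = "18h",
    transient: float = 600.0,
) -> SubjectSummary:
    """Window an RR series and aggregate it per the given duration mode.

    1min/10min modes use a single window of that length taken right after
    the transient; 1h/18h modes use 10-minute windows.  A recording shorter
    than the mode's nominal span is analysed in full (the windows that fit).
    """
    if duration_mode not in DURATION_MODES:
        raise ValueError(f"unknown duration mode {duration_mode!r}")
    span = DURATION_MODES[duration_mode]
    window = 60.0 if duration_mode == "1min" else 600.0
    spec = WindowSpec(window_length=window, total_duration=span, transient=transient)
    return aggregate_subject(
        windowed_metrics(rr, spec), duration_mode, subject_id=rr.subject_id
    )
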