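"""Synthetic pulse-train generators with known Cv/Lv/Lg statistics.

Three constructions have closed-form expectations and serve as oracles:

* gamma-renewal trains (i.i.d. gamma(z, τ) intervals): E[Cv] = 1/√z,
  E[Lv] = 3/(2z+1), hence Lg = 3z/(2z+1) — 1 at the Poisson point z = 1,
  3/2 in the regular limit z → ∞;
* two-state long/short Markov chains over {τ+δ, τ−δ} with switching
  probability p: Cv = δ/τ, Lv = 3p δ²/τ², hence Lg = 3p — 3 for strict
  alternation, 3/2 for random arrangement, ≈0 for rare switching;
* locally regular trains with slow sinusoidal rate modulation, for which
  Lv ≪ Cv² and so Lg ≪ 1.

A labelled synthetic cohort emulates the screening setting: negative
subjects are locally regular modulated trains; premature-contraction-like
(PVC/PAC) subjects have short-beat/compensatory-pause motifs inserted at a
given per-beat rate; fibrillation-like (AF) subjects are low-shape
gamma-renewal trains with the same slow modulation.  The observation-noise
model jitters pulse times with i.i.d. Gaussian noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import PulseTrain, RRSeries, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "GammaRenewalConfig",
    "LongShortConfig",
    "RateModulatedConfig",
    "CohortConfig",
    "ExpectedMetrics",
    "gen_gamma_renewal",
    "gen_long_short",
    "gen_rate_modulated",
    "gen_cohort",
    "jitter_pulses",
    "shuffle_intervals",
    "closed_form_oracle",
]


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class GammaRenewalConfig:
    """Renewal process with gamma-distributed intervals (shape z, scale τ ms).

    z is the regularity parameter: z = 1 is Poisson, large z is near-regular.
    The properly normalised gamma density is used, so the mean interval is zτ.
    """

    z: float
    tau: float = 800.0
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z <= 0 or self.tau <= 0 or self.n < 2:
            raise ConfigError("invalid configuration: need z > 0, tau > 0, n >= 2")


@dataclass(frozen=True)
class LongShortConfig:
    """Two-state Markov chain over long (τ+δ) and short (τ−δ) intervals.

    With probability p the next interval switches state, otherwise repeats;
    long-run occupancy is 1/2 each for p > 0.
    """

    tau: float = 800.0
    delta: float = 100.0
    p: float = 0.5
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta < self.tau:
            raise ConfigError("invalid configuration: need 0 < delta < tau")
        if not 0 <= self.p <= 1:
            raise ConfigError("invalid configuration: need 0 <= p <= 1")
        if self.n < 2:
            raise ConfigError("invalid configuration: need n >= 2")


@dataclass(frozen=True)
class RateModulatedConfig:
    """Locally near-regular train whose mean rate drifts sinusoidally."""

    base_rate: float = 1.25  # beats/s (800 ms mean interval)
    modulation_depth: float = 0.3
    modulation_period: float = 60.0  # s
    local_jitter: float = 0.005  # fractional SD of beat-to-beat noise
    n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.modulation_period <= 0 or self.n < 2:
            raise ConfigError(
                "invalid configuration: need base_rate > 0, period > 0, n >= 2"
            )
        if not 0 <= self.modulation_depth < 1:
            raise ConfigError("invalid configuration: modulation_depth in [0, 1)")
        if self.local_jitter < 0:
            raise ConfigError("invalid configuration: local_jitter >= 0")


def gen_gamma_renewal(cfg: GammaRenewalConfig) -> RRSeries:
    """n i.i.d. gamma(shape z, scale τ) intervals, deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    intervals = rng.gamma(shape=cfg.z, scale=cfg.tau, size=cfg.n)
    # gamma draws can underflow to 0 for very small z; keep intervals positive
    intervals = np.maximum(intervals, 1e-12)
    return RRSeries(intervals=intervals, subject_id=f"gamma_z{cfg.z:g}")


def gen_long_short(cfg: LongShortConfig) -> RRSeries:
    """Markov long/short interval chain; starts in the long state."""
    rng = np.random.default_rng(cfg.seed)
    switches = rng.random(cfg.n - 1) < cfg.p
    # state 0 = long, 1 = short; cumulative parity of switches
    state = np.concatenate(([0], np.cumsum(switches) % 2))
    intervals = np.where(state == 0, cfg.tau + cfg.delta, cfg.tau - cfg.delta)
    return RRSeries(intervals=intervals.astype(float), subject_id=f"ls_p{cfg.p:g}")


def _modulated_intervals(
    rng: np.random.Generator,
    n: int,
    tau_ms: float,
    depth: float,
    period_s: float,
    jitter: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Sequential draw of locally regular intervals with a slow sinusoidal
    modulation of the instantaneous mean interval."""
    eps = rng.standard_normal(n)
    intervals = np.empty(n)
    t = 0.0  # s
    omega = 2.0 * math.pi / period_s
    floor = 0.05 * tau_ms
    for i in range(n):
        mean_i = tau_ms * (1.0 + depth * math.sin(omega * t + phase))
        intervals[i] = max(mean_i * (1.0 + jitter * eps[i]), floor)
        t += intervals[i] / 1000.0
    return intervals


def gen_rate_modulated(cfg: RateModulatedConfig) -> RRSeries:
    """Locally regular pulse train with slowly drifting rate (Lg ≪ 1)."""
    rng = np.random.default_rng(cfg.seed)
    tau_ms = 1000.0 / cfg.base_rate
    intervals = _modulated_intervals(
        rng,
        cfg.n,
        tau_ms,
        cfg.modulation_depth,
        cfg.modulation_period,
        cfg.local_jitter,
    )
    return RRSeries(intervals=intervals, subject_id="rate_modulated")


def jitter_pulses(pulses: PulseTrain, sigma_ms: float, seed: int = 0) -> PulseTrain:
    """Observation-noise model: add i.i.d. Gaussian noise (SD ``sigma_ms``)
    to every pulse time, then re-sort to restore strict ordering.

    Exact ties after sorting are collapsed by an epsilon shift.  Re-sorting
    (rather than discarding inverted pairs) keeps the beat count unchanged.
    """
    if sigma_ms < 0:
        raise ConfigError("invalid configuration: sigma_ms must be >= 0")
    if sigma_ms == 0:
        return pulses
    rng = np.random.default_rng(seed)
    noisy = pulses.times + rng.normal(0.0, sigma_ms / 1000.0, size=len(pulses))
    n_inversions = int(np.sum(np.diff(noisy) <= 0))
    if n_inversions:
        logger.debug(
            "jitter sigma=%g ms inverted %d pulse pair(s); re-sorting",
            sigma_ms,
            n_inversions,
        )
    noisy = np.sort(noisy)
    if np.any(np.diff(noisy) <= 0):  # exact ties: measure zero but possible
        noisy = np.maximum.accumulate(noisy + np.arange(noisy.size) * 1e-9)
    return PulseTrain(times=noisy, subject_id=pulses.subject_id)


def shuffle_intervals(rr: RRSeries, seed: int = 0) -> RRSeries:
    """Random permutation of the intervals: preserves Cv exactly, destroys
    the local arrangement that Lv and Lg measure."""
    rng = np.random.default_rng(seed)
    return RRSeries(
        intervals=rng.permutation(rr.intervals),
        subject_id=rr.subject_id,
        start_time=rr.start_time,
    )


# ---------------------------------------------------------------------------
# labelled cohort


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic screening cohort with per-class generative signatures.

    PVC/PAC-like subjects get premature-beat motifs — one short interval
    (``short_fraction`` of the local mean) immediately followed by a
    compensatory long interval preserving the two-interval sum — inserted at
    a per-beat rate; that rate is recorded as the subject's disorder ratio.
    AF-like subjects are low-shape gamma-renewal trains (persistently
    irregular) with the same slow rate modulation as everyone else.
    """

    n_negative: int = 30
    n_pvc: int = 8
    n_pac: int = 6
    n_af: int = 8
    recording_duration: float = 4200.0  # s, incl. the 600 s transient
    mean_interval_range: tuple[float, float] = (700.0, 950.0)  # ms
    modulation_depth: float = 0.08
    modulation_period: float = 300.0  # s
    local_jitter: float = 0.025
    pvc_rate: float = 0.20
    pvc_short_fraction: float = 0.55
    pac_rate: float = 0.15
    pac_short_fraction: float = 0.70
    af_z: float = 1.5
    negative_premature_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_negative, self.n_pvc, self.n_pac, self.n_af) < 0:
            raise ConfigError("invalid configuration: subject counts must be >= 0")
        for r in (self.pvc_rate, self.pac_rate, self.negative_premature_rate):
            if not 0 <= r <= 1:
                raise ConfigError("invalid configuration: insertion rates in [0, 1]")
        if self.recording_duration <= 0 or self.af_z <= 0:
            raise ConfigError("invalid configuration")
        lo, hi = self.mean_interval_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid configuration: bad mean_interval_range")


def _insert_premature(
    rng: np.random.Generator,
    intervals: np.ndarray,
    rate: float,
    short_fraction: float,
) -> tuple[np.ndarray, float]:
    """Insert short-beat/compensatory-pause motifs in place.

    Each motif rewrites an adjacent interval pair (I_i, I_{i+1}) as
    (s·I_i, I_i + I_{i+1} − s·I_i), keeping the local mean.  Returns the
    modified array and the achieved per-beat motif rate.
    """
    n = intervals.size
    if rate == 0 or n < 3:
        return intervals, 0.0
    out = intervals.copy()
    hits = np.flatnonzero(rng.random(n - 1) < rate)
    used = -2
    n_motifs = 0
    for i in hits:
        if i <= used + 1:  # avoid overlapping the previous motif
            continue
        short = short_fraction * out[i]
        out[i + 1] = out[i] + out[i + 1] - short
        out[i] = short
        used = i
        n_motifs += 1
    return out, n_motifs / n


def _trim_to_duration(intervals: np.ndarray, duration_s: float) -> np.ndarray:
    """Keep intervals up to (and including) the first beat past duration."""
    cum = np.cumsum(intervals)
    idx = np.searchsorted(cum, duration_s * 1000.0)
    return intervals[: min(idx + 1, intervals.size)]


def gen_cohort(cfg: CohortConfig) -> list[SubjectRecord]:
    """Generate the labelled synthetic cohort, deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    records: list[SubjectRecord] = []
    classes = (
        [("NEG", cfg.negative_premature_rate, 0.60, None)] * cfg.n_negative
        + [("PVC", cfg.pvc_rate, cfg.pvc_short_fraction, None)] * cfg.n_pvc
        + [("PAC", cfg.pac_rate, cfg.pac_short_fraction, None)] * cfg.n_pac
        + [("AF", 0.0, 0.0, cfg.af_z)] * cfg.n_af
    )
    for idx, (label, rate, short_frac, af_z) in enumerate(classes):
        tau = rng.uniform(*cfg.mean_interval_range)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        n = int(cfg.recording_duration * 1000.0 / tau * 1.15) + 10
        if af_z is not None:
            # persistently irregular: gamma-renewal with slowly drifting mean
            base = _modulated_intervals(
                rng, n, tau, cfg.modulation_depth, cfg.modulation_period, 0.0, phase
            )
            intervals = rng.gamma(shape=af_z, scale=base / af_z)
            intervals = np.maximum(intervals, 0.02 * tau)
            ratios = {"PVC": 0.0, "PAC": 0.0, "AF": 1.0}
        else:
            intervals = _modulated_intervals(
                rng,
                n,
                tau,
                cfg.modulation_depth,
                cfg.modulation_period,
                cfg.local_jitter,
                phase,
            )
            intervals, achieved = _insert_premature(rng, intervals, rate, short_frac)
            ratios = {"PVC": 0.0, "PAC": 0.0, "AF": 0.0}
            if label == "PAC":
                ratios["PAC"] = achieved
            else:  # premature background in negatives counts as ventricular
                ratios["PVC"] = achieved
        intervals = _trim_to_duration(intervals, cfg.recording_duration)
        rr = RRSeries(intervals=intervals, subject_id=f"S{idx:03d}_{label}")
        records.append(SubjectRecord(rr=rr, disorder_ratios=ratios))
    return records


# ---------------------------------------------------------------------------
# closed forms


class ExpectedMetrics(NamedTuple):
    cv: float
    lv: float
    lg: float


def closed_form_oracle(process: str, **params: float) -> ExpectedMetrics:
    """Analytic (Cv, Lv, Lg) for the two tractable processes.

    ``gamma_renewal`` (parameter z): (1/√z, 3/(2z+1), 3z/(2z+1)).
    ``long_short`` (parameters p, tau, delta): (δ/τ, 3p δ²/τ², 3p).
    """
    if process == "gamma_renewal":
        z = float(params["z"])
        if z <= 0:
            raise ConfigError("invalid configuration: z > 0 required")
        return ExpectedMetrics(
            cv=1.0 / math.sqrt(z), lv=3.0 / (2.0 * z + 1.0), lg=3.0 * z / (2.0 * z + 1.0)
        )
    if process == "long_short":
        p = float(params["p"])
        tau = float(params.get("tau", 800.0))
        delta = float(params.get("delta", 100.0))
        if not (0 <= p <= 1 and 0 < delta < tau):
            raise ConfigError("invalid configuration for long_short")
        r = delta / tau
        return ExpectedMetrics(cv=r, lv=3.0 * p * r**2, lg=3.0 * p)
    raise ConfigError(f"unsupported process {process!r}")
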