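"""Decision-zone classification in the (log₁₀Lv, log₁₀Lg) plane.

A disorder's decision zone is the region  log₁₀Lv > a  AND  log₁₀Lg > b
(or < b); premature contractions (short/long alternation, Lg near 3) sit
above the Lg threshold while fibrillation (randomly arranged intervals,
Lg ≤ 3/2) sits below it.  Zone parameters are selected by exhaustive grid
search maximising the Matthews correlation coefficient (MCC), the balanced
confusion-matrix score used throughout.  Single-metric thresholding on
log₁₀Cv or log₁₀Lv is provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateLabelsError",
    "DecisionZone",
    "ConfusionCounts",
    "classify_zone",
    "classify_single_metric",
    "confusion",
    "rates",
    "mcc",
    "optimize_zone",
    "optimize_single_threshold",
    "ZoneResult",
    "ThresholdResult",
]


class DegenerateLabelsError(ValueError):
    """Raised when a cohort has only one class for the requested disorder."""


@dataclass(frozen=True)
class DecisionZone:
    """Two-constraint decision region for one disorder.

    Membership is strict:  log₁₀Lv > a  and  log₁₀Lg > b  when
    ``direction == "greater"`` (``< b`` for ``"less"``); boundary points are
    negative.
    """

    disorder: str
    a: float
    b: float
    direction: str = "greater"

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")

    def contains(self, log10_lv: float, log10_lg: float) -> bool:
        if log10_lv <= self.a:
            return False
        if self.direction == "greater":
            return log10_lg > self.b
        return log10_lg < self.b

    def to_dict(self) -> dict:
        return {
            "disorder": self.disorder,
            "a": self.a,
            "b": self.b,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionZone":
        return cls(
            disorder=str(d["disorder"]),
            a=float(d["a"]),
            b=float(d["b"]),
            direction=str(d.get("direction", "greater")),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_tn, self.n_fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_tn + self.n_fn


def classify_zone(summary, zone: DecisionZone) -> bool:
    """True iff the subject's summary point lies inside the decision zone.

    An undefined Lg (regular pulsation) classifies as negative with a logged
    flag; an undefined log₁₀Lv is an error.
    """
    lv = summary.log10_lv
    lg = summary.log10_lg
    if lv is None:
        raise ValueError("metric unavailable: log10_lv undefined")
    if lg is None:
        logger.info("undefined Lg for %r: classified negative",
                    getattr(summary, "subject_id", None))
        return False
    return zone.contains(lv, lg)


def classify_single_metric(summary, metric: str, threshold: float) -> bool:
    """Positive iff the named metric (log10_cv or log10_lv) exceeds threshold."""
    if metric not in ("log10_cv", "log10_lv"):
        raise ValueError(f"unsupported metric {metric!r}")
    value = getattr(summary, metric)
    if value is None:
        raise ValueError(f"metric unavailable: {metric} undefined")
    return value > threshold


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate binary predictions against binary labels."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("misaligned inputs: predictions and labels differ in length")
    return ConfusionCounts(
        n_tp=int(np.sum(pred & lab)),
        n_fp=int(np.sum(pred & ~lab)),
        n_tn=int(np.sum(~pred & ~lab)),
        n_fn=int(np.sum(~pred & lab)),
    )


def rates(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(TPR, TNR); an undefined rate (empty class) is returned as None."""
    tpr = c.n_tp / (c.n_tp + c.n_fn) if (c.n_tp + c.n_fn) else None
    tnr = c.n_tn / (c.n_tn + c.n_fp) if (c.n_tn + c.n_fp) else None
    return tpr, tnr


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    num = c.n_tp * c.n_tn - c.n_fp * c.n_fn
    den = (
        (c.n_tp + c.n_fp)
        * (c.n_tp + c.n_fn)
        * (c.n_tn + c.n_fp)
        * (c.n_tn + c.n_fn)
    )
    if den == 0:
        return 0.0
    return num / np.sqrt(den)


# ---------------------------------------------------------------------------
# MCC-maximising parameter selection


class ZoneResult(NamedTuple):
    zone: DecisionZone
    mcc: float


class ThresholdResult(NamedTuple):
    threshold: float
    mcc: float


def _grid(values: np.ndarray, step: float, pad: float) -> np.ndarray:
    lo = np.floor((values.min() - pad) / step) * step
    hi = np.ceil((values.max() + pad) / step) * step
    return np.arange(lo, hi + step / 2, step)


def _mcc_matrix(tp, fp, tn, fn):
    """Vectorised MCC over arrays of confusion counts (0 where degenerate)."""
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / np.sqrt(den[ok])
    return out


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise DegenerateLabelsError(
            "degenerate labels: need at least one positive and one negative subject"
        )


def optimize_zone(
    summaries: Sequence,
    labels: Sequence[int],
    disorder: str = "",
    step: float = 0.01,
    pad: float = 0.05,
) -> ZoneResult:
    """Exhaustive grid search for the MCC-maximising zone (a, b, direction).

    The grids cover the observed metric ranges padded by ``pad`` at
    resolution ``step``.  Ties are broken deterministically: smaller a, then
    smaller \\|b\\|, then direction "greater".
    """
    lv = np.asarray([s.log10_lv for s in summaries], dtype=float)
    lg = np.asarray([s.log10_lg for s in summaries], dtype=float)
    y = np.asarray(labels, dtype=float)
    if lv.shape != y.shape:
        raise ValueError("misaligned inputs: summaries and labels differ in length")
    _check_labels(y)

    a_grid = _grid(lv, step, pad)
    b_grid = _grid(lg, step, pad)
    A = (lv[None, :] > a_grid[:, None]).astype(float)  # (na, n)
    Bg = (lg[None, :] > b_grid[:, None]).astype(float)  # (nb, n)

    best: tuple[float, float, float, int] | None = None  # mcc, a, |b|, dir-rank
    best_zone: DecisionZone | None = None
    n_pos = y.sum()
    n = y.size
    for rank, direction in enumerate(("greater", "less")):
        B = Bg if direction == "greater" else 1.0 - Bg
        tp = (A * y) @ B.T  # (na, nb)
        pp = A @ B.T
        fp = pp - tp
        fn = n_pos - tp
        tn = n - pp - fn
        m = _mcc_matrix(tp, fp, tn, fn)
        # deterministic tie-break within this direction
        flat = np.round(m, 12)
        top = flat.max()
        ia, ib = np.argwhere(flat == top)[0][0], None
        cand = np.argwhere(flat == top)
        # smallest a first (rows ascending), then smallest |b|
        rows = cand[:, 0]
        min_row = rows.min()
        in_row = cand[rows == min_row]
        ib = in_row[np.argmin(np.abs(b_grid[in_row[:, 1]])), 1]
        ia = min_row
        key = (-top, a_grid[ia], abs(b_grid[ib]), rank)
        if best is None or key < best:
            best = key
            best_zone = DecisionZone(
                disorder=disorder,
                a=float(a_grid[ia]),
                b=float(b_grid[ib]),
                direction=direction,
            )
    assert best is not None and best_zone is not None
    return ZoneResult(zone=best_zone, mcc=float(-best[0]))


def optimize_single_threshold(
    summaries: Sequence,
    labels: Sequence[int],
    metric: str = "log10_lv",
    step: float = 0.01,
    pad: float = 0.05,
) -> ThresholdResult:
    """1-D analogue of :func:`optimize_zone` for a single metric threshold.

    Ties are broken toward the smallest threshold.
    """
    if metric not in ("log10_cv", "log10_lv"):
        raise ValueError(f"unsupported metric {metric!r}")
    x = np.asarray([getattr(s, metric) for s in summaries], dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("misaligned inputs: summaries and labels differ in length")
    _check_labels(y)
    grid = _grid(x, step, pad)
    P = (x[None, :] > grid[:, None]).astype(float)
    tp = P @ y
    pp = P.sum(axis=1)
    fp = pp - tp
    fn = y.sum() - tp
    tn = y.size - pp - fn
    m = np.round(_mcc_matrix(tp, fp, tn, fn), 12)
    i = int(np.argmax(m))  # argmax returns the first (smallest threshold)
    return ThresholdResult(threshold=float(grid[i]), mcc=float(m[i]))
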