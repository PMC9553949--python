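"""Independent reference implementations used as test oracles.

Deliberately naive (explicit loops, textbook formulas) so they stay
independent of the vectorised code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_cv(x) -> float:
    """Population SD over mean, written out longhand."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return math.sqrt(var) / mean


def naive_lv(x) -> float:
    """Term-by-term local variation."""
    x = list(map(float, x))
    n = len(x)
    total = 0.0
    for i in range(n - 1):
        total += ((x[i] - x[i + 1]) / (x[i] + x[i + 1])) ** 2
    return 3.0 * total / (n - 1)


def batch_se(intervals, stat, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of a statistic via contiguous batch means."""
    x = np.asarray(intervals, dtype=float)
    batches = np.array_split(x, n_batches)
    vals = np.array([stat(b) for b in batches])
    return float(vals.std(ddof=1) / math.sqrt(n_batches))


def brute_force_zone(lv, lg, labels, a_grid, b_grid):
    """Exhaustive loop over (a, b, direction) maximising MCC.

    Tie-break: higher MCC, then smaller a, then smaller |b|, then
    direction 'greater'.  Returns (a, b, direction, mcc).
    """
    lv = np.asarray(lv)
    lg = np.asarray(lg)
    labels = np.asarray(labels, dtype=bool)
    best = None
    for rank, direction in enumerate(("greater", "less")):
        for a in a_grid:
            for b in b_grid:
                if direction == "greater":
                    pred = (lv > a) & (lg > b)
                else:
                    pred = (lv > a) & (lg < b)
                tp = int(np.sum(pred & labels))
                fp = int(np.sum(pred & ~labels))
                tn = int(np.sum(~pred & ~labels))
                fn = int(np.sum(~pred & labels))
                den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                m = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
                key = (-round(m, 12), a, abs(b), rank)
                if best is None or key < best[0]:
                    best = (key, (float(a), float(b), direction, round(m, 12)))
    return best[1]
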