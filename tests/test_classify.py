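"""Decision zones, confusion statistics, MCC, and parameter optimisation."""

from types import SimpleNamespace

import numpy as np
import pytest

from hrvlg.classify import (
    ConfusionCounts,
    DecisionZone,
    DegenerateLabelsError,
    classify_single_metric,
    classify_zone,
    confusion,
    mcc,
    optimize_single_threshold,
    optimize_zone,
    rates,
)

from oracles import brute_force_zone


def point(lv, lg, cv=0.0):
    return SimpleNamespace(log10_lv=lv, log10_lg=lg, log10_cv=cv, subject_id="x")


class TestZoneMembership:
    def test_af_zone(self):
        zone = DecisionZone("AF", a=-1.3, b=0.15, direction="less")
        assert classify_zone(point(-0.5, 0.0), zone) is True
        assert classify_zone(point(-0.5, 0.3), zone) is False

    def test_pvc_zone(self):
        zone = DecisionZone("PVC", a=-1.3, b=0.14, direction="greater")
        assert classify_zone(point(-0.5, 0.3), zone) is True

    def test_low_lv_always_negative(self):
        for zone in (
            DecisionZone("PVC", -1.3, 0.14, "greater"),
            DecisionZone("AF", -1.3, 0.15, "less"),
        ):
            assert classify_zone(point(-3.0, 0.0), zone) is False

    def test_boundary_is_negative(self):
        zone = DecisionZone("PVC", a=-1.0, b=0.2, direction="greater")
        assert classify_zone(point(-1.0, 0.5), zone) is False
        assert classify_zone(point(-0.5, 0.2), zone) is False

    def test_undefined_lg_classified_negative(self):
        zone = DecisionZone("PVC", a=-1.0, b=0.2)
        assert classify_zone(point(-0.5, None), zone) is False

    def test_undefined_lv_is_error(self):
        zone = DecisionZone("PVC", a=-1.0, b=0.2)
        with pytest.raises(ValueError, match="metric unavailable"):
            classify_zone(point(None, 0.0), zone)

    def test_single_metric_threshold(self):
        assert classify_single_metric(point(-0.5, 0, cv=-1.0), "log10_cv", -1.5)
        assert not classify_single_metric(point(-0.5, 0, cv=-1.0), "log10_cv", -0.5)


class TestConfusionAndScores:
    def test_confusion_counting(self):
        c = confusion([1, 1, 1], [1, 0, 0])
        assert (c.n_tp, c.n_fp, c.n_tn, c.n_fn) == (1, 2, 0, 0)

    def test_confusion_perfect_and_inverted(self):
        assert confusion([1, 1, 0, 0], [1, 1, 0, 0]) == ConfusionCounts(2, 0, 2, 0)
        assert confusion([1, 0], [0, 1]) == ConfusionCounts(0, 1, 0, 1)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError, match="misaligned"):
            confusion([1, 0], [1])

    def test_rates(self):
        assert rates(ConfusionCounts(2, 0, 2, 0)) == (1.0, 1.0)
        assert rates(ConfusionCounts(1, 4, 4, 3)) == (0.25, 0.5)
        tpr, tnr = rates(ConfusionCounts(0, 1, 1, 0))
        assert tpr is None

    def test_mcc_values(self):
        assert mcc(ConfusionCounts(2, 0, 2, 0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(0, 2, 0, 2)) == pytest.approx(-1.0)
        assert mcc(ConfusionCounts(50, 10, 40, 0)) == pytest.approx(
            2000 / np.sqrt(60 * 50 * 50 * 40), abs=1e-9
        )

    def test_mcc_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 0, 3, 0)) == 0.0

    def test_mcc_symmetries(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            swapped = ConfusionCounts(int(tn), int(fn), int(tp), int(fp))
            inverted = ConfusionCounts(int(fp), int(tp), int(fn), int(tn))
            assert mcc(swapped) == pytest.approx(mcc(c), abs=1e-12)
            assert mcc(inverted) == pytest.approx(-mcc(c), abs=1e-12)


def planted_cohort(n=200, a=-1.0, b=0.2, seed=0, gap=0.0075):
    """Points uniform in the plane, pushed off thin strips around the planted
    boundaries so a 0.01 grid can separate the classes exactly; sentinel
    points at the strip edges pin the separating zone down to one grid step."""
    rng = np.random.default_rng(seed)
    lv = rng.uniform(-3.0, 0.3, size=n - 4)
    lg = rng.uniform(-1.0, 1.0, size=n - 4)

    def push(v, edge):
        lo, hi = edge - 2 * gap, edge + gap
        inside = (v > lo) & (v < hi)
        v[inside] = np.where(v[inside] < edge, lo, hi)
        return v

    lv, lg = push(lv, a), push(lg, b)
    # pin each boundary from both sides
    lv = np.append(lv, [a - 2 * gap, a + gap, a + 0.5, a + 0.5])
    lg = np.append(lg, [b + 0.5, b + 0.5, b - 2 * gap, b + gap])
    labels = ((lv > a) & (lg > b)).astype(int)
    pts = [point(l, g) for l, g in zip(lv, lg)]
    return pts, labels


class TestOptimization:
    def test_zone_parameter_recovery(self):
        """Grid search recovers a planted (a, b, greater) zone with MCC 1."""
        pts, labels = planted_cohort(seed=11)
        result = optimize_zone(pts, labels, "PVC")
        assert result.mcc == pytest.approx(1.0)
        assert result.zone.direction == "greater"
        assert abs(result.zone.a - (-1.0)) <= 0.01 + 1e-9
        assert abs(result.zone.b - 0.2) <= 0.01 + 1e-9

    def test_zone_recovery_less_direction(self):
        rng = np.random.default_rng(2)
        lv = rng.uniform(-2.0, 0.0, 150)
        lg = np.concatenate([rng.uniform(-0.9, 0.05, 75), rng.uniform(0.25, 0.9, 75)])
        labels = ((lv > -1.3) & (lg < 0.1)).astype(int)
        assert 0 < labels.sum() < len(labels)
        result = optimize_zone([point(l, g) for l, g in zip(lv, lg)], labels)
        assert result.zone.direction == "less"
        assert result.mcc == pytest.approx(1.0)

    def test_degenerate_labels_rejected(self):
        pts, _ = planted_cohort(n=20, seed=3)
        with pytest.raises(DegenerateLabelsError):
            optimize_zone(pts, np.zeros(20, dtype=int))
        with pytest.raises(DegenerateLabelsError):
            optimize_single_threshold(pts, np.ones(20, dtype=int))

    def test_zone_beats_single_lv_threshold(self):
        """The zone family contains pure-Lv rules, so its optimum dominates."""
        rng = np.random.default_rng(7)
        pts = [point(l, g) for l, g in zip(rng.normal(-1, 0.8, 120),
                                           rng.normal(0, 0.4, 120))]
        labels = (rng.random(120) < 0.3).astype(int)
        labels[:2] = [0, 1]
        zone = optimize_zone(pts, labels)
        thr = optimize_single_threshold(pts, labels, "log10_lv")
        assert zone.mcc >= thr.mcc - 1e-12

    def test_matches_brute_force_enumeration(self):
        """Vectorised grid search equals the exhaustive loop oracle."""
        rng = np.random.default_rng(19)
        for trial in range(3):
            n = 40
            lv = np.round(rng.uniform(-2.0, 0.0, n), 2)
            lg = np.round(rng.uniform(-0.5, 0.5, n), 2)
            labels = (rng.random(n) < 0.4).astype(int)
            labels[:2] = [0, 1]
            pts = [point(l, g) for l, g in zip(lv, lg)]
            res = optimize_zone(pts, labels, step=0.05, pad=0.05)
            a_grid = np.arange(
                np.floor((lv.min() - 0.05) / 0.05) * 0.05,
                np.ceil((lv.max() + 0.05) / 0.05) * 0.05 + 0.025,
                0.05,
            )
            b_grid = np.arange(
                np.floor((lg.min() - 0.05) / 0.05) * 0.05,
                np.ceil((lg.max() + 0.05) / 0.05) * 0.05 + 0.025,
                0.05,
            )
            a, b, direction, m = brute_force_zone(lv, lg, labels, a_grid, b_grid)
            assert res.mcc == pytest.approx(m, abs=1e-9)
            assert res.zone.direction == direction
            assert res.zone.a == pytest.approx(a, abs=1e-9)
            assert res.zone.b == pytest.approx(b, abs=1e-9)

    def test_single_threshold_separable(self):
        pts = [point(v, 0.0, cv=v) for v in [-2.0, -1.8, -1.6, 0.0, 0.2, 0.4]]
        labels = [0, 0, 0, 1, 1, 1]
        thr = optimize_single_threshold(pts, labels, "log10_lv")
        assert thr.mcc == pytest.approx(1.0)
        assert -1.6 <= thr.threshold < 0.0

    def test_single_threshold_recovers_bayes_boundary(self):
        """Two overlapping Gaussians: optimum near the midpoint crossing."""
        rng = np.random.default_rng(23)
        n = 1000
        x = np.concatenate([rng.normal(-1.0, 0.2, n // 2),
                            rng.normal(0.0, 0.2, n // 2)])
        labels = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
        pts = [point(v, 0.0) for v in x]
        thr = optimize_single_threshold(pts, labels, "log10_lv")
        assert abs(thr.threshold - (-0.5)) < 0.05
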