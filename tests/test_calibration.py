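"""Matching, accuracy curves, breakpoint fitting, recovery and size limit."""

import itertools
import warnings

import numpy as np
import pytest

from twpscope import calibration as cal
from twpscope.morphometry import Particle, ParticleTable


def make_table(centroids_um, mfds_um, px=1.5):
    parts = [
        Particle(
            id=i + 1, area_um2=100.0, perimeter_um=30.0, fd_um=m * 1.3, mfd_um=m,
            circularity=0.8, centroid_x_um=float(x), centroid_y_um=float(y),
            bbox=(0, 0, 1, 1), pixel_count=10,
        )
        for i, ((x, y), m) in enumerate(zip(centroids_um, mfds_um))
    ]
    return ParticleTable(particles=parts, pixel_size_um=px)


def test_identical_tables_match_perfectly():
    tab = make_table([(10, 10), (50, 80), (200, 30)], [20, 40, 60])
    m = cal.match_particles(tab, tab, max_dist_um=20)
    assert m.n_matched == 3
    assert m.missed_ref_ids == [] and m.false_positive_ids == []
    pairs = cal.accuracy_pairs(tab, tab, m)
    assert all(p.accuracy_pct == pytest.approx(100.0) for p in pairs)


def test_detections_beyond_radius_never_match():
    ref = make_table([(10, 10)], [20])
    det = make_table([(100, 100)], [20])
    m = cal.match_particles(ref, det, max_dist_um=20)
    assert m.n_matched == 0
    assert m.missed_ref_ids == [1]
    assert m.false_positive_ids == [1]


def test_greedy_matching_equals_exhaustive_optimum_on_small_case():
    """3 references, 2 detections in range: greedy nearest-centroid picks
    the assignment an exhaustive search over all one-to-one maps finds."""
    ref_xy = [(0.0, 0.0), (10.0, 0.0), (30.0, 0.0)]
    det_xy = [(1.0, 0.0), (12.0, 0.0)]
    ref = make_table(ref_xy, [20, 20, 20])
    det = make_table(det_xy, [20, 20])
    m = cal.match_particles(ref, det, max_dist_um=15)
    assert m.n_matched == 2
    assert m.missed_ref_ids == [3]
    # exhaustive: all injective maps det -> ref, minimal total distance
    best = None
    for perm in itertools.permutations(range(3), 2):
        cost = sum(
            np.hypot(ref_xy[r][0] - det_xy[d][0], ref_xy[r][1] - det_xy[d][1])
            for d, r in enumerate(perm)
        )
        if best is None or cost < best[0]:
            best = (cost, perm)
    got = {(r, d + 1) for r, d, _ in [(p[0], p[1] - 1, p[2]) for p in m.pairs]}
    want = {(perm_r + 1, d + 1) for d, perm_r in enumerate(best[1])}
    assert got == want


def test_loess_of_constant_accuracy_is_flat():
    pairs = [cal.AccuracyPair(x, x) for x in np.linspace(10, 200, 40)]
    curve = cal.accuracy_curve(pairs, 0.75)
    assert np.allclose(curve["accuracy_pct"], 100.0, atol=1e-6)


def test_loess_tracks_noiseless_piecewise_curve():
    xs = np.linspace(5, 120, 120)
    acc = np.where(xs >= 25, 90.0, 90.0 - 4.0 * (25 - xs))
    pairs = [cal.AccuracyPair(x, x * a / 100) for x, a in zip(xs, acc)]
    curve = cal.accuracy_curve(pairs, 0.3)
    far = curve["reference_mfd_um"] > 45
    assert np.allclose(curve.loc[far, "accuracy_pct"], 90.0, rtol=0.01)


def test_loess_handles_duplicate_x():
    pairs = [cal.AccuracyPair(50.0, 45.0)] * 10 + [cal.AccuracyPair(60.0, 55.0)] * 10
    curve = cal.accuracy_curve(pairs)
    assert len(curve) > 0


def test_loess_span_validation():
    pairs = [cal.AccuracyPair(x, x) for x in np.linspace(10, 100, 20)]
    with pytest.raises(ValueError):
        cal.accuracy_curve(pairs, 0.0)


def test_breakpoint_recovered_from_synthetic_hinge():
    rng = np.random.default_rng(1)
    x = rng.uniform(10, 200, 101)
    acc = np.where(x >= 25, 90.0, 90.0 - 4.0 * (25 - x)) + rng.normal(0, 2, x.size)
    pairs = [cal.AccuracyPair(float(a), float(a * v / 100)) for a, v in zip(x, acc)]
    fit = cal.fit_breakpoint(pairs)
    assert fit.converged
    assert fit.breakpoint_um == pytest.approx(25.0, abs=3.0)
    assert fit.plateau_pct == pytest.approx(90.0, abs=2.0)
    assert abs(fit.slope_post) < 0.05
    assert fit.slope_pre > 2.0


def test_pure_line_is_flagged_degenerate():
    x = np.linspace(10, 100, 30)
    pairs = [cal.AccuracyPair(float(a), float(a * (50 + a) / 100)) for a in x]
    fit = cal.fit_breakpoint(pairs)
    assert fit.converged
    assert fit.degenerate


def test_plateau_only_data_is_flagged_degenerate():
    x = np.linspace(30, 200, 40)
    pairs = [cal.AccuracyPair(float(a), float(a * 0.9)) for a in x]
    fit = cal.fit_breakpoint(pairs)
    assert fit.converged
    assert fit.degenerate
    assert abs(fit.slope_pre) < 0.05 or abs(fit.slope_post) < 0.05


def test_recovery_perfect_detection_is_100_everywhere():
    truth = [np.array([10, 20, 40, 80.0])] * 3
    curve = cal.recovery_curve(truth, truth, np.array([5.0, 15, 35]))
    assert np.allclose(curve.mean_pct, 100.0)
    assert np.allclose(curve.sd_pct, 0.0)


def test_recovery_arithmetic_17_of_20():
    truth = [np.full(20, 50.0)]
    det = [np.full(17, 50.0)]
    curve = cal.recovery_curve(truth, det, np.array([35.0]))
    assert curve.mean_pct[0] == pytest.approx(85.0)


def test_recovery_nondecreasing_when_only_small_particles_missed():
    rng = np.random.default_rng(2)
    truth = [rng.uniform(10, 100, 50) for _ in range(3)]
    det = [t[t >= 35.0] for t in truth]
    curve = cal.recovery_curve(truth, det, np.array([10.0, 20, 30, 40, 50]))
    assert (np.diff(curve.mean_pct) >= -1e-9).all()


def test_recovery_scale_invariance():
    truth = [np.r_[np.full(10, 20.0), np.full(10, 60.0)]]
    det = [np.r_[np.full(7, 20.0), np.full(9, 60.0)]]
    c1 = cal.recovery_curve(truth, det, np.array([10.0, 40.0]))
    c2 = cal.recovery_curve(
        [np.tile(truth[0], 2)], [np.tile(det[0], 2)], np.array([10.0, 40.0])
    )
    assert np.allclose(c1.mean_pct, c2.mean_pct)


def test_recovery_threshold_without_truth_is_dropped():
    truth = [np.array([20.0, 30.0])]
    det = [np.array([20.0, 30.0])]
    with pytest.warns(UserWarning, match="dropped"):
        curve = cal.recovery_curve(truth, det, np.array([10.0, 50.0]))
    assert list(curve.thresholds_um) == [10.0]


def test_size_limit_rule_selects_first_threshold_reaching_80():
    curve = cal.RecoveryCurve(
        thresholds_um=np.array([25.0, 35.0, 45.0]),
        mean_pct=np.array([70.0, 85.0, 90.0]),
        sd_pct=np.zeros(3), se_pct=np.zeros(3), n_replicates=np.full(3, 3),
    )
    assert cal.select_size_limit(curve, 80.0) == 35.0


def test_size_limit_none_when_never_reached():
    curve = cal.RecoveryCurve(
        thresholds_um=np.array([25.0, 35.0]),
        mean_pct=np.array([50.0, 60.0]),
        sd_pct=np.zeros(2), se_pct=np.zeros(2), n_replicates=np.full(2, 3),
    )
    with pytest.warns(UserWarning, match="never reaches"):
        assert cal.select_size_limit(curve, 80.0) is None


def test_size_limit_first_point_qualifying():
    curve = cal.RecoveryCurve(
        thresholds_um=np.array([10.0, 20.0]),
        mean_pct=np.array([82.0, 90.0]),
        sd_pct=np.zeros(2), se_pct=np.zeros(2), n_replicates=np.full(2, 3),
    )
    assert cal.select_size_limit(curve, 80.0) == 10.0


def test_diagnostic_plots_are_written(tmp_path):
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 150, 60)
    acc = np.where(x >= 25, 90.0, 90.0 - 4 * (25 - x)) + rng.normal(0, 2, 60)
    pairs = [cal.AccuracyPair(float(a), float(a * v / 100)) for a, v in zip(x, acc)]
    fit = cal.fit_breakpoint(pairs)
    cal.plot_accuracy(pairs, tmp_path / "accuracy.png", fit=fit)
    curve = cal.recovery_curve(
        [x], [x[x >= 30]], np.array([10.0, 20, 30, 40])
    )
    cal.plot_recovery(curve, tmp_path / "recovery.png")
    assert (tmp_path / "accuracy.png").stat().st_size > 0
    assert (tmp_path / "recovery.png").stat().st_size > 0
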