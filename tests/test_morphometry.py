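"""Component labelling, adjustable watershed and particle measurement."""

import numpy as np
import pytest

from twpscope import morphometry as mm
from twpscope.geometry import boundary_corner_points

from conftest import disc_mask


def dumbbell(r=20, sep=30, shape=(80, 110)):
    """Two fused discs of radius r with centres sep apart.

    For r=20, sep=30 the neck half-width is sqrt(r^2 - (sep/2)^2) ~ 13.2 px,
    so each distance basin is ~6.8 px deep relative to the saddle.
    """
    c = shape[0] // 2
    m = disc_mask(shape, (c, 35), r) | disc_mask(shape, (c, 35 + sep), r)
    return m


def test_label_empty_mask_has_zero_components():
    assert mm.label_components(np.zeros((5, 5), bool)).max() == 0


def test_diagonal_pixels_are_one_component_under_8_connectivity():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    assert mm.label_components(mask).max() == 1


def test_n_disjoint_discs_get_n_labels():
    mask = np.zeros((100, 100), bool)
    centers = [(20, 20), (20, 70), (70, 20), (70, 70), (45, 45)]
    for c in centers:
        mask |= disc_mask(mask.shape, c, 8)
    assert mm.label_components(mask).max() == len(centers)


def test_watershed_leaves_single_convex_disc_alone():
    mask = disc_mask((60, 60), (30, 30), 20)
    out = mm.adjustable_watershed(mask, 3.0)
    assert mm.label_components(out).max() == 1
    assert np.array_equal(out, mask)


def test_watershed_splits_fused_dumbbell_at_tolerance_3():
    mask = dumbbell()
    out = mm.adjustable_watershed(mask, 3.0)
    assert mm.label_components(out).max() == 2


def test_watershed_merges_dumbbell_above_basin_depth():
    mask = dumbbell()  # basin depth ~6.8 px
    out = mm.adjustable_watershed(mask, 8.0)
    assert mm.label_components(out).max() == 1


def test_watershed_never_adds_foreground():
    rng = np.random.default_rng(3)
    for _ in range(10):
        mask = np.zeros((70, 70), bool)
        for _ in range(rng.integers(1, 5)):
            mask |= disc_mask(mask.shape, rng.integers(10, 60, 2), rng.integers(4, 14))
        out = mm.adjustable_watershed(mask, 3.0)
        assert not (out & ~mask).any()


def test_watershed_split_line_loss_is_bounded():
    mask = dumbbell()
    out = mm.adjustable_watershed(mask, 3.0)
    removed = int(mask.sum() - out.sum())
    # one split of a neck ~27 px across: at most one line of that length
    assert 0 < removed <= 30


@pytest.mark.parametrize("w,h", [(10, 4), (30, 30), (50, 7)])
def test_rectangle_measurements_are_analytic(w, h):
    mask = np.zeros((h + 10, w + 10), bool)
    mask[5 : 5 + h, 5 : 5 + w] = True
    table = mm.measure_particles(mm.label_components(mask), 1.0)
    p = table.particles[0]
    assert p.mfd_um == pytest.approx(min(w, h), abs=1.0)
    assert p.fd_um == pytest.approx(np.hypot(w, h), abs=1.0)
    assert p.area_um2 == w * h


def test_digital_disc_is_nearly_circular():
    mask = disc_mask((130, 130), (65, 65), 50)
    table = mm.measure_particles(mm.label_components(mask), 1.0)
    p = table.particles[0]
    assert p.circularity >= 0.95
    assert p.fd_um == pytest.approx(100, abs=2)
    assert p.mfd_um == pytest.approx(100, abs=2)


def test_fd_equals_brute_force_on_random_shapes():
    rng = np.random.default_rng(5)
    for _ in range(10):
        mask = np.zeros((50, 50), bool)
        for _ in range(rng.integers(1, 3)):
            mask |= disc_mask(mask.shape, rng.integers(12, 38, 2), rng.integers(3, 10))
        table = mm.measure_particles(mm.label_components(mask), 1.0)
        for p in table.particles:
            sl = np.s_[p.bbox[0] : p.bbox[2], p.bbox[1] : p.bbox[3]]
            pts = boundary_corner_points(mask[sl])
            d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=2)
            assert p.fd_um == pytest.approx(np.sqrt(d2.max()), abs=1e-9)


def test_single_pixel_particle_convention():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    p = mm.measure_particles(mm.label_components(mask), 1.5).particles[0]
    assert p.fd_um == p.mfd_um == 1.5


def test_disc_circularity_stays_near_one_across_diameters():
    for r in (5, 15, 40, 60):
        mask = disc_mask((2 * r + 10,) * 2, (r + 5, r + 5), r)
        p = mm.measure_particles(mm.label_components(mask), 1.0).particles[0]
        assert 0.95 <= p.circularity <= 1.0


def test_circularity_decreases_with_rectangle_aspect():
    circs = []
    for w in (10, 40, 120):
        mask = np.zeros((20, w + 10), bool)
        mask[5:15, 5 : 5 + w] = True
        circs.append(
            mm.measure_particles(mm.label_components(mask), 1.0).particles[0].circularity
        )
    assert circs[0] > circs[1] > circs[2]


def test_measurement_invariance_to_translation_and_rotation():
    mask = np.zeros((80, 80), bool)
    mask[20:50, 30:42] = True
    base = mm.measure_particles(mm.label_components(mask), 1.0).particles[0]
    shifted = np.roll(np.roll(mask, 17, axis=0), -9, axis=1)
    rotated = np.rot90(mask)
    for variant in (shifted, rotated):
        p = mm.measure_particles(mm.label_components(variant), 1.0).particles[0]
        assert p.fd_um == pytest.approx(base.fd_um, abs=1.0)
        assert p.mfd_um == pytest.approx(base.mfd_um, abs=1.0)
        assert p.area_um2 == base.area_um2


def test_filter_window_semantics():
    mask = np.zeros((40, 260), bool)
    # three squares of side 13, 23 and 240/... -> mFDs 13, 23, 30 px = um
    mask[5:18, 5:18] = True
    mask[5:28, 40:63] = True
    mask[5:35, 90:250] = True
    table = mm.measure_particles(mm.label_components(mask), 1.0)
    assert sorted(round(p.mfd_um) for p in table.particles) == [13, 23, 30]
    out = mm.filter_particles(table, 23.0, 2000.0)  # min bound inclusive
    assert len(out) == 2
    assert out.n_before_filter == 3
    empty = mm.filter_particles(table, 500.0, 2000.0)
    assert len(empty) == 0 and empty.n_before_filter == 3
    # [0, inf) is the identity window
    assert len(mm.filter_particles(table, 0.0, float("inf"))) == 3
    with pytest.raises(ValueError):
        mm.filter_particles(table, 100.0, 50.0)


def test_particle_table_csv_roundtrip(tmp_path, small_scene_table):
    table = mm.filter_particles(small_scene_table, 35.0, 2000.0)
    path = table.write_csv(tmp_path / "particles.csv")
    back = mm.ParticleTable.read_csv(path)
    assert len(back) == len(table)
    assert back.pixel_size_um == table.pixel_size_um
    assert back.min_mfd_um == 35.0
    assert back.n_before_filter == table.n_before_filter
    for a, b in zip(table.particles, back.particles):
        assert a.mfd_um == pytest.approx(b.mfd_um)
        assert a.bbox == b.bbox
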