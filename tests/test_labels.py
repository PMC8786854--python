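import numpy as np
import pytest
from scipy import ndimage, stats

from axonseg import labels
from axonseg.core import BACKGROUND, BORDER, FIBER, STRUCT8, ClassMap, GrayImage, InstanceMap


def square_mask(size=10, at=(10, 10), shape=(40, 40), label=1):
    m = np.zeros(shape, dtype=np.int32)
    m[at[0]:at[0] + size, at[1]:at[1] + size] = label
    return InstanceMap(m)


# ---------------------------------------------------------------------------
# instance_to_classmap


def test_classmap_empty_mask_is_all_background():
    cm = labels.instance_to_classmap(InstanceMap(np.zeros((8, 8), np.int32)), 2)
    assert (cm.classes == BACKGROUND).all()


def test_classmap_square_border_ring_counts():
    """10x10 square, border width 1: 100 fiber px and a 44-px dilation ring."""
    cm = labels.instance_to_classmap(square_mask(10), border_width=1)
    assert (cm.classes == FIBER).sum() == 100
    # brute-force ring: 12x12 dilated square minus the 10x10 interior
    assert (cm.classes == BORDER).sum() == 12 * 12 - 10 * 10


def test_classmap_partition_sums_to_image_size(fiber_fixture):
    _, mask = fiber_fixture
    cm = labels.instance_to_classmap(mask, 2)
    counts = np.bincount(cm.classes.ravel(), minlength=3)
    assert counts.sum() == mask.labels.size
    assert (cm.classes[mask.labels > 0] == FIBER).all()


def test_classmap_close_instances_keep_fiber_separation():
    """Two instances 2 px apart: border bands meet, fiber pixels never touch."""
    m = np.zeros((30, 40), np.int32)
    m[10:20, 5:15] = 1
    m[10:20, 17:27] = 2  # gap columns 15-16
    cm = labels.instance_to_classmap(InstanceMap(m), border_width=2)
    assert (cm.classes[:, 15:17] != FIBER).all()
    fiber1 = cm.classes == FIBER
    grown1 = ndimage.binary_dilation(m == 1, STRUCT8)
    assert not (grown1 & (m == 2)).any()  # fiber supports non-adjacent
    assert (cm.classes[10:20, 15:17] == BORDER).all()  # bands meet in the gap


# ---------------------------------------------------------------------------
# shape scores


def test_circularity_disk_is_near_one():
    from skimage.draw import disk

    m = np.zeros((80, 80), np.int32)
    rr, cc = disk((40, 40), 30.5)
    m[rr, cc] = 1
    fs = labels.shape_score(InstanceMap(m), 1)
    assert 0.95 <= fs.circularity <= 1.05
    assert fs.area == (m == 1).sum()


def test_circularity_square_near_analytic_value():
    # continuous square: C = pi/4; the Crofton estimator underestimates the
    # perimeter of axis-aligned shapes, biasing C high by up to ~0.12
    fs = labels.shape_score(square_mask(20), 1)
    assert abs(fs.circularity - np.pi / 4) < 0.12


def test_elongation_lowers_score_at_fixed_area():
    rect = np.zeros((80, 80), np.int32)
    rect[10:16, 10:70] = 1  # 60x6 = 360 px
    sq = np.zeros((80, 80), np.int32)
    sq[10:29, 10:29] = 1  # 19x19 = 361 px
    s_rect = labels.shape_score(InstanceMap(rect), 1)
    s_sq = labels.shape_score(InstanceMap(sq), 1)
    assert s_rect.score < s_sq.score


def test_circularity_decreases_with_aspect_ratio():
    """Rectangles of ~fixed area and growing aspect ratio: C strictly falls."""
    cs = []
    for h, w in [(24, 24), (16, 36), (12, 48), (8, 72), (6, 96)]:
        m = np.zeros((120, 120), np.int32)
        m[10:10 + h, 10:10 + w] = 1
        cs.append(labels.shape_score(InstanceMap(m), 1).circularity)
    assert all(a > b for a, b in zip(cs, cs[1:]))


def test_shape_score_missing_label_fails(fiber_fixture):
    _, mask = fiber_fixture
    with pytest.raises(ValueError, match="not present"):
        labels.shape_score(mask, 9999)


# ---------------------------------------------------------------------------
# tile sampling


def _two_disks(r1=10, r2=None):
    """Two disks with area (hence score) ratio ~3:1; C ~ 1 for both."""
    from skimage.draw import disk

    r2 = r2 if r2 else r1 * np.sqrt(3.0)
    m = np.zeros((120, 220), np.int32)
    rr, cc = disk((60, 50), r1 + 0.5)
    m[rr, cc] = 1
    rr, cc = disk((60, 150), r2 + 0.5)
    m[rr, cc] = 2
    return InstanceMap(m)


def test_fiber_centered_single_instance_degenerate():
    mask = square_mask(10, at=(15, 15), shape=(64, 64))
    img = GrayImage(np.zeros((64, 64), np.uint8))
    specs = labels.sample_tiles(img, mask, "fiber_centered", 5, 32, seed=0)
    assert len(specs) == 5
    assert all(s.source_label == 1 for s in specs)
    assert len({(s.center_row, s.center_col) for s in specs}) == 1


def test_area_based_draw_ratio_follows_scores():
    mask = _two_disks()
    img = GrayImage(np.zeros(mask.shape, np.uint8))
    specs = labels.sample_tiles(img, mask, "area_based", 10_000, 64, seed=42)
    n2 = sum(1 for s in specs if s.source_label == 2)
    n1 = len(specs) - n2
    assert abs(n2 / n1 - 3.0) < 0.15  # within 5% of the 3:1 score ratio
    # repeated draws of the same instance are flagged for augmentation
    assert any(s.augmented for s in specs)


def test_area_based_chi_square_goodness_of_fit(fiber_fixture):
    """Empirical multinomial frequencies match normalized scores (alpha=0.01)."""
    img, mask = fiber_fixture
    scores = {f.label_id: f.score for f in labels.shape_scores(mask)}
    ids = sorted(scores)
    probs = np.array([scores[i] for i in ids])
    probs /= probs.sum()
    specs = labels.sample_tiles(img, mask, "area_based", 10_000, 64, seed=7)
    counts = np.array(
        [sum(1 for s in specs if s.source_label == i) for i in ids]
    )
    res = stats.chisquare(counts, probs * len(specs))
    assert res.pvalue > 0.01


def test_random_sampling_mostly_misses_sparse_fibers():
    """On a mostly-empty field, random tiles usually contain no fiber."""
    from axonseg import imgen

    cfg = imgen.FixtureConfig(
        image_height=512, image_width=512, n_fibers=8,
        radius_range=(5.0, 10.0), clump_fraction=1.0, seed=9,
    )
    img, mask = imgen.generate_fiber_field(cfg)
    assert (mask.labels == 0).mean() > 0.8
    specs = labels.sample_tiles(img, mask, "random", 1000, 64, seed=1)
    empty = sum(
        1 for s in specs
        if not (mask.labels[labels.tile_window(s, mask.shape)] > 0).any()
    )
    assert empty >= 500


def test_instance_strategies_fail_on_empty_mask():
    img = GrayImage(np.zeros((64, 64), np.uint8))
    empty = InstanceMap(np.zeros((64, 64), np.int32))
    for strategy in ("area_based", "fiber_centered"):
        with pytest.raises(ValueError, match="no annotated instances"):
            labels.sample_tiles(img, empty, strategy, 5, 32, seed=0)


def test_tile_windows_clamped_inside_image(fiber_fixture):
    img, mask = fiber_fixture
    for strategy in labels.STRATEGIES:
        for s in labels.sample_tiles(img, mask, strategy, 50, 128, seed=3):
            rs, cs = labels.tile_window(s, img.shape)
            assert 0 <= rs.start and rs.stop <= img.shape[0]
            assert 0 <= cs.start and cs.stop <= img.shape[1]
            assert rs.stop - rs.start == 128 and cs.stop - cs.start == 128


def test_proportional_allocation_scales_with_area_then_caps():
    counts = labels.proportional_allocation([100, 300, 600], 100, cap=45)
    assert counts.tolist() == [10, 30, 45]


# ---------------------------------------------------------------------------
# augmentation


def test_flip_augmentation_emits_four_distinct_variants():
    spec = labels.TileSpec(32, 32, 32, source_label=1)
    out = labels.augment_tile(spec, square_mask(10), "flips")
    assert len(out) == 4
    assert {s.flips for s in out} == set(labels.FLIPS)


def test_center_jitter_centers_inside_instance_support():
    mask = square_mask(40, at=(10, 10), shape=(64, 64))
    spec = labels.TileSpec(30, 30, 16, source_label=1)
    out = labels.augment_tile(spec, mask, "center_jitter", seed=3)
    assert len(out) == 10
    # jittered centers are pixels of the source instance (before clamping
    # the 16-px window, which cannot move them outside the 40-px bbox here)
    for s in out:
        assert mask.labels[s.center_row, s.center_col] == 1
    again = labels.augment_tile(spec, mask, "center_jitter", seed=3)
    assert out == again  # determinism


def test_center_jitter_rejects_small_fiber():
    mask = square_mask(6, at=(20, 20), shape=(64, 64))
    spec = labels.TileSpec(23, 23, 32, source_label=1)
    with pytest.raises(ValueError, match="bounding box"):
        labels.augment_tile(spec, mask, "center_jitter", seed=0)


# ---------------------------------------------------------------------------
# equalization


def test_equalize_constant_tile_unchanged():
    tile = np.full((8, 8), 77, np.uint8)
    assert (labels.equalize_tile(tile) == 77).all()


def test_equalize_two_valued_cdf_mapping():
    tile = np.full((10, 10), 200, np.uint8)
    tile.ravel()[:40] = 10  # 40% at 10, 60% at 200
    eq = labels.equalize_tile(tile)
    assert set(eq.ravel()) == {102, 255}  # round(0.4*255), round(1.0*255)


def test_equalize_idempotent_within_one_bin():
    rng = np.random.default_rng(0)
    tile = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    once = labels.equalize_tile(tile)
    twice = labels.equalize_tile(once)
    h1, _ = np.histogram(once, bins=32, range=(0, 256))
    h2, _ = np.histogram(twice, bins=32, range=(0, 256))
    assert np.abs(h1 - h2).max() <= np.ceil(once.size / 32)


def test_equalize_invariant_to_affine_rescaling():
    rng = np.random.default_rng(1)
    tile = rng.integers(20, 120, (32, 32)).astype(np.uint8)
    rescaled = (tile.astype(np.int32) * 2 + 10).clip(0, 255).astype(np.uint8)
    a = labels.equalize_tile(tile)
    b = labels.equalize_tile(rescaled)
    assert np.abs(a.astype(int) - b.astype(int)).max() <= 1


# ---------------------------------------------------------------------------
# class weights


def test_class_weights_symmetric_case():
    cm = ClassMap(np.repeat(np.array([[0, 1, 2]], np.uint8), 3, axis=0).T)
    w = labels.class_weights([cm])
    assert np.allclose(w, 1.0)


def test_class_weights_inverse_frequency_arithmetic():
    classes = np.zeros((10, 10), np.uint8)
    classes.ravel()[:25] = 1
    classes.ravel()[25:30] = 2  # frequencies 0.70 / 0.25 / 0.05
    w = labels.class_weights([ClassMap(classes)])
    expected = np.array([1 / 0.70, 1 / 0.25, 1 / 0.05])
    expected /= expected.mean()
    assert np.allclose(w, expected)
    assert w.argmax() == BORDER  # rarest class gets the largest weight


def test_class_weights_absent_class_fails():
    classes = np.zeros((4, 4), np.uint8)
    classes[0, 0] = 1
    with pytest.raises(ValueError, match="border"):
        labels.class_weights([ClassMap(classes)])
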