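"""Attention-MIL: tissue detection, bags, forward invariances, aggregation,
training behavior and heatmaps."""

import numpy as np
import pytest

from typiselect.mil import (
    AttentionMILClassifier,
    Bag,
    MILConfig,
    Patch,
    aggregate_slide,
    attention_heatmap,
    bag_loss,
    detect_tissue,
    evaluate_model,
    extract_patches,
    make_bags,
)
from typiselect.synthetic import SlideGeneratorConfig, gen_slide_image


def disk_image(size=200, radius=60, color=(150, 60, 120)):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    img = np.full((size, size, 3), 245, dtype=np.uint8)
    img[disk] = color
    return img, disk


class TestTissueDetection:
    def test_pure_white_image_is_all_background(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert not detect_tissue(img).any()

    def test_colored_disk_is_recovered(self):
        img, disk = disk_image()
        mask = detect_tissue(img)
        iou = (mask & disk).sum() / (mask | disk).sum()
        assert iou >= 0.95

    def test_detection_is_idempotent_on_masked_image(self):
        img, _ = disk_image()
        mask = detect_tissue(img)
        masked = img.copy()
        masked[~mask] = 255
        mask2 = detect_tissue(masked)
        iou = (mask & mask2).sum() / (mask | mask2).sum()
        assert iou >= 0.95

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            detect_tissue(np.zeros((10, 10)))


class TestPatchExtraction:
    def test_returns_all_eligible_when_budget_allows(self):
        img, disk = disk_image(size=256, radius=100)
        mask = detect_tissue(img)
        patches = extract_patches(img, mask, 32, max_patches=5000, seed=0)
        eligible = sum(
            mask[r : r + 32, c : c + 32].mean() >= 0.5
            for r in range(0, 225, 32)
            for c in range(0, 225, 32)
        )
        assert len(patches) == eligible

    def test_budget_caps_sample(self):
        img, disk = disk_image(size=256, radius=100)
        mask = detect_tissue(img)
        patches = extract_patches(img, mask, 32, max_patches=3, seed=0)
        assert len(patches) == 3

    def test_every_patch_meets_tissue_threshold(self):
        img, disk = disk_image(size=256, radius=100)
        mask = detect_tissue(img)
        for p in extract_patches(img, mask, 32, min_tissue_fraction=0.5, seed=1):
            r, c = p.location
            assert mask[r : r + 32, c : c + 32].mean() >= 0.5

    def test_no_eligible_positions_rejected(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(ValueError):
            extract_patches(img, np.zeros((64, 64), dtype=bool), 32)


def _dummy_patches(n, size=8, seed=0):
    g = np.random.default_rng(seed)
    return [
        Patch(
            pixels=g.integers(0, 256, (size, size, 3)).astype(np.uint8),
            slide_id="s",
            location=(0, 0),
        )
        for _ in range(n)
    ]


class TestBags:
    def test_partition_when_enough_patches(self):
        patches = _dummy_patches(500)
        bags = make_bags(patches, n_bags=5, bag_size=100, seed=0)
        ids = [id(p) for b in bags for p in b.patches]
        assert len(ids) == len(set(ids)) == 500

    def test_reuse_across_bags_without_within_bag_duplicates(self):
        patches = _dummy_patches(150)
        bags = make_bags(patches, n_bags=3, bag_size=100, seed=0)
        for b in bags:
            assert len({id(p) for p in b.patches}) == 100

    def test_single_bag_identity(self):
        patches = _dummy_patches(100)
        (bag,) = make_bags(patches, n_bags=1, bag_size=100, seed=0)
        assert {id(p) for p in bag.patches} == {id(p) for p in patches}

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError):
            make_bags(_dummy_patches(5), n_bags=1, bag_size=10)


class TestAggregation:
    def test_geometric_mean_example(self):
        out = aggregate_slide([[0.8, 0.1, 0.1], [0.2, 0.4, 0.4]])
        np.testing.assert_allclose(out, [0.5, 0.25, 0.25], rtol=1e-12)

    def test_single_and_identical_bags_are_identity(self):
        p = np.array([0.7, 0.2, 0.1])
        np.testing.assert_allclose(aggregate_slide([p]), p, rtol=1e-12)
        np.testing.assert_allclose(aggregate_slide([p, p, p]), p, rtol=1e-12)

    def test_matches_naive_geometric_mean_loop(self, rng):
        P = rng.dirichlet(np.ones(3), size=8)
        naive = np.ones(3)
        for row in P:
            naive = naive * row
        naive = naive ** (1 / len(P))
        naive = naive / naive.sum()
        np.testing.assert_allclose(aggregate_slide(P), naive, rtol=1e-10)

    def test_bag_order_invariance(self, rng):
        P = rng.dirichlet(np.ones(3), size=6)
        np.testing.assert_allclose(aggregate_slide(P), aggregate_slide(P[::-1]), rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_slide([])


class TestBagLoss:
    def test_perfect_prediction_is_zero(self):
        assert bag_loss([1.0, 0.0, 0.0], 0) == pytest.approx(0.0)

    def test_uniform_prediction_is_log_k(self):
        assert bag_loss([1 / 3, 1 / 3, 1 / 3], 1) == pytest.approx(np.log(3), rel=1e-12)

    def test_monotone_in_true_class_probability(self):
        losses = [bag_loss([p, (1 - p) / 2, (1 - p) / 2], 0) for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]


class TestMetrics:
    def test_perfect_predictions(self):
        acc, f1, cm = evaluate_model([0, 1, 2], [0, 1, 2], 3)
        assert acc == 1.0 and f1 == 1.0
        np.testing.assert_array_equal(cm, np.eye(3, dtype=int))

    def test_confusion_total_is_n(self):
        _, _, cm = evaluate_model([0, 0, 1, 2, 2], [1, 0, 1, 2, 0], 3)
        assert cm.sum() == 5

    def test_hand_built_nine_slides(self):
        y_true = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        y_pred = [0, 0, 1, 1, 1, 1, 2, 0, 2]
        acc, f1, cm = evaluate_model(y_true, y_pred, 3)
        assert acc == pytest.approx(7 / 9)
        # per-class F1 by hand: c0 p=2/3 r=2/3; c1 p=3/4 r=1; c2 p=1 r=2/3
        f1_hand = np.mean([2 / 3, 2 * (3 / 4) / (3 / 4 + 1), 2 * (2 / 3) / (1 + 2 / 3)])
        assert f1 == pytest.approx(f1_hand)
        np.testing.assert_array_equal(cm, [[2, 1, 0], [0, 3, 0], [1, 0, 2]])


@pytest.fixture(scope="module")
def trained_tiny():
    """A model trained on a small cleanly separable slide set."""
    cfg = SlideGeneratorConfig.separable(image_size=192)
    slides = {}
    for k in range(3):
        for i in range(4):
            img, fg = gen_slide_image(k, False, cfg, seed=50 * k + i)
            slides[f"s{k}_{i}"] = {
                "image": img,
                "fg_mask": fg,
                "label": k,
                "split": "validation" if i == 3 else "train",
            }
    mil_cfg = MILConfig.tiny(n_bags=3, bag_size=12, n_epochs=8, learning_rate=3e-3)
    clf = AttentionMILClassifier(config=mil_cfg, random_state=0).fit(slides)
    return clf, slides, mil_cfg


class TestForward:
    def test_single_patch_bag_has_unit_attention(self, trained_tiny):
        clf, slides, cfg = trained_tiny
        img = slides["s0_0"]["image"]
        patch = Patch(img[:32, :32], "s0_0", (0, 0))
        probs, a = clf.predict_bag([patch])
        np.testing.assert_allclose(a, [1.0])
        assert probs.sum() == pytest.approx(1.0)

    def test_patch_order_permutation_is_exactly_invariant(self, trained_tiny):
        clf, slides, cfg = trained_tiny
        img = slides["s1_0"]["image"]
        patches = [Patch(img[r : r + 32, c : c + 32], "x", (r, c)) for r, c in
                   [(64, 64), (64, 96), (96, 64), (96, 96)]]
        p1, _ = clf.predict_bag(patches)
        p2, _ = clf.predict_bag(patches[::-1])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_duplicating_every_patch_preserves_probabilities(self, trained_tiny):
        clf, slides, cfg = trained_tiny
        img = slides["s2_0"]["image"]
        patches = [Patch(img[r : r + 32, c : c + 32], "x", (r, c)) for r, c in
                   [(64, 64), (64, 96), (96, 64)]]
        p1, _ = clf.predict_bag(patches)
        p2, _ = clf.predict_bag(patches + patches)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_wrong_patch_size_rejected(self, trained_tiny):
        clf, _, _ = trained_tiny
        with pytest.raises(ValueError):
            clf.predict_bag([Patch(np.zeros((16, 16, 3), dtype=np.uint8), "x", (0, 0))])


class TestTraining:
    def test_zero_epochs_rejected(self, trained_tiny):
        _, slides, _ = trained_tiny
        cfg = MILConfig.tiny(n_epochs=0)
        with pytest.raises(ValueError):
            AttentionMILClassifier(config=cfg).fit(slides)

    def test_learning_reduces_validation_loss(self, trained_tiny):
        clf, _, _ = trained_tiny
        assert min(clf.validation_losses_) < clf.validation_losses_[0]

    def test_zero_learning_rate_selects_first_epoch(self, trained_tiny):
        _, slides, _ = trained_tiny
        cfg = MILConfig.tiny(n_bags=2, bag_size=8, n_epochs=3, learning_rate=0.0)
        clf = AttentionMILClassifier(config=cfg, random_state=0).fit(slides)
        np.testing.assert_allclose(
            clf.validation_losses_, clf.validation_losses_[0], rtol=1e-9
        )
        assert clf.selected_epoch_ == 1

    def test_separable_slides_classified_correctly(self, trained_tiny):
        clf, slides, _ = trained_tiny
        test = {}
        cfg = SlideGeneratorConfig.separable(image_size=192)
        for k in range(3):
            for i in range(2):
                img, fg = gen_slide_image(k, False, cfg, seed=1000 + 50 * k + i)
                test[f"t{k}_{i}"] = {"image": img, "label": k}
        pred = clf.predict(test, seed=7)
        truth = np.array([d["label"] for d in test.values()])
        assert (pred == truth).mean() >= 0.9


class TestHeatmap:
    def test_constant_attention_maps_to_zero(self, trained_tiny):
        clf, slides, cfg = trained_tiny
        img = slides["s0_0"]["image"]
        patch = Patch(img[:32, :32], "s0_0", (0, 0))
        bag = Bag("b", "s0_0", [patch])
        heat = attention_heatmap(clf, img.shape[:2], [bag])
        assert heat[:32, :32].max() == 0.0  # single weight min-max normalizes to 0

    def test_max_attention_patch_reaches_one(self, trained_tiny):
        clf, slides, _ = trained_tiny
        img = slides["s0_0"]["image"]
        mask = detect_tissue(img)
        patches = extract_patches(img, mask, 32, seed=0, slide_id="s0_0")
        bags = make_bags(patches, n_bags=2, bag_size=min(10, len(patches)), seed=1)
        heat = attention_heatmap(clf, img.shape[:2], bags)
        assert heat.max() == pytest.approx(1.0)
        assert heat.min() >= 0.0

    def test_png_rendering(self, trained_tiny, tmp_path):
        from typiselect.mil import save_heatmap_png

        clf, slides, _ = trained_tiny
        img = slides["s0_0"]["image"]
        mask = detect_tissue(img)
        patches = extract_patches(img, mask, 32, seed=0)
        bags = make_bags(patches, n_bags=1, bag_size=min(10, len(patches)), seed=1)
        heat = attention_heatmap(clf, img.shape[:2], bags)
        out = tmp_path / "heat.png"
        save_heatmap_png(heat, out, thumbnail=img)
        assert out.stat().st_size > 0
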