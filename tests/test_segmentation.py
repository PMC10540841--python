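import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriface.segmentation import (
    SegModel,
    SegTrainConfig,
    dice,
    iou,
    miou,
    predict_mask,
    split_dataset,
    train_seg,
)
from nutriface.unet import UNet


def _mask(h, w, fg):
    m = np.zeros((h, w), dtype=np.uint8)
    m[fg] = 255
    return m


class TestSplitDataset:
    def test_515_gives_412_103(self):
        train, test = split_dataset(list(range(515)), fraction=0.8, seed=0)
        assert (len(train), len(test)) == (412, 103)
        assert sorted(train + test) == list(range(515))

    def test_seed_changes_partition_not_sizes(self):
        a = split_dataset(list(range(10)), fraction=0.8, seed=1)
        b = split_dataset(list(range(10)), fraction=0.8, seed=2)
        assert (len(a[0]), len(a[1])) == (8, 2) == (len(b[0]), len(b[1]))
        assert set(a[1]) != set(b[1])

    def test_explicit_counts(self):
        train, test = split_dataset(list(range(515)), counts=(381, 134), seed=3)
        assert (len(train), len(test)) == (381, 134)

    def test_wrong_counts_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), counts=(8, 3))

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], fraction=0.8)  # round(1.6)=2 -> empty test

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], fraction=0.5)


class TestOverlapMetrics:
    def test_identical_masks(self):
        m = _mask(10, 10, (slice(2, 5), slice(2, 5)))
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0
        assert miou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _mask(10, 10, (slice(0, 2), slice(0, 2)))
        b = _mask(10, 10, (slice(5, 7), slice(5, 7)))
        assert dice(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_half_overlap_counts(self):
        a = np.zeros((20, 20), dtype=np.uint8)
        b = np.zeros((20, 20), dtype=np.uint8)
        a.ravel()[:100] = 255
        b.ravel()[50:150] = 255
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(50 / 150)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert dice(z, z) == 1.0
        assert iou(z, z) == 1.0

    def test_complement_masks(self):
        a = _mask(2, 2, (0, 0))
        b = 255 - a
        assert iou(a, b) == 0.0

    def test_non_binary_rejected(self):
        a = np.full((4, 4), 3, dtype=np.uint8)
        with pytest.raises(ValueError):
            dice(a, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=100, derandomize=True)
    def test_dice_iou_identity(self, bits_a, bits_b):
        fg_a = (np.array(list(np.binary_repr(bits_a, 16))) == "1").reshape(4, 4)
        fg_b = (np.array(list(np.binary_repr(bits_b, 16))) == "1").reshape(4, 4)
        a, b = _mask(4, 4, fg_a), _mask(4, 4, fg_b)
        d, j = dice(a, b), iou(a, b)
        assert d == pytest.approx(2 * j / (1 + j))
        assert j <= d <= 1.0
        assert d == dice(b, a)


class TestPredictMask:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        net = UNet(base_channels=4, levels=2, seed=0)
        return SegModel(net=net, config=SegTrainConfig(image_size=16))

    def test_threshold_extremes(self, tiny_model, rng):
        face = rng.random((16, 16))
        assert (predict_mask(tiny_model, face, threshold=0.0) == 255).all()
        assert (predict_mask(tiny_model, face, threshold=1.01) == 0).all()

    def test_threshold_monotonicity(self, tiny_model, rng):
        face = rng.random((16, 16))
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            fg = predict_mask(tiny_model, face, threshold=t) == 255
            if prev is not None:
                assert not (fg & ~prev).any()  # raising t never adds pixels
            prev = fg

    def test_output_binary(self, tiny_model, rng):
        out = predict_mask(tiny_model, rng.random((16, 16)))
        assert set(np.unique(out)) <= {0, 255}


class TestTrainSeg:
    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError):
            train_seg([])

    def test_shape_mismatch_rejected(self, rng):
        face = rng.random((16, 16))
        mask = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(ValueError):
            train_seg([(face, mask)])

    def test_non_binary_mask_rejected(self, rng):
        face = rng.random((16, 16))
        mask = np.full((16, 16), 9, dtype=np.uint8)
        with pytest.raises(ValueError):
            train_seg([(face, mask)])

    def test_loss_decreases_and_deterministic(self, rng):
        face = rng.random((32, 32))
        mask = _mask(32, 32, (slice(8, 24), slice(8, 24)))
        cfg = SegTrainConfig(
            epochs=8, learning_rate=1e-3, base_channels=4, levels=2,
            image_size=32, seed=3,
        )
        model1, hist1 = train_seg([(face, mask)], cfg)
        model2, hist2 = train_seg([(face, mask)], cfg)
        assert hist1[-1]["loss"] < hist1[0]["loss"]
        assert hist1 == hist2
        for k in model1.net.params:
            assert np.array_equal(model1.net.params[k], model2.net.params[k])

    def test_validation_history(self, rng):
        face = rng.random((16, 16))
        mask = _mask(16, 16, (slice(4, 12), slice(4, 12)))
        cfg = SegTrainConfig(
            epochs=2, learning_rate=1e-3, base_channels=4, levels=2,
            image_size=16,
        )
        _, hist = train_seg([(face, mask)], cfg, val_pairs=[(face, mask)])
        assert all("val_dice" in row for row in hist)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        face = rng.random((16, 16))
        mask = _mask(16, 16, (slice(4, 12), slice(4, 12)))
        cfg = SegTrainConfig(
            epochs=1, learning_rate=1e-3, base_channels=4, levels=2,
            image_size=16,
        )
        model, _ = train_seg([(face, mask)], cfg)
        path = tmp_path / "seg.npz"
        model.save(path)
        loaded = SegModel.load(path)
        assert loaded.config == model.config
        assert np.array_equal(
            predict_mask(loaded, face), predict_mask(model, face)
        )


class TestTrainingProgress:
    def test_validation_dice_improves_over_epochs(self, seg_fixtures_128):
        """Held-out Dice after 10 epochs beats epoch 1, averaged over seeds."""
        train_pairs = [(img, m) for img, _, m in seg_fixtures_128[:8]]
        val_pairs = [(img, m) for img, _, m in seg_fixtures_128[36:40]]
        first, last = [], []
        for seed in (0, 1, 2):
            cfg = SegTrainConfig(
                epochs=10, learning_rate=5e-4, momentum=0.5, rms_alpha=0.8,
                base_channels=16, levels=3, image_size=128, seed=seed,
            )
            _, hist = train_seg(train_pairs, cfg, val_pairs=val_pairs)
            first.append(hist[0]["val_dice"])
            last.append(hist[-1]["val_dice"])
        assert np.mean(last) >= np.mean(first)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"split_fraction": 0.0},
            {"split_fraction": 1.0},
            {"learning_rate": 0.0},
            {"epochs": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegTrainConfig(**kwargs)
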