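"""Segmenter contracts: soft Dice loss, augmentation, training, inference."""
import numpy as np
import pytest

from echoseg.datatypes import Chamber, View
from echoseg.errors import ModelError, ShapeError
from echoseg.nets import (
    AugmentationPolicy,
    PixelSegmenter,
    SegmenterConfig,
    augment_pair,
    predict_masks,
    soft_dice_loss,
)
from echoseg.phantom import PhantomSpec, make_phantom_frame
from echoseg.stats import dice_score


class TestSoftDiceLoss:
    def test_perfect_prediction_is_zero(self):
        t = (np.random.default_rng(0).random((16, 16)) < 0.3).astype(float)
        assert soft_dice_loss(t, t, smooth=1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_empty_prediction_approaches_one(self):
        t = np.ones((10, 10))
        assert soft_dice_loss(np.zeros((10, 10)), t, smooth=1e-9) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_half_overlapping_squares(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[0:10, 0:10] = 1  # 100 px
        b[0:10, 5:15] = 1  # 100 px, overlap 50
        assert soft_dice_loss(a, b, smooth=1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_in_binary_arguments(self):
        rng = np.random.default_rng(1)
        a = (rng.random((12, 12)) < 0.4).astype(float)
        b = (rng.random((12, 12)) < 0.4).astype(float)
        assert soft_dice_loss(a, b) == pytest.approx(soft_dice_loss(b, a))

    def test_strictly_decreases_with_nested_overlap(self):
        t = np.zeros((20, 20))
        t[5:15, 5:15] = 1
        losses = []
        for k in (2, 5, 8):
            p = np.zeros((20, 20))
            p[5: 5 + k, 5:15] = 1  # growing subset of the target
            losses.append(soft_dice_loss(p, t))
        assert losses[0] > losses[1] > losses[2]

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            soft_dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAugmentation:
    @pytest.fixture()
    def pair(self):
        spec = PhantomSpec(view=View.A2C, image_size=64, pixel_spacing=2.0, seed=0)
        return make_phantom_frame(spec, 0.2)

    def test_deterministic_in_seed(self, pair):
        frame, masks = pair
        policy = AugmentationPolicy(apply_fraction=1.0)
        f1, m1 = augment_pair(frame, masks, policy, seed=9)
        f2, m2 = augment_pair(frame, masks, policy, seed=9)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert all(np.array_equal(m1[ch], m2[ch]) for ch in m1.masks)

    def test_zero_apply_fraction_is_identity(self, pair):
        frame, masks = pair
        f, m = augment_pair(frame, masks, AugmentationPolicy(apply_fraction=0.0), seed=1)
        assert np.array_equal(f.pixels, frame.pixels)

    def test_masks_stay_binary_and_channels_preserved(self, pair):
        frame, masks = pair
        policy = AugmentationPolicy(apply_fraction=1.0)
        for seed in range(6):
            _, m = augment_pair(frame, masks, policy, seed=seed)
            assert set(m.masks) == set(masks.masks)
            for arr in m.masks.values():
                assert arr.dtype == bool

    def test_pure_rotation_preserves_mask_area(self, pair):
        frame, masks = pair
        policy = AugmentationPolicy(
            apply_fraction=1.0, shift_fraction=0.0, zoom_fraction=0.0, shear_max=0.0,
            horizontal_flip=False, crop_size=None, photometric=False,
            rotation_max_deg=10.0,
        )
        before = masks[Chamber.LV].sum()
        _, m = augment_pair(frame, masks, policy, seed=4)
        assert m[Chamber.LV].sum() == pytest.approx(before, rel=0.02)


def _phantom_training_set(n=8, seed=0):
    images, targets = [], []
    for i in range(n):
        spec = PhantomSpec(
            view=View.A2C, image_size=64, pixel_spacing=2.0,
            speckle_strength=0.3, seed=seed + i,
        )
        frame, masks = make_phantom_frame(spec, (i % 8) / 8.0)
        images.append(frame.pixels)
        stack = np.stack(
            [masks[Chamber.LV], masks[Chamber.LA]], axis=-1
        ).astype(float)
        targets.append(stack)
    return images, targets


class TestPixelSegmenter:
    def test_overfit_sanity_on_eight_frames(self):
        """A tiny segmenter overfit on 8 frames reproduces them at Dice >= 0.95."""
        images, targets = _phantom_training_set()
        cfg = SegmenterConfig.tiny((Chamber.LV, Chamber.LA))
        model = PixelSegmenter(cfg)
        model.fit(images, targets, epochs=60, seed=0)
        dices = []
        for img, t in zip(images, targets):
            proba = model.predict_proba(img)
            for c in range(2):
                dices.append(dice_score(proba[..., c] > 0.5, t[..., c] > 0.5))
        assert np.mean(dices) >= 0.95

    def test_training_is_bit_reproducible(self):
        images, targets = _phantom_training_set(4)
        cfg = SegmenterConfig.tiny((Chamber.LV, Chamber.LA))
        r1 = PixelSegmenter(cfg).fit(images, targets, epochs=5, seed=3)
        r2 = PixelSegmenter(cfg).fit(images, targets, epochs=5, seed=3)
        assert np.array_equal(r1.validation_loss, r2.validation_loss)

    def test_untrained_model_raises(self):
        model = PixelSegmenter(SegmenterConfig.tiny((Chamber.LV,)))
        with pytest.raises(ModelError):
            model.predict_proba(np.zeros((64, 64)))

    def test_blank_input_yields_valid_structure(self):
        images, targets = _phantom_training_set(4)
        model = PixelSegmenter(SegmenterConfig.tiny((Chamber.LV, Chamber.LA)))
        model.fit(images, targets, epochs=3, seed=0)
        from echoseg.datatypes import UltrasoundFrame

        blank = UltrasoundFrame(pixels=np.zeros((64, 64)), pixel_spacing=2.0)
        out = predict_masks(model, blank)
        assert set(out.masks) == {Chamber.LV, Chamber.LA}

    def test_exact_half_probability_thresholds_to_background(self):
        """Strict > 0.5 rule: a probability of exactly 0.5 is background."""
        proba = np.full((8, 8), 0.5)
        assert not (proba > 0.5).any()

    def test_wrong_input_size_raises(self):
        images, targets = _phantom_training_set(4)
        model = PixelSegmenter(SegmenterConfig.tiny((Chamber.LV, Chamber.LA)))
        model.fit(images, targets, epochs=2, seed=0)
        from echoseg.datatypes import UltrasoundFrame

        big = UltrasoundFrame(pixels=np.zeros((128, 128)), pixel_spacing=1.0)
        with pytest.raises(ModelError):
            predict_masks(model, big)

    def test_save_load_round_trip(self, tmp_path):
        images, targets = _phantom_training_set(4)
        model = PixelSegmenter(SegmenterConfig.tiny((Chamber.LV, Chamber.LA)))
        model.fit(images, targets, epochs=4, seed=0)
        model.save(tmp_path / "m")
        loaded = PixelSegmenter.load(tmp_path / "m")
        assert np.array_equal(
            loaded.predict_proba(images[0]), model.predict_proba(images[0])
        )
        manifest = (tmp_path / "m" / "manifest.json").read_text()
        assert "W1" in manifest and "chambers" in manifest
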