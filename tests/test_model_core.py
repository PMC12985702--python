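"""Model construction, loss, training contracts, checkpoints, prediction."""

import math

import numpy as np
import pytest

from endobleed import model_core as mc
from endobleed import scene_synth as ss
from endobleed import weak_labels as wl
from endobleed.dataset_io import CuratedSample, normalize
from endobleed.eval_suite import dice_iou

SPEC = mc.ModelSpec(input_size=128)


def _scene(seed=5, frac=0.25, vessel=True, bone=True):
    return ss.make_scene(
        ss.SceneParams(image_size=128, plume_area_frac=frac, vessel_on=vessel,
                       bone_on=bone, seed=seed)
    )


class TestBuildAndPredict:
    def test_forward_shape_and_finiteness(self):
        model = mc.build_model(SPEC, seed=0)
        logits = model.predict_logits(np.zeros((128, 128, 3), dtype=np.uint8))
        assert logits.shape == (128, 128)
        assert np.isfinite(logits).all()

    def test_shape_contract_holds_off_square_sizes(self):
        model = mc.build_model(SPEC, seed=0)
        logits = model.predict_logits(np.zeros((96, 80, 3), dtype=np.uint8))
        assert logits.shape == (96, 80)

    def test_seeded_build_reproducible(self):
        img = _scene().image
        a = mc.build_model(SPEC, seed=3).predict_logits(img)
        b = mc.build_model(SPEC, seed=3).predict_logits(img)
        assert np.array_equal(a, b)
        c = mc.build_model(SPEC, seed=4).predict_logits(img)
        assert not np.array_equal(a, c)

    def test_predict_mask_threshold_strictness(self):
        # logit exactly 0 -> probability 0.5 -> strictly-greater gives False
        probs = mc._sigmoid(np.zeros((4, 4)))
        assert not (probs > 0.5).any()
        # elementwise oracle on random logits
        rng = np.random.default_rng(1)
        z = rng.normal(0, 3, size=(32, 32))
        brute = np.array(
            [[1 / (1 + math.exp(-z[i, j])) > 0.5 for j in range(32)] for i in range(32)]
        )
        assert np.array_equal(mc._sigmoid(z) > 0.5, brute)

    def test_uint8_input_warns_and_predicts(self):
        model = mc.build_model(SPEC, seed=0)
        img = _scene().image
        with pytest.warns(UserWarning):
            warned = mc.predict_mask(model, img)
        silent = mc.predict_mask(model, normalize(img))
        assert np.array_equal(warned, silent)


class TestBceLogitLoss:
    def test_zero_logits_give_ln2(self):
        for t in (np.zeros(10), np.ones(10)):
            assert mc.bce_logit_loss(np.zeros(10), t) == pytest.approx(math.log(2))

    def test_saturated_correct_logits_near_zero(self):
        t = np.array([1.0, 1.0, 0.0, 0.0])
        z = np.array([20.0, 20.0, -20.0, -20.0])
        assert mc.bce_logit_loss(z, t) < 1e-8

    def test_matches_direct_high_precision_formula(self, rng):
        z = rng.normal(0, 4, size=50)
        t = (rng.random(50) > 0.5).astype(float)
        direct = -np.mean(
            [
                ti * math.log(1 / (1 + math.exp(-zi)))
                + (1 - ti) * math.log(1 - 1 / (1 + math.exp(-zi)))
                for zi, ti in zip(z, t)
            ]
        )
        assert mc.bce_logit_loss(z, t) == pytest.approx(direct, rel=1e-10)

    def test_non_binary_targets_rejected(self):
        with pytest.raises(ValueError):
            mc.bce_logit_loss(np.zeros(3), np.array([0.0, 0.5, 1.0]))


class TestCheckpoint:
    def test_round_trip_bit_identical_predictions(self, tmp_path):
        scene = _scene()
        model = mc.build_model(SPEC, seed=2)
        model.fit_scaler(
            mc.extract_features(scene.image, SPEC).reshape(-1, SPEC.n_features)
        )
        before = model.predict_logits(scene.image)
        ckpt = model.checkpoint(epoch=3, monitored=0.5, cfg_hash="x")
        ckpt.save(tmp_path / "m.npz")
        loaded = mc.Checkpoint.load(tmp_path / "m.npz")
        after = mc.PixelSegmenter.from_checkpoint(loaded).predict_logits(scene.image)
        assert np.array_equal(before, after)
        assert loaded.epoch == 3 and loaded.config_hash == "x"


def _tiny_cfg(**kw):
    base = dict(input_size=128, max_epochs=12, pixels_per_image=400, seed=0)
    base.update(kw)
    return mc.TrainConfig(**base)


class TestTrainBase:
    def test_patience_zero_stops_at_first_non_improving_epoch(self):
        scene = _scene()
        mask, _ = wl.weak_label(scene.image)
        pairs = [(scene.image, mask)]
        cfg = _tiny_cfg(patience_base=0, improvement_epsilon=1e9)
        model = mc.build_model(SPEC, seed=0)
        result = mc.train_base(model, pairs, pairs, cfg)
        # epoch 1 always improves over -inf; epoch 2 cannot beat a 1e9 margin
        assert len(result.history) == 2

    def test_best_so_far_column_is_non_increasing(self):
        scene = _scene()
        mask, _ = wl.weak_label(scene.image)
        pairs = [(scene.image, mask)] * 4
        model = mc.build_model(SPEC, seed=0)
        result = mc.train_base(model, pairs, pairs, _tiny_cfg(patience_base=12))
        best = result.history.best_val.to_numpy()
        assert (np.diff(best) <= 0).all()

    def test_single_image_overfit_reaches_high_dice(self):
        """Sanity: the model can fit one frame's weak label almost exactly."""
        scene = _scene(seed=5)
        mask, _ = wl.weak_label(scene.image)
        cfg = mc.TrainConfig(input_size=128, max_epochs=200, patience_base=200,
                             pixels_per_image=1000, seed=0)
        model = mc.build_model(SPEC, seed=0)
        mc.train_base(model, [(scene.image, mask)] * 64, [(scene.image, mask)], cfg)
        pred = mc._sigmoid(model.predict_logits(scene.image)) > 0.5
        assert dice_iou(pred, mask).dice >= 0.95

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            mc.train_base(mc.build_model(SPEC, 0), [], [], _tiny_cfg())


class TestFinetune:
    @staticmethod
    def _base_ckpt():
        scene = _scene(seed=1)
        mask, _ = wl.weak_label(scene.image)
        model = mc.build_model(SPEC, seed=0)
        return mc.train_base(
            model, [(scene.image, mask)] * 2, [(scene.image, mask)], _tiny_cfg(max_epochs=2)
        ).checkpoint

    @staticmethod
    def _curated(source="cur0"):
        scene = _scene(seed=2, vessel=False, bone=False)
        return [
            CuratedSample(scene.image, scene.bleeding_mask, "bleeding_red_mask",
                          "a", source)
        ]

    def test_shared_sources_refused_as_leakage(self):
        gt = [mc.EvalImage(_scene(3).image, [np.zeros((128, 128), bool)], "cur0")]
        with pytest.raises(mc.LeakageError):
            mc.finetune(self._base_ckpt(), self._curated("cur0"), gt, _tiny_cfg())

    def test_flat_metric_stream_stops_at_epoch_eleven(self):
        """Patience 10 with an unreachable improvement margin: 1 improving
        epoch plus 10 flat ones."""
        gt = [mc.EvalImage(_scene(3).image, [np.zeros((128, 128), bool)], "mon0")]
        cfg = _tiny_cfg(max_epochs=50, patience_finetune=10, improvement_epsilon=1e9)
        result = mc.finetune(self._base_ckpt(), self._curated(), gt, cfg)
        assert len(result.history) == 11


class TestTwoStageBehavior:
    def test_finetune_suppresses_distractors_and_keeps_bleeding(self, seed_runs):
        """Zero-mask fine-tuning must cut distractor false positives while
        bleeding-scene Dice stays close to the base model's."""
        from endobleed import pipeline as pl

        run = seed_runs[0]
        study = run["study"]
        fp_base = pl.distractor_fp_area(run["base"].checkpoint, study.distractor_scenes)
        fp_ft = pl.distractor_fp_area(run["ft"].checkpoint, study.distractor_scenes)
        assert fp_ft < fp_base
        d_base = pl.bleeding_dice(run["base"].checkpoint, study.bleeding_scenes)
        d_ft = pl.bleeding_dice(run["ft"].checkpoint, study.bleeding_scenes)
        assert d_base - d_ft <= 0.05
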