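"""Classifier architectures, schedules, and training behaviour."""

import numpy as np
import pytest

from osteostage.model_zoo import (
    ArchSpec,
    TrainConfig,
    build_model,
    default_train_config,
    predict_batch,
    sample_to_input,
    train,
)
from osteostage.nn.layers import BatchNorm, ConvNd
from osteostage.types import BENIGN, MALIGNANT, Sample


class TestArchContracts:
    def test_resnet50_2d_full_width_maps_173_patches_to_probability_pairs(self):
        model = build_model(ArchSpec("resnet50_2d"))
        x = np.random.default_rng(0).random((4, 3, 173, 173), dtype=np.float32)
        p = predict_batch(model, x)
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all() and (p <= 1).all()

    def test_resnet18_3d_accepts_145_cube_with_3x3x3_stem(self):
        model = build_model(ArchSpec("resnet18_3d"))
        assert model.stem_conv.kernel == (3, 3, 3)
        x = np.random.default_rng(1).random((1, 1, 145, 145, 39), dtype=np.float32)
        p = predict_batch(model, x)
        assert p.shape == (1, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_resnext_uses_cardinality_32_grouped_convolutions(self):
        model = build_model(ArchSpec("resnext50_2d_c32", width_mult=0.5))
        grouped = [
            m for blk in model.stages for m in _walk(blk) if isinstance(m, ConvNd) and m.groups > 1
        ]
        assert grouped and all(c.groups == 32 for c in grouped)
        plain = build_model(ArchSpec("resnet50_2d", width_mult=0.5))
        x = np.random.default_rng(2).random((2, 3, 48, 48), dtype=np.float32)
        assert predict_batch(model, x).shape == predict_batch(plain, x).shape == (2, 2)

    def test_resnet50_3d_is_bottleneck_and_deeper_than_18(self):
        m18 = build_model(ArchSpec("resnet18_3d", width_mult=0.25))
        m50 = build_model(ArchSpec("resnet50_3d", width_mult=0.25))
        assert len(m50.params()) > len(m18.params())

    def test_unknown_arch_and_bad_outputs_rejected(self):
        with pytest.raises(ValueError):
            ArchSpec("vgg16")
        with pytest.raises(ValueError):
            ArchSpec("resnet50_2d", n_outputs=3)


def _walk(module):
    yield module
    for v in module.__dict__.values():
        if hasattr(v, "__dict__") and hasattr(v, "params"):
            yield from _walk(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if hasattr(item, "params"):
                    yield from _walk(item)


class TestTrainConfig:
    def test_experiment_presets(self):
        c1 = default_train_config("exp1_2d")
        assert (c1.lr0, c1.lr_drop_factor, c1.lr_drop_every_epochs) == (1e-3, 0.8, 7)
        assert c1.weight_decay == 2e-4 and c1.max_epochs == 100
        c4 = default_train_config("exp4_3d")
        assert (c4.lr0, c4.lr_drop_factor, c4.lr_drop_every_epochs) == (3e-3, 0.85, 5)
        assert c4.early_stop_patience == 10
        c5 = default_train_config("exp5_3d_k")
        assert c5.lr0 == 5e-3 and c5.lr_drop_factor == 0.85
        with pytest.raises(ValueError):
            default_train_config("exp7")

    def test_lr_schedule_closed_form(self):
        c = default_train_config("exp1_2d")
        assert c.lr_at(0) == 1e-3
        assert c.lr_at(6) == 1e-3
        assert c.lr_at(7) == pytest.approx(1e-3 * 0.8)
        for epoch in range(40):
            assert c.lr_at(epoch) == pytest.approx(1e-3 * 0.8 ** (epoch // 7))


def _separable_arrays(n=96, size=24, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros((n, 3, size, size), dtype=np.float32)
    y = []
    for i in range(n):
        lab = i % 2
        x[i] = (0.65 if lab else 0.35) + rng.normal(0, 0.08, size=(3, size, size))
        y.append(MALIGNANT if lab else BENIGN)
    return x, y


class TestTraining:
    def test_one_epoch_history_finite(self):
        x, y = _separable_arrays(n=8, size=16)
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        hist = train(model, x, y, None, None, TrainConfig(max_epochs=1, batch_size=4))
        assert len(hist.train_loss) == 1 and np.isfinite(hist.train_loss[0])

    def test_empty_training_set_rejected(self):
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 3, 16, 16), np.float32), [], None, None, TrainConfig())

    def test_recorded_lr_matches_schedule(self):
        x, y = _separable_arrays(n=8, size=16)
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        cfg = TrainConfig(lr0=1e-2, lr_drop_factor=0.5, lr_drop_every_epochs=2, max_epochs=5)
        hist = train(model, x, y, None, None, cfg)
        assert hist.lr == [1e-2 * 0.5 ** (e // 2) for e in range(5)]

    def test_training_reproducible_for_fixed_seed(self):
        x, y = _separable_arrays(n=16, size=16)
        h = []
        for _ in range(2):
            model = build_model(ArchSpec("resnet50_2d", width_mult=0.125, seed=3))
            h.append(train(model, x, y, None, None, TrainConfig(max_epochs=2, seed=5)))
        assert h[0].train_loss == h[1].train_loss

    def test_early_stopping_halts_within_patience_of_best(self):
        x, y = _separable_arrays(n=32, size=16)
        vx, vy = _separable_arrays(n=16, size=16, seed=1)
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        cfg = TrainConfig(lr0=5e-3, max_epochs=60, early_stop_patience=3, batch_size=8)
        hist = train(model, x, y, vx, vy, cfg)
        n = len(hist.epochs)
        assert n < 60  # stopped early
        assert n - 1 - hist.best_epoch <= cfg.early_stop_patience

    def test_separable_toy_cohort_exceeds_090_within_30_epochs(self):
        x, y = _separable_arrays(n=120, size=24)
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125, seed=1))
        cfg = TrainConfig(lr0=1e-2, max_epochs=30, batch_size=16, seed=0)
        train(model, x[:96], y[:96], x[96:], y[96:], cfg)
        p = predict_batch(model, x[96:])
        acc = np.mean([(pi[1] >= 0.5) == (yi == MALIGNANT) for pi, yi in zip(p, y[96:])])
        assert acc > 0.9


class TestPredictBatch:
    def test_rows_sum_to_one_and_duplicates_identical(self):
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        x = np.random.default_rng(0).random((3, 3, 24, 24), dtype=np.float32)
        xx = np.concatenate([x, x[:1]], axis=0)
        p = predict_batch(model, xx)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(p[0], p[3], atol=1e-7)

    def test_batch_of_one_matches_row_in_larger_batch(self):
        model = build_model(ArchSpec("resnet50_2d", width_mult=0.125))
        x = np.random.default_rng(4).random((5, 3, 24, 24), dtype=np.float32)
        p_all = predict_batch(model, x)
        p_one = predict_batch(model, x[2:3])
        np.testing.assert_allclose(p_one[0], p_all[2], atol=1e-5)


class TestSampleToInput:
    def test_2d_sample_replicated_to_three_channels(self):
        s = Sample(pixels=np.full((10, 12), 100, np.uint8), lesion_id="L", strategy="E'")
        x = sample_to_input(s, target_hw=16)
        assert x.shape == (3, 16, 16)
        np.testing.assert_array_equal(x[0], x[2])
        assert x.max() <= 1.0

    def test_3d_sample_gains_channel_axis(self):
        s = Sample(pixels=np.zeros((9, 9, 5), np.uint8), lesion_id="L", strategy="L")
        assert sample_to_input(s).shape == (1, 9, 9, 5)
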