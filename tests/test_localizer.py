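"""Localizer: configs, early stopping, patch sampling, inference plumbing."""
import numpy as np
import pytest

from pelvimetry import (
    ConfigError,
    DataError,
    HeatmapConfig,
    LandmarkSet,
    LocalizerConfig,
    PreprocessConfig,
    VolumeGrid,
    build_localizer,
    load_checkpoint,
    make_heatmap_targets,
    predict_landmarks,
    sample_training_patch,
    save_checkpoint,
    train,
)
from pelvimetry.geometry import LANDMARK_LABELS
from pelvimetry.heatmap import HeatmapStack
from pelvimetry.localizer import StubHeatmapModel, TrainingHistory, run_early_stopping
from pelvimetry.preprocess import preprocess_volume, voxel_to_physical


def toy_volume_and_landmarks(shape=(32, 32, 8), spacing=(1.5, 1.5, 4.3), seed=0):
    rng = np.random.default_rng(seed)
    vol = VolumeGrid(
        data=rng.normal(0, 0.05, size=shape).astype(np.float32), spacing=spacing
    )
    margin = np.minimum(4, np.asarray(shape) // 4)
    voxels = rng.integers(margin, np.asarray(shape) - margin, size=(5, 3))
    pts = {
        l: voxel_to_physical(v.astype(float), vol) for l, v in zip(LANDMARK_LABELS, voxels)
    }
    return vol, LandmarkSet(pts)


class TestEarlyStopping:
    def test_forced_sequence_stops_after_patience(self):
        losses = [1.0, 0.9] + [0.9] * 50
        stopped, selected = run_early_stopping(losses, patience=50)
        assert stopped == 52
        assert selected == 2

    def test_improving_sequence_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 30))
        stopped, selected = run_early_stopping(losses, patience=5)
        assert (stopped, selected) == (30, 30)

    def test_config_rejects_patience_at_max_epochs(self):
        with pytest.raises(ConfigError):
            LocalizerConfig(max_epochs=10, early_stop_patience=10)


class TestPatchSampling:
    def test_small_volume_fully_contained_and_padded(self):
        cfg = LocalizerConfig.tiny(patch_size=(16, 16, 8))
        vol, lm = toy_volume_and_landmarks(shape=(8, 8, 4))
        targets = make_heatmap_targets(lm, vol, HeatmapConfig(sigma_voxels=2))
        x, y, info = sample_training_patch(vol, targets, cfg, np.random.default_rng(0))
        assert x.shape == (1, 16, 16, 8)
        assert y.shape == (5, 16, 16, 8)
        # whole volume present somewhere in the patch
        assert np.isclose(np.sum(np.abs(x)), np.sum(np.abs(vol.data)), rtol=1e-5)

    def test_centered_draw_contains_landmark(self):
        cfg = LocalizerConfig.tiny(patch_size=(16, 16, 8), centered_fraction=1.0)
        vol, lm = toy_volume_and_landmarks()
        targets = make_heatmap_targets(lm, vol, HeatmapConfig(sigma_voxels=2))
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y, info = sample_training_patch(vol, targets, cfg, rng)
            assert info["mode"] == "centered"
            assert y.max() > 0.9  # some landmark's peak voxel is inside

    def test_centered_uniform_ratio(self):
        cfg = LocalizerConfig.tiny(patch_size=(16, 16, 8), centered_fraction=0.7)
        vol, lm = toy_volume_and_landmarks()
        targets = make_heatmap_targets(lm, vol, HeatmapConfig(sigma_voxels=2))
        rng = np.random.default_rng(2)
        modes = [
            sample_training_patch(vol, targets, cfg, rng)[2]["mode"] for _ in range(1000)
        ]
        frac = modes.count("centered") / len(modes)
        assert frac == pytest.approx(0.7, abs=0.05)


class TestTraining:
    def test_empty_sets_rejected(self):
        with pytest.raises(DataError):
            train([], [], LocalizerConfig.tiny())

    def test_overfit_single_phantom_reduces_loss(self, tiny_run):
        vol, lm = toy_volume_and_landmarks(seed=3)
        # add a visible blob at each landmark so there is signal to fit
        for label in LANDMARK_LABELS:
            from pelvimetry.preprocess import physical_to_voxel

            v = np.round(physical_to_voxel(lm[label], vol)).astype(int)
            vol.data[tuple(v)] += 3.0
        cfg = LocalizerConfig.tiny(
            seed=0, patch_size=(16, 16, 8), max_epochs=3, early_stop_patience=2,
            steps_per_epoch=15, batch_size=2, base_channels=4, depth=1,
        )
        model, history = train(
            [(vol, lm)], [(vol, lm)], cfg,
            preprocess_config=tiny_run.preprocess,
            heatmap_config=HeatmapConfig(sigma_voxels=2),
        )
        assert history.train_loss[-1] < history.train_loss[0]
        assert history.selected_epoch == int(np.argmin(history.val_loss)) + 1

    def test_training_reproducible_under_seed(self, tiny_run):
        vol, lm = toy_volume_and_landmarks(seed=5)
        cfg = LocalizerConfig.tiny(
            seed=11, patch_size=(16, 16, 8), max_epochs=2, early_stop_patience=1,
            steps_per_epoch=5, batch_size=2, base_channels=2, depth=1,
        )
        kwargs = dict(
            preprocess_config=tiny_run.preprocess,
            heatmap_config=HeatmapConfig(sigma_voxels=2),
        )
        _m1, h1 = train([(vol, lm)], [(vol, lm)], cfg, **kwargs)
        _m2, h2 = train([(vol, lm)], [(vol, lm)], cfg, **kwargs)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss


class TestInference:
    def test_stub_model_recovers_ground_truth(self, tiny_run):
        vol, lm = toy_volume_and_landmarks(seed=7)
        hm = HeatmapConfig(sigma_voxels=2)
        stub = StubHeatmapModel(lambda v: make_heatmap_targets(lm, v, hm))
        pred, conf, flags = predict_landmarks(
            stub, vol, preprocess_config=tiny_run.preprocess, heatmap_config=hm
        )
        for label in LANDMARK_LABELS:
            # voxel-resolution agreement on the resampled grid
            assert np.linalg.norm(pred[label] - lm[label]) <= np.linalg.norm(vol.spacing)

    def test_translation_equivariance_of_predictions(self, tiny_run):
        vol, lm = toy_volume_and_landmarks(seed=8)
        hm = HeatmapConfig(sigma_voxels=2)
        shift = np.array([10.0, -20.0, 4.3])
        moved = VolumeGrid(
            data=vol.data.copy(), spacing=vol.spacing, origin=vol.origin + shift
        )
        lm_moved = lm.transformed(np.eye(3), shift)
        stub = StubHeatmapModel(lambda v: make_heatmap_targets(lm, v, hm))
        stub_moved = StubHeatmapModel(lambda v: make_heatmap_targets(lm_moved, v, hm))
        p1, _, _ = predict_landmarks(stub, vol, preprocess_config=tiny_run.preprocess)
        p2, _, _ = predict_landmarks(stub_moved, moved, preprocess_config=tiny_run.preprocess)
        for label in LANDMARK_LABELS:
            assert p2[label] - p1[label] == pytest.approx(shift, abs=1e-6)

    def test_overlap_invariance_on_constant_field(self, tiny_run):
        """Mean blending of overlapping windows is exact for a model whose
        output depends only on voxel content, here a constant field."""

        class ConstantModel:
            out_channels = 5

            def required_multiple(self):
                return (1, 1, 1)

            def forward(self, x):
                out = np.zeros((x.shape[0], 5) + x.shape[2:], dtype=np.float32)
                out[:, 2] = 0.7
                return out

        vol, _lm = toy_volume_and_landmarks(seed=9)
        m = ConstantModel()
        p0, c0, _ = predict_landmarks(
            m, vol, preprocess_config=tiny_run.preprocess, patch_size=(16, 16, 8), overlap=0.0
        )
        p1, c1, _ = predict_landmarks(
            m, vol, preprocess_config=tiny_run.preprocess, patch_size=(16, 16, 8), overlap=0.5
        )
        assert c0 == c1
        assert p0["C"] == pytest.approx(p1["C"])

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = LocalizerConfig.tiny(patch_size=(16, 16, 8), base_channels=2, depth=1)
        model = build_localizer(cfg)
        hist = TrainingHistory(train_loss=[1.0, 0.5], val_loss=[1.1, 0.6], selected_epoch=2)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model, cfg, hist)
        model2, cfg2, hist2 = load_checkpoint(path)
        assert cfg2 == cfg
        assert hist2.selected_epoch == 2
        x = np.random.default_rng(0).standard_normal((1, 1, 16, 16, 8)).astype(np.float32)
        assert np.array_equal(model.forward(x), model2.forward(x))
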