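import numpy as np
import pytest

from immunopet import (
    AugmentationPolicy,
    CytActNet,
    ModelConfig,
    TumorCube,
    assign_folds,
    load_ensemble,
    predict_cytact,
    save_ensemble,
    train_cv,
)
from immunopet.cnn import Adam, CNNError, _fit

TINY = ModelConfig(cube_vox=4, channels=(2, 2), epochs=2, batch_size=8, rng_seed=0)


def toy_cubes(n, side=4, seed=0):
    rng = np.random.default_rng(seed)
    cubes, targets = [], []
    for i in range(n):
        scale = rng.uniform(0.2, 1.0)
        data = (rng.random((side,) * 3) * scale).astype(np.float32)
        cubes.append(TumorCube(data=data, spacing_mm=2.0, norm_mode="none",
                               patient_id=f"P{i}", lesion_id=f"L{i}"))
        targets.append(float(data.mean()))
    return cubes, np.array(targets)


class TestFolds:
    def test_near_equal_partition(self):
        fold_id = assign_folds(20, 10, seed=1)
        sizes = np.bincount(fold_id, minlength=10)
        assert sizes.tolist() == [2] * 10

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = np.bincount(assign_folds(23, 10, seed=1))
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 23

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(assign_folds(30, 5, 7), assign_folds(30, 5, 7))

    def test_too_few_samples_rejected(self):
        with pytest.raises(CNNError):
            assign_folds(5, 10, 0)


class TestNetwork:
    def test_predict_deterministic(self):
        net = CytActNet(TINY)
        cubes, _ = toy_cubes(3)
        x = np.stack([c.data for c in cubes])
        p1 = net.predict(x)
        p2 = net.predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_rejected(self):
        net = CytActNet(TINY)
        with pytest.raises(CNNError, match="cube_vox"):
            net.predict(np.zeros((2, 8, 8, 8), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path):
        net = CytActNet(TINY)
        cubes, _ = toy_cubes(2)
        x = np.stack([c.data for c in cubes])
        net.save(tmp_path / "m.npz")
        back = CytActNet.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(net.predict(x), back.predict(x))

    def test_training_reduces_loss(self):
        cubes, y = toy_cubes(32, seed=3)
        x = np.stack([c.data for c in cubes])
        net = CytActNet(TINY, rng=np.random.default_rng(0))
        cfg = ModelConfig(cube_vox=4, channels=(2, 2), epochs=10, batch_size=8,
                          lr=3e-3, rng_seed=0)
        hist = _fit(net, x, y, cfg, np.random.default_rng(1))
        assert hist[-1] < hist[0]

    def test_nan_loss_aborts(self):
        cubes, y = toy_cubes(8)
        x = np.stack([c.data for c in cubes])
        net = CytActNet(TINY, rng=np.random.default_rng(0))
        cfg = ModelConfig(cube_vox=4, channels=(2, 2), epochs=2, batch_size=8,
                          lr=1e12, rng_seed=0)
        with pytest.raises(CNNError, match="diverged|non-finite"):
            _fit(net, x, y * 1e30, cfg, np.random.default_rng(1))

    def test_odd_cube_size_rejected(self):
        with pytest.raises(CNNError):
            ModelConfig(cube_vox=12, channels=(2, 2, 2))


class TestEnsemble:
    def test_constant_output_models_average(self):
        # freeze toy weights so each model outputs a constant c_i
        models = []
        for c_i in (0.5, 1.5, 2.5):
            net = CytActNet(TINY, rng=np.random.default_rng(0))
            for layer in net.layers:
                for _, p in layer.params():
                    p[...] = 0.0
            net.layers[-1].b[...] = c_i
            models.append(net)
        cube = toy_cubes(1)[0][0]
        assert predict_cytact(models, cube) == pytest.approx(1.5)

    def test_ensemble_save_load(self, tmp_path):
        cubes, y = toy_cubes(12)
        cv, models = train_cv(cubes, y, cfg=TINY, folds=3,
                              policy=AugmentationPolicy(n_copies=2, rng_seed=0))
        save_ensemble(models, tmp_path)
        back = load_ensemble(tmp_path)
        assert len(back) == 3
        for cube in cubes[:2]:
            assert predict_cytact(back, cube) == pytest.approx(
                predict_cytact(models, cube), abs=1e-6
            )


class TestTrainCV:
    def test_every_sample_predicted_once(self):
        cubes, y = toy_cubes(12)
        cv, models = train_cv(cubes, y, cfg=TINY, folds=3,
                              policy=AugmentationPolicy(n_copies=2, rng_seed=0))
        assert np.isfinite(cv.oof_pred).all()
        assert len(models) == 3
        assert np.bincount(cv.fold_id).tolist() == [4, 4, 4]

    def test_constant_targets_converge_toward_constant(self):
        cubes, _ = toy_cubes(12, seed=5)
        cfg = ModelConfig(cube_vox=4, channels=(2, 2), epochs=15, batch_size=8,
                          lr=3e-3, rng_seed=0)
        cv, _ = train_cv(cubes, np.zeros(12), cfg=cfg, folds=3,
                         policy=AugmentationPolicy(n_copies=2, rng_seed=0))
        assert np.mean(cv.oof_pred**2) < 0.05

    def test_reproducible_end_to_end(self):
        cubes, y = toy_cubes(12)
        pol = AugmentationPolicy(n_copies=2, rng_seed=3)
        cv1, _ = train_cv(cubes, y, cfg=TINY, folds=3, policy=pol)
        cv2, _ = train_cv(cubes, y, cfg=TINY, folds=3, policy=pol)
        np.testing.assert_array_equal(cv1.oof_pred, cv2.oof_pred)

    def test_fold_membership_independent_of_targets(self):
        # no-leakage: validation membership depends only on n, folds, seed
        cubes, y = toy_cubes(12)
        pol = AugmentationPolicy(n_copies=2, rng_seed=0)
        cv1, _ = train_cv(cubes, y, cfg=TINY, folds=3, policy=pol)
        cv2, _ = train_cv(cubes, np.zeros(12), cfg=TINY, folds=3, policy=pol)
        np.testing.assert_array_equal(cv1.fold_id, cv2.fold_id)

    def test_target_count_mismatch_rejected(self):
        cubes, y = toy_cubes(12)
        with pytest.raises(CNNError):
            train_cv(cubes, y[:-1], cfg=TINY, folds=3)

    def test_regenerate_per_epoch_runs(self):
        cubes, y = toy_cubes(8)
        cfg = ModelConfig(cube_vox=4, channels=(2,), epochs=2, batch_size=8,
                          rng_seed=0, regenerate_per_epoch=True)
        cv, _ = train_cv(cubes, y, cfg=cfg, folds=2,
                         policy=AugmentationPolicy(n_copies=2, rng_seed=0))
        assert np.isfinite(cv.oof_pred).all()
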