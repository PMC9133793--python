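import numpy as np
import pandas as pd
import pytest

from oddwave.containers import EpochsData, default_layout
from oddwave.decode import (
    DecodeConfig,
    decode_timecourse,
    estimate_epoch_noise_covariance,
    subset_trials,
    temporal_generalization,
)


def make_epochs(data, sfreq=100.0):
    """Wrap an array as z-normalized epochs with dummy metadata."""
    n, p, t = data.shape
    times = -50.0 + 10.0 * np.arange(t)
    return EpochsData(
        data=data,
        times=times,
        sfreq=sfreq,
        layout=default_layout(p),
        trials=pd.DataFrame(
            {"stimulus": ["A"] * n, "position_in_train": [1] * n, "train_index": range(n)}
        ),
        normalization_state="z-normalized",
    )


class TestNoiseNormalizer:
    def test_white_noise_gives_identity_whitener(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1000, 32, 10))
        labels = np.arange(1000) % 2
        norm = estimate_epoch_noise_covariance(X, labels)
        assert np.linalg.norm(norm.covariance - np.eye(32)) < 0.1
        assert np.linalg.norm(norm.whitener - np.eye(32)) < 0.1
        assert np.allclose(norm.whitener @ norm.covariance @ norm.whitener.T, np.eye(32), atol=1e-6)

    def test_full_shrinkage_gives_diagonal_whitener(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 6, 4))
        norm = estimate_epoch_noise_covariance(X, np.arange(50) % 2, shrinkage=1.0)
        off = norm.whitener - np.diag(np.diag(norm.whitener))
        assert np.abs(off).max() == 0.0
        assert norm.shrinkage_gamma == 1.0

    def test_two_sensor_known_covariance_recovered(self):
        # correlated noise with covariance [[2, 1], [1, 2]]
        true_cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        L = np.linalg.cholesky(true_cov)
        rng = np.random.default_rng(2)
        X = np.einsum("pq,nqt->npt", L, rng.standard_normal((4000, 2, 5)))
        norm = estimate_epoch_noise_covariance(X, np.arange(4000) % 2)
        assert np.allclose(norm.covariance, true_cov, atol=0.1)
        whitened = np.einsum("pq,nqt->npt", norm.whitener, X)
        emp = np.cov(whitened.transpose(0, 2, 1).reshape(-1, 2).T)
        assert np.allclose(emp, np.eye(2), atol=0.05)

    def test_too_few_trials_per_condition(self):
        X = np.zeros((3, 4, 2))
        with pytest.raises(ValueError, match=">= 2 trials"):
            estimate_epoch_noise_covariance(X, np.array([0, 0, 1]))


class TestDecodeTimecourse:
    def test_chance_level_under_null(self):
        # exchangeable labels on pure noise: long-run mean accuracy is 50%
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            epochs = make_epochs(rng.standard_normal((60, 8, 6)))
            labels = np.array(["a", "b"] * 30)
            res = decode_timecourse(epochs, labels, DecodeConfig(n_repetitions=2, seed=seed))
            means.append(res.accuracy.mean())
        grand = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 0.5) < 2 * sem + 0.01

    def test_perfectly_separable_single_timepoint(self):
        rng = np.random.default_rng(3)
        data = 0.3 * rng.standard_normal((40, 8, 9))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        data[20:, 0, 4] += 10.0  # class difference only at time index 4
        res = decode_timecourse(make_epochs(data), labels, DecodeConfig(n_repetitions=3, seed=0))
        assert res.accuracy[4] == pytest.approx(1.0)
        others = np.delete(res.accuracy, 4)
        assert np.all(np.abs(others - 0.5) < 0.35)

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for delta in (0.0, 1.0, 3.0):
            rng = np.random.default_rng(42)  # identical noise for all levels
            data = rng.standard_normal((60, 8, 5))
            data[30:, :, 2] += delta / np.sqrt(8)
            labels = np.array(["a"] * 30 + ["b"] * 30)
            res = decode_timecourse(make_epochs(data), labels, DecodeConfig(n_repetitions=5, seed=1))
            accs.append(res.accuracy[2])
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] > 0.9

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        epochs = make_epochs(rng.standard_normal((40, 6, 7)))
        labels = np.array(["a", "b"] * 20)
        r1 = decode_timecourse(epochs, labels, DecodeConfig(n_repetitions=3, seed=11))
        r2 = decode_timecourse(epochs, labels, DecodeConfig(n_repetitions=3, seed=11))
        assert np.array_equal(r1.accuracy, r2.accuracy)

    def test_train_test_hygiene(self):
        rng = np.random.default_rng(6)
        epochs = make_epochs(rng.standard_normal((40, 6, 4)))
        labels = np.array(["a", "b"] * 20)
        res = decode_timecourse(
            epochs, labels, DecodeConfig(n_repetitions=2, seed=0, record_folds=True)
        )
        assert res.fold_log
        for entry in res.fold_log:
            test = set(entry["test_trials"].tolist())
            fit = set(entry["normalizer_trials"].tolist())
            assert not test & fit
            assert test | fit == set(range(40))

    def test_requires_normalized_epochs(self):
        epochs = make_epochs(np.zeros((20, 4, 3)))
        epochs.normalization_state = "raw"
        with pytest.raises(ValueError, match="z-normalized"):
            decode_timecourse(epochs, np.array(["a", "b"] * 10))

    def test_too_few_trials_for_folds(self):
        rng = np.random.default_rng(7)
        epochs = make_epochs(rng.standard_normal((8, 4, 3)))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="folds"):
            decode_timecourse(epochs, labels, DecodeConfig(n_folds=5, n_repetitions=1, seed=0))


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse_on_decimated_grid(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((40, 6, 12))
        data[20:, 0, :] += 1.0
        labels = np.array(["a"] * 20 + ["b"] * 20)
        cfg = DecodeConfig(n_repetitions=2, seed=4, tg_downsample=2)
        epochs = make_epochs(data)
        tg = temporal_generalization(epochs, labels, cfg)
        tc = decode_timecourse(epochs.decimate(2), labels, cfg)
        assert np.all(np.abs(tg.diagonal - tc.accuracy) < 1e-12)
        assert tg.matrix.shape == (6, 6)

    def test_sustained_pattern_generalizes_and_transients_do_not(self):
        rng = np.random.default_rng(9)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        cfg = DecodeConfig(n_repetitions=3, seed=2, tg_downsample=1)

        sustained = rng.standard_normal((60, 8, 8))
        sustained[30:, 0, :] += 3.0  # same pattern at every time point
        tg_s = temporal_generalization(make_epochs(sustained), labels, cfg)
        off = ~np.eye(8, dtype=bool)
        assert tg_s.matrix[off].mean() > 0.9

        transient = rng.standard_normal((60, 8, 8))
        for t in range(8):  # orthogonal pattern per time point
            transient[30:, t, t] += 3.0
        tg_t = temporal_generalization(make_epochs(transient), labels, cfg)
        assert np.diag(tg_t.matrix).mean() > 0.9
        assert tg_t.matrix[off].mean() < 0.65


class TestSubsetTrials:
    def test_identity_when_target_equals_available(self):
        idx = {"a": np.arange(10)}
        out = subset_trials(idx, 10, seed=0)
        assert np.array_equal(out["a"], idx["a"])

    def test_cardinality_and_containment(self):
        idx = {"a": np.arange(600)}
        out = subset_trials(idx, 200, seed=1)
        assert out["a"].size == 200
        assert np.unique(out["a"]).size == 200
        assert np.isin(out["a"], idx["a"]).all()

    def test_deterministic(self):
        idx = {"a": np.arange(100), "b": np.arange(100, 180)}
        assert all(
            np.array_equal(subset_trials(idx, 50, seed=9)[k], subset_trials(idx, 50, seed=9)[k])
            for k in idx
        )

    def test_target_exceeding_availability(self):
        with pytest.raises(ValueError, match="exceeds"):
            subset_trials({"a": np.arange(5)}, 6)
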