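"""biLSTM classifier: forward contract, gradients, training behaviour.

Tests use deliberately small architectures (few hidden units, short
sequences); the default 100-unit configuration exercises the same code
paths.
"""

import numpy as np
import pytest

import gaitspeed as gs
from gaitspeed.classifier import BiLSTMModel, clip_global_norm

import oracles


def sinusoid_pattern(freq_cycles, T, label, seed=0, noise=0.05, phase_seed=None):
    """A 5-channel pattern whose rows oscillate at a known frequency.

    ``phase_seed`` pins the per-row phases (patterns sharing it differ
    only by noise — a maximally easy class structure); by default phases
    are drawn from ``seed`` and vary per pattern.
    """
    rng = np.random.default_rng(seed)
    phase_rng = np.random.default_rng(phase_seed) if phase_seed is not None else rng
    t = np.arange(T)
    rows = []
    for i in range(5):
        phase = phase_rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * freq_cycles * t / T + phase)
        x = x + noise * rng.standard_normal(T)
        rows.append((x - x.min()) / (x.max() - x.min()))
    return gs.WalkingSpeedPattern(np.vstack(rows), label, f"sin{freq_cycles}-{seed}")


def sinusoid_dataset(freqs=(2, 8, 16), per_class=10, T=40, class_phases=False):
    pats = []
    for label, f in enumerate(freqs):
        for j in range(per_class):
            pats.append(
                sinusoid_pattern(
                    f, T, label, seed=1000 * label + j,
                    phase_seed=label if class_phases else None,
                )
            )
    return pats


SMALL = gs.ModelConfig(input_size=5, hidden_units=12, n_classes=3)


class TestForward:
    def test_probabilities_sum_to_one(self):
        model = gs.build_model(SMALL, seed=0)
        X = np.random.default_rng(0).random((4, 20, 5))
        probs = model.forward(X)
        assert probs.shape == (4, 3)
        assert np.allclose(probs.sum(axis=1), 1, atol=1e-6)

    def test_batch_independence(self):
        model = gs.build_model(SMALL, seed=0)
        X = np.random.default_rng(1).random((6, 15, 5)).astype(np.float32)
        probs = model.forward(X)
        perm = [3, 1, 5, 0, 4, 2]
        probs_perm = model.forward(X[perm])
        assert np.array_equal(probs_perm, probs[perm])

    def test_seeded_determinism_is_bitwise(self):
        X = np.random.default_rng(2).random((3, 10, 5))
        a = gs.build_model(SMALL, seed=7).forward(X)
        b = gs.build_model(SMALL, seed=7).forward(X)
        assert np.array_equal(a, b)

    def test_wrong_input_size_raises(self):
        model = gs.build_model(SMALL, seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((2, 10, 4)))

    def test_backprop_matches_finite_differences(self):
        """BPTT gradients agree with central finite differences (float64)."""
        m = BiLSTMModel(gs.ModelConfig(input_size=2, hidden_units=4, n_classes=3), seed=0)
        for k in m.params:
            m.params[k] = m.params[k].astype(np.float64)
        rng = np.random.default_rng(1)
        X = rng.random((3, 7, 2))
        y = np.array([0, 1, 2])
        _, grads = m.loss_and_grads(X, y)
        eps = 1e-6
        for k in m.params:
            flat = m.params[k].ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = m.loss_and_grads(X, y)[0]
                flat[idx] = orig - eps
                lm = m.loss_and_grads(X, y)[0]
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters(self):
        pats = sinusoid_dataset(per_class=3, T=20)
        model = gs.build_model(SMALL, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        gs.train(model, pats, config=gs.TrainingConfig(learning_rate=0.0, max_epochs=3, seed=0))
        for k, v in model.params.items():
            assert np.array_equal(v, before[k])

    def test_clip_global_norm_exact(self):
        grads = {"a": np.array([3.0, 0.0]), "b": np.array([0.0, 4.0])}
        pre = clip_global_norm(grads, 0.9)
        assert pre == pytest.approx(5.0)
        post = np.sqrt(sum((g ** 2).sum() for g in grads.values()))
        assert post == pytest.approx(0.9)
        # below threshold: untouched
        grads = {"a": np.array([0.3, 0.4])}
        clip_global_norm(grads, 0.9)
        assert np.allclose(grads["a"], [0.3, 0.4])

    def test_separable_classes_reach_full_training_accuracy(self):
        """Far-separated oscillation frequencies are linearly separable
        (verified by a nearest-centroid check on per-row peak counts), and
        the network fits them completely."""
        raw = sinusoid_dataset(freqs=(2, 16), per_class=15, T=40)[:30]
        # interleave the classes: with shuffle "never", label-sorted input
        # would make the trailing partial batch single-class every epoch
        pats = [raw[i] for pair in zip(range(15), range(15, 30)) for i in pair]
        counts = np.array([[oracles.count_peaks_scan(row) for row in p.signals] for p in pats])
        labels = np.array([p.label for p in pats])
        centroids = [counts[labels == c].mean(axis=0) for c in (0, 1)]
        nearest = np.array([
            int(np.argmin([np.linalg.norm(c - m) for m in centroids])) for c in counts
        ])
        assert (nearest == labels).all()  # separability oracle

        cfg2 = gs.ModelConfig(input_size=5, hidden_units=100, n_classes=2)
        model = gs.build_model(cfg2, seed=3)
        trained = gs.train(model, pats, config=gs.TrainingConfig(max_epochs=50, seed=3))
        assert gs.accuracy_percent(trained, pats) == 100.0

    def test_training_is_reproducible(self):
        pats = sinusoid_dataset(per_class=4, T=25)
        runs = []
        for _ in range(2):
            model = gs.build_model(SMALL, seed=5)
            trained = gs.train(model, pats[:9], pats[9:],
                               gs.TrainingConfig(max_epochs=4, seed=5, validation_frequency=2))
            runs.append(trained)
        assert runs[0].history == runs[1].history
        assert runs[0].validation_checks == runs[1].validation_checks
        a, _ = gs.predict(runs[0], pats)
        b, _ = gs.predict(runs[1], pats)
        assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gs.train(gs.build_model(SMALL), [], config=gs.TrainingConfig(max_epochs=1))


class TestPredict:
    def test_argmax_and_tie_rule(self):
        # zero weights -> uniform probabilities -> lowest class index wins
        model = gs.build_model(SMALL, seed=0)
        for k in model.params:
            model.params[k][:] = 0
        pats = sinusoid_dataset(per_class=2, T=15)
        labels, probs = gs.predict(model, pats)
        assert np.allclose(probs, 1 / 3)
        assert (labels == 0).all()

    def test_accuracy_equals_independent_recount(self):
        pats = sinusoid_dataset(per_class=5, T=30)
        model = gs.build_model(SMALL, seed=2)
        trained = gs.train(model, pats, config=gs.TrainingConfig(max_epochs=10, seed=2))
        labels, _ = gs.predict(trained, pats)
        manual = 100.0 * sum(
            int(pred == p.label) for pred, p in zip(labels, pats)
        ) / len(pats)
        assert gs.accuracy_percent(trained, pats) == pytest.approx(manual)

    def test_save_load_round_trip(self, tmp_path):
        pats = sinusoid_dataset(per_class=2, T=15)
        model = gs.build_model(SMALL, seed=4)
        trained = gs.train(model, pats, config=gs.TrainingConfig(max_epochs=2, seed=4))
        gs.save_model(trained, tmp_path / "model.npz")
        loaded = gs.load_model(tmp_path / "model.npz")
        assert loaded.config == trained.config
        _, p0 = gs.predict(trained, pats)
        _, p1 = gs.predict(loaded, pats)
        assert np.array_equal(p0, p1)
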