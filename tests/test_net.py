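"""3D-CNN scorer: architecture, aggregation, training mechanics."""

import numpy as np
import pytest

from pocketscreen.featurize import GridSpec
from pocketscreen.net import (
    AggregationConfig, ArchitectureError, NetworkConfig, ScoringModel, TrainConfig,
    boltzmann_aggregate, init_network, train,
)

SMALL_SPEC = GridSpec(edge_voxels=8, spacing=1.0, scheme="entity")
SMALL_CFG = NetworkConfig(conv=((4, 3, 2), (8, 3, 1)), fc_hidden=8)


class TestBoltzmannAggregate:
    def test_equal_scores_identity(self):
        for beta in (0.0, 1.0, 17.3):
            assert boltzmann_aggregate([2.5, 2.5, 2.5], beta) == pytest.approx(2.5)

    def test_beta_zero_is_mean(self):
        assert boltzmann_aggregate([0.0, 1.0], 0.0) == pytest.approx(0.5)

    def test_closed_form_beta_one(self):
        assert boltzmann_aggregate([0.0, 1.0], 1.0) == pytest.approx(np.e / (1 + np.e))

    def test_large_beta_approaches_max(self):
        assert boltzmann_aggregate([0.0, 1.0], 50.0) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_beta_and_bounded(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=12)
        vals = [boltzmann_aggregate(s, b) for b in np.linspace(0, 20, 40)]
        assert np.all(np.diff(vals) >= -1e-12)
        assert s.min() <= vals[0] and vals[-1] <= s.max() + 1e-12

    def test_permutation_invariant(self):
        s = [0.3, -1.2, 4.0, 0.9]
        assert boltzmann_aggregate(s, 1.3) == pytest.approx(boltzmann_aggregate(s[::-1], 1.3))

    def test_overflow_safe(self):
        assert np.isfinite(boltzmann_aggregate([1000.0, 999.0], 5.0))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            boltzmann_aggregate([], 1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            AggregationConfig(beta=-1.0)


class TestArchitecture:
    def test_forward_finite_scalar_on_zero_grid(self):
        model = init_network(NetworkConfig(), GridSpec(), seed=1)
        g = np.zeros((1, 16, 30, 30, 30), dtype=np.uint8)
        out = model.forward(g)
        assert out.shape == (1,) and np.isfinite(out[0])

    def test_same_seed_identical_parameters(self):
        a = init_network(SMALL_CFG, SMALL_SPEC, seed=4)
        b = init_network(SMALL_CFG, SMALL_SPEC, seed=4)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_parameter_count_closed_form(self):
        # default stack on 30³/16-channel input, summed by hand:
        # conv 27·16·32+32 + 27·32·64+64 + 27·64·64+64 ×2 + 8·64·64+64
        # fc 64·256+256, out 256·1+1
        assert NetworkConfig().n_parameters(16, 30) == 340257
        model = init_network(NetworkConfig(), GridSpec(), seed=0)
        assert sum(p.size for p in model.parameters()) == 340257

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ArchitectureError):
            init_network(NetworkConfig(conv=((8, 5, 4), (8, 5, 1))),
                         GridSpec(edge_voxels=8, scheme="entity"))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=2)
        g = np.random.default_rng(0).integers(0, 2, (3, 2, 8, 8, 8)).astype(np.uint8)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ScoringModel.load(path)
        assert np.allclose(model.forward(g), loaded.forward(g))


class TestPredict:
    def test_single_pose_equals_its_score(self):
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=0)
        g = np.random.default_rng(1).integers(0, 2, (1, 2, 8, 8, 8)).astype(np.uint8)
        agg, per = model.predict_affinity(g)
        assert agg == pytest.approx(per[0])

    def test_pose_order_invariant_and_bounded(self):
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=0)
        g = np.random.default_rng(2).integers(0, 2, (6, 2, 8, 8, 8)).astype(np.uint8)
        a, per = model.predict_affinity(g)
        b, _ = model.predict_affinity(g[::-1])
        assert a == pytest.approx(b)
        assert per.min() - 1e-6 <= a <= per.max() + 1e-6

    def test_grid_spec_mismatch_rejected(self):
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            model.forward(np.zeros((1, 2, 9, 9, 9), dtype=np.uint8))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Numeric gradient check through conv + dense + Boltzmann loss."""
        cfg = NetworkConfig(conv=((2, 3, 2),), fc_hidden=3)
        spec = GridSpec(edge_voxels=5, scheme="entity")
        model = init_network(cfg, spec, seed=3)
        rng = np.random.default_rng(0)
        G = rng.integers(0, 2, (2, 3, 2, 5, 5, 5)).astype(np.uint8)  # 2 ex × 3 poses
        y = np.array([1.0, 2.0])
        params = model.parameters()
        # analytic gradient of the batch MSE with aggregation
        from pocketscreen.net import _boltzmann_grad
        scores = model.forward(G.reshape(6, 2, 5, 5, 5), train=True).reshape(2, 3)
        agg, dsd = _boltzmann_grad(scores.astype(float), model.agg.beta)
        resid = agg - y
        model.backward(((2.0 / 2) * resid[:, None] * dsd).reshape(6))
        grads = model.gradients()

        def loss():
            s = model.forward(G.reshape(6, 2, 5, 5, 5)).reshape(2, 3)
            a, _ = _boltzmann_grad(s.astype(float), model.agg.beta)
            return float(np.mean((a - y) ** 2))

        eps = 1e-3
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g.reshape(-1)[idx], abs=2e-3)


class TestTraining:
    def _toy_dataset(self, n=24, poses=2, seed=0):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 2, (n, poses, 2, 8, 8, 8)).astype(np.uint8)
        y = G[:, :, 1].sum(axis=(1, 2, 3, 4)).astype(float) / 100.0 + 4.0
        return G, y

    def test_loss_decreases(self):
        G, y = self._toy_dataset()
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=1)
        trace = train(model, G, y, TrainConfig(epochs=8, batch_size=8, seed=0,
                                               augment_rot90=False))
        assert trace[-1] < trace[0]

    def test_reproducible_given_seed(self):
        G, y = self._toy_dataset()
        t1 = train(init_network(SMALL_CFG, SMALL_SPEC, seed=1), G, y,
                   TrainConfig(epochs=2, batch_size=8, seed=5))
        t2 = train(init_network(SMALL_CFG, SMALL_SPEC, seed=1), G, y,
                   TrainConfig(epochs=2, batch_size=8, seed=5))
        assert t1 == t2

    def test_constant_labels_converge(self):
        rng = np.random.default_rng(3)
        one = rng.integers(0, 2, (1, 2, 2, 8, 8, 8)).astype(np.uint8)
        G = np.repeat(one, 16, axis=0)
        y = np.full(16, 5.0)
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=2)
        train(model, G, y, TrainConfig(epochs=30, batch_size=16, seed=1,
                                       learning_rate=3e-3, augment_rot90=False,
                                       weight_decay=0.0))
        pred, _ = model.predict_affinity(G[0])
        assert abs(pred - 5.0) < 0.1

    def test_divergence_aborts(self):
        G, y = self._toy_dataset(n=8)
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=1)
        with pytest.raises((RuntimeError, FloatingPointError), match="diverged"):
            train(model, G, y * 1e30, TrainConfig(epochs=50, batch_size=8,
                                                  learning_rate=1e20, seed=0))

    def test_bad_inputs_rejected(self):
        G, y = self._toy_dataset(n=4)
        model = init_network(SMALL_CFG, SMALL_SPEC, seed=1)
        with pytest.raises(ValueError):
            train(model, G, y[:-1])
        with pytest.raises(ValueError):
            train(model, G, np.full(4, np.nan))
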