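import numpy as np
import pytest

from hypercal.network import BiLSTMAttention, NetConfig

TINY = NetConfig(hidden1=3, hidden2=2, dense=3, attn_dim=2, seed=1)


def _mean_target_problem(n=200, t=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, t))
    return X, X.mean(axis=1)


class TestForward:
    def test_attention_weights_sum_to_one(self):
        m = BiLSTMAttention(TINY, seq_len=8)
        X = np.random.default_rng(0).standard_normal((5, 8))
        alpha = m.attention_weights(X)
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_predictions(self):
        X = np.random.default_rng(1).standard_normal((4, 6))
        a = BiLSTMAttention(TINY, 6).forward(X)
        b = BiLSTMAttention(TINY, 6).forward(X)
        np.testing.assert_array_equal(a, b)

    def test_batch_output_shape(self):
        m = BiLSTMAttention(TINY, 9)
        X = np.zeros((7, 9))
        assert m.forward(X).shape == (7,)

    def test_wrong_seq_len_rejected(self):
        with pytest.raises(ValueError, match="bands"):
            BiLSTMAttention(TINY, 9).forward(np.zeros((2, 5)))

    def test_backward_stream_only_when_forward_merge_zeroed(self):
        """Zeroing the forward-merge weights makes the layer-2 forward LSTM inert."""
        m = BiLSTMAttention(TINY, 7)
        X = np.random.default_rng(2).standard_normal((3, 7))
        m.params["l2_Mf"][:] = 0.0
        base = m.forward(X)
        for k in ("l2f_Wx", "l2f_Wh", "l2f_b"):
            m.params[k][:] = np.random.default_rng(3).standard_normal(m.params[k].shape)
        np.testing.assert_allclose(m.forward(X), base, atol=1e-12)


class TestKernels:
    def test_jit_kernels_match_numpy_reference(self):
        """The compiled recurrent kernels agree with the vectorized NumPy path."""
        import hypercal.network as net

        rng = np.random.default_rng(0)
        T, B, H = 7, 5, 3
        pre = rng.standard_normal((T, B, 4 * H))
        Wh = 0.3 * rng.standard_normal((H, 4 * H))
        hs1, cs1, g1 = net._lstm_steps(pre, Wh)
        hs2, cs2, g2 = net._lstm_steps_py(pre, Wh)
        np.testing.assert_allclose(hs1, hs2, atol=1e-14)
        np.testing.assert_allclose(g1, g2, atol=1e-14)
        dhs = rng.standard_normal((T, B, H))
        WhT = np.ascontiguousarray(Wh.T)
        d1 = net._lstm_back_steps(dhs, hs1, cs1, g1, WhT)
        d2 = net._lstm_back_steps_py(dhs, hs2, cs2, g2, WhT)
        np.testing.assert_allclose(d1, d2, atol=1e-14)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences on 10 random parameters agree to 1e-4."""
        m = BiLSTMAttention(TINY, seq_len=5)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 5))
        y = rng.standard_normal(4)
        _, grads = m.loss_and_grads(X, y)
        keys = sorted(m.params)
        eps = 1e-5
        checked = 0
        while checked < 10:
            k = keys[rng.integers(len(keys))]
            flat = m.params[k].ravel()
            idx = int(rng.integers(flat.size))
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = m.loss_and_grads(X, y)
            flat[idx] = orig - eps
            lm, _ = m.loss_and_grads(X, y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana))
            checked += 1

    @pytest.mark.parametrize("cfg", [
        NetConfig(hidden1=3, hidden2=2, dense=2, seed=2, bidirectional=False, attention=False),
        NetConfig(hidden1=3, hidden2=2, dense=2, seed=2, attention=False),
        NetConfig(hidden1=3, hidden2=2, dense=2, attn_dim=3, seed=2, attention_kind="dot"),
    ], ids=["lstm", "bilstm", "dot-attention"])
    def test_gradients_for_model_variants(self, cfg):
        m = BiLSTMAttention(cfg, seq_len=4)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((3, 4))
        y = rng.standard_normal(3)
        _, grads = m.loss_and_grads(X, y)
        eps = 1e-5
        for k in sorted(m.params):
            flat = m.params[k].ravel()
            idx = int(rng.integers(flat.size))
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = m.loss_and_grads(X, y)
            flat[idx] = orig - eps
            lm, _ = m.loss_and_grads(X, y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[k].ravel()[idx]) <= 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_recovers_mean_of_spectrum(self):
        X, y = _mean_target_problem()
        cfg = NetConfig(hidden1=8, hidden2=8, dense=16, attn_dim=8,
                        lr=0.01, num_epochs=60, batch_size=32, seed=0)
        m = BiLSTMAttention(cfg, 20)
        m.fit(X, y)
        pred = m.predict(X)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.99

    def test_zero_epochs_leaves_model_initialized(self):
        X, y = _mean_target_problem(n=30, t=6)
        cfg = NetConfig(hidden1=3, hidden2=2, dense=2, num_epochs=0, seed=4)
        m = BiLSTMAttention(cfg, 6)
        before = {k: v.copy() for k, v in m.params.items()}
        history = m.fit(X, y)
        assert history.train_mse == [] and history.val_mse == []
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])

    def test_loss_decreases_on_recoverable_target(self):
        """Median over seeds: last-epoch loss <= first-epoch loss."""
        deltas = []
        for seed in range(20):
            X, y = _mean_target_problem(n=60, t=8, seed=seed)
            cfg = NetConfig(hidden1=4, hidden2=3, dense=4, attn_dim=3,
                            lr=0.02, num_epochs=15, batch_size=20, seed=seed)
            m = BiLSTMAttention(cfg, 8)
            h = m.fit(X, y)
            deltas.append(h.train_mse[-1] - h.train_mse[0])
        assert np.median(deltas) < 0

    def test_divergence_raises(self):
        X, y = _mean_target_problem(n=40, t=6)
        cfg = NetConfig(hidden1=3, hidden2=3, dense=3, lr=1e160, num_epochs=50,
                        batch_size=40, seed=0)
        with np.errstate(all="ignore"), pytest.raises(FloatingPointError, match="learning rate"):
            BiLSTMAttention(cfg, 6).fit(X, y)

    def test_constant_targets_rejected(self):
        X, _ = _mean_target_problem(n=20, t=5)
        with pytest.raises(ValueError, match="constant"):
            BiLSTMAttention(TINY, 5).fit(X, np.ones(20))


@pytest.fixture(scope="module")
def trained():
    X, y = _mean_target_problem(n=80, t=10, seed=3)
    cfg = NetConfig(hidden1=4, hidden2=4, dense=6, attn_dim=4,
                    lr=0.02, num_epochs=25, batch_size=20, seed=3)
    m = BiLSTMAttention(cfg, 10)
    m.fit(X, y)
    return m, X


class TestPredict:
    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            BiLSTMAttention(TINY, 5).predict(np.zeros((1, 5)))

    def test_deterministic(self, trained):
        m, X = trained
        np.testing.assert_array_equal(m.predict(X), m.predict(X))

    def test_single_row_matches_batch(self, trained):
        m, X = trained
        batch = m.predict(X[:5])
        singles = np.array([m.predict(X[i:i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_order_sensitivity(self, trained):
        """A trained bidirectional net distinguishes wavelength order."""
        m, X = trained
        assert np.abs(m.predict(X[:8]) - m.predict(X[:8, ::-1])).max() > 1e-6

    def test_save_load_round_trip(self, trained, tmp_path):
        m, X = trained
        m.save(tmp_path / "ckpt")
        clone = BiLSTMAttention.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(m.predict(X), clone.predict(X))
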