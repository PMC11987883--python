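"""Neural-network layers: analytic gradients vs finite differences, and the
time-weighted attention layer against a brute-force oracle."""

import numpy as np
import pytest

from farrowcast import nn


def fd_check(layer, x, train, rng, n_probes=4, eps=1e-6, tol=1e-4):
    """Compare analytic parameter/input gradients with central differences."""
    R = rng.normal(size=layer.forward(x, train=train).shape)

    def loss():
        return float((layer.forward(x, train=train) * R).sum())

    layer.zero_grads()
    layer.forward(x, train=train)
    dx = layer.backward(R)

    for k, P in layer.params.items():
        for _ in range(n_probes):
            idx = np.unravel_index(rng.integers(P.size), P.shape)
            orig = P[idx]
            P[idx] = orig + eps
            lp = loss()
            P[idx] = orig - eps
            lm = loss()
            P[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = layer.grads[k][idx]
            assert abs(num - ana) <= tol * max(1.0, abs(num)), f"{k}{idx}: {num} vs {ana}"
    for _ in range(n_probes):
        idx = np.unravel_index(rng.integers(x.size), x.shape)
        orig = x[idx]
        x[idx] = orig + eps
        lp = loss()
        x[idx] = orig - eps
        lm = loss()
        x[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - dx[idx]) <= tol * max(1.0, abs(num)), f"input{idx}"


class TestGradients:
    def test_conv1d(self, rng):
        fd_check(nn.Conv1d(2, 3, 5, rng), rng.normal(size=(2, 9, 2)), False, rng)

    def test_batchnorm_train_mode(self, rng):
        fd_check(nn.BatchNorm1d(3), rng.normal(size=(4, 5, 3)), True, rng)

    def test_elu(self, rng):
        fd_check(nn.ELU(), rng.normal(size=(3, 4, 2)), False, rng)

    def test_lstm(self, rng):
        fd_check(nn.LSTM(2, 4, rng), rng.normal(size=(3, 7, 2)), False, rng)

    def test_ptwsa(self, rng):
        fd_check(nn.PTWSA(5, 4, rng), rng.normal(size=(2, 5, 4)), False, rng)

    def test_linear(self, rng):
        fd_check(nn.Linear(4, 2, rng), rng.normal(size=(3, 4)), False, rng)

    def test_stacked_pipeline(self, rng):
        seq = nn.Sequential([
            nn.Conv1d(1, 2, 3, rng), nn.BatchNorm1d(2), nn.ELU(),
            nn.LSTM(2, 3, rng), nn.ELU(),
            nn.PTWSA(6, 3, rng), nn.MeanPoolTime(), nn.Linear(3, 1, rng),
        ])
        fd_check(seq, rng.normal(size=(2, 6, 1)), True, rng)


def bruteforce_attention(H, Wq, Wk, Wv, scale):
    """Textbook scaled-dot-product self-attention, double loop."""
    t, d = H.shape
    Q, K, V = H @ Wq, H @ Wk, H @ Wv
    O = np.zeros_like(H)
    for i in range(t):
        scores = np.array([Q[i] @ K[j] / scale for j in range(t)])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        O[i] = sum(w[j] * V[j] for j in range(t))
    return O


class TestPTWSA:
    def test_reduces_to_plain_self_attention(self, rng):
        # P = 0 and unit time weights must reproduce the textbook oracle
        layer = nn.PTWSA(5, 8, rng)
        layer.params["P"][...] = 0.0
        layer.params["w_time"][...] = 1.0
        H = rng.normal(size=(1, 5, 8))
        out = layer.forward(H)
        oracle = bruteforce_attention(H[0], layer.params["Wq"], layer.params["Wk"],
                                      layer.params["Wv"], layer.scale)
        assert np.abs(out[0] - oracle).max() < 1e-6

    def test_attention_rows_sum_to_one(self, rng):
        layer = nn.PTWSA(7, 4, rng)
        layer.forward(rng.normal(size=(3, 7, 4)))
        assert np.allclose(layer.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_step_attention_is_identity(self, rng):
        layer = nn.PTWSA(1, 3, rng)
        layer.params["P"][...] = 0.0
        for k in ("Wq", "Wk", "Wv"):
            layer.params[k][...] = np.eye(3)
        H = rng.normal(size=(1, 1, 3))
        out = layer.forward(H)
        assert np.allclose(layer.last_attention, 1.0)
        assert np.allclose(out, H)

    def test_time_weight_concentrates_attention(self, rng):
        # growing w_time[j] must monotonically raise column-j attention mass
        layer = nn.PTWSA(6, 4, rng, scale_mode="sqrt_d")
        layer.params["P"][...] = 0.0
        for k in ("Wq", "Wk", "Wv"):
            layer.params[k][...] = np.eye(4)
        H = np.abs(rng.normal(size=(1, 6, 4))) + 0.1  # positive scores
        masses = []
        for factor in (1.0, 5.0, 25.0):
            layer.params["w_time"][...] = 1.0
            layer.params["w_time"][2] = factor
            layer.forward(H)
            masses.append(layer.last_attention[0, :, 2].mean())
        assert masses[0] < masses[1] < masses[2]

    def test_literal_d_scale_mode(self, rng):
        layer = nn.PTWSA(4, 9, rng, scale_mode="d")
        assert layer.scale == 9.0
        with pytest.raises(ValueError):
            nn.PTWSA(4, 9, rng, scale_mode="bogus")

    def test_nonfinite_parameters_rejected(self, rng):
        layer = nn.PTWSA(3, 2, rng)
        layer.params["w_time"][0] = np.nan
        with pytest.raises(FloatingPointError):
            layer.forward(rng.normal(size=(1, 3, 2)))


class TestShapes:
    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_conv_preserves_length_for_odd_kernels(self, k, rng):
        layer = nn.Conv1d(2, 4, k, rng)
        out = layer.forward(rng.normal(size=(2, 11, 2)))
        assert out.shape == (2, 11, 4)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.Conv1d(1, 1, 4, rng)

    def test_lstm_returns_full_sequence(self, rng):
        out = nn.LSTM(3, 5, rng).forward(rng.normal(size=(2, 9, 3)))
        assert out.shape == (2, 9, 5)

    def test_zero_weight_lstm_outputs_zero(self, rng):
        layer = nn.LSTM(2, 3, rng)
        for k in layer.params:
            layer.params[k][...] = 0.0
        out = layer.forward(rng.normal(size=(1, 4, 2)))
        assert np.allclose(out, 0.0)

    def test_lstm_gradient_reaches_first_step(self, rng):
        layer = nn.LSTM(1, 3, rng)
        x = rng.normal(size=(1, 6, 1))
        out = layer.forward(x)
        dout = np.zeros_like(out)
        dout[:, -1, :] = 1.0  # loss touches only the final hidden state
        layer.zero_grads()
        dx = layer.backward(dout)
        assert np.abs(dx[0, 0, 0]) > 0.0

    def test_dropout_eval_identity_train_masks(self, rng):
        layer = nn.Dropout(0.5, rng)
        x = np.ones((4, 10, 3))
        assert np.array_equal(layer.forward(x, train=False), x)
        masked = layer.forward(x, train=True)
        assert set(np.unique(masked)) <= {0.0, 2.0}  # inverted scaling
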