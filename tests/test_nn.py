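"""Recurrent cells vs independent oracles; gradients vs finite differences."""

import numpy as np
import pytest

from temporalcropnet import nn

SIG1 = 1.0 / (1.0 + np.exp(-1.0))  # sigma(1)


def make_lstm(rng, d, h, scale=0.5):
    return nn.LSTMParams(
        T={k: scale * rng.standard_normal((d, h)) for k in "yfpg"},
        W={k: scale * rng.standard_normal((h, h)) for k in "yfpg"},
        b={k: scale * rng.standard_normal(h) for k in "yfpg"},
    )


def make_gru(rng, d, h, scale=0.5):
    return nn.GRUParams(
        T={k: scale * rng.standard_normal((d, h)) for k in "usd"},
        W={k: scale * rng.standard_normal((h, h)) for k in "usd"},
        b={k: scale * rng.standard_normal(h) for k in "usd"},
    )


def lstm_oracle(x, h, c, p):
    """Element-by-element loop oracle for one LSTM step."""
    d_in, hid = p.T["y"].shape
    out_h = np.zeros(hid)
    out_c = np.zeros(hid)
    for j in range(hid):
        a = {k: p.b[k][j] for k in "yfpg"}
        for k in "yfpg":
            for i in range(d_in):
                a[k] += x[i] * p.T[k][i, j]
            for i in range(hid):
                a[k] += h[i] * p.W[k][i, j]
        sig = lambda v: 1 / (1 + np.exp(-v))
        y, f, pg = sig(a["y"]), sig(a["f"]), sig(a["p"])
        g = np.tanh(a["g"])
        out_c[j] = f * c[j] + y * g
        out_h[j] = pg * np.tanh(out_c[j])
    return out_h, out_c


def gru_oracle(x, d, p):
    d_in, hid = p.T["u"].shape
    sig = lambda v: 1 / (1 + np.exp(-v))
    # reset vector first: unit i's reset gate scales its own recurrent input
    s_full = np.array(
        [
            sig(
                p.b["s"][j]
                + sum(x[i] * p.T["s"][i, j] for i in range(d_in))
                + sum(d[i] * p.W["s"][i, j] for i in range(hid))
            )
            for j in range(hid)
        ]
    )
    out = np.zeros(hid)
    for j in range(hid):
        au = p.b["u"][j]
        ad = p.b["d"][j]
        for i in range(d_in):
            au += x[i] * p.T["u"][i, j]
            ad += x[i] * p.T["d"][i, j]
        for i in range(hid):
            au += d[i] * p.W["u"][i, j]
            ad += s_full[i] * d[i] * p.W["d"][i, j]
        u = sig(au)
        g = np.tanh(ad)
        out[j] = (1 - u) * d[j] + u * g
    return out


class TestCells:
    def test_lstm_zero_weights_zero_state(self):
        p = nn.LSTMParams(
            T={k: np.zeros((2, 3)) for k in "yfpg"},
            W={k: np.zeros((3, 3)) for k in "yfpg"},
            b={k: np.zeros(3) for k in "yfpg"},
        )
        h, c = nn.lstm_step(np.ones(2), np.zeros(3), np.zeros(3), p)
        np.testing.assert_array_equal(h, 0)
        np.testing.assert_array_equal(c, 0)

    def test_lstm_scalar_hand_values(self):
        one = lambda: np.ones((1, 1))
        p = nn.LSTMParams(
            T={k: one() for k in "yfpg"},
            W={k: one() for k in "yfpg"},
            b={k: np.zeros(1) for k in "yfpg"},
        )
        h, c = nn.lstm_step(np.array([1.0]), np.zeros(1), np.zeros(1), p)
        assert c == pytest.approx(SIG1 * np.tanh(1.0), abs=1e-10)  # ~0.5568
        assert h == pytest.approx(SIG1 * np.tanh(SIG1 * np.tanh(1.0)), abs=1e-10)  # ~0.3696

    def test_lstm_saturated_gates_carry_cell_state(self):
        p = nn.LSTMParams(
            T={k: np.zeros((1, 1)) for k in "yfpg"},
            W={k: np.zeros((1, 1)) for k in "yfpg"},
            b={"y": np.array([-10.0]), "f": np.array([10.0]), "p": np.zeros(1), "g": np.zeros(1)},
        )
        c_prev = np.array([0.7])
        _, c = nn.lstm_step(np.zeros(1), np.zeros(1), c_prev, p)
        assert c == pytest.approx(0.7, abs=1e-3)

    def test_gru_scalar_hand_values(self):
        one = lambda: np.ones((1, 1))
        p = nn.GRUParams(
            T={k: one() for k in "usd"}, W={k: one() for k in "usd"}, b={k: np.zeros(1) for k in "usd"}
        )
        d = nn.gru_step(np.array([1.0]), np.zeros(1), p)
        assert d == pytest.approx(SIG1 * np.tanh(1.0), abs=1e-10)  # ~0.5568

    def test_gru_saturated_update_preserves_state(self):
        p = nn.GRUParams(
            T={k: np.zeros((1, 1)) for k in "usd"},
            W={k: np.zeros((1, 1)) for k in "usd"},
            b={"u": np.array([-10.0]), "s": np.zeros(1), "d": np.zeros(1)},
        )
        d = nn.gru_step(np.zeros(1), np.array([0.42]), p)
        assert d == pytest.approx(0.42, abs=1e-4)

    def test_shape_mismatch_raises(self):
        rng = np.random.default_rng(0)
        p = make_lstm(rng, 2, 3)
        with pytest.raises(ValueError):
            nn.lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)
        g = make_gru(rng, 2, 3)
        with pytest.raises(ValueError):
            nn.gru_step(np.ones(2), np.zeros(5), g)

    @pytest.mark.parametrize("trial", range(10))
    def test_cells_match_loop_oracles(self, trial):
        # >= 100 random instances overall across dims <= 3
        rng = np.random.default_rng(trial)
        for _ in range(10):
            d_in = int(rng.integers(1, 4))
            hid = int(rng.integers(1, 4))
            p = make_lstm(rng, d_in, hid, scale=1.0)
            x = rng.standard_normal(d_in)
            h0 = rng.standard_normal(hid)
            c0 = rng.standard_normal(hid)
            h, c = nn.lstm_step(x, h0, c0, p)
            ho, co = lstm_oracle(x, h0, c0, p)
            np.testing.assert_allclose(np.atleast_1d(h), ho, atol=1e-10)
            np.testing.assert_allclose(np.atleast_1d(c), co, atol=1e-10)
            g = make_gru(rng, d_in, hid, scale=1.0)
            dout = nn.gru_step(x, h0, g)
            np.testing.assert_allclose(np.atleast_1d(dout), gru_oracle(x, h0, g), atol=1e-10)

    def test_gate_ranges(self):
        # all sigmoid gates in (0,1), tanh candidates in (-1,1): bound outputs
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = make_gru(rng, 2, 3, scale=2.0)
            d_prev = rng.uniform(-1, 1, 3)
            d = nn.gru_step(rng.standard_normal(2), d_prev, p)
            # convex combination of d_prev and tanh candidate stays in (-1,1)
            assert np.all(np.abs(d) < 1.0 + 1e-12)
            pl = make_lstm(rng, 2, 3, scale=2.0)
            h, _c = nn.lstm_step(rng.standard_normal(2), d_prev, rng.uniform(-1, 1, 3), pl)
            assert np.all(np.abs(h) < 1.0)  # |p * tanh(c)| < 1


class TestStacks:
    def test_single_layer_equals_unrolled_steps(self):
        rng = np.random.default_rng(2)
        p = make_lstm(rng, 2, 3)
        X = rng.standard_normal((4, 2))
        last, seqs = nn.stacked_forward(X, [p], "lstm")
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(4):
            h, c = nn.lstm_step(X[t], h, c, p)
        np.testing.assert_allclose(last, h, atol=1e-12)
        np.testing.assert_allclose(seqs[0][-1], h, atol=1e-12)

    def test_zero_weights_all_hidden_zero(self):
        zero = lambda shape: np.zeros(shape)
        layers = [
            nn.LSTMParams(
                T={k: zero((2, 3)) for k in "yfpg"},
                W={k: zero((3, 3)) for k in "yfpg"},
                b={k: zero(3) for k in "yfpg"},
            ),
            nn.LSTMParams(
                T={k: zero((3, 3)) for k in "yfpg"},
                W={k: zero((3, 3)) for k in "yfpg"},
                b={k: zero(3) for k in "yfpg"},
            ),
        ]
        last, seqs = nn.stacked_forward(np.ones((3, 2)), layers, "lstm")
        np.testing.assert_array_equal(last, 0)
        for s in seqs:
            np.testing.assert_array_equal(s, 0)

    def test_two_layer_hand_unrolling(self):
        rng = np.random.default_rng(5)
        l1 = make_gru(rng, 1, 1)
        l2 = make_gru(rng, 1, 1)
        X = rng.standard_normal((3, 1))
        last, _ = nn.stacked_forward(X, [l1, l2], "gru")
        d1 = np.zeros(1)
        d2 = np.zeros(1)
        for t in range(3):
            d1 = np.atleast_1d(nn.gru_step(X[t], d1, l1))
            d2 = np.atleast_1d(nn.gru_step(d1, d2, l2))
        np.testing.assert_allclose(np.atleast_1d(last), d2, atol=1e-12)


class TestHybrid:
    def test_bias_passthrough_when_weights_zero(self):
        m = nn.init_hybrid(2, 2, hidden_units=3, lstm_layers=1, gru_layers=1, seed=0)
        for _key, arr in nn.iter_params(m):
            arr[...] = 0.0
        m.final.b[:] = [0.4, 0.02]
        out = nn.hybrid_forward(np.ones((3, 2)), m)
        np.testing.assert_allclose(out, [0.4, 0.02])
        out2 = nn.hybrid_forward(np.full((3, 2), 7.0), m)
        np.testing.assert_allclose(out2, [0.4, 0.02])

    def test_branch_permutation_symmetry(self):
        rng = np.random.default_rng(8)
        m = nn.init_hybrid(2, 2, hidden_units=3, lstm_layers=1, gru_layers=1, seed=3)
        X = rng.standard_normal((3, 2))
        base = nn.hybrid_forward(X, m)
        # swap the concatenation order along with the final weight rows
        k = m.fcn_lstm.b.shape[0]
        swapped = nn.HybridModel(
            lstm_stack=m.lstm_stack,
            gru_stack=m.gru_stack,
            fcn_lstm=m.fcn_lstm,
            fcn_gru=m.fcn_gru,
            final=nn.DenseParams(np.vstack([m.final.W[k:], m.final.W[:k]]), m.final.b),
            activation=m.activation,
        )
        hL, _ = nn.stacked_forward(X, m.lstm_stack, "lstm")
        hG, _ = nn.stacked_forward(X, m.gru_stack, "gru")
        yL = np.maximum(hL @ m.fcn_lstm.W + m.fcn_lstm.b, 0)
        yG = np.maximum(hG @ m.fcn_gru.W + m.fcn_gru.b, 0)
        manual = np.concatenate([yG, yL]) @ swapped.final.W + swapped.final.b
        np.testing.assert_allclose(manual, base, atol=1e-12)

    def test_single_cell_composition(self):
        # hidden=1, L=G=1: the hybrid is the composition of the two cell
        # oracles with two affine maps
        m = nn.init_hybrid(1, 1, hidden_units=1, lstm_layers=1, gru_layers=1,
                           activation="linear", seed=4)
        X = np.array([[0.3], [0.7]])
        h = np.zeros(1)
        c = np.zeros(1)
        for t in range(2):
            h, c = nn.lstm_step(X[t], h, c, m.lstm_stack[0])
        d = np.zeros(1)
        for t in range(2):
            d = np.atleast_1d(nn.gru_step(X[t], d, m.gru_stack[0]))
        yL = np.atleast_1d(h) @ m.fcn_lstm.W + m.fcn_lstm.b
        yG = d @ m.fcn_gru.W + m.fcn_gru.b
        manual = np.concatenate([yL, yG]) @ m.final.W + m.final.b
        np.testing.assert_allclose(nn.hybrid_forward(X, m), manual, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        m = nn.init_hybrid(2, 2, hidden_units=2, seed=0)
        X = np.full((3, 2), np.nan)
        with pytest.raises(ValueError):
            nn.hybrid_forward(X, m)


class TestGradients:
    @pytest.mark.parametrize("lstm_layers,gru_layers", [(1, 1), (2, 2), (2, 0), (0, 2)])
    def test_backprop_matches_finite_differences(self, lstm_layers, gru_layers):
        rng = np.random.default_rng(11)
        m = nn.init_hybrid(
            2, 2, hidden_units=3, lstm_layers=lstm_layers, gru_layers=gru_layers,
            activation="tanh", seed=1,
        )
        X = rng.standard_normal((4, 3, 2))
        Y = rng.standard_normal((4, 2))

        def loss():
            out = nn.hybrid_forward(X, m)
            return ((out - Y) ** 2).mean()

        cache = nn._hybrid_forward_cached(X, m)
        err = cache[0] - Y
        grads = nn.hybrid_backward(X, 2 * err / err.size, m, cache)
        flat = nn.flatten_grads(m, grads)
        eps = 1e-6
        checked = 0
        for key, arr in nn.iter_params(m):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 4)):
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert flat[key][idx] == pytest.approx(num, abs=5e-7, rel=1e-4)
                checked += 1
                it.iternext()
        assert checked > 50


class TestInit:
    def test_seed_determinism(self):
        a = nn.init_hybrid(2, 2, hidden_units=5, seed=7)
        b = nn.init_hybrid(2, 2, hidden_units=5, seed=7)
        for (ka, va), (kb, vb) in zip(nn.iter_params(a), nn.iter_params(b)):
            assert ka == kb
            np.testing.assert_array_equal(va, vb)

    def test_different_seeds_differ(self):
        a = nn.init_hybrid(2, 2, hidden_units=5, seed=7)
        b = nn.init_hybrid(2, 2, hidden_units=5, seed=8)
        assert any(
            not np.array_equal(va, vb)
            for (_, va), (_, vb) in zip(nn.iter_params(a), nn.iter_params(b))
        )

    def test_shapes(self):
        m = nn.init_hybrid(2, 2, hidden_units=50, lstm_layers=2, gru_layers=2, seed=0)
        assert m.lstm_stack[0].T["y"].shape == (2, 50)
        assert m.lstm_stack[1].T["y"].shape == (50, 50)
        assert m.gru_stack[0].T["u"].shape == (2, 50)
        assert m.final.W.shape == (100, 2)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            nn.init_hybrid(2, 2, lstm_layers=0, gru_layers=0)
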