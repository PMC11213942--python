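"""Recurrent network primitives for the hybrid stacked LSTM-GRU forecaster.

Everything is plain numpy (float64) with hand-written reverse-mode
gradients, verified against central finite differences in the test suite.
The cells are the canonical LSTM and GRU formulations with per-gate input
weights ``T``, recurrent weights ``W`` and additive biases ``b``:

LSTM (input gate y, forget gate f, output gate p, candidate C~)::

    y_t = sigma(x_t Ty + h_{t-1} Wy + by)
    f_t = sigma(x_t Tf + h_{t-1} Wf + bf)
    p_t = sigma(x_t Tp + h_{t-1} Wp + bp)
    C~  = tanh (x_t Tg + h_{t-1} Wg + bg)
    C_t = f_t * C_{t-1} + y_t * C~
    h_t = p_t * tanh(C_t)

GRU (update gate u, reset gate s)::

    u_t = sigma(x_t Tu + d_{t-1} Wu + bu)
    s_t = sigma(x_t Ts + d_{t-1} Ws + bs)
    d~  = tanh (x_t Td + (s_t * d_{t-1}) Wd + bd)
    d_t = (1 - u_t) * d_{t-1} + u_t * d~

Stacking: layer l consumes the full hidden sequence of layer l-1.  The two
branch outputs (top-layer hidden state at the final step) pass through one
fully connected layer each (ReLU), are concatenated, and a final linear
layer produces the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMParams",
    "GRUParams",
    "DenseParams",
    "HybridModel",
    "lstm_step",
    "gru_step",
    "stacked_forward",
    "hybrid_forward",
    "init_hybrid",
    "AdamOptimizer",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_LSTM_GATES = ("y", "f", "p", "g")
_GRU_GATES = ("u", "s", "d")


@dataclass
class LSTMParams:
    """Per-gate weights of one LSTM layer (gates y, f, p and candidate g)."""

    T: dict[str, np.ndarray]  # input weights, (D, H) per gate
    W: dict[str, np.ndarray]  # recurrent weights, (H, H) per gate
    b: dict[str, np.ndarray]  # biases, (H,) per gate

    @property
    def hidden(self) -> int:
        return self.T["y"].shape[1]


@dataclass
class GRUParams:
    """Per-gate weights of one GRU layer (gates u, s and candidate d)."""

    T: dict[str, np.ndarray]
    W: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    @property
    def hidden(self) -> int:
        return self.T["u"].shape[1]


@dataclass
class DenseParams:
    W: np.ndarray
    b: np.ndarray


@dataclass
class HybridModel:
    """Parameter container for the stacked LSTM-GRU hybrid.

    Either stack may be empty (single-branch ablations); the full hybrid has
    at least one layer in each.  ``scaler`` holds per-feature min-max
    state ``(mins, maxs)`` fitted on the training split, shared between
    inputs and targets (both live in the same feature space).
    """

    lstm_stack: list[LSTMParams]
    gru_stack: list[GRUParams]
    fcn_lstm: DenseParams | None
    fcn_gru: DenseParams | None
    final: DenseParams
    activation: str = "relu"
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def input_dim(self) -> int:
        stack = self.lstm_stack or self.gru_stack
        key = "y" if self.lstm_stack else "u"
        return stack[0].T[key].shape[0]

    @property
    def output_dim(self) -> int:
        return self.final.b.shape[0]


# ---------------------------------------------------------------------------
# Single-step cells


def lstm_step(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One canonical LSTM step; accepts (D,) vectors or (B, D) batches."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=np.float64))
    if x.shape[1] != p.T["y"].shape[0] or h_prev.shape[1] != p.hidden:
        raise ValueError("lstm_step: input/hidden shapes do not match parameters")
    y = _sigmoid(x @ p.T["y"] + h_prev @ p.W["y"] + p.b["y"])
    f = _sigmoid(x @ p.T["f"] + h_prev @ p.W["f"] + p.b["f"])
    pg = _sigmoid(x @ p.T["p"] + h_prev @ p.W["p"] + p.b["p"])
    g = np.tanh(x @ p.T["g"] + h_prev @ p.W["g"] + p.b["g"])
    c = f * c_prev + y * g
    h = pg * np.tanh(c)
    return h.squeeze(), c.squeeze()


def gru_step(x: np.ndarray, d_prev: np.ndarray, p: GRUParams) -> np.ndarray:
    """One canonical GRU step; accepts (D,) vectors or (B, D) batches."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    d_prev = np.atleast_2d(np.asarray(d_prev, dtype=np.float64))
    if x.shape[1] != p.T["u"].shape[0] or d_prev.shape[1] != p.hidden:
        raise ValueError("gru_step: input/hidden shapes do not match parameters")
    u = _sigmoid(x @ p.T["u"] + d_prev @ p.W["u"] + p.b["u"])
    s = _sigmoid(x @ p.T["s"] + d_prev @ p.W["s"] + p.b["s"])
    g = np.tanh(x @ p.T["d"] + (s * d_prev) @ p.W["d"] + p.b["d"])
    d = (1.0 - u) * d_prev + u * g
    return d.squeeze()


# ---------------------------------------------------------------------------
# Sequence layers with caches (training path)


def _lstm_layer_forward(X: np.ndarray, p: LSTMParams):
    B, T, _ = X.shape
    H = p.hidden
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        xt = X[:, t]
        y = _sigmoid(xt @ p.T["y"] + h @ p.W["y"] + p.b["y"])
        f = _sigmoid(xt @ p.T["f"] + h @ p.W["f"] + p.b["f"])
        pg = _sigmoid(xt @ p.T["p"] + h @ p.W["p"] + p.b["p"])
        g = np.tanh(xt @ p.T["g"] + h @ p.W["g"] + p.b["g"])
        c_new = f * c + y * g
        hc = np.tanh(c_new)
        h_new = pg * hc
        cache.append((xt, h, c, y, f, pg, g, c_new, hc))
        h, c = h_new, c_new
        Hs[:, t] = h
    return Hs, cache


def _lstm_layer_backward(dH: np.ndarray, p: LSTMParams, cache):
    B, T, _ = dH.shape
    D = p.T["y"].shape[0]
    grads = {
        "T": {k: np.zeros_like(v) for k, v in p.T.items()},
        "W": {k: np.zeros_like(v) for k, v in p.W.items()},
        "b": {k: np.zeros_like(v) for k, v in p.b.items()},
    }
    dX = np.zeros((B, T, D))
    dh_next = np.zeros((B, p.hidden))
    dc_next = np.zeros((B, p.hidden))
    for t in reversed(range(T)):
        xt, h_prev, c_prev, y, f, pg, g, c_new, hc = cache[t]
        dh = dH[:, t] + dh_next
        dpg = dh * hc
        dap = dpg * pg * (1 - pg)
        dc = dh * pg * (1 - hc**2) + dc_next
        df = dc * c_prev
        daf = df * f * (1 - f)
        dy = dc * g
        day = dy * y * (1 - y)
        dg = dc * y
        dag = dg * (1 - g**2)
        dc_next = dc * f
        das = {"y": day, "f": daf, "p": dap, "g": dag}
        dxt = np.zeros((B, D))
        dh_prev = np.zeros((B, p.hidden))
        for k, da in das.items():
            dxt += da @ p.T[k].T
            dh_prev += da @ p.W[k].T
            grads["T"][k] += xt.T @ da
            grads["W"][k] += h_prev.T @ da
            grads["b"][k] += da.sum(axis=0)
        dX[:, t] = dxt
        dh_next = dh_prev
    return dX, grads


def _gru_layer_forward(X: np.ndarray, p: GRUParams):
    B, T, _ = X.shape
    H = p.hidden
    d = np.zeros((B, H))
    Ds = np.empty((B, T, H))
    cache = []
    for t in range(T):
        xt = X[:, t]
        u = _sigmoid(xt @ p.T["u"] + d @ p.W["u"] + p.b["u"])
        s = _sigmoid(xt @ p.T["s"] + d @ p.W["s"] + p.b["s"])
        sd = s * d
        g = np.tanh(xt @ p.T["d"] + sd @ p.W["d"] + p.b["d"])
        d_new = (1.0 - u) * d + u * g
        cache.append((xt, d, u, s, sd, g))
        d = d_new
        Ds[:, t] = d
    return Ds, cache


def _gru_layer_backward(dD: np.ndarray, p: GRUParams, cache):
    B, T, _ = dD.shape
    D_in = p.T["u"].shape[0]
    grads = {
        "T": {k: np.zeros_like(v) for k, v in p.T.items()},
        "W": {k: np.zeros_like(v) for k, v in p.W.items()},
        "b": {k: np.zeros_like(v) for k, v in p.b.items()},
    }
    dX = np.zeros((B, T, D_in))
    dd_next = np.zeros((B, p.hidden))
    for t in reversed(range(T)):
        xt, d_prev, u, s, sd, g = cache[t]
        dd = dD[:, t] + dd_next
        du = dd * (g - d_prev)
        dau = du * u * (1 - u)
        dg = dd * u
        dad = dg * (1 - g**2)
        dsd = dad @ p.W["d"].T
        ds = dsd * d_prev
        das = ds * s * (1 - s)
        dd_prev = dd * (1 - u) + dsd * s + dau @ p.W["u"].T + das @ p.W["s"].T
        dX[:, t] = dau @ p.T["u"].T + das @ p.T["s"].T + dad @ p.T["d"].T
        grads["T"]["u"] += xt.T @ dau
        grads["T"]["s"] += xt.T @ das
        grads["T"]["d"] += xt.T @ dad
        grads["W"]["u"] += d_prev.T @ dau
        grads["W"]["s"] += d_prev.T @ das
        grads["W"]["d"] += sd.T @ dad
        grads["b"]["u"] += dau.sum(axis=0)
        grads["b"]["s"] += das.sum(axis=0)
        grads["b"]["d"] += dad.sum(axis=0)
        dd_next = dd_prev
    return dX, grads


def stacked_forward(
    seq: np.ndarray, stack: list, cell_kind: str
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run a stack of recurrent layers over a sequence.

    Layer 1 consumes the input sequence; layer l consumes layer l-1's full
    hidden sequence.  Initial states are zero.  Returns the top layer's
    hidden state at the final step plus every layer's full hidden sequence.
    ``seq`` may be (T, D) or batched (B, T, D).
    """
    X = np.asarray(seq, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    seqs = []
    for layer in stack:
        if cell_kind == "lstm":
            X, _ = _lstm_layer_forward(X, layer)
        elif cell_kind == "gru":
            X, _ = _gru_layer_forward(X, layer)
        else:
            raise ValueError(f"unknown cell kind {cell_kind!r}")
        seqs.append(X[0] if single else X)
    last = X[:, -1]
    return (last[0] if single else last), seqs


# ---------------------------------------------------------------------------
# Hybrid forward/backward


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "linear":
        return x
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(pre: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (pre > 0).astype(pre.dtype)
    if kind == "linear":
        return np.ones_like(pre)
    if kind == "tanh":
        return 1 - np.tanh(pre) ** 2
    raise ValueError(f"unknown activation {kind!r}")


def hybrid_forward(seq: np.ndarray, m: HybridModel) -> np.ndarray:
    """Prediction of the hybrid model for scaled input sequences.

    Branch outputs ``y_L = phi(W_L H_T^L + b_L)`` and
    ``y_G = phi(W_G H_T^G + b_G)`` are concatenated and mapped through the
    final linear layer.  Operates in scaled feature space; callers apply
    the model scaler.  Accepts (T, D) or (B, T, D).
    """
    X = np.asarray(seq, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("hybrid_forward: non-finite inputs")
    single = X.ndim == 2
    if single:
        X = X[None]
    parts = []
    if m.lstm_stack:
        hL, _ = stacked_forward(X, m.lstm_stack, "lstm")
        parts.append(_act(hL @ m.fcn_lstm.W + m.fcn_lstm.b, m.activation))
    if m.gru_stack:
        hG, _ = stacked_forward(X, m.gru_stack, "gru")
        parts.append(_act(hG @ m.fcn_gru.W + m.fcn_gru.b, m.activation))
    concat = np.concatenate(parts, axis=1)
    out = concat @ m.final.W + m.final.b
    return out[0] if single else out


def _hybrid_forward_cached(X: np.ndarray, m: HybridModel):
    """Forward with all caches kept for the backward pass."""
    caches = {"lstm": [], "gru": []}
    branch = {}
    cur = X
    for layer in m.lstm_stack:
        cur, c = _lstm_layer_forward(cur, layer)
        caches["lstm"].append((cur, c))
    if m.lstm_stack:
        hL = cur[:, -1]
        preL = hL @ m.fcn_lstm.W + m.fcn_lstm.b
        branch["lstm"] = (hL, preL, _act(preL, m.activation))
    cur = X
    for layer in m.gru_stack:
        cur, c = _gru_layer_forward(cur, layer)
        caches["gru"].append((cur, c))
    if m.gru_stack:
        hG = cur[:, -1]
        preG = hG @ m.fcn_gru.W + m.fcn_gru.b
        branch["gru"] = (hG, preG, _act(preG, m.activation))
    parts = [branch[k][2] for k in ("lstm", "gru") if k in branch]
    concat = np.concatenate(parts, axis=1)
    out = concat @ m.final.W + m.final.b
    return out, concat, branch, caches


def hybrid_backward(X: np.ndarray, dout: np.ndarray, m: HybridModel, cache):
    """Gradients of the loss wrt every model parameter.

    ``cache`` is the tuple returned by :func:`_hybrid_forward_cached`;
    ``dout`` is dLoss/dOutput (B, output_dim).  Returns a nested grads
    structure mirroring :class:`HybridModel`.
    """
    out, concat, branch, caches = cache
    grads: dict = {"final": DenseParams(concat.T @ dout, dout.sum(axis=0))}
    dconcat = dout @ m.final.W.T
    offset = 0
    for kind, stack, fcn, lb, lf in (
        ("lstm", m.lstm_stack, m.fcn_lstm, _lstm_layer_backward, None),
        ("gru", m.gru_stack, m.fcn_gru, _gru_layer_backward, None),
    ):
        if not stack:
            continue
        h_top, pre, post = branch[kind]
        width = post.shape[1]
        dpost = dconcat[:, offset : offset + width]
        offset += width
        dpre = dpost * _act_grad(pre, m.activation)
        grads[f"fcn_{kind}"] = DenseParams(h_top.T @ dpre, dpre.sum(axis=0))
        dh_top = dpre @ fcn.W.T
        # gradient flows only into the last timestep of the top layer
        top_seq = caches[kind][-1][0]
        dH = np.zeros_like(top_seq)
        dH[:, -1] = dh_top
        layer_grads = []
        for li in reversed(range(len(stack))):
            _, layer_cache = caches[kind][li]
            dH, g = lb(dH, stack[li], layer_cache)
            layer_grads.append(g)
        grads[kind] = list(reversed(layer_grads))
    return grads


# ---------------------------------------------------------------------------
# Initialization and optimizer


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


def init_hybrid(
    input_dim: int,
    output_dim: int,
    hidden_units: int = 50,
    lstm_layers: int = 2,
    gru_layers: int = 2,
    fcn_units: int | None = None,
    activation: str = "relu",
    seed: int = 0,
) -> HybridModel:
    """Scaled-uniform (±1/sqrt(fan_in)) initialization; deterministic per seed."""
    if input_dim < 1 or output_dim < 1 or hidden_units < 1:
        raise ValueError("dimensions must be >= 1")
    if lstm_layers < 0 or gru_layers < 0 or lstm_layers + gru_layers == 0:
        raise ValueError("need at least one recurrent layer overall")
    rng = np.random.default_rng(seed)
    fcn_units = fcn_units or hidden_units

    def lstm_layer(d_in: int) -> LSTMParams:
        return LSTMParams(
            T={k: _uniform(rng, (d_in, hidden_units), d_in) for k in _LSTM_GATES},
            W={k: _uniform(rng, (hidden_units, hidden_units), hidden_units) for k in _LSTM_GATES},
            b={k: np.zeros(hidden_units) for k in _LSTM_GATES},
        )

    def gru_layer(d_in: int) -> GRUParams:
        return GRUParams(
            T={k: _uniform(rng, (d_in, hidden_units), d_in) for k in _GRU_GATES},
            W={k: _uniform(rng, (hidden_units, hidden_units), hidden_units) for k in _GRU_GATES},
            b={k: np.zeros(hidden_units) for k in _GRU_GATES},
        )

    lstm_stack = [lstm_layer(input_dim if i == 0 else hidden_units) for i in range(lstm_layers)]
    gru_stack = [gru_layer(input_dim if i == 0 else hidden_units) for i in range(gru_layers)]
    fcn_lstm = (
        DenseParams(_uniform(rng, (hidden_units, fcn_units), hidden_units), np.zeros(fcn_units))
        if lstm_layers
        else None
    )
    fcn_gru = (
        DenseParams(_uniform(rng, (hidden_units, fcn_units), hidden_units), np.zeros(fcn_units))
        if gru_layers
        else None
    )
    concat_dim = fcn_units * ((lstm_layers > 0) + (gru_layers > 0))
    final = DenseParams(_uniform(rng, (concat_dim, output_dim), concat_dim), np.zeros(output_dim))
    return HybridModel(lstm_stack, gru_stack, fcn_lstm, fcn_gru, final, activation)


def iter_params(m: HybridModel):
    """Yield (key, array) references for every trainable array."""
    for kind, stack in (("lstm", m.lstm_stack), ("gru", m.gru_stack)):
        for li, layer in enumerate(stack):
            for group in ("T", "W", "b"):
                for gate, arr in getattr(layer, group).items():
                    yield f"{kind}.{li}.{group}.{gate}", arr
    for name, dense in (("fcn_lstm", m.fcn_lstm), ("fcn_gru", m.fcn_gru), ("final", m.final)):
        if dense is None:
            continue
        yield f"{name}.W", dense.W
        yield f"{name}.b", dense.b


def flatten_grads(m: HybridModel, grads: dict):
    """Flatten the nested grads structure to match :func:`iter_params` keys."""
    flat = {}
    for kind in ("lstm", "gru"):
        for li, g in enumerate(grads.get(kind, [])):
            for group in ("T", "W", "b"):
                for gate, arr in g[group].items():
                    flat[f"{kind}.{li}.{group}.{gate}"] = arr
    if "fcn_lstm" in grads:
        flat["fcn_lstm.W"] = grads["fcn_lstm"].W
        flat["fcn_lstm.b"] = grads["fcn_lstm"].b
    if "fcn_gru" in grads:
        flat["fcn_gru.W"] = grads["fcn_gru"].W
        flat["fcn_gru.b"] = grads["fcn_gru"].b
    flat["final.W"] = grads["final"].W
    flat["final.b"] = grads["final"].b
    return flat


class AdamOptimizer:
    """Adaptive-moment gradient descent updating parameters in place."""

    def __init__(self, model: HybridModel, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in iter_params(model)}
        self.v = {k: np.zeros_like(v) for k, v in iter_params(model)}

    def step(self, grads: dict) -> None:
        flat = flatten_grads(self.model, grads)
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for key, arr in iter_params(self.model):
            g = flat[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
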