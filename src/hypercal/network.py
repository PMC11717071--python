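"""BiLSTM-Attention regressor for spectra, implemented in NumPy.

The spectrum is treated as an ordered sequence over wavelength: one
reflectance value per step, in increasing-wavelength order. Architecture:

1. Two stacked bidirectional LSTM layers (per-direction hidden sizes
   ``hidden1`` then ``hidden2``). At every step the forward and backward
   hidden states are merged through a tanh-weighted combination

       O_t = tanh(W_fwd h_fwd_t + W_bwd h_bwd_t + b)

2. Additive attention pooling over steps: a learned projection of width
   ``attn_dim`` scores each merged state, scores are softmax-normalized to a
   distribution, and the context vector is the attention-weighted sum of the
   merged states. (A dot-product scoring variant is available.)
3. A tanh dense layer of width ``dense`` and a scalar linear output.

Targets are standardized to zero mean / unit sd on the training set before
optimization (Adam on mean squared error); predictions are de-standardized.
Plain unidirectional LSTM and no-attention BiLSTM variants are included for
model comparisons. All gradients are computed by hand-written backpropagation
and are validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["NetConfig", "BiLSTMAttention", "TrainingHistory"]


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters of the recurrent regressor."""

    lr: float = 0.01
    num_epochs: int = 30
    batch_size: int = 16
    hidden1: int = 10
    hidden2: int = 10
    dense: int = 20
    attn_dim: int = 20
    seed: int = 0
    bidirectional: bool = True
    attention: bool = True
    attention_kind: str = "additive"  # or "dot"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        for name in ("num_epochs", "batch_size", "hidden1", "hidden2", "dense", "attn_dim"):
            if getattr(self, name) < (0 if name == "num_epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if self.attention_kind not in ("additive", "dot"):
            raise ValueError("attention_kind must be 'additive' or 'dot'")


@dataclass
class TrainingHistory:
    """Per-epoch mean squared error on standardized targets."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _lstm_init(rng, d_in: int, h: int) -> dict[str, np.ndarray]:
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget-gate bias at 1, standard recurrent initialization
    return {"Wx": _glorot(rng, (d_in, 4 * h)), "Wh": _glorot(rng, (h, 4 * h)), "b": b}


def _lstm_steps_py(pre: np.ndarray, Wh: np.ndarray):
    """Recurrent loop, time-major: pre (T, B, 4H) already holds x@Wx + b."""
    T, B, H4 = pre.shape
    H = H4 // 4
    hs = np.empty((T, B, H))
    cs = np.empty((T, B, H))
    gates = np.empty((T, B, H4))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        z = pre[t] + np.dot(h, Wh)
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[t, :, :H] = i
        gates[t, :, H:2 * H] = f
        gates[t, :, 2 * H:3 * H] = g
        gates[t, :, 3 * H:] = o
        cs[t] = c
        hs[t] = h
    return hs, cs, gates


def _lstm_back_steps_py(dhs, hs, cs, gates, WhT):
    """Reverse recurrent loop (time-major); returns pre-activation grads."""
    T, B, H = dhs.shape
    dzs = np.empty((T, B, 4 * H))
    dh_rec = np.zeros((B, H))
    dc = np.zeros((B, H))
    zero = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[t, :, :H]
        f = gates[t, :, H:2 * H]
        g = gates[t, :, 2 * H:3 * H]
        o = gates[t, :, 3 * H:]
        c_prev = cs[t - 1] if t > 0 else zero
        dh = dhs[t] + dh_rec
        tc = np.tanh(cs[t])
        dc = dc + dh * o * (1.0 - tc * tc)
        dzt = np.empty((B, 4 * H))
        dzt[:, :H] = dc * g * i * (1.0 - i)
        dzt[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
        dzt[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
        dzt[:, 3 * H:] = dh * tc * o * (1.0 - o)
        dzs[t] = dzt
        dh_rec = np.dot(dzt, WhT)
        dc = dc * f
    return dzs


def _lstm_steps_loops(pre, Wh):
    """Scalar-loop variant of _lstm_steps_py for JIT compilation."""
    T, B, H4 = pre.shape
    H = H4 // 4
    hs = np.empty((T, B, H))
    cs = np.empty((T, B, H))
    gates = np.empty((T, B, H4))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        z = pre[t] + np.dot(h, Wh)
        for bi in range(B):
            for j in range(H):
                i = 1.0 / (1.0 + np.exp(-z[bi, j]))
                f = 1.0 / (1.0 + np.exp(-z[bi, H + j]))
                g = np.tanh(z[bi, 2 * H + j])
                o = 1.0 / (1.0 + np.exp(-z[bi, 3 * H + j]))
                cv = f * c[bi, j] + i * g
                c[bi, j] = cv
                h[bi, j] = o * np.tanh(cv)
                gates[t, bi, j] = i
                gates[t, bi, H + j] = f
                gates[t, bi, 2 * H + j] = g
                gates[t, bi, 3 * H + j] = o
                cs[t, bi, j] = cv
                hs[t, bi, j] = h[bi, j]
    return hs, cs, gates


def _lstm_back_steps_loops(dhs, hs, cs, gates, WhT):
    """Scalar-loop variant of _lstm_back_steps_py for JIT compilation."""
    T, B, H = dhs.shape
    dzs = np.empty((T, B, 4 * H))
    dh_rec = np.zeros((B, H))
    dc = np.zeros((B, H))
    dzt = np.empty((B, 4 * H))
    for t in range(T - 1, -1, -1):
        for bi in range(B):
            for j in range(H):
                i = gates[t, bi, j]
                f = gates[t, bi, H + j]
                g = gates[t, bi, 2 * H + j]
                o = gates[t, bi, 3 * H + j]
                c_prev = cs[t - 1, bi, j] if t > 0 else 0.0
                dh = dhs[t, bi, j] + dh_rec[bi, j]
                tc = np.tanh(cs[t, bi, j])
                dcv = dc[bi, j] + dh * o * (1.0 - tc * tc)
                dzt[bi, j] = dcv * g * i * (1.0 - i)
                dzt[bi, H + j] = dcv * c_prev * f * (1.0 - f)
                dzt[bi, 2 * H + j] = dcv * i * (1.0 - g * g)
                dzt[bi, 3 * H + j] = dh * tc * o * (1.0 - o)
                dc[bi, j] = dcv * f
        dzs[t] = dzt
        dh_rec = np.dot(dzt, WhT)
    return dzs


try:  # JIT the recurrent loops; the NumPy path above is the reference fallback
    from numba import njit

    _lstm_steps = njit(cache=False)(_lstm_steps_loops)
    _lstm_back_steps = njit(cache=False)(_lstm_back_steps_loops)
except ImportError:  # pragma: no cover
    _lstm_steps = _lstm_steps_py
    _lstm_back_steps = _lstm_back_steps_py


def _lstm_forward(x: np.ndarray, Wx, Wh, b):
    """x: (B, T, Din) -> hidden states (B, T, H) plus backprop cache."""
    pre_t = np.ascontiguousarray((x @ Wx + b).transpose(1, 0, 2))  # (T, B, 4H)
    hs_t, cs_t, gates_t = _lstm_steps(pre_t, Wh)
    cache = {"x": x, "hs_t": hs_t, "cs_t": cs_t, "gates_t": gates_t, "H": Wh.shape[0]}
    return hs_t.transpose(1, 0, 2), cache


def _lstm_backward(dhs: np.ndarray, cache, Wx, Wh):
    """dhs: (B, T, H) gradients flowing into each step's hidden state."""
    x, hs_t, H = cache["x"], cache["hs_t"], cache["H"]
    B, T, _ = x.shape
    dhs_t = np.ascontiguousarray(dhs.transpose(1, 0, 2))
    dzs_t = _lstm_back_steps(dhs_t, hs_t, cache["cs_t"], cache["gates_t"],
                             np.ascontiguousarray(Wh.T))
    TB = T * B
    # dWh = sum_t h_{t-1}^T dz_t as one matmul over the shifted state sequence
    h_prev = np.concatenate([np.zeros((1, B, H)), hs_t[:-1]], axis=0)
    dWh = h_prev.reshape(TB, H).T @ dzs_t.reshape(TB, 4 * H)
    dzs = dzs_t.transpose(1, 0, 2)
    dWx = x.reshape(B * T, -1).T @ dzs.reshape(B * T, 4 * H)
    db = dzs_t.sum(axis=(0, 1))
    dx = dzs @ Wx.T
    return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTMAttention:
    """Stacked (bi)LSTM regressor with optional attention pooling.

    ``forward`` is usable on an initialized model (deterministic given
    ``config.seed``); ``predict`` additionally requires a fitted target scaler
    and reports on the raw analyte scale.
    """

    def __init__(self, config: NetConfig, seq_len: int):
        if seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        self.config = config
        self.seq_len = seq_len
        self.fitted = False
        self.y_mean: float | None = None
        self.y_std: float | None = None
        # single global input-conditioning factor learned at fit time; a
        # scalar (not per-column) so differences between preprocessing
        # variants reaching the network are preserved
        self.x_scale: float = 1.0
        self.params = self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- parameters -------------------------------------------------------

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h1, h2 = cfg.hidden1, cfg.hidden2
        p: dict[str, np.ndarray] = {}
        for name, d_in, h in (("l1f", 1, h1), ("l2f", h1, h2)):
            for k, v in _lstm_init(rng, d_in, h).items():
                p[f"{name}_{k}"] = v
        if cfg.bidirectional:
            for name, d_in, h in (("l1b", 1, h1), ("l2b", h1, h2)):
                for k, v in _lstm_init(rng, d_in, h).items():
                    p[f"{name}_{k}"] = v
        for lname, h in (("l1", h1), ("l2", h2)):
            p[f"{lname}_Mf"] = _glorot(rng, (h, h))
            if cfg.bidirectional:
                p[f"{lname}_Mb"] = _glorot(rng, (h, h))
            p[f"{lname}_mb"] = np.zeros(h)
        if cfg.attention:
            if cfg.attention_kind == "additive":
                p["att_W"] = _glorot(rng, (h2, cfg.attn_dim))
                p["att_b"] = np.zeros(cfg.attn_dim)
                p["att_v"] = _glorot(rng, (cfg.attn_dim, 1))[:, 0]
            else:
                p["att_q"] = _glorot(rng, (h2, 1))[:, 0]
        p["den_W"] = _glorot(rng, (h2, cfg.dense))
        p["den_b"] = np.zeros(cfg.dense)
        p["out_w"] = _glorot(rng, (cfg.dense, 1))[:, 0]
        p["out_b"] = np.zeros(1)
        return p

    # -- forward ----------------------------------------------------------

    def _bilayer_forward(self, x, lname):
        """One stacked layer: (bi)LSTM + tanh merge. x: (B, T, Din)."""
        p = self.params
        hf, cache_f = _lstm_forward(x, p[f"{lname}f_Wx"], p[f"{lname}f_Wh"], p[f"{lname}f_b"])
        pre = hf @ p[f"{lname}_Mf"] + p[f"{lname}_mb"]
        cache = {"f": cache_f, "hf": hf}
        if self.config.bidirectional:
            xr = x[:, ::-1]
            hb_rev, cache_b = _lstm_forward(
                xr, p[f"{lname}b_Wx"], p[f"{lname}b_Wh"], p[f"{lname}b_b"]
            )
            hb = hb_rev[:, ::-1]
            pre = pre + hb @ p[f"{lname}_Mb"]
            cache.update(b=cache_b, hb=hb)
        M = np.tanh(pre)
        cache["M"] = M
        return M, cache

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Standardized-scale predictions for X (n, seq_len)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.seq_len:
            raise ValueError(f"input has {X.shape[1]} bands, model expects {self.seq_len}")
        p = self.params
        x1 = X[:, :, None]
        M1, c1 = self._bilayer_forward(x1, "l1")
        M2, c2 = self._bilayer_forward(M1, "l2")
        B, T, H2 = M2.shape
        if self.config.attention:
            if self.config.attention_kind == "additive":
                u = np.tanh(M2 @ p["att_W"] + p["att_b"])   # (B, T, attn)
                s = u @ p["att_v"]                          # (B, T)
            else:
                u = None
                s = M2 @ p["att_q"]
            s = s - s.max(axis=1, keepdims=True)
            e = np.exp(s)
            alpha = e / e.sum(axis=1, keepdims=True)
            ctx = (alpha[:, :, None] * M2).sum(axis=1)
        else:
            u, alpha = None, None
            ctx = M2[:, -1]
        d = np.tanh(ctx @ p["den_W"] + p["den_b"])
        yhat = d @ p["out_w"] + p["out_b"][0]
        if not want_cache:
            return yhat
        cache = {"X": X, "c1": c1, "c2": c2, "M1": M1, "M2": M2,
                 "u": u, "alpha": alpha, "ctx": ctx, "d": d}
        return yhat, cache

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-step attention distribution (rows sum to 1)."""
        if not self.config.attention:
            raise RuntimeError("model built without attention")
        _, cache = self.forward(np.asarray(X, dtype=float) / self.x_scale, want_cache=True)
        return cache["alpha"]

    # -- backward ---------------------------------------------------------

    def _bilayer_backward(self, dM, cache, lname, grads):
        p = self.params
        M = cache["M"]
        dpre = dM * (1.0 - M * M)
        B, T, H = dpre.shape
        BT = B * T
        hf = cache["hf"]
        grads[f"{lname}_Mf"] = hf.reshape(BT, -1).T @ dpre.reshape(BT, H)
        grads[f"{lname}_mb"] = dpre.sum(axis=(0, 1))
        dhf = dpre @ p[f"{lname}_Mf"].T
        dx, g = _lstm_backward(dhf, cache["f"], p[f"{lname}f_Wx"], p[f"{lname}f_Wh"])
        for k, v in g.items():
            grads[f"{lname}f_{k}"] = v
        if self.config.bidirectional:
            hb = cache["hb"]
            grads[f"{lname}_Mb"] = hb.reshape(BT, -1).T @ dpre.reshape(BT, H)
            dhb = dpre @ p[f"{lname}_Mb"].T
            dxb_rev, gb = _lstm_backward(
                dhb[:, ::-1], cache["b"], p[f"{lname}b_Wx"], p[f"{lname}b_Wh"]
            )
            for k, v in gb.items():
                grads[f"{lname}b_{k}"] = v
            dx = dx + dxb_rev[:, ::-1]
        return dx

    def loss_and_grads(self, X: np.ndarray, y_std: np.ndarray):
        """Mean squared error on standardized targets and its gradients."""
        p = self.params
        yhat, cache = self.forward(X, want_cache=True)
        B = len(yhat)
        err = yhat - y_std
        loss = float(err @ err / B)
        dyhat = 2.0 * err / B

        grads: dict[str, np.ndarray] = {}
        d, ctx, M2 = cache["d"], cache["ctx"], cache["M2"]
        grads["out_w"] = d.T @ dyhat
        grads["out_b"] = np.array([dyhat.sum()])
        dd = np.outer(dyhat, p["out_w"])
        dpre_d = dd * (1.0 - d * d)
        grads["den_W"] = ctx.T @ dpre_d
        grads["den_b"] = dpre_d.sum(axis=0)
        dctx = dpre_d @ p["den_W"].T

        if self.config.attention:
            alpha, u = cache["alpha"], cache["u"]
            Bn, T, H2 = M2.shape
            dalpha = (dctx[:, None, :] * M2).sum(axis=2)              # (B, T)
            dM2 = alpha[:, :, None] * dctx[:, None, :]
            ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
            if self.config.attention_kind == "additive":
                grads["att_v"] = (u * ds[:, :, None]).sum(axis=(0, 1))
                du = ds[:, :, None] * p["att_v"]
                dpre_u = du * (1.0 - u * u)
                BT = Bn * T
                grads["att_W"] = M2.reshape(BT, H2).T @ dpre_u.reshape(BT, -1)
                grads["att_b"] = dpre_u.sum(axis=(0, 1))
                dM2 = dM2 + dpre_u @ p["att_W"].T
            else:
                grads["att_q"] = (M2 * ds[:, :, None]).sum(axis=(0, 1))
                dM2 = dM2 + ds[:, :, None] * p["att_q"]
        else:
            dM2 = np.zeros_like(M2)
            dM2[:, -1] = dctx

        dM1 = self._bilayer_backward(dM2, cache["c2"], "l2", grads)
        self._bilayer_backward(dM1, cache["c1"], "l1", grads)
        return loss, grads

    # -- training ---------------------------------------------------------

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        track_history: bool = True,
    ) -> TrainingHistory:
        """Minimize MSE on standardized targets with Adam minibatches.

        The target scaler (mean/sd) and the global input-conditioning scale
        come from the training data only.
        Raises on divergence (NaN loss — learning rate too high).
        """
        cfg = self.config
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std())
        if self.y_std == 0:
            raise ValueError("training targets are constant; cannot standardize")
        sx = float(X.std())
        self.x_scale = sx if sx > 0 else 1.0
        X = X / self.x_scale
        ys = (y - self.y_mean) / self.y_std
        if X_val is not None:
            X_val = np.atleast_2d(np.asarray(X_val, dtype=float)) / self.x_scale
            yvs = (np.asarray(y_val, float).ravel() - self.y_mean) / self.y_std
        bs = min(cfg.batch_size, n)
        rng = np.random.default_rng(cfg.seed + 1)
        history = TrainingHistory()
        for _epoch in range(cfg.num_epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                rows = perm[start:start + bs]
                loss, grads = self.loss_and_grads(X[rows], ys[rows])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {_epoch + 1}; "
                        f"learning rate {cfg.lr} is likely too high"
                    )
                self._adam_step(grads, cfg.lr)
                losses.append(loss)
            if track_history:
                history.train_mse.append(float(np.mean(losses)))
                if X_val is not None:
                    pv = self.forward(X_val)
                    history.val_mse.append(float(np.mean((pv - yvs) ** 2)))
        self.fitted = True
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        """De-standardized scalar predictions; requires a fitted model."""
        if not self.fitted:
            raise RuntimeError("model is not fitted; call fit() first")
        return self.forward(np.asarray(X, dtype=float) / self.x_scale) * self.y_std + self.y_mean

    def validation_mse(self, X: np.ndarray, y: np.ndarray) -> float:
        """MSE on standardized targets (the tuning fitness)."""
        ys = (np.asarray(y, float).ravel() - self.y_mean) / self.y_std
        preds = self.forward(np.asarray(X, dtype=float) / self.x_scale)
        return float(np.mean((preds - ys) ** 2))

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint: named-array archive + JSON config (bit-exact)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        meta = {
            "config": asdict(self.config),
            "seq_len": self.seq_len,
            "fitted": self.fitted,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "x_scale": self.x_scale,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "BiLSTMAttention":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        model = cls(NetConfig(**meta["config"]), meta["seq_len"])
        with np.load(directory / "params.npz") as npz:
            model.params = {k: npz[k].copy() for k in npz.files}
        model.fitted = meta["fitted"]
        model.y_mean = meta["y_mean"]
        model.y_std = meta["y_std"]
        model.x_scale = meta.get("x_scale", 1.0)
        return model
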