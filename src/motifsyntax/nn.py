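"""A compact, deterministic numpy implementation of the hybrid CNN+GRU predictor.

The network maps an encoded sequence (L x C one-hot(+track) matrix) to a scalar.
Architecture: ``n_blocks`` repeats of LayerNorm -> Conv1D (valid) -> ReLU ->
MaxPool, followed by a GRU whose final hidden state feeds a small dense head.
All parameters are float32 numpy arrays; gradients are computed by manual
backpropagation and optimised with Adam. Every source of randomness
(initialisation, minibatch order) is driven by a single integer seed, so
training is bit-reproducible on a fixed backend.

Variable-length input is handled with zero padding plus an explicit valid
length per sequence: convolution windows that touch padding are marked
invalid, excluded from pooling maxima, and the GRU output is read at the last
valid step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: tuple = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LayerNorm(Layer):
    """Normalises each position's channel vector; learned per-channel gain/bias."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"g": np.ones(channels, dtype=_F32), "b": np.zeros(channels, dtype=_F32)}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.params["g"] * xhat + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["g"]
        self.grads["g"] = (dout * xhat).sum(axis=(0, 1))
        self.grads["b"] = dout.sum(axis=(0, 1))
        dxhat = dout * g
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution over the position axis."""

    def __init__(self, in_channels: int, filters: int, width: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.width = width
        self.in_channels = in_channels
        self.filters = filters
        scale = np.sqrt(2.0 / (width * in_channels))
        self.params = {
            "W": (rng.standard_normal((width * in_channels, filters)) * scale).astype(_F32),
            "b": np.zeros(filters, dtype=_F32),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, L, C) -> (B, P, width*C) with P = L - width + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)  # (B,P,C,w)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, self.width * self.in_channels
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._im2col(x)
        if train:
            self._cache = (cols, x.shape)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        B, P, _ = dout.shape
        F = self.filters
        self.grads["W"] = cols.reshape(-1, cols.shape[-1]).T @ dout.reshape(-1, F)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(B, P, self.width, self.in_channels)
        dx = np.zeros(xshape, dtype=_F32)
        for k in range(self.width):
            dx[:, k : k + P, :] += dcols[:, :, k, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._cache = (x > 0,)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (mask,) = self._cache
        return dout * mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling in ceil mode (a partial last window is kept).

    Positions past a sequence's valid length — and ceil-mode padding — are
    excluded from the maxima, so padding never leaks into downstream layers.
    """

    def __init__(self, width: int) -> None:
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray, train: bool, valid: np.ndarray | None = None) -> np.ndarray:
        B, L, C = x.shape
        n = -(-L // self.width)
        pad = n * self.width - L
        if pad:
            x = np.concatenate([x, np.zeros((B, pad, C), dtype=x.dtype)], axis=1)
        if valid is None:
            valid = np.full(B, L, dtype=int)
        xt = x.reshape(B, n, self.width, C)
        pos = np.arange(n * self.width).reshape(n, self.width)
        invalid = pos[None, :, :, None] >= valid[:, None, None, None]
        xt = np.where(invalid, -np.inf, xt)
        idx = xt.argmax(axis=2)
        out = np.take_along_axis(xt, idx[:, :, None, :], axis=2).squeeze(2)
        out = np.where(np.isfinite(out), out, 0.0).astype(_F32)
        if train:
            self._cache = (idx, (B, L, C), np.isfinite(xt).any(axis=2))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape, finite = self._cache
        B, L, C = xshape
        n = dout.shape[1]
        dxt = np.zeros((B, n, self.width, C), dtype=_F32)
        np.put_along_axis(dxt, idx[:, :, None, :], (dout * finite)[:, :, None, :], axis=2)
        return dxt.reshape(B, n * self.width, C)[:, :L]


class GRU(Layer):
    """Gated recurrent unit; emits the hidden state at each sequence's last valid step."""

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        sx = np.sqrt(1.0 / in_channels)
        sh = np.sqrt(1.0 / units)
        p = {}
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = (rng.standard_normal((in_channels, units)) * sx).astype(_F32)
            p[f"U{gate}"] = (rng.standard_normal((units, units)) * sh).astype(_F32)
            p[f"b{gate}"] = np.zeros(units, dtype=_F32)
        self.params = p

    def forward(self, x: np.ndarray, train: bool, last_step: np.ndarray | None = None) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        h = np.zeros((B, self.units), dtype=_F32)
        if last_step is None:
            last_step = np.full(B, T - 1, dtype=int)
        steps = []
        out = np.zeros((B, self.units), dtype=_F32)
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(xt @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * c
            if train:
                steps.append((xt, h, z, r, c))
            take = last_step == t
            if take.any():
                out[take] = h_new[take]
            h = h_new
        if train:
            self._cache = (steps, last_step, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        steps, last_step, xshape = self._cache
        p = self.params
        for name in p:
            self.grads[name] = np.zeros_like(p[name])
        g = self.grads
        dx = np.zeros(xshape, dtype=_F32)
        dh = np.zeros_like(dout)
        T = xshape[1]
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, c = steps[t]
            dh = dh + dout * (last_step == t)[:, None]
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dc_pre = dc * (1.0 - c * c)
            g["Wh"] += xt.T @ dc_pre
            g["bh"] += dc_pre.sum(axis=0)
            dx[:, t, :] += dc_pre @ p["Wh"].T
            drh = dc_pre @ p["Uh"].T
            g["Uh"] += (r * h_prev).T @ dc_pre
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            g["Wz"] += xt.T @ dz_pre
            g["Uz"] += h_prev.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            g["Wr"] += xt.T @ dr_pre
            g["Ur"] += h_prev.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)
            dx[:, t, :] += dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            dh = dh_prev + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        return dx


class Dropout(Layer):
    """Inverted dropout; active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate).astype(_F32) / (1.0 - self.rate)
        self._cache = (mask,)
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if not self._cache:
            return dout
        (mask,) = self._cache
        return dout * mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": (rng.standard_normal((in_features, out_features)) * scale).astype(_F32),
            "b": np.zeros(out_features, dtype=_F32),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = (x,)
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


@dataclass
class ConvBlock:
    norm: LayerNorm
    conv: Conv1D
    relu: ReLU
    pool: MaxPool1D


class Adam:
    """Adam with decoupled weight decay (applied to weights, not gains/biases)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[int, dict[str, np.ndarray]] = {}
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self.m.setdefault(li, {k: np.zeros_like(v) for k, v in layer.params.items()})
            v = self.v.setdefault(li, {k: np.zeros_like(p) for k, p in layer.params.items()})
            for k, grad in layer.grads.items():
                m[k] = self.b1 * m[k] + (1.0 - self.b1) * grad
                v[k] = self.b2 * v[k] + (1.0 - self.b2) * grad * grad
                step = self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                if self.weight_decay and k[0] in "WU":
                    step = step + self.lr * self.weight_decay * layer.params[k]
                layer.params[k] -= step.astype(_F32)


class ConvGRUNetwork:
    """The assembled predictor: conv blocks, GRU, dense head; scalar output."""

    def __init__(
        self,
        n_channels: int,
        n_blocks: int,
        filters: int,
        kernel_width: int,
        pool_width: int,
        gru_units: int,
        dense_units: int,
        seed: int,
        dropout: float = 0.0,
    ) -> None:
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 100_003)
        self.n_blocks = n_blocks
        self.kernel_width = kernel_width
        self.pool_width = pool_width
        self.blocks: list[ConvBlock] = []
        c = n_channels
        for _ in range(n_blocks):
            self.blocks.append(
                ConvBlock(LayerNorm(c), Conv1D(c, filters, kernel_width, rng), ReLU(), MaxPool1D(pool_width))
            )
            c = filters
        self.gru = GRU(c, gru_units, rng)
        self.do_gru = Dropout(dropout, drop_rng)
        self.fc1 = Dense(gru_units, dense_units, rng)
        self.fc_relu = ReLU()
        self.do_fc = Dropout(dropout, drop_rng)
        self.fc2 = Dense(dense_units, 1, rng)

    # ------------------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.blocks:
            out += [b.norm, b.conv, b.relu, b.pool]
        out += [self.gru, self.do_gru, self.fc1, self.fc_relu, self.do_fc, self.fc2]
        return out

    def architecture(self) -> list[dict]:
        """Structural description (conv/pool widths) used for receptive-field math."""
        arch = []
        for _ in range(self.n_blocks):
            arch.append({"kind": "conv", "width": self.kernel_width, "stride": 1})
            arch.append({"kind": "pool", "width": self.pool_width, "stride": self.pool_width})
        return arch

    # ------------------------------------------------------------------
    def _valid_after(self, valid: np.ndarray, block_index: int) -> np.ndarray:
        """Valid conv-output length per sequence after the given block's conv."""
        v = valid.copy()
        for _ in range(block_index):
            v = np.maximum(v - self.kernel_width + 1, 0)
            v = -(-v // self.pool_width)
        return np.maximum(v - self.kernel_width + 1, 0)

    def forward(
        self,
        x: np.ndarray,
        valid: np.ndarray | None = None,
        train: bool = False,
        collect: int | None = None,
    ):
        """Run the network; returns predictions (B,) or conv activations.

        ``collect`` = 1-based conv-block index: return that block's post-ReLU
        activations (B, positions, filters) instead of predictions.
        """
        B, L, _ = x.shape
        if valid is None:
            valid = np.full(B, L, dtype=int)
        h = x.astype(_F32)
        v = valid.astype(int)
        for bi, blk in enumerate(self.blocks, start=1):
            h = blk.norm.forward(h, train)
            h = blk.conv.forward(h, train)
            h = blk.relu.forward(h, train)
            v = np.maximum(v - self.kernel_width + 1, 0)
            if collect == bi:
                act = h.copy()
                pos = np.arange(h.shape[1])
                act[pos[None, :] >= v[:, None]] = 0.0
                return act
            h = blk.pool.forward(h, train, valid=v)
            v = -(-v // self.pool_width)
        if h.shape[1] == 0:
            raise ValueError("sequence too short: no positions remain before the GRU")
        last_step = np.maximum(v - 1, 0)
        h = self.gru.forward(h, train, last_step=last_step)
        h = self.do_gru.forward(h, train)
        h = self.fc1.forward(h, train)
        h = self.fc_relu.forward(h, train)
        h = self.do_fc.forward(h, train)
        out = self.fc2.forward(h, train)
        return out[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = self.fc2.backward(dpred[:, None])
        d = self.do_fc.backward(d)
        d = self.fc_relu.backward(d)
        d = self.fc1.backward(d)
        d = self.do_gru.backward(d)
        d = self.gru.backward(d)
        for blk in reversed(self.blocks):
            d = blk.pool.backward(d)
            d = blk.relu.backward(d)
            d = blk.conv.backward(d)
            d = blk.norm.backward(d)

    # ------------------------------------------------------------------
    def get_params(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_params(self, snapshot: list[dict[str, np.ndarray]]) -> None:
        for layer, saved in zip(self.layers, snapshot):
            for k in layer.params:
                layer.params[k] = saved[k].copy()

    def predict(self, x: np.ndarray, valid: np.ndarray | None = None, batch_size: int = 512) -> np.ndarray:
        out = np.empty(x.shape[0], dtype=float)
        for i in range(0, x.shape[0], batch_size):
            sl = slice(i, i + batch_size)
            out[sl] = self.forward(x[sl], None if valid is None else valid[sl], train=False)
        return out

    def conv_activations(
        self, x: np.ndarray, block: int, valid: np.ndarray | None = None, batch_size: int = 512
    ) -> np.ndarray:
        if not 1 <= block <= self.n_blocks:
            raise ValueError(f"conv block index {block} outside 1..{self.n_blocks}")
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            sl = slice(i, i + batch_size)
            chunks.append(self.forward(x[sl], None if valid is None else valid[sl], train=False, collect=block))
        return np.concatenate(chunks, axis=0)


def train_network(
    net: ConvGRUNetwork,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    learning_rate: float,
    batch_size: int,
    max_epochs: int,
    patience: int,
    seed: int,
    weight_decay: float = 0.0,
    valid_train: np.ndarray | None = None,
    valid_val: np.ndarray | None = None,
    verbose: bool = False,
) -> list[dict]:
    """Minibatch Adam training with early stopping on validation MSE.

    Returns the per-epoch training log; the network is left holding the
    parameters of the best validation epoch.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(learning_rate, weight_decay=weight_decay)
    n = x_train.shape[0]
    log: list[dict] = []
    best_val = np.inf
    best_params = net.get_params()
    bad_epochs = 0
    stale = 0  # epochs since last improvement, for lr decay
    layers = net.layers
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            vb = None if valid_train is None else valid_train[idx]
            pred = net.forward(xb, vb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; try a lower learning rate"
                )
            total += loss * len(idx)
            net.backward((2.0 / len(idx)) * err.astype(_F32))
            opt.step(layers)
        train_mse = total / n
        val_pred = net.predict(x_val, valid_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        log.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
        if verbose:
            print(f"epoch {epoch}: train_mse={train_mse:.4f} val_mse={val_mse:.4f}")
        if val_mse < best_val - 1e-6:
            best_val = val_mse
            best_params = net.get_params()
            bad_epochs = 0
            stale = 0
        else:
            bad_epochs += 1
            stale += 1
            if bad_epochs >= patience:
                break
            if stale >= 4:  # halve lr when validation stalls for several epochs
                opt.lr = max(opt.lr * 0.5, learning_rate / 16)
                stale = 0
    net.set_params(best_params)
    return log
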