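"""Bidirectional LSTM binary classifier implemented directly on NumPy.

The network mirrors the standard sequence-classification stack used for
evoked-potential shape recognition: two bidirectional LSTM layers (the first
returning full sequences, the second returning the final hidden states of
both directions) followed by a single dense unit with sigmoid activation,
trained with binary cross-entropy and Adam.

Forward and backward passes are written explicitly.  Gate math follows the
standard formulation

    i, f, o = sigmoid(W x + U h + b) slices,  g = tanh(...)
    c_t = f * c_{t-1} + i * g,  h_t = o * tanh(c_t)

with Glorot-uniform input kernels, orthogonal recurrent kernels, and a unit
forget-gate bias.  All randomness (initialization, batch shuffling) flows
from a single integer seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, m: int, dtype) -> np.ndarray:
    a = rng.normal(size=(max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    q = q if n >= m else q.T
    return q[:n, :m].astype(dtype)


@dataclass
class _LSTMDirection:
    """Parameters of one direction of one LSTM layer."""

    W: np.ndarray  # (n_in, 4H) input kernel, gate order i|f|g|o
    U: np.ndarray  # (H, 4H) recurrent kernel
    b: np.ndarray  # (4H,)

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, units: int, dtype):
        W = _glorot(rng, n_in, 4 * units, dtype)
        U = np.concatenate(
            [_orthogonal(rng, units, units, dtype) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0  # unit forget bias
        return cls(W, U, b)

    def forward(self, x: np.ndarray):
        """Run over time. x: (B, T, n_in) -> h_seq (B, T, H) plus caches."""
        B, T, _ = x.shape
        H = self.U.shape[0]
        dtype = self.W.dtype
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        xw = x.reshape(B * T, -1) @ self.W  # precompute input projections
        xw = xw.reshape(B, T, 4 * H)
        gates = np.empty((T, B, 4 * H), dtype=dtype)
        cs = np.empty((T, B, H), dtype=dtype)
        hs = np.empty((T, B, H), dtype=dtype)
        for t in range(T):
            z = xw[:, t, :] + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            cs[t] = c
            hs[t] = h
        cache = (x, gates, cs, hs)
        return hs.transpose(1, 0, 2), cache

    def backward(self, dh_seq: np.ndarray, cache):
        """Backprop through time.

        dh_seq: (B, T, H) gradient w.r.t. every hidden output.  Returns
        (dx, grads) where grads matches (dW, dU, db).
        """
        x, gates, cs, hs = cache
        B, T, n_in = x.shape
        H = self.U.shape[0]
        dtype = self.W.dtype
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            tc = np.tanh(c)
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dtc = dh * o * (1.0 - tc * tc) + dc_next
            di = dtc * g
            dg = dtc * i
            df = dtc * c_prev
            dc_next = dtc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
        return dx, (dW, dU, db)

    @property
    def params(self):
        return [self.W, self.U, self.b]


@dataclass
class _BiLSTMLayer:
    fwd: _LSTMDirection
    bwd: _LSTMDirection

    @classmethod
    def init(cls, rng, n_in, units, dtype):
        return cls(
            _LSTMDirection.init(rng, n_in, units, dtype),
            _LSTMDirection.init(rng, n_in, units, dtype),
        )

    def forward(self, x: np.ndarray):
        h_f, cache_f = self.fwd.forward(x)
        h_b, cache_b = self.bwd.forward(x[:, ::-1, :])
        out = np.concatenate([h_f, h_b[:, ::-1, :]], axis=2)
        return out, (cache_f, cache_b)

    def backward(self, dout: np.ndarray, cache):
        cache_f, cache_b = cache
        H = self.fwd.U.shape[0]
        dx_f, grads_f = self.fwd.backward(dout[:, :, :H], cache_f)
        dx_b, grads_b = self.bwd.backward(dout[:, ::-1, H:], cache_b)
        return dx_f + dx_b[:, ::-1, :], (grads_f, grads_b)

    @property
    def params(self):
        return self.fwd.params + self.bwd.params


class BiLSTMClassifier:
    """Two-layer bidirectional LSTM with a sigmoid read-out unit."""

    def __init__(
        self,
        n_points: int,
        n_channels: int = 4,
        units: int = 50,
        n_layers: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.n_points = int(n_points)
        self.n_channels = int(n_channels)
        self.units = int(units)
        self.n_layers = int(n_layers)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.layers: list[_BiLSTMLayer] = []
        n_in = n_channels
        for _ in range(n_layers):
            self.layers.append(_BiLSTMLayer.init(rng, n_in, units, self.dtype))
            n_in = 2 * units
        self.w_out = _glorot(rng, 2 * units, 1, self.dtype)[:, 0]
        self.b_out = np.zeros(1, dtype=self.dtype)

    # -- forward / backward ------------------------------------------------

    def _head_input(self, h_seq: np.ndarray) -> np.ndarray:
        """Final states of both directions: forward at t=T-1, backward at t=0."""
        H = self.units
        return np.concatenate([h_seq[:, -1, :H], h_seq[:, 0, H:]], axis=1)

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.n_points, self.n_channels):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"({self.n_points}, {self.n_channels})"
            )
        caches = []
        out = x
        for layer in self.layers:
            out, cache = layer.forward(out)
            caches.append(cache)
        feat = self._head_input(out)
        logit = feat @ self.w_out + self.b_out[0]
        p = _sigmoid(logit)
        if keep_cache:
            return p, (caches, out, feat)
        return p

    def _backward(self, x, y, p, cache):
        """Gradients of mean binary cross-entropy w.r.t. all parameters."""
        caches, h_seq, feat = cache
        B = len(y)
        H = self.units
        dlogit = (p - y) / B
        dw_out = feat.T @ dlogit
        db_out = np.array([dlogit.sum()], dtype=self.dtype)
        dfeat = np.outer(dlogit, self.w_out)
        dh_seq = np.zeros_like(h_seq)
        dh_seq[:, -1, :H] = dfeat[:, :H]
        dh_seq[:, 0, H:] = dfeat[:, H:]
        layer_grads = [None] * self.n_layers
        dout = dh_seq
        for li in range(self.n_layers - 1, -1, -1):
            dout, grads = self.layers[li].backward(dout, caches[li])
            layer_grads[li] = grads
        flat = []
        for grads_f, grads_b in layer_grads:
            flat.extend(grads_f)
            flat.extend(grads_b)
        flat.append(dw_out)
        flat.append(db_out)
        return flat

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.append(self.w_out)
        out.append(self.b_out)
        return out

    def loss_and_grads(self, x, y):
        x = np.asarray(x, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype)
        p, cache = self.forward(x, keep_cache=True)
        eps = 1e-7
        pc = np.clip(p, eps, 1.0 - eps)
        loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
        grads = self._backward(x, y, p, cache)
        return loss, grads, p

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        seed: int = 0,
        early_stop_loss: float | None = None,
        verbose: bool = False,
    ) -> dict:
        """Adam + minibatch training; returns per-epoch history."""
        x = np.asarray(x, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype)
        rng = np.random.default_rng(seed)
        params = self.params
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0
        history = {"loss": [], "accuracy": []}
        n = len(y)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, grads, p = self.loss_and_grads(x[idx], y[idx])
                losses.append(loss * len(idx))
                correct += int(np.sum((p >= 0.5) == (y[idx] >= 0.5)))
                step += 1
                lr_t = learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for pi, (par, g) in enumerate(zip(params, grads)):
                    m[pi] = beta1 * m[pi] + (1 - beta1) * g
                    v[pi] = beta2 * v[pi] + (1 - beta2) * g * g
                    par -= (lr_t * m[pi] / (np.sqrt(v[pi]) + eps)).astype(self.dtype)
            epoch_loss = float(np.sum(losses) / n)
            epoch_acc = correct / n
            history["loss"].append(epoch_loss)
            history["accuracy"].append(epoch_acc)
            if verbose:
                print(f"epoch {epoch + 1}: loss={epoch_loss:.4f} acc={epoch_acc:.4f}")
            if early_stop_loss is not None and epoch_loss < early_stop_loss:
                break
        return history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.forward(x), dtype=float)

    # -- serialization -----------------------------------------------------

    _PARAM_NAMES = ("W", "U", "b")

    def save(self, directory: str | Path) -> None:
        """Write weights (npz) and a JSON architecture sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for tag, direction in (("fwd", layer.fwd), ("bwd", layer.bwd)):
                for name, arr in zip(self._PARAM_NAMES, direction.params):
                    arrays[f"layer{li}_{tag}_{name}"] = arr
        arrays["w_out"] = self.w_out
        arrays["b_out"] = self.b_out
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "n_points": self.n_points,
            "n_channels": self.n_channels,
            "units": self.units,
            "n_layers": self.n_layers,
            "seed": self.seed,
            "dtype": self.dtype.name,
            "channel_order": ["condensation", "rarefaction", "difference",
                              "alternating"],
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "BiLSTMClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(
            n_points=meta["n_points"],
            n_channels=meta["n_channels"],
            units=meta["units"],
            n_layers=meta["n_layers"],
            seed=meta["seed"],
            dtype=np.dtype(meta["dtype"]),
        )
        with np.load(directory / "weights.npz") as data:
            for li, layer in enumerate(model.layers):
                for tag, direction in (("fwd", layer.fwd), ("bwd", layer.bwd)):
                    direction.W = data[f"layer{li}_{tag}_W"]
                    direction.U = data[f"layer{li}_{tag}_U"]
                    direction.b = data[f"layer{li}_{tag}_b"]
            model.w_out = data["w_out"]
            model.b_out = data["b_out"]
        return model
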