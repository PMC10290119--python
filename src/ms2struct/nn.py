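"""Compact NumPy neural-network layer library with manual backpropagation.

Implements exactly the pieces the two encoders and the SMILES decoder need:
token embeddings, dense layers, a batched GRU (with right-padding masks),
strided 1-D convolution, softmax cross-entropy, and Adam. Forward passes
cache what the analytic backward passes need; everything is float64-free
(float32) and vectorized over the batch, which is fast enough for the
desk-scale models this package trains.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class Module:
    """Base: parameter/grad registry shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.add_param("W", (0.1 * rng.standard_normal((n_tokens, dim))).astype(DTYPE))

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.params["W"][ids]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.grads["W"], self._ids, dout)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.add_param("W", _glorot(rng, (d_in, d_out)))
        self.add_param("b", np.zeros(d_out, dtype=DTYPE))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class GRU(Module):
    """Single-layer batched GRU over right-padded sequences.

    Gate layout along the last axis is (reset, update, candidate). Masked
    (padding) steps carry the hidden state through unchanged, so the final
    state equals the state at each sequence's last real token.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_hidden = d_hidden
        self.add_param("W_ih", _glorot(rng, (d_in, 3 * d_hidden)))
        self.add_param("W_hh", _glorot(rng, (d_hidden, 3 * d_hidden)))
        self.add_param("b", np.zeros(3 * d_hidden, dtype=DTYPE))

    def step(self, x: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, tuple]:
        H = self.d_hidden
        gi = x @ self.params["W_ih"] + self.params["b"]
        gh = h @ self.params["W_hh"]
        r = sigmoid(gi[:, :H] + gh[:, :H])
        z = sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
        n = np.tanh(gi[:, 2 * H :] + r * gh[:, 2 * H :])
        h_new = (1.0 - z) * n + z * h
        return h_new, (x, h, r, z, n, gh[:, 2 * H :])

    def step_backward(self, dh_new: np.ndarray, cache: tuple) -> tuple[np.ndarray, np.ndarray]:
        """Returns (dx, dh_prev) and accumulates weight grads."""
        x, h, r, z, n, hn = cache
        H = self.d_hidden
        dn = dh_new * (1.0 - z)
        dz = dh_new * (h - n)
        dh = dh_new * z
        dn_pre = dn * (1.0 - n * n)
        dr = dn_pre * hn
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        dgi = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
        dgh = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
        self.grads["W_ih"] += x.T @ dgi
        self.grads["W_hh"] += h.T @ dgh
        self.grads["b"] += dgi.sum(axis=0)
        dx = dgi @ self.params["W_ih"].T
        dh += dgh @ self.params["W_hh"].T
        return dx, dh

    def forward(
        self, xs: np.ndarray, mask: np.ndarray | None = None, h0: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """xs: (B, T, d_in); mask: (B, T) 1 for real tokens. Returns (hs, h_T)."""
        B, T, _ = xs.shape
        h = np.zeros((B, self.d_hidden), dtype=DTYPE) if h0 is None else h0
        self._caches = []
        self._mask = mask
        hs = np.empty((B, T, self.d_hidden), dtype=DTYPE)
        for t in range(T):
            h_new, cache = self.step(xs[:, t], h)
            if mask is not None:
                m = mask[:, t : t + 1]
                h_new = m * h_new + (1.0 - m) * h
            self._caches.append(cache)
            hs[:, t] = h_new
            h = h_new
        return hs, h

    def backward(
        self, dhs: np.ndarray | None, dh_last: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gradients w.r.t. per-step outputs and/or final state.

        Returns (dxs, dh0).
        """
        T = len(self._caches)
        cache0 = self._caches[0]
        B = cache0[0].shape[0]
        d_in = cache0[0].shape[1]
        dxs = np.zeros((B, T, d_in), dtype=DTYPE)
        dh = np.zeros((B, self.d_hidden), dtype=DTYPE)
        if dh_last is not None:
            dh += dh_last
        for t in range(T - 1, -1, -1):
            if dhs is not None:
                dh = dh + dhs[:, t]
            if self._mask is not None:
                m = self._mask[:, t : t + 1]
                dh_carry = (1.0 - m) * dh
                dh = m * dh
            else:
                dh_carry = 0.0
            dx, dh = self.step_backward(dh, self._caches[t])
            dh = dh + dh_carry
            dxs[:, t] = dx
        return dxs, dh


class Conv1d(Module):
    """Valid-mode strided 1-D convolution: (B, C_in, L) -> (B, C_out, Lo)."""

    def __init__(
        self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        limit = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.add_param(
            "W", rng.uniform(-limit, limit, size=(c_in * kernel, c_out)).astype(DTYPE)
        )
        self.add_param("b", np.zeros(c_out, dtype=DTYPE))

    def out_len(self, L: int) -> int:
        return (L - self.kernel) // self.stride + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        Lo = self.out_len(L)
        cols = np.empty((B, Lo, C, self.kernel), dtype=DTYPE)
        for k in range(self.kernel):
            cols[:, :, :, k] = x[:, :, k : k + Lo * self.stride : self.stride].transpose(0, 2, 1)
        return cols.reshape(B, Lo, C * self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.params["W"] + self.params["b"]  # (B, Lo, C_out)
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._x_shape
        d = dout.transpose(0, 2, 1)  # (B, Lo, C_out)
        Lo = d.shape[1]
        self.grads["W"] += np.tensordot(self._cols, d, axes=([0, 1], [0, 1]))
        self.grads["b"] += d.sum(axis=(0, 1))
        dcols = (d @ self.params["W"].T).reshape(B, Lo, C, self.kernel)
        dx = np.zeros((B, C, L), dtype=DTYPE)
        for k in range(self.kernel):
            dx[:, :, k : k + Lo * self.stride : self.stride] += dcols[:, :, :, k].transpose(
                0, 2, 1
            )
        return dx


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Masked mean cross-entropy over (B, T, V) logits.

    Returns (loss, dlogits, correct) where ``correct`` flags argmax hits at
    unmasked positions (the per-token accuracy numerator).
    """
    shifted = logits - logits.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=-1, keepdims=True)
    B, T, V = probs.shape
    rows = np.arange(B)[:, None], np.arange(T)[None, :]
    picked = probs[rows[0], rows[1], targets]
    n_real = mask.sum()
    loss = float(-(np.log(np.maximum(picked, 1e-12)) * mask).sum() / max(n_real, 1))
    dlogits = probs.copy()
    dlogits[rows[0], rows[1], targets] -= 1.0
    dlogits *= (mask / max(n_real, 1))[:, :, None]
    correct = (logits.argmax(axis=-1) == targets) & (mask > 0)
    return loss, dlogits.astype(DTYPE), correct


class Adam:
    """Adam optimizer over a list of Modules, with gradient-norm clipping."""

    def __init__(
        self,
        modules: list[Module],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float = 5.0,
    ) -> None:
        self.modules = modules
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules
        ]

    def zero_grad(self) -> None:
        for mod in self.modules:
            mod.zero_grad()

    def step(self) -> None:
        if self.clip_norm is not None:
            total = 0.0
            for mod in self.modules:
                for g in mod.grads.values():
                    total += float((g * g).sum())
            norm = np.sqrt(total)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                for mod in self.modules:
                    for g in mod.grads.values():
                        g *= scale
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for mod, m, v in zip(self.modules, self.m, self.v):
            for k, p in mod.params.items():
                g = mod.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bias1) / (np.sqrt(v[k] / bias2) + self.eps)


def collect_params(modules: list[Module], prefix_list: list[str]) -> dict[str, np.ndarray]:
    out = {}
    for mod, prefix in zip(modules, prefix_list):
        for k, v in mod.params.items():
            out[f"{prefix}.{k}"] = v
    return out


def load_params(modules: list[Module], prefix_list: list[str], state: dict) -> None:
    for mod, prefix in zip(modules, prefix_list):
        for k in mod.params:
            mod.params[k][...] = state[f"{prefix}.{k}"]
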