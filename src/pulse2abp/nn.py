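"""Minimal NumPy sequence-network engine: LSTM, dropout, linear head, Adam.

Implements the standard LSTM memory cell (forget/input/output gates and
cell state) with full backpropagation through time, a per-timestep
linear projection, inverted dropout, and the Adam optimizer.  The
engine is deliberately small: batched dense algebra via BLAS, a Python
loop over time steps, float32 parameters by default.  Gradients are
verified against finite differences in the test suite.

Layers consume ``(batch, time, features)`` arrays and produce
``(batch, time, units)`` arrays; sequence length is arbitrary and may
differ between calls.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np
from scipy.special import expit as _sigmoid


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class LSTM(Layer):
    """Single LSTM layer; gate order in the fused weight is (i, f, o, g).

    The sigmoid gates occupy one contiguous block so the forward loop
    needs a single sigmoid and a single tanh per step.  The forget-gate
    bias is initialized to 1 so early training does not erase the cell
    state; other weights are uniform in ``[-1/sqrt(H), 1/sqrt(H)]``.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        if in_dim < 1 or hidden < 1:
            raise ValueError("layer sizes must be positive")
        k = 1.0 / np.sqrt(hidden)
        self.in_dim = in_dim
        self.hidden = hidden
        self.Wx = rng.uniform(-k, k, (in_dim, 4 * hidden)).astype(dtype)
        self.Wh = rng.uniform(-k, k, (hidden, 4 * hidden)).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden : 2 * hidden] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache: dict | None = None

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        dtype = self.Wx.dtype
        x = np.ascontiguousarray(x, dtype=dtype)
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        A = np.empty((B, T, 4 * H), dtype=dtype)  # post-activation gates
        C = np.empty((B, T, H), dtype=dtype)
        TC = np.empty_like(C)
        Hs = np.empty_like(C)
        xw = x @ self.Wx + self.b  # input contribution for all t at once
        for t in range(T):
            a = xw[:, t] + h @ self.Wh
            a[:, : 3 * H] = _sigmoid(a[:, : 3 * H])
            g = np.tanh(a[:, 3 * H :])
            a[:, 3 * H :] = g
            c = a[:, H : 2 * H] * c + a[:, :H] * g
            tc = np.tanh(c)
            h = a[:, 2 * H : 3 * H] * tc
            A[:, t] = a
            C[:, t], TC[:, t], Hs[:, t] = c, tc, h
        if train:
            self._cache = {"x": x, "A": A, "C": C, "TC": TC, "H": Hs}
        return Hs

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward pass")
        cc = self._cache
        x, A, C, TC, Hs = (cc[k] for k in ("x", "A", "C", "TC", "H"))
        B, T, _ = x.shape
        H = self.hidden
        dtype = self.Wx.dtype
        dout = dout.astype(dtype, copy=False)
        I, F, O, G = (A[..., :H], A[..., H : 2 * H],
                      A[..., 2 * H : 3 * H], A[..., 3 * H :])
        # vectorized per-gate derivative factors, multiplied by dc or dh
        # inside the sequential loop
        c_prev = np.concatenate([np.zeros((B, 1, H), dtype=dtype), C[:, :-1]], axis=1)
        k_i = G * I * (1.0 - I)           # ∂a_i ← dc
        k_f = c_prev * F * (1.0 - F)      # ∂a_f ← dc
        k_o = TC * O * (1.0 - O)          # ∂a_o ← dh
        k_g = I * (1.0 - G * G)           # ∂a_g ← dc
        k_c = O * (1.0 - TC * TC)         # dc  ← dh
        dA = np.empty((B, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            dh = dout[:, t] + dh_next
            dc = dh * k_c[:, t] + dc_next
            a = dA[:, t]
            a[:, :H] = dc * k_i[:, t]
            a[:, H : 2 * H] = dc * k_f[:, t]
            a[:, 2 * H : 3 * H] = dh * k_o[:, t]
            a[:, 3 * H :] = dc * k_g[:, t]
            dc_next = dc * F[:, t]
            dh_next = a @ self.Wh.T
        # fused parameter-gradient accumulation over all timesteps
        h_prev = np.concatenate(
            [np.zeros((B, 1, H), dtype=dtype), Hs[:, :-1]], axis=1
        )
        flat_dA = dA.reshape(B * T, 4 * H)
        self.dWx += x.reshape(B * T, -1).T @ flat_dA
        self.dWh += h_prev.reshape(B * T, H).T @ flat_dA
        self.db += flat_dA.sum(axis=0)
        self._cache = None
        if not need_dx:
            return None
        return dA @ self.Wx.T


class Dense(Layer):
    """Per-timestep affine projection (B, T, in) -> (B, T, out)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-k, k, (in_dim, out_dim)).astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(self.W.dtype, copy=False)
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(self.W.dtype, copy=False)
        x = self._x
        flat = dout.reshape(-1, dout.shape[-1])
        self.dW += x.reshape(-1, x.shape[-1]).T @ flat
        self.db += flat.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        for i, layer in enumerate(reversed(self.layers)):
            is_first = i == len(self.layers) - 1
            if is_first and not need_input_grad and isinstance(layer, LSTM):
                return layer.backward(dout, need_dx=False)
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads().values():
                g[:] = 0

    def param_items(self) -> list[tuple[Layer, str, np.ndarray]]:
        return [
            (layer, name, arr)
            for layer in self.layers
            for name, arr in layer.params().items()
        ]


def parameter_digest(nets: Sequence[Sequential]) -> str:
    """SHA-256 over all parameter bytes, in registration order."""
    h = hashlib.sha256()
    for net in nets:
        for _, name, arr in net.param_items():
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def clip_global_norm(grads: Sequence[np.ndarray], max_norm: float) -> float:
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adaptive-moment optimizer over an explicit parameter list."""

    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad
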