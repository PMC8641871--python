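"""Network architectures and a compact numpy layer framework.

Three emulator variants share a convolutional front end (two bias-free
kernel-3 convolutions with 64 filters, each ReLU-activated and followed by
batch normalization) and differ in the head: two dense layers (FF), two
long short-term-memory layers (LSTM), or two gated-recurrent-unit layers
(GRU), always closing with a single ReLU output unit whose weights carry an
l2 penalty. A gradient-descent linear regression serves as baseline.

Layer parameterizations follow the common deep-learning conventions:
convolutions carry no additive bias (redundant under the following
normalization), batch normalization has a learnable scale and shift per
channel, LSTM cells use one bias vector per gate, and GRU cells use separate
input and recurrent biases per gate (the "reset after" formulation). Under
these conventions the trainable-parameter totals for a 90-day window are
369,857 (FF), 79,425 (LSTM) and 63,297 (GRU).

All arithmetic is float64; backward passes are hand-written and verified
against finite differences in the test suite.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ArchitectureError, FormatError

Variant = Literal["FF", "LSTM", "GRU", "LR"]

_BN_MOMENTUM = 0.99  # running-statistics memory
_BN_EPS = 1e-3


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------

def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal layer interface: parameters, forward, backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) stride-1 1-D convolution without additive bias.

    Input (n, length, c_in) -> output (n, length - kernel + 1, c_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        # stored flattened as (kernel * c_in, c_out), kernel-major rows
        self.w = _glorot_uniform(rng, (kernel * c_in, c_out), kernel * c_in, c_out)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (n, L, c) -> (n, L', kernel, c) -> (n*L', kernel*c)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        win = np.moveaxis(win, 3, 2)  # (n, L', kernel, c)
        return np.ascontiguousarray(win).reshape(-1, self.kernel * self.c_in)

    def forward(self, x, training):
        n, length, _ = x.shape
        if length < self.kernel:
            raise ArchitectureError(f"input length {length} < kernel {self.kernel}")
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.w
        return out.reshape(n, length - self.kernel + 1, self.c_out)

    def backward(self, dy):
        n, lp, _ = dy.shape
        dy_flat = dy.reshape(-1, self.c_out)
        self.dw[...] = self._cols.T @ dy_flat
        dcols = (dy_flat @ self.w.T).reshape(n, lp, self.kernel, self.c_in)
        dx = np.zeros(self._x_shape)
        for k in range(self.kernel):
            dx[:, k:k + lp, :] += dcols[:, :, k, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class BatchNorm(Layer):
    """Per-channel normalization over batch (and time) axes with learnable
    scale/shift; exponential running statistics are used at inference."""

    def __init__(self, channels: int, momentum: float = _BN_MOMENTUM, eps: float = _BN_EPS):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = x.size // x.shape[-1]
            self._xc = x - mu
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = self._xc * self._inv_std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        m = self._m
        # standard batch-norm gradient with batch statistics
        dvar = (dxhat * self._xc).sum(axis=axes) * (-0.5) * self._inv_std**3
        dmu = -(dxhat.sum(axis=axes)) * self._inv_std
        return dxhat * self._inv_std + (2.0 / m) * dvar * self._xc + dmu / m


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine layer ``x @ w + b`` with optional l2 penalty on the weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l2: float = 0.0):
        self.w = _glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        if self.l2:
            self.dw += 2.0 * self.l2 * self.w
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def penalty(self) -> float:
        return float(self.l2 * np.sum(self.w**2))


class LSTM(Layer):
    """Long short-term-memory layer, gate order (input, forget, cell, output),
    single bias vector per gate, forget-gate bias initialized to one."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        u = units
        self.units = u
        self.return_sequences = return_sequences
        self.w = _glorot_uniform(rng, (n_in, 4 * u), n_in, 4 * u)
        self.u = np.concatenate([_orthogonal(rng, u) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0  # forget-gate bias
        self.dw = np.zeros_like(self.w)
        self.du = np.zeros_like(self.u)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.u, self.b]

    def grads(self):
        return [self.dw, self.du, self.db]

    def forward(self, x, training):
        n, T, _ = x.shape
        u = self.units
        self._x = x
        xw = x @ self.w + self.b  # (n, T, 4u)
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._cache = []
        hs = np.empty((n, T, u))
        for t in range(T):
            z = xw[:, t] + h @ self.u
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dy):
        n, T, _ = self._x.shape
        u = self.units
        if self.return_sequences:
            dh_out = dy
        else:
            dh_out = np.zeros((n, T, u))
            dh_out[:, -1] = dy
        dxw = np.empty((n, T, 4 * u))
        self.du[...] = 0.0
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dh_out[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dxw[:, t] = dz
            self.du += h_prev.T @ dz
            dh_next = dz @ self.u.T
        dxw_flat = dxw.reshape(-1, 4 * u)
        self.dw[...] = self._x.reshape(-1, self._x.shape[2]).T @ dxw_flat
        self.db[...] = dxw_flat.sum(axis=0)
        return (dxw_flat @ self.w.T).reshape(self._x.shape)


class GRU(Layer):
    """Gated-recurrent-unit layer, gate order (update, reset, candidate),
    with separate input and recurrent bias vectors ("reset after")."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        u = units
        self.units = u
        self.return_sequences = return_sequences
        self.w = _glorot_uniform(rng, (n_in, 3 * u), n_in, 3 * u)
        self.u = np.concatenate([_orthogonal(rng, u) for _ in range(3)], axis=1)
        self.b = np.zeros((2, 3 * u))  # row 0: input bias, row 1: recurrent bias
        self.dw = np.zeros_like(self.w)
        self.du = np.zeros_like(self.u)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.u, self.b]

    def grads(self):
        return [self.dw, self.du, self.db]

    def forward(self, x, training):
        n, T, _ = x.shape
        u = self.units
        self._x = x
        xw = x @ self.w + self.b[0]
        h = np.zeros((n, u))
        self._cache = []
        hs = np.empty((n, T, u))
        for t in range(T):
            hu = h @ self.u + self.b[1]
            z = _sigmoid(xw[:, t, :u] + hu[:, :u])
            r = _sigmoid(xw[:, t, u:2 * u] + hu[:, u:2 * u])
            hh = np.tanh(xw[:, t, 2 * u:] + r * hu[:, 2 * u:])
            h_prev = h
            h = z * h_prev + (1 - z) * hh
            hs[:, t] = h
            self._cache.append((z, r, hh, hu[:, 2 * u:], h_prev))
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dy):
        n, T, _ = self._x.shape
        u = self.units
        if self.return_sequences:
            dh_out = dy
        else:
            dh_out = np.zeros((n, T, u))
            dh_out[:, -1] = dy
        dxw = np.empty((n, T, 3 * u))
        self.du[...] = 0.0
        db_rec = np.zeros(3 * u)
        dh_next = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            z, r, hh, huh, h_prev = self._cache[t]
            dh = dh_out[:, t] + dh_next
            dz = dh * (h_prev - hh) * z * (1 - z)
            dhh_pre = dh * (1 - z) * (1 - hh**2)
            dr = dhh_pre * huh
            dr_pre = dr * r * (1 - r)
            dhuh = dhh_pre * r
            dxw[:, t, :u] = dz
            dxw[:, t, u:2 * u] = dr_pre
            dxw[:, t, 2 * u:] = dhh_pre
            dhu = np.concatenate([dz, dr_pre, dhuh], axis=1)
            self.du += h_prev.T @ dhu
            db_rec += dhu.sum(axis=0)
            dh_next = dh * z + dhu @ self.u.T
        dxw_flat = dxw.reshape(-1, 3 * u)
        self.dw[...] = self._x.reshape(-1, self._x.shape[2]).T @ dxw_flat
        self.db[0] = dxw_flat.sum(axis=0)
        self.db[1] = db_rec
        return (dxw_flat @ self.w.T).reshape(self._x.shape)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

class Model:
    """Sequential stack of layers mapping a (n, delta, 4) batch to (n,)."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = np.asarray(dy, dtype=float)[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions, independent of batch composition."""
        x = np.asarray(x, dtype=float)
        chunks = [self.forward(x[i:i + batch_size], training=False)
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def penalty(self) -> float:
        return sum(l.penalty() for l in self.layers if isinstance(l, Dense))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    # batch-norm running statistics are state but not trainable parameters
    def get_state(self) -> list[np.ndarray]:
        state = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


# ---------------------------------------------------------------------------
# Architecture specification and builders
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network variant."""

    variant: Variant
    delta: int = 90
    n_channels: int = 4
    conv_filters: int = 64
    kernel: int = 3
    units: int = 64
    l2: float = 0.01

    def __post_init__(self):
        if self.variant not in ("FF", "LSTM", "GRU", "LR"):
            raise ArchitectureError(f"unknown variant {self.variant!r}")
        if min(self.n_channels, self.conv_filters, self.kernel, self.units) <= 0:
            raise ArchitectureError("unit counts and kernel size must be positive")
        if self.variant != "LR" and self.delta < 2 * (self.kernel - 1) + 1:
            raise ArchitectureError(
                f"delta={self.delta} leaves no output after two valid kernel-{self.kernel} convolutions"
            )
        if self.variant == "LR" and self.delta < 1:
            raise ArchitectureError("delta must be positive")

    @property
    def conv_out_length(self) -> int:
        return self.delta - 2 * (self.kernel - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**d)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Construct a trainable network for the given spec with seeded weights."""
    rng = np.random.default_rng(seed)
    if spec.variant == "LR":
        return build_baseline(spec.delta, seed=seed, n_channels=spec.n_channels)
    f, k, u = spec.conv_filters, spec.kernel, spec.units
    layers: list[Layer] = [
        Conv1D(spec.n_channels, f, k, rng), ReLU(), BatchNorm(f),
        Conv1D(f, f, k, rng), ReLU(), BatchNorm(f),
    ]
    if spec.variant == "FF":
        layers += [
            Flatten(),
            Dense(spec.conv_out_length * f, u, rng), ReLU(),
            Dense(u, u, rng), ReLU(),
        ]
    else:
        cell = LSTM if spec.variant == "LSTM" else GRU
        layers += [
            cell(f, u, rng, return_sequences=True),
            cell(u, u, rng, return_sequences=False),
        ]
    layers += [Dense(u, 1, rng, l2=spec.l2), ReLU()]
    return Model(layers)


def build_baseline(delta: int, seed: int = 0, n_channels: int = 4) -> Model:
    """Gradient-descent linear regression on the flattened window.

    Raw output may be negative; clamping happens only in post-processing.
    """
    if delta < 1:
        raise ArchitectureError("delta must be positive")
    rng = np.random.default_rng(seed)
    return Model([Flatten(), Dense(delta * n_channels, 1, rng)])


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact trainable-parameter count implied by the layer conventions.

    Independent of ``build_model``: computed arithmetically so it can serve
    as a cross-check on the constructed networks.
    """
    f, k, u, c = spec.conv_filters, spec.kernel, spec.units, spec.n_channels
    if spec.variant == "LR":
        return spec.delta * c + 1
    total = k * c * f + 2 * f          # conv1 (bias-free) + batch norm
    total += k * f * f + 2 * f         # conv2 + batch norm
    if spec.variant == "FF":
        flat = spec.conv_out_length * f
        total += (flat + 1) * u + (u + 1) * u
    elif spec.variant == "LSTM":
        total += 4 * ((f + u) * u + u)          # layer 1, single bias per gate
        total += 4 * ((u + u) * u + u)          # layer 2
    else:  # GRU, separate input/recurrent biases per gate
        total += 3 * ((f + u) * u + 2 * u)
        total += 3 * ((u + u) * u + 2 * u)
    total += (u + 1) * 1               # output unit
    return total


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(directory: str | Path, model: Model, spec: ArchitectureSpec,
               scaler=None, meta: dict | None = None) -> None:
    """Persist weights, architecture spec, and the fitted scaler sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p for i, p in enumerate(model.params())}
    arrays.update({f"state_{i}": s for i, s in enumerate(model.get_state())})
    np.savez(directory / "weights.npz", **arrays)
    payload = {"spec": spec.to_dict(), "meta": meta or {}}
    (directory / "spec.json").write_text(json.dumps(payload, indent=2))
    if scaler is not None:
        scaler.save(directory / "scaler.json")


def load_model(directory: str | Path):
    """Rebuild a saved model; returns (model, spec, scaler_or_None, meta)."""
    from .weather import ScalerParams

    directory = Path(directory)
    spec_path = directory / "spec.json"
    if not spec_path.exists():
        raise FormatError(f"{directory} does not contain spec.json")
    payload = json.loads(spec_path.read_text())
    spec = ArchitectureSpec.from_dict(payload["spec"])
    model = build_model(spec, seed=0)
    with np.load(directory / "weights.npz") as data:
        params = [data[f"param_{i}"] for i in range(len(model.params()))]
        state = [data[k] for k in sorted(
            (k for k in data.files if k.startswith("state_")),
            key=lambda s: int(s.split("_")[1]))]
    model.set_weights(params)
    model.set_state(state)
    scaler = None
    if (directory / "scaler.json").exists():
        scaler = ScalerParams.load(directory / "scaler.json")
    return model, spec, scaler, payload.get("meta", {})
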