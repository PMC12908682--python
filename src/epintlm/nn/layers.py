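"""Neural-network layers built on the autodiff core.

Conventions: activations are batch-first ``(B, L, C)`` float32; every
layer draws its initial weights from the ``numpy.random.Generator``
passed at construction, so a model is fully determined by one seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def parameter(data, name: str = "") -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)
    return t


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Tiny module base: parameter registry and train/eval switching."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[key] = value
        super().__setattr__(key, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = parameter(glorot(rng, d_in, d_out, (d_in, d_out)), "dense.weight")
        self.bias = parameter(np.zeros(d_out), "dense.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class Conv1d(Module):
    """Valid conv, stride 1, batch-first (B, L, C_in) -> (B, L-K+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in = kernel * c_in
        self.weight = parameter(
            glorot(rng, fan_in, c_out, (kernel, c_in, c_out)), "conv.weight")
        self.bias = parameter(np.zeros(c_out), "conv.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel normalization over batch and length axes of (B, L, C).

    Training mode uses batch statistics and updates exponential running
    estimates; inference mode uses the running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(channels), "bn.gamma")
        self.beta = parameter(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            n = float(np.prod([x.shape[a] for a in axes]))
            unbiased = var.data.reshape(-1) * (n / max(n - 1.0, 1.0))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xhat = centered * ag.power(var + self.eps, -0.5)
        else:
            shape = (1,) * (x.ndim - 1) + (-1,)
            mu = Tensor(self.running_mean.reshape(shape))
            sd = Tensor((1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape))
            xhat = (x - mu) * sd
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class GRU(Module):
    """Single-direction GRU layer (gate order: reset, update, candidate).

    Input (B, L, d_in) -> hidden states (B, L, h).  The input projection
    for all timesteps is computed in one matmul before the recurrence.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        self.w_ih = parameter(glorot(rng, d_in, 3 * hidden, (d_in, 3 * hidden)), "gru.w_ih")
        self.w_hh = parameter(glorot(rng, hidden, 3 * hidden, (hidden, 3 * hidden)), "gru.w_hh")
        self.b_ih = parameter(np.zeros(3 * hidden), "gru.b_ih")
        self.b_hh = parameter(np.zeros(3 * hidden), "gru.b_hh")

    def __call__(self, x: Tensor) -> Tensor:
        xp = ag.matmul(x, self.w_ih) + self.b_ih  # (B, L, 3h)
        return ag.gru_sequence(xp, self.w_hh, self.b_hh, reverse=self.reverse)


class BiGRU(Module):
    """Stacked bidirectional GRU; output concatenates the two directions."""

    def __init__(self, d_in: int, hidden_per_dir: int, layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = layers
        dims = [d_in] + [2 * hidden_per_dir] * layers
        for i in range(layers):
            setattr(self, f"fwd{i}", GRU(dims[i], hidden_per_dir, rng, reverse=False))
            setattr(self, f"bwd{i}", GRU(dims[i], hidden_per_dir, rng, reverse=True))

    def __call__(self, x: Tensor) -> Tensor:
        out = x
        for i in range(self.layers):
            f = getattr(self, f"fwd{i}")(out)
            b = getattr(self, f"bwd{i}")(out)
            out = ag.concat([f, b], axis=2)
        return out


class MultiHeadAttention(Module):
    """Scaled dot-product attention with H heads and a shared output projection.

    Self-attention when ``kv`` is the same tensor as ``q``; cross-attention
    otherwise.  Returns the projected output and the detached per-head
    attention weights ``(B, H, L_q, L_k)`` (each query row sums to 1).
    """

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d % heads:
            raise ValueError(f"head count {heads} must divide model dim {d}")
        self.d = d
        self.heads = heads
        self.d_head = d // heads
        self.w_q = Dense(d, d, rng)
        self.w_k = Dense(d, d, rng)
        self.w_v = Dense(d, d, rng)
        self.w_o = Dense(d, d, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return ag.transpose(ag.reshape(x, (B, L, self.heads, self.d_head)),
                            (0, 2, 1, 3))

    def __call__(self, q_in: Tensor, kv_in: Tensor | None = None):
        kv_in = q_in if kv_in is None else kv_in
        B, Lq, _ = q_in.shape
        Lk = kv_in.shape[1]
        q = self._split(self.w_q(q_in), B, Lq)          # (B, H, Lq, dh)
        k = self._split(self.w_k(kv_in), B, Lk)
        v = self._split(self.w_v(kv_in), B, Lk)
        scores = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        attn = ag.softmax(scores, axis=-1)              # (B, H, Lq, Lk)
        ctx = ag.matmul(attn, v)                        # (B, H, Lq, dh)
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (B, Lq, self.d))
        return self.w_o(ctx), attn.data.copy()
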