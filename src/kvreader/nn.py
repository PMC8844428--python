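"""Minimal reverse-mode automatic differentiation and a small
Transformer encoder, in NumPy.

The desk-scale encoder (2 layers, width 64 by default) shares one set
of weights between SMILES spans and natural-language text, exactly as
the full-scale model shares its encoder across modalities; only the
embedding table distinguishes the two vocabulary namespaces.  The
autodiff engine implements just the operations the encoder and the
training objectives need; every operation's gradient is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# autodiff core

def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- operators
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return self._node(data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            return ga, gb

        return self._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return self._node(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return self._node(np.swapaxes(self.data, a, b), (self,),
                          lambda g: (np.swapaxes(g, a, b),))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.full_like(self.data, 1.0) * g,)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._node(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self) -> "Tensor":
        mask = (self.data > 0).astype(self.data.dtype)
        return self._node(self.data * mask, (self,), lambda g: (g * mask,))

    def gelu(self) -> "Tensor":
        """tanh approximation of the Gaussian error linear unit."""
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            return (g * grad,)

        return self._node(data, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return self._node(t, (self,), lambda g: (g * (1.0 - t ** 2),))

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Row gather along axis 0 (embedding lookup / position select)."""
        idx = np.asarray(indices)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._node(self.data[idx], (self,), backward)

    # -- backward pass
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=np.float64)
                else:
                    parent.grad = parent.grad + g


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._node(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    y = np.exp(out)

    def backward(g):
        return (g - y * g.sum(axis=axis, keepdims=True),)

    return Tensor._node(out, (x,), backward)


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = (x * x).sum(axis=-1, keepdims=True).pow(0.5) + eps
    return x / norm


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets; logits (N, V)."""
    n = logits.shape[0]
    ls = log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), targets] = 1.0
    return -(ls * Tensor(onehot)).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# layers

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _init(rng: np.random.Generator, *shape, scale: float | None = None):
    if scale is None:
        scale = 1.0 / math.sqrt(shape[0])
    return rng.normal(0.0, scale, size=shape)


class Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Parameter(_init(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MultiHeadAttention:
    def __init__(self, rng, width: int, heads: int):
        assert width % heads == 0
        self.width, self.heads = width, heads
        self.d_head = width // heads
        self.wq = Dense(rng, width, width)
        self.wk = Dense(rng, width, width)
        self.wv = Dense(rng, width, width)
        self.wo = Dense(rng, width, width)

    def __call__(self, x: Tensor, attn_bias: np.ndarray | None) -> Tensor:
        B, T, D = x.shape
        h, dk = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,T,D) -> (B,h,T,dk)
            return t.reshape(B, T, h, dk).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.swapaxes(-1, -2) * (1.0 / math.sqrt(dk))
        if attn_bias is not None:
            scores = scores + Tensor(attn_bias)  # (B,1,1,T) additive mask
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, D)
        return self.wo(ctx)

    def parameters(self):
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class TransformerLayer:
    """Pre-norm block: attention then feedforward, each with a residual."""

    def __init__(self, rng, width: int, heads: int, ff_width: int):
        self.ln1 = LayerNorm(width)
        self.attn = MultiHeadAttention(rng, width, heads)
        self.ln2 = LayerNorm(width)
        self.ff1 = Dense(rng, width, ff_width)
        self.ff2 = Dense(rng, ff_width, width)

    def __call__(self, x: Tensor, attn_bias) -> Tensor:
        x = x + self.attn(self.ln1(x), attn_bias)
        return x + self.ff2(self.ff1(self.ln2(x)).gelu())

    def parameters(self):
        return (self.ln1.parameters() + self.attn.parameters()
                + self.ln2.parameters() + self.ff1.parameters()
                + self.ff2.parameters())


@dataclass
class EncoderConfig:
    """Desk-scale defaults; the architecture is size-agnostic."""

    layers: int = 2
    width: int = 64
    heads: int = 4
    ff_width: int = 256
    vocab_size: int = 0
    max_positions: int = 264  # >= 128 text + 2 x (64 + 2) packed spans + CLS

    def __post_init__(self) -> None:
        if self.width % self.heads:
            raise ValueError("width must be divisible by heads")


class TransformerEncoder:
    """Token + position embeddings, pre-norm transformer stack, final norm."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        # token embeddings start near unit norm so that distinct token
        # content dominates the residual stream; positional embeddings
        # start small to keep pooled representations from sharing one
        # large common direction (which would flatten cosine scores)
        self.tok_emb = Parameter(
            _init(rng, config.vocab_size, config.width,
                  scale=config.width ** -0.5))
        self.pos_emb = Parameter(
            _init(rng, config.max_positions, config.width, scale=0.02))
        self.layers = [TransformerLayer(rng, config.width, config.heads,
                                        config.ff_width)
                       for _ in range(config.layers)]
        self.ln_f = LayerNorm(config.width)

    def parameters(self) -> list[Parameter]:
        ps = [self.tok_emb, self.pos_emb]
        for layer in self.layers:
            ps.extend(layer.parameters())
        ps.extend(self.ln_f.parameters())
        return ps

    def __call__(self, ids: np.ndarray, pad_id: int,
                 final_norm: bool = True) -> Tensor:
        """Encode a padded id matrix (B, T) into hidden states (B, T, width).

        ``final_norm=False`` returns the raw residual stream, in which
        each position's token embedding survives additively; feature-
        based pooling uses this so the cosine objective keeps a direct
        gradient path into the embeddings.
        """
        B, T = ids.shape
        if T > self.config.max_positions:
            raise ValueError("sequence longer than max_positions")
        x = self.tok_emb.take_rows(ids) + self.pos_emb.take_rows(
            np.broadcast_to(np.arange(T), (B, T)))
        bias = np.where(ids == pad_id, -1e9, 0.0)[:, None, None, :]
        for layer in self.layers:
            x = layer(x, bias)
        return self.ln_f(x) if final_norm else x

    # -- persistence -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float64)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, directory) -> "TransformerEncoder":
        directory = Path(directory)
        config = EncoderConfig(**json.loads(
            (directory / "config.json").read_text()))
        enc = cls(config, seed=0)
        with np.load(directory / "weights.npz") as state:
            enc.load_state_dict(dict(state))
        return enc


# ---------------------------------------------------------------------------
# optimizer

class AdamW:
    """Adam with decoupled weight decay and linear warmup / linear decay.

    ``warmup`` is the proportion of ``total_steps`` spent ramping the
    learning rate from 0 to ``lr``; afterwards it decays linearly to 0
    (constant if ``total_steps`` is None).
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01,
                 warmup: float = 0.2, total_steps: int | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.warmup = warmup
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def _schedule(self) -> float:
        if self.total_steps is None:
            return 1.0
        frac = self.t / max(self.total_steps, 1)
        if self.warmup > 0 and frac < self.warmup:
            return frac / self.warmup
        if self.warmup >= 1.0:
            return frac
        return max(0.0, (1.0 - frac) / (1.0 - self.warmup))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.lr * self._schedule()
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.weight_decay * p.data)


def clip_grad_norm(params: list[Parameter], max_norm: float = 1.0) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
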