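"""Neural building blocks on top of :mod:`supconvoice.autodiff`.

Layers follow the usual Module pattern: parameters are named ``Tensor``
objects with ``requires_grad=True``, collected recursively, and updated by
:class:`AdamW`.  Initialisation is fully determined by the numpy ``Generator``
passed to each constructor, so a model built twice from the same seed has
bit-identical parameters.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

#: parameter dtype; single precision keeps the large frame tensors cheap
DTYPE = np.float32

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "SelfAttentionBlock",
    "AdamW",
    "softmax",
    "cross_entropy",
]


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                named.append((key, value))
            elif isinstance(value, Module):
                named.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return named

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, flag: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def release_graphs(self) -> None:
        """Drop retained forward-pass tensors (hook activations and their
        upstream graphs) so a stored model holds only its parameters."""
        for mod in self.modules():
            if hasattr(mod, "attn_out"):
                mod.attn_out = None
        self.zero_grad()

    #: names of non-trainable ndarray attributes carried in the state dict
    buffer_names: tuple[str, ...] = ()

    def named_buffers(self, prefix: str = "") -> list[tuple[str, "Module", str]]:
        out = []
        for name in self.buffer_names:
            out.append((f"{prefix}{name}", self, name))
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                out.extend(value.named_buffers(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state[name] = np.array(getattr(owner, attr), copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = {name: (owner, attr) for name, owner, attr in self.named_buffers()}
        if set(own) | set(buffers) != set(state):
            raise ValueError("state dict keys do not match model parameters")
        for name, p in own.items():
            p.data = state[name].copy()
        for name, (owner, attr) in buffers.items():
            setattr(owner, attr, state[name].copy())

    training: bool = True


class Linear(Module):
    """Affine map ``x @ W + b`` with Kaiming-uniform initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        bound = math.sqrt(1.0 / in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)).astype(DTYPE),
                             requires_grad=True)
        self.bias = (Tensor(rng.uniform(-bound, bound, size=(out_dim,)).astype(DTYPE),
                            requires_grad=True) if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Feature-wise standardisation over the batch axis.

    Training uses batch statistics and tracks exponential running averages;
    evaluation standardises with the running statistics, so single clips are
    scored deterministically.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu.data[0]).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var.data[0]).astype(DTYPE)
            return centred / ((var + self.eps) ** 0.5) * self.gamma + self.beta
        scale = np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * (1.0 / scale) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only while ``training`` and ``rate > 0``.

    The mask stream comes from the ``Generator`` supplied at construction, so
    a fixed seed yields a reproducible training trajectory.
    """

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * mask


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True).detach()
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax negative log-likelihood over the batch.

    ``labels`` are integer class ids of shape (N,).
    """
    labels = np.asarray(labels)
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True).detach()
    log_z = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - log_z
    picked = log_probs[np.arange(n), labels]
    return -picked.sum() * (1.0 / n)


class SelfAttentionBlock(Module):
    """Pre-norm transformer block: LN → single-head attention → LN → MLP.

    ``attn_out`` (the output-projection activations of the attention sublayer,
    shape B×T×d) is stashed on every forward pass as the hook point used by
    gradient-based relevance mapping.
    """

    def __init__(self, dim: int, rng: np.random.Generator, ffn_mult: int = 2, dropout: float = 0.0):
        self.ln1 = LayerNorm(dim)
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn1 = Linear(dim, dim * ffn_mult, rng)
        self.ffn2 = Linear(dim * ffn_mult, dim, rng)
        # zero-initialised residual gates: the block starts as an exact
        # identity and capacity enters only as the gates are learned
        self.attn_gate = Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)
        self.ffn_gate = Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)
        self.scale = 1.0 / math.sqrt(dim)
        self.attn_out: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        q, k, v = self.q(h), self.k(h), self.v(h)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        proj = self.out_proj(ctx)
        x = x + proj * self.attn_gate
        # hook point for relevance mapping: the attention sublayer's output
        # as it enters the residual stream (the activation that feeds the
        # decision), not the bare projection, which the zero-initialised
        # gate would decouple from the logit
        self.attn_out = x
        h = self.ln2(x)
        return x + self.ffn2(self.ffn1(h).relu()) * self.ffn_gate


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 2e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=float) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=float) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / bias1
            v_hat = v / bias2
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)
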