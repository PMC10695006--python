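"""Neural-network layers and the Adam optimiser on top of the autodiff engine.

Layers hold their parameters as ``Tensor`` objects with ``requires_grad``
set; a module exposes them through ``parameters()`` so the optimiser and the
checkpoint writer can enumerate them in a stable order.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["Module", "Linear", "Embedding", "GRUCell", "MLP", "Adam", "dropout_mask"]


class Module:
    """Base container: collects parameters from attributes and sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, dim: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(indices)


class GRUCell(Module):
    """Gated recurrent unit; gates fused into single (in, 3H) / (H, 3H) maps."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.w_x = Tensor(_glorot(rng, in_dim, 3 * hidden_dim), requires_grad=True)
        # orthogonal recurrent maps keep the hidden dynamics well-conditioned
        w_h = np.concatenate([_orthogonal(rng, hidden_dim) for _ in range(3)], axis=1)
        self.w_h = Tensor(w_h, requires_grad=True)
        self.bias = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_dim
        gx = x @ self.w_x + self.bias
        gh = h @ self.w_h
        r = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
        z = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h

    def run(self, inputs: list[Tensor], h0: Tensor, reverse: bool = False) -> list[Tensor]:
        """Unroll over a list of per-timestep inputs; returns hidden states."""
        order = reversed(inputs) if reverse else inputs
        h = h0
        states = []
        for x in order:
            h = self(x, h)
            states.append(h)
        return states[::-1] if reverse else states


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator, activation: str = "relu"):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation

    def __call__(self, x: Tensor, dropout: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self.activation == "relu" else x.tanh()
                if dropout > 0.0 and rng is not None:
                    x = x * dropout_mask(x.shape, dropout, rng)
        return x


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted-dropout mask (constant in the graph)."""
    keep = 1.0 - rate
    return Tensor((rng.random(shape) < keep).astype(np.float64) / keep)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
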