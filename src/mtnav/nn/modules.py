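"""Network building blocks: linear layers, MLPs, an LSTM cell, and Adam."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Module", "Linear", "MLP", "LSTMCell", "Adam"]


class Module:
    """Base class: parameter collection plus JSON-friendly (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_list(self) -> list[list]:
        return [p.data.tolist() for p in self.parameters()]

    def load_state_list(self, state: list[list]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, arr in zip(params, state):
            a = np.asarray(arr, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = a

    def copy_from(self, other: "Module", tau: float = 1.0) -> None:
        """Polyak update: self <- tau*other + (1-tau)*self."""
        for p, q in zip(self.parameters(), other.parameters()):
            p.data = tau * q.data + (1.0 - tau) * p.data


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Feedforward stack; ``activation`` applied between layers, not after the last."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu"):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self.activation == "relu" else x.tanh()
        return x


class LSTMCell(Module):
    """Single-layer LSTM cell operating on (batch, n_in) slices."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        scale = np.sqrt(1.0 / (n_in + n_hidden))
        self.W = Tensor(rng.normal(0.0, scale, (n_in + n_hidden, 4 * n_hidden)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z.copy()), Tensor(z.copy())

    def __call__(self, x: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        h, c = state
        gates = concat([x, h], axis=-1) @ self.W + self.b
        n = self.n_hidden
        i = gates[:, 0 * n:1 * n].sigmoid()
        f = gates[:, 1 * n:2 * n].sigmoid()
        g = gates[:, 2 * n:3 * n].tanh()
        o = gates[:, 3 * n:4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, (h_new, c_new)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
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
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
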