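"""Neural building blocks: linear/MLP layers, character CNN, BiLSTM, Adam.

All layers hold their weights as :class:`~famgraph.autodiff.Tensor`
parameters and operate on batched, padded inputs with explicit masks so the
whole sentence batch runs through vectorized NumPy kernels.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, dropout, where_mask

NEG_INF = -1e9


class Module:
    """Base class with recursive parameter collection."""

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

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, d in zip(params, state):
            if p.data.shape != d.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {d.shape}")
            p.data = d.copy()


def xavier(rng: np.random.Generator, *shape: int) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = xavier(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """One hidden layer, ReLU, dropout before the output projection."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_in: int,
        d_out: int,
        dropout_p: float = 0.5,
        hidden: int | None = None,
    ):
        hidden = hidden or d_out
        self.fc1 = Linear(rng, d_in, hidden)
        self.fc2 = Linear(rng, hidden, d_out)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng: np.random.Generator, train: bool) -> Tensor:
        h = self.fc1(x).relu()
        h = dropout(h, self.dropout_p, rng, train)
        return self.fc2(h)


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n: int, d: int, pad_zero: bool = False):
        w = rng.normal(0.0, 0.1, size=(n, d))
        if pad_zero:
            w[0] = 0.0
        self.W = Tensor(w, requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W[idx]


class CharCNN(Module):
    """Character-level convolutions with max-over-positions pooling.

    One convolution per kernel size; each produces ``n_filters`` features
    via max-pooling over window positions, concatenated across kernel
    sizes.  Tokens shorter than a kernel are zero-padded (the PAD character
    embedding row is fixed at zero) so at least one window always exists.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        n_chars: int,
        char_dim: int,
        kernel_sizes: tuple[int, ...],
        n_filters: int,
    ):
        self.embedding = Embedding(rng, n_chars, char_dim, pad_zero=True)
        self.kernel_sizes = tuple(kernel_sizes)
        self.n_filters = n_filters
        self.filters = [Linear(rng, k * char_dim, n_filters) for k in kernel_sizes]

    @property
    def out_dim(self) -> int:
        return len(self.kernel_sizes) * self.n_filters

    def __call__(self, char_idx: np.ndarray, lengths: np.ndarray) -> Tensor:
        """char_idx: (N, Lmax) int padded with 0; lengths: (N,) char counts.

        Returns (N, out_dim).
        """
        N, L = char_idx.shape
        emb = self.embedding(char_idx)  # (N, L, d)
        outs = []
        for k, filt in zip(self.kernel_sizes, self.filters):
            n_win = L - k + 1
            if n_win < 1:
                raise ValueError("padded char sequences shorter than a kernel")
            # im2col: windows (N, n_win, k*d)
            windows = concat([emb[:, j : j + n_win, :] for j in range(k)], axis=-1)
            conv = filt(windows)  # (N, n_win, F)
            # windows that start beyond max(len, k) - k are padding-only
            valid = np.arange(n_win)[None, :] <= np.maximum(lengths, k)[:, None] - k
            conv = where_mask(conv, valid[:, :, None], NEG_INF)
            outs.append(conv.max(axis=1))  # (N, F)
        return concat(outs, axis=-1)


class LSTM(Module):
    """Unidirectional LSTM over padded batches with a carry mask."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.d_hidden = d_hidden
        self.Wx = xavier(rng, d_in, 4 * d_hidden)
        self.Wh = xavier(rng, d_hidden, 4 * d_hidden)
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        """x: (B, T, d_in); mask: (B, T) bool. Returns (B, T, d_hidden)."""
        B, T, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = [None] * T  # type: ignore[list-item]
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            xt = x[:, t, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[:, t : t + 1].astype(float))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            outs[t] = h
        cols = [o.reshape(B, 1, H) for o in outs]
        return concat(cols, axis=1)


class BiLSTM(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.fwd = LSTM(rng, d_in, d_hidden)
        self.bwd = LSTM(rng, d_in, d_hidden)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self.fwd(x, mask), self.bwd(x, mask, reverse=True)], axis=-1)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
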