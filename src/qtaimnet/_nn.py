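"""Minimal NumPy neural-network primitives: shifted softplus, dense
stacks with hand-written reverse-mode gradients, and an Adam optimizer.

Everything operates on flat ``{name: ndarray}`` parameter dictionaries so a
whole model (representation + heads) can share one optimizer state.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


def ssp(x: np.ndarray) -> np.ndarray:
    """Shifted softplus ln(0.5 e^x + 0.5) = softplus(x) - ln 2."""
    return np.logaddexp(0.0, x) - np.log(2.0)


def ssp_grad(x: np.ndarray) -> np.ndarray:
    # d/dx softplus(x) = sigmoid(x), computed stably
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_dense(rng: np.random.Generator, d_in: int, d_out: int) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform fan-in initialization; zero bias."""
    bound = 1.0 / np.sqrt(d_in)
    W = rng.uniform(-bound, bound, size=(d_in, d_out))
    b = np.zeros(d_out)
    return W, b


def init_mlp(rng: np.random.Generator, sizes: Sequence[int], params: Params, prefix: str) -> None:
    """Create dense parameters for layers sizes[0] -> ... -> sizes[-1]."""
    for k in range(len(sizes) - 1):
        W, b = init_dense(rng, sizes[k], sizes[k + 1])
        params[f"{prefix}.{k}.W"] = W
        params[f"{prefix}.{k}.b"] = b


def mlp_n_layers(params: Params, prefix: str) -> int:
    k = 0
    while f"{prefix}.{k}.W" in params:
        k += 1
    return k


def mlp_forward(params: Params, prefix: str, x: np.ndarray) -> Tuple[np.ndarray, list]:
    """Dense stack with ssp between layers and a linear final layer."""
    n_layers = mlp_n_layers(params, prefix)
    cache: List[Tuple[np.ndarray, np.ndarray]] = []
    h = x
    for k in range(n_layers):
        pre = h @ params[f"{prefix}.{k}.W"] + params[f"{prefix}.{k}.b"]
        cache.append((h, pre))
        h = ssp(pre) if k < n_layers - 1 else pre
    return h, cache


def mlp_backward(
    params: Params, prefix: str, cache: list, dy: np.ndarray, grads: Params
) -> np.ndarray:
    """Backprop through :func:`mlp_forward`; accumulates into ``grads``."""
    n_layers = len(cache)
    d = dy
    for k in range(n_layers - 1, -1, -1):
        h_in, pre = cache[k]
        if k < n_layers - 1:
            d = d * ssp_grad(pre)
        gW = h_in.T @ d
        gb = d.sum(axis=0)
        key_W, key_b = f"{prefix}.{k}.W", f"{prefix}.{k}.b"
        grads[key_W] = grads.get(key_W, 0.0) + gW
        grads[key_b] = grads.get(key_b, 0.0) + gb
        d = d @ params[key_W].T
    return d


class Adam:
    """Adam optimizer over a flat parameter dictionary."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, g in grads.items():
            g = np.asarray(g, dtype=float)
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            params[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
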