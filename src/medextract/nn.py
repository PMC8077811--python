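"""Numpy neural-network primitives: LSTM, dense softmax, linear-chain CRF, Adam.

Everything is explicit forward/backward on numpy arrays. Gradients are
hand-derived and checked against finite differences in the test suite. The
CRF supports the marginal formulation: forward-backward per-token marginals
are trained with a categorical cross-entropy objective (backpropagated
through both recursions), decoded by per-token marginal argmax; joint Viterbi
decoding is available separately.

Shapes: batches are (B, T, D) right-padded; sequence content beyond a row's
length is ignored by construction (losses are masked, and the backward
direction re-reverses by true length).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot", "Adam", "LSTM", "Dense",
    "softmax_xent", "reverse_by_length",
    "crf_forward_backward", "crf_marginal_loss", "crf_viterbi",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class Adam:
    """Adaptive-moment optimizer over a dict of named parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class LSTM:
    """Single-direction LSTM over right-padded batches.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias initializes to 1. Optional variational recurrent
    dropout applies one fixed mask per sequence to the recurrent input.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim, self.hidden = input_dim, hidden
        self.W = glorot(rng, (input_dim, 4 * hidden))
        self.U = glorot(rng, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.U": self.U, f"{prefix}.b": self.b}

    def forward(self, x: np.ndarray, rdrop_mask: np.ndarray | None = None):
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, T, H))
        cache = {"x": x, "rmask": rdrop_mask, "steps": []}
        h_prev = np.zeros((B, H))
        c_prev = np.zeros((B, H))
        xW = x @ self.W  # (B,T,4H), hoisted out of the time loop
        for t in range(T):
            h_in = h_prev * rdrop_mask if rdrop_mask is not None else h_prev
            z = xW[:, t] + h_in @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_t = o * tc
            cache["steps"].append((h_prev, c_prev, h_in, i, f, g, o, tc))
            h[:, t] = h_t
            h_prev, c_prev = h_t, c
        return h, cache

    def backward(self, dh_out: np.ndarray, cache, compute_dx: bool = False):
        """Backprop; ``dh_out`` is (B,T,H). Returns (grads, dx or None)."""
        x, rmask = cache["x"], cache["rmask"]
        B, T, _ = x.shape
        H = self.hidden
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x) if compute_dx else None
        dz_all = np.zeros((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, h_in, i, f, g, o, tc = cache["steps"][t]
            dh = dh_out[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dz_all[:, t] = dz
            dU += h_in.T @ dz
            dh_prev = dz @ self.U.T
            if rmask is not None:
                dh_prev = dh_prev * rmask
            dh_next = dh_prev
        # batched input-weight gradient: fold (B,T) together
        flat_x = x.reshape(B * T, -1)
        flat_dz = dz_all.reshape(B * T, -1)
        dW = flat_x.T @ flat_dz
        db = flat_dz.sum(axis=0)
        if compute_dx:
            dx = (flat_dz @ self.W.T).reshape(x.shape)
        return {"W": dW, "U": dU, "b": db}, dx


class Dense:
    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = glorot(rng, (input_dim, output_dim))
        self.b = np.zeros(output_dim)

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def forward(self, h: np.ndarray) -> np.ndarray:
        return h @ self.W + self.b

    def backward(self, h: np.ndarray, dlogits: np.ndarray):
        flat_h = h.reshape(-1, h.shape[-1])
        flat_d = dlogits.reshape(-1, dlogits.shape[-1])
        grads = {"W": flat_h.T @ flat_d, "b": flat_d.sum(axis=0)}
        dh = (flat_d @ self.W.T).reshape(h.shape)
        return grads, dh


def softmax_xent(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Masked mean cross-entropy; returns (loss, dlogits).

    ``logits`` (B,T,K), ``targets`` (B,T) int, ``mask`` (B,T) in {0,1}.
    """
    shifted = logits - logits.max(axis=-1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    n = max(mask.sum(), 1.0)
    B, T, K = logits.shape
    idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
    loss = -(logp[idx] * mask).sum() / n
    dlogits = np.exp(logp)
    dlogits[idx] -= 1.0
    dlogits *= (mask / n)[:, :, None]
    return loss, dlogits


def reverse_by_length(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``length`` steps, leaving padding in place."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
        out[b, L:] = x[b, L:]
    return out


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def crf_forward_backward(emissions: np.ndarray, transitions: np.ndarray):
    """Alpha/beta recursions in log space for one sequence (T,K).

    Returns (alpha, beta, logZ, log_marginals).
    """
    T, K = emissions.shape
    alpha = np.zeros((T, K))
    beta = np.zeros((T, K))
    alpha[0] = emissions[0]
    for t in range(1, T):
        alpha[t] = emissions[t] + _logsumexp(alpha[t - 1][:, None] + transitions, axis=0)
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(transitions + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    logZ = _logsumexp(alpha[-1], axis=0)
    log_marg = alpha + beta - logZ
    return alpha, beta, logZ, log_marg


def crf_marginal_loss(emissions: np.ndarray, transitions: np.ndarray, y: np.ndarray):
    """Cross-entropy on forward-backward marginals, with exact gradients.

    Loss = -sum_t log p(y_t | x), p the per-token CRF marginal. Returns
    (loss, d_emissions, d_transitions); the gradient is reverse-mode through
    both recursions (softmax weights of each logsumexp).
    """
    T, K = emissions.shape
    alpha, beta, logZ, log_marg = crf_forward_backward(emissions, transitions)
    loss = -log_marg[np.arange(T), y].sum()

    g_alpha = np.zeros((T, K))
    g_beta = np.zeros((T, K))
    g_alpha[np.arange(T), y] -= 1.0
    g_beta[np.arange(T), y] -= 1.0
    # logZ = LSE(alpha[T-1]) consumed T times with weight +1 each
    g_alpha[-1] += T * np.exp(alpha[-1] - logZ)

    dE = np.zeros_like(emissions)
    dA = np.zeros_like(transitions)

    # beta recursion: beta[t] depends on beta[t+1]; visit consumers first
    for t in range(T - 1):
        scores = transitions + (emissions[t + 1] + beta[t + 1])[None, :]
        V = np.exp(scores - beta[t][:, None])  # softmax over j per row i
        contrib = V * g_beta[t][:, None]
        dA += contrib
        dE[t + 1] += contrib.sum(axis=0)
        g_beta[t + 1] += contrib.sum(axis=0)

    # alpha recursion, reverse order
    for t in range(T - 1, 0, -1):
        scores = alpha[t - 1][:, None] + transitions
        S = np.exp(scores - (alpha[t] - emissions[t])[None, :])  # softmax over i per col j
        dE[t] += g_alpha[t]
        contrib = S * g_alpha[t][None, :]
        dA += contrib
        g_alpha[t - 1] += contrib.sum(axis=1)
    dE[0] += g_alpha[0]
    return loss, dE, dA


def crf_viterbi(emissions: np.ndarray, transitions: np.ndarray) -> np.ndarray:
    """Joint max-probability decoding for one sequence."""
    T, K = emissions.shape
    score = emissions[0].copy()
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + transitions
        back[t] = cand.argmax(axis=0)
        score = emissions[t] + cand.max(axis=0)
    path = np.zeros(T, dtype=np.int64)
    path[-1] = score.argmax()
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path
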