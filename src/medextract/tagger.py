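"""Bidirectional LSTM sequence tagger with optional CRF output layer.

Architecture: per-token input vectors (frozen embeddings, optionally
concatenated with rule features) -> dropout -> two LSTMs reading the
sentence forward and backward, their hidden states concatenated -> dropout
-> dense projection to the 15 IOB tags. The output layer is either softmax
with categorical cross-entropy, or a linear-chain CRF trained on
forward-backward marginals with the same cross-entropy objective and decoded
by per-token marginal argmax (joint Viterbi decoding is available behind a
flag).

Training uses Adam at learning rate 1e-3 for up to 50 epochs with early
stopping on development loss (patience 8) and learning-rate reduction on
plateau (factor 0.1). Hyperparameters are tuned by random search over the
configuration grid (15 iterations by default), scored by development
micro-F.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .labels import N_TAGS, TAGS, TAG_TO_INDEX
from .evaluation import ConfusionCounts, micro_prf, token_confusion
from .nn import (
    Adam,
    Dense,
    LSTM,
    crf_marginal_loss,
    crf_viterbi,
    reverse_by_length,
    softmax_xent,
)

__all__ = [
    "ConfigError", "TaggerConfig", "TaggerModel", "TrainHistory",
    "EarlyStopping", "ReduceLROnPlateau",
    "build_model", "train", "predict", "random_search",
    "encode_tags", "decode_tags", "save_model", "load_model",
]

HIDDEN_GRID = (128, 256, 512)
BATCH_GRID = (64, 128)
DROPOUT_GRID = (0.0, 0.1, 0.2, 0.3, 0.5, 0.6, 0.7)

DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "hidden_size": HIDDEN_GRID,
    "batch_size": BATCH_GRID,
    "dropout_before": DROPOUT_GRID,
    "dropout_after": DROPOUT_GRID,
    "recurrent_dropout": DROPOUT_GRID,
}


class ConfigError(ValueError):
    """A hyperparameter outside its allowed grid."""


@dataclass(frozen=True)
class TaggerConfig:
    hidden_size: int = 128
    batch_size: int = 64
    dropout_before: float = 0.0
    dropout_after: float = 0.0
    recurrent_dropout: float = 0.0
    use_crf: bool = False
    viterbi: bool = False          # joint decoding instead of marginal argmax
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 8
    plateau_factor: float = 0.1
    plateau_patience: int = 3
    plateau_min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size not in HIDDEN_GRID:
            raise ConfigError(f"hidden_size must be in {HIDDEN_GRID}")
        if self.batch_size not in BATCH_GRID:
            raise ConfigError(f"batch_size must be in {BATCH_GRID}")
        for name in ("dropout_before", "dropout_after", "recurrent_dropout"):
            if getattr(self, name) not in DROPOUT_GRID:
                raise ConfigError(f"{name} must be in {DROPOUT_GRID}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.max_epochs < 1 or self.patience < 1:
            raise ConfigError("max_epochs and patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    dev_loss: list[float] = field(default_factory=list)
    dev_f: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class EarlyStopping:
    """Stop when the monitored loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.best_epoch = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; True means training should stop now."""
        self.epoch += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = self.epoch
        return self.epoch - self.best_epoch >= self.patience


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after a loss plateau."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 3,
                 min_delta: float = 1e-4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; True when the rate was just reduced."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False


class TaggerModel:
    """BiLSTM (optionally CRF-topped) tagger over fixed per-token inputs."""

    def __init__(self, config: TaggerConfig, input_dim: int):
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        H = config.hidden_size
        self.fwd = LSTM(input_dim, H, rng)
        self.bwd = LSTM(input_dim, H, rng)
        self.out = Dense(2 * H, N_TAGS, rng)
        self.transitions = (
            0.01 * rng.standard_normal((N_TAGS, N_TAGS)) if config.use_crf else None
        )

    def params(self) -> dict[str, np.ndarray]:
        p = {**self.fwd.params("fwd"), **self.bwd.params("bwd"),
             **self.out.params("out")}
        if self.transitions is not None:
            p["crf.A"] = self.transitions
        return p

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        own = self.params()
        for k, v in values.items():
            own[k][...] = v

    # ---- forward/backward over one padded batch ----

    def _encode(self, X: np.ndarray, lengths: np.ndarray, train_rng=None):
        cfg = self.config
        caches: dict = {}
        if train_rng is not None and cfg.dropout_before > 0:
            keep = 1 - cfg.dropout_before
            m = (train_rng.random(X.shape) < keep) / keep
            X = X * m
            caches["drop_in"] = m
        rmask_f = rmask_b = None
        if train_rng is not None and cfg.recurrent_dropout > 0:
            keep = 1 - cfg.recurrent_dropout
            rmask_f = (train_rng.random((X.shape[0], cfg.hidden_size)) < keep) / keep
            rmask_b = (train_rng.random((X.shape[0], cfg.hidden_size)) < keep) / keep
        h_f, cache_f = self.fwd.forward(X, rmask_f)
        X_rev = reverse_by_length(X, lengths)
        h_b_rev, cache_b = self.bwd.forward(X_rev, rmask_b)
        h_b = reverse_by_length(h_b_rev, lengths)
        H = np.concatenate([h_f, h_b], axis=2)
        if train_rng is not None and cfg.dropout_after > 0:
            keep = 1 - cfg.dropout_after
            m = (train_rng.random(H.shape) < keep) / keep
            H = H * m
            caches["drop_out"] = m
        caches.update(cache_f=cache_f, cache_b=cache_b, lengths=lengths, H=H)
        logits = self.out.forward(H)
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        g_out, dH = self.out.backward(caches["H"], dlogits)
        if "drop_out" in caches:
            dH = dH * caches["drop_out"]
        Hs = self.config.hidden_size
        g_f, _ = self.fwd.backward(dH[:, :, :Hs], caches["cache_f"])
        dH_b_rev = reverse_by_length(dH[:, :, Hs:], caches["lengths"])
        g_b, _ = self.bwd.backward(dH_b_rev, caches["cache_b"])
        grads = {**{f"fwd.{k}": v for k, v in g_f.items()},
                 **{f"bwd.{k}": v for k, v in g_b.items()},
                 **{f"out.{k}": v for k, v in g_out.items()}}
        return grads

    def batch_loss(self, X, Y, lengths, train_rng=None):
        """Masked mean loss and parameter gradients for one padded batch."""
        logits, caches = self._encode(X, lengths, train_rng)
        B, T, _ = logits.shape
        mask = np.zeros((B, T))
        for b, L in enumerate(lengths):
            mask[b, :L] = 1
        if self.transitions is None:
            loss, dlogits = softmax_xent(logits, Y, mask)
            grads = self._backward(dlogits, caches)
        else:
            n = max(int(lengths.sum()), 1)
            loss = 0.0
            dlogits = np.zeros_like(logits)
            dA = np.zeros_like(self.transitions)
            for b, L in enumerate(lengths):
                if L == 0:
                    continue
                l_b, dE, dA_b = crf_marginal_loss(
                    logits[b, :L], self.transitions, Y[b, :L]
                )
                loss += l_b
                dlogits[b, :L] = dE / n
                dA += dA_b / n
            loss /= n
            grads = self._backward(dlogits, caches)
            grads["crf.A"] = dA
        return loss, grads

    def decode(self, X, lengths) -> list[np.ndarray]:
        logits, _ = self._encode(X, lengths, train_rng=None)
        out = []
        for b, L in enumerate(lengths):
            if L == 0:
                out.append(np.zeros(0, dtype=np.int64))
            elif self.transitions is None:
                out.append(logits[b, :L].argmax(axis=1))
            elif self.config.viterbi:
                out.append(crf_viterbi(logits[b, :L], self.transitions))
            else:
                from .nn import crf_forward_backward

                *_, log_marg = crf_forward_backward(logits[b, :L], self.transitions)
                out.append(log_marg.argmax(axis=1))
        return out


def build_model(config: TaggerConfig, input_dim: int) -> TaggerModel:
    """Construct a seed-deterministic tagger for the given input width."""
    return TaggerModel(config, input_dim)


def encode_tags(iob: Sequence[str]) -> np.ndarray:
    return np.array([TAG_TO_INDEX[t] for t in iob], dtype=np.int64)


def decode_tags(ids: Sequence[int]) -> list[str]:
    return [TAGS[i] for i in ids]


def _pad_batch(items: list[tuple[np.ndarray, np.ndarray]]):
    B = len(items)
    T = max(x.shape[0] for x, _ in items)
    D = items[0][0].shape[1]
    X = np.zeros((B, T, D))
    Y = np.zeros((B, T), dtype=np.int64)
    lengths = np.zeros(B, dtype=np.int64)
    for b, (x, y) in enumerate(items):
        X[b, : len(y)] = x
        Y[b, : len(y)] = y
        lengths[b] = len(y)
    return X, Y, lengths


def _dataset_loss(model: TaggerModel, data, batch_size: int) -> float:
    total, n = 0.0, 0
    for start in range(0, len(data), batch_size):
        chunk = data[start : start + batch_size]
        X, Y, lengths = _pad_batch(chunk)
        loss, _ = model.batch_loss(X, Y, lengths, train_rng=None)
        tokens = int(lengths.sum())
        total += loss * tokens
        n += tokens
    return total / max(n, 1)


def _dataset_f(model: TaggerModel, data, batch_size: int) -> float:
    counts = ConfusionCounts()
    for start in range(0, len(data), batch_size):
        chunk = data[start : start + batch_size]
        X, Y, lengths = _pad_batch(chunk)
        for (x_, y), pred in zip(chunk, model.decode(X, lengths)):
            counts.add(token_confusion(decode_tags(y), decode_tags(pred)))
    return micro_prf(counts).overall.f_measure


def train(
    model: TaggerModel,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    dev_set: list[tuple[np.ndarray, np.ndarray]],
    config: TaggerConfig | None = None,
) -> tuple[TaggerModel, TrainHistory]:
    """Optimize the tagger; returns the best-development-loss checkpoint.

    ``train_set`` / ``dev_set`` are lists of (input matrix (T, D), tag-id
    vector (T,)) pairs. Gradient batches are shuffled per epoch with the
    config seed; embeddings are outside the model and therefore frozen.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    plateau = ReduceLROnPlateau(
        opt, cfg.plateau_factor, cfg.plateau_patience, cfg.plateau_min_delta
    )
    history = TrainHistory()
    best_params = {k: v.copy() for k, v in model.params().items()}
    best_loss = float("inf")
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss, n_tokens = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            chunk = [train_set[i] for i in order[start : start + cfg.batch_size]]
            X, Y, lengths = _pad_batch(chunk)
            loss, grads = model.batch_loss(X, Y, lengths, train_rng=rng)
            opt.step(grads)
            tokens = int(lengths.sum())
            epoch_loss += loss * tokens
            n_tokens += tokens
        dev_loss = _dataset_loss(model, dev_set, cfg.batch_size) if dev_set else (
            epoch_loss / max(n_tokens, 1)
        )
        history.train_loss.append(epoch_loss / max(n_tokens, 1))
        history.dev_loss.append(dev_loss)
        history.dev_f.append(_dataset_f(model, dev_set, cfg.batch_size) if dev_set else 0.0)
        history.learning_rates.append(opt.lr)
        if dev_loss < best_loss:
            best_loss = dev_loss
            best_params = {k: v.copy() for k, v in model.params().items()}
            history.best_epoch = epoch
        plateau.update(dev_loss)
        if stopper.update(dev_loss):
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = cfg.max_epochs
    model.set_params(best_params)
    return model, history


def predict(
    model: TaggerModel, inputs: list[np.ndarray], batch_size: int | None = None
) -> list[list[str]]:
    """IOB tag sequences for a list of per-sentence input matrices."""
    bs = batch_size or model.config.batch_size
    out: list[list[str]] = []
    for start in range(0, len(inputs), bs):
        chunk = inputs[start : start + bs]
        for x in chunk:
            if x.shape[1] != model.input_dim:
                raise ValueError(
                    f"input dimension {x.shape[1]} != model dimension {model.input_dim}"
                )
        items = [(x, np.zeros(x.shape[0], dtype=np.int64)) for x in chunk]
        X, _Y, lengths = _pad_batch(items) if items else (None, None, None)
        if X is None:
            continue
        out.extend(decode_tags(p) for p in model.decode(X, lengths))
    return out


def random_search(
    space: dict[str, Sequence],
    train_set,
    dev_set,
    n_iter: int = 15,
    seed: int = 0,
    base: TaggerConfig | None = None,
    input_dim: int | None = None,
):
    """Random hyperparameter search scored by development micro-F.

    Samples exactly ``n_iter`` configurations uniformly from the grid
    (seed-reproducible), trains each, and returns
    ``(best_config, best_model, trials)`` where trials is the full log of
    (config, dev_F) pairs and best is the argmax.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    base = base or TaggerConfig()
    if input_dim is None:
        input_dim = train_set[0][0].shape[1]
    rng = random.Random(seed)
    trials: list[tuple[TaggerConfig, float]] = []
    best: tuple[float, TaggerConfig, TaggerModel] | None = None
    for k in range(n_iter):
        sampled = {name: rng.choice(list(values)) for name, values in space.items()}
        cfg = replace(base, **sampled)
        model = build_model(cfg, input_dim)
        model, _history = train(model, train_set, dev_set, cfg)
        score = _dataset_f(model, dev_set, cfg.batch_size)
        trials.append((cfg, score))
        if best is None or score > best[0]:
            best = (score, cfg, model)
    assert best is not None
    return best[1], best[2], trials


def save_model(model: TaggerModel, path) -> None:
    """Single-archive serialization: config JSON + parameter arrays."""
    payload = {f"param::{k}": v for k, v in model.params().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({**asdict(model.config), "input_dim": model.input_dim}).encode(),
        dtype=np.uint8,
    )
    np.savez(Path(path), **payload)


def load_model(path) -> TaggerModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["config_json"].tobytes()).decode())
        input_dim = meta.pop("input_dim")
        cfg = TaggerConfig(**meta)
        model = TaggerModel(cfg, input_dim)
        model.set_params(
            {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
        )
    return model
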