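"""Token representations: embedding providers, rule features, input fusion.

Three provider families share one contract (``dimension`` plus a
sentence-level lookup returning one fixed-length vector per token, frozen at
tagging time):

* ``StaticSkipGramEmbedding`` — skip-gram with negative sampling trained on
  the (synthetic) training corpus; the baseline representation.
* ``SubwordSkipGramEmbedding`` — the same objective, but a word is the mean
  of its character n-gram vectors (n = 3–6, with word-boundary markers), so
  out-of-vocabulary words still compose a representation from their
  substrings.
* ``RecurrentLMEmbedding`` — a contextual provider: a small character-aware
  bidirectional recurrent language model (subword-composed inputs; a forward
  LSTM trained to predict the next token and a backward LSTM the previous
  one); a token's embedding is the concatenation of the two hidden states,
  so it varies with sentence context.

The rule layer's IOB tags enter the tagger as one-hot vectors over the fixed
15-tag inventory, concatenated after the embedding block.
"""

from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np
from scipy import sparse

from .labels import N_TAGS, TAG_TO_INDEX
from .nn import Adam, Dense, LSTM, reverse_by_length, softmax_xent

__all__ = [
    "EmbeddingProvider",
    "StaticSkipGramEmbedding",
    "SubwordSkipGramEmbedding",
    "RecurrentLMEmbedding",
    "train_static_embedding",
    "encode_rule_features",
    "build_inputs",
    "write_word_vectors",
    "read_word_vectors",
]


class EmbeddingProvider(Protocol):
    dimension: int
    mode: str

    def embed_sentence(self, tokens: Sequence[str]) -> np.ndarray: ...


def _build_vocab(sentences: Sequence[Sequence[str]], min_count: int = 1):
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            t = tok.casefold()
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return vocab, counts


def _skipgram_pairs(sentences, vocab_index, window, rng):
    pairs = []
    for sent in sentences:
        ids = [vocab_index.get(t.casefold()) for t in sent]
        for i, center in enumerate(ids):
            if center is None:
                continue
            w = rng.integers(1, window + 1)
            for j in range(max(0, i - w), min(len(ids), i + w + 1)):
                if j != i and ids[j] is not None:
                    pairs.append((center, ids[j]))
    return np.array(pairs, dtype=np.int64) if pairs else np.zeros((0, 2), dtype=np.int64)


def _sgns_train(center_rows, n_centers, n_context, pairs, dimension, epochs,
                negatives, lr, counts_arr, rng):
    """Shared SGNS loop; ``center_rows`` maps center ids to component rows.

    ``center_rows`` is a (n_centers, n_components) sparse row-stochastic
    matrix: identity for plain word vectors, n-gram membership (row-averaged)
    for the subword variant.
    """
    n_comp = center_rows.shape[1]
    W_in = (rng.random((n_comp, dimension)) - 0.5) / dimension
    W_out = np.zeros((n_context, dimension))
    if len(pairs) == 0:
        raise ValueError("empty corpus: no skip-gram pairs")
    noise = counts_arr.astype(np.float64) ** 0.75
    noise /= noise.sum()
    batch = 512
    for _epoch in range(epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), batch):
            sel = pairs[order[start : start + batch]]
            centers, contexts = sel[:, 0], sel[:, 1]
            B = len(sel)
            neg = rng.choice(n_context, size=(B, negatives), p=noise)
            rows = center_rows[centers]                      # (B, n_comp) sparse
            v_c = rows @ W_in                                # (B, d)
            ctx_ids = np.concatenate([contexts[:, None], neg], axis=1)  # (B, 1+k)
            v_o = W_out[ctx_ids]                             # (B, 1+k, d)
            score = np.einsum("bd,bkd->bk", v_c, v_o)
            sign = np.full_like(score, -1.0)
            sign[:, 0] = 1.0
            sig = 1.0 / (1.0 + np.exp(-np.clip(sign * score, -50, 50)))
            coeff = sign * (sig - 1.0)                       # d(-logsig)/dscore
            d_vc = np.einsum("bk,bkd->bd", coeff, v_o)
            d_vo = coeff[:, :, None] * v_c[:, None, :]
            W_in -= lr * (rows.T @ d_vc)
            np.add.at(W_out, ctx_ids.reshape(-1), -lr * d_vo.reshape(-1, W_out.shape[1]))
    return W_in, W_out


class StaticSkipGramEmbedding:
    """Plain skip-gram with negative sampling; one static vector per word."""

    mode = "static"

    def __init__(self, vectors: dict[str, np.ndarray], dimension: int,
                 unk_vector: np.ndarray):
        self.vectors = vectors
        self.dimension = dimension
        self.unk_vector = unk_vector

    @classmethod
    def train(cls, sentences: Sequence[Sequence[str]], dimension: int = 100,
              window: int = 5, epochs: int = 5, negatives: int = 5,
              lr: float = 0.025, min_count: int = 1, seed: int = 0):
        if not any(len(s) for s in sentences):
            raise ValueError("empty corpus")
        rng = np.random.default_rng(seed)
        vocab, counts = _build_vocab(sentences, min_count)
        index = {t: i for i, t in enumerate(vocab)}
        pairs = _skipgram_pairs(sentences, index, window, rng)
        counts_arr = np.array([counts[t] for t in vocab])
        eye = sparse.identity(len(vocab), format="csr")
        W_in, _ = _sgns_train(eye, len(vocab), len(vocab), pairs, dimension,
                              epochs, negatives, lr, counts_arr, rng)
        unk = (rng.random(dimension) - 0.5) / dimension
        return cls({t: W_in[i] for t, i in index.items()}, dimension, unk)

    def embed_sentence(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack(
            [self.vectors.get(t.casefold(), self.unk_vector) for t in tokens]
        ) if tokens else np.zeros((0, self.dimension))


def _char_ngrams(word: str, n_min: int = 3, n_max: int = 6) -> list[str]:
    marked = f"<{word}>"
    return [
        marked[i : i + n]
        for n in range(n_min, n_max + 1)
        for i in range(len(marked) - n + 1)
    ]


class SubwordSkipGramEmbedding:
    """Skip-gram whose word vectors are means of character n-gram vectors."""

    mode = "subword"

    def __init__(self, ngram_vectors: dict[str, np.ndarray], dimension: int,
                 unk_vector: np.ndarray, n_min: int = 3, n_max: int = 6):
        self.ngram_vectors = ngram_vectors
        self.dimension = dimension
        self.unk_vector = unk_vector
        self.n_min, self.n_max = n_min, n_max

    @classmethod
    def train(cls, sentences: Sequence[Sequence[str]], dimension: int = 100,
              window: int = 5, epochs: int = 5, negatives: int = 5,
              lr: float = 0.025, min_count: int = 1, seed: int = 0,
              n_min: int = 3, n_max: int = 6):
        if not any(len(s) for s in sentences):
            raise ValueError("empty corpus")
        rng = np.random.default_rng(seed)
        vocab, counts = _build_vocab(sentences, min_count)
        index = {t: i for i, t in enumerate(vocab)}
        grams: dict[str, int] = {}
        rows, cols, vals = [], [], []
        for t, i in index.items():
            gs = _char_ngrams(t, n_min, n_max) or [f"<{t}>"]
            for g in gs:
                gid = grams.setdefault(g, len(grams))
                rows.append(i)
                cols.append(gid)
                vals.append(1.0 / len(gs))
        comp = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(vocab), len(grams))
        )
        pairs = _skipgram_pairs(sentences, index, window, rng)
        counts_arr = np.array([counts[t] for t in vocab])
        W_in, _ = _sgns_train(comp, len(vocab), len(vocab), pairs, dimension,
                              epochs, negatives, lr, counts_arr, rng)
        unk = (rng.random(dimension) - 0.5) / dimension
        return cls({g: W_in[gid] for g, gid in grams.items()}, dimension, unk,
                   n_min, n_max)

    def _word_vector(self, word: str) -> np.ndarray:
        gs = [
            self.ngram_vectors[g]
            for g in _char_ngrams(word.casefold(), self.n_min, self.n_max)
            if g in self.ngram_vectors
        ]
        return np.mean(gs, axis=0) if gs else self.unk_vector

    def embed_sentence(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self._word_vector(t) for t in tokens]) if tokens else (
            np.zeros((0, self.dimension))
        )


def train_static_embedding(sentences, dimension: int = 100, window: int = 5,
                           seed: int = 0, subword: bool = False, **kwargs):
    """Train a static provider on tokenized sentences (seed-deterministic)."""
    cls = SubwordSkipGramEmbedding if subword else StaticSkipGramEmbedding
    return cls.train(sentences, dimension=dimension, window=window, seed=seed, **kwargs)


class RecurrentLMEmbedding:
    """Contextual provider: bidirectional recurrent LM over subword inputs.

    A forward LSTM is trained to predict the next token and a backward LSTM
    the previous one (cross-entropy over the corpus vocabulary); a token's
    embedding is the concatenation of the two hidden states, hence
    context-dependent. Dimension = 2 * hidden.
    """

    mode = "contextual"

    def __init__(self, base: SubwordSkipGramEmbedding, hidden: int = 32,
                 seed: int = 0):
        self.base = base
        self.hidden = hidden
        self.dimension = 2 * hidden
        rng = np.random.default_rng(seed)
        self.fwd = LSTM(base.dimension, hidden, rng)
        self.bwd = LSTM(base.dimension, hidden, rng)
        self._rng = rng
        self._out_fwd: Dense | None = None
        self._out_bwd: Dense | None = None

    @classmethod
    def train(cls, sentences: Sequence[Sequence[str]], hidden: int = 32,
              base_dimension: int = 32, epochs: int = 3, lr: float = 1e-3,
              seed: int = 0):
        if not any(len(s) for s in sentences):
            raise ValueError("empty corpus")
        base = SubwordSkipGramEmbedding.train(
            sentences, dimension=base_dimension, epochs=2, seed=seed
        )
        self = cls(base, hidden, seed)
        vocab, _ = _build_vocab(sentences)
        index = {t: i for i, t in enumerate(vocab)}
        V = len(vocab)
        self._out_fwd = Dense(hidden, V, self._rng)
        self._out_bwd = Dense(hidden, V, self._rng)
        params = {**self.fwd.params("fwd"), **self.bwd.params("bwd"),
                  **self._out_fwd.params("of"), **self._out_bwd.params("ob")}
        opt = Adam(params, lr=lr)
        data = [s for s in sentences if len(s) >= 2]
        rng = np.random.default_rng(seed + 1)
        for _epoch in range(epochs):
            order = rng.permutation(len(data))
            for start in range(0, len(data), 32):
                batch = [data[i] for i in order[start : start + 32]]
                X, lengths = self._pad([self.base.embed_sentence(s) for s in batch])
                ids = np.zeros(X.shape[:2], dtype=np.int64)
                for b, s in enumerate(batch):
                    for t, tok in enumerate(s):
                        ids[b, t] = index.get(tok.casefold(), 0)
                self._lm_step(X, ids, lengths, opt)
        return self

    @staticmethod
    def _pad(mats):
        T = max(m.shape[0] for m in mats)
        X = np.zeros((len(mats), T, mats[0].shape[1]))
        lengths = np.zeros(len(mats), dtype=np.int64)
        for b, m in enumerate(mats):
            X[b, : m.shape[0]] = m
            lengths[b] = m.shape[0]
        return X, lengths

    def _lm_step(self, X, ids, lengths, opt):
        B, T, _ = X.shape
        # forward LM: h_t predicts token t+1
        mask_next = np.zeros((B, T))
        for b, L in enumerate(lengths):
            mask_next[b, : max(L - 1, 0)] = 1
        targets_next = np.roll(ids, -1, axis=1)
        h_f, cache_f = self.fwd.forward(X)
        logits_f = self._out_fwd.forward(h_f)
        loss_f, dl_f = softmax_xent(logits_f, targets_next, mask_next)
        g_of, dh_f = self._out_fwd.backward(h_f, dl_f)
        g_f, _ = self.fwd.backward(dh_f, cache_f)

        X_rev = reverse_by_length(X, lengths)
        ids_rev = np.zeros_like(ids)
        for b, L in enumerate(lengths):
            ids_rev[b, :L] = ids[b, :L][::-1]
        targets_prev = np.roll(ids_rev, -1, axis=1)
        h_b, cache_b = self.bwd.forward(X_rev)
        logits_b = self._out_bwd.forward(h_b)
        loss_b, dl_b = softmax_xent(logits_b, targets_prev, mask_next)
        g_ob, dh_b = self._out_bwd.backward(h_b, dl_b)
        g_b, _ = self.bwd.backward(dh_b, cache_b)

        opt.step({
            **{f"fwd.{k}": v for k, v in g_f.items()},
            **{f"bwd.{k}": v for k, v in g_b.items()},
            **{f"of.{k}": v for k, v in g_of.items()},
            **{f"ob.{k}": v for k, v in g_ob.items()},
        })
        return loss_f + loss_b

    def embed_sentence(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dimension))
        x = self.base.embed_sentence(tokens)[None, :, :]
        lengths = np.array([len(tokens)])
        h_f, _ = self.fwd.forward(x)
        h_b_rev, _ = self.bwd.forward(reverse_by_length(x, lengths))
        h_b = reverse_by_length(h_b_rev, lengths)
        return np.concatenate([h_f[0], h_b[0]], axis=1)


def encode_rule_features(iob: Sequence[str]) -> np.ndarray:
    """One-hot encode a rule-layer IOB sequence over the fixed 15-tag order."""
    out = np.zeros((len(iob), N_TAGS))
    for i, tag in enumerate(iob):
        if tag not in TAG_TO_INDEX:
            raise ValueError(f"unknown IOB tag: {tag!r}")
        out[i, TAG_TO_INDEX[tag]] = 1.0
    return out


def build_inputs(
    tokens: Sequence[str],
    provider: EmbeddingProvider,
    rule_iob: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-token input matrix: embedding block first, rule block last.

    With rule features enabled the width is ``provider.dimension + 15``;
    disabled (ablation), it is ``provider.dimension`` exactly.
    """
    emb = provider.embed_sentence(tokens)
    if rule_iob is None:
        return emb
    if len(rule_iob) != len(tokens):
        raise ValueError(
            f"rule features length {len(rule_iob)} != token count {len(tokens)}"
        )
    return np.concatenate([emb, encode_rule_features(rule_iob)], axis=1)


def write_word_vectors(provider: StaticSkipGramEmbedding, path) -> None:
    """Plain word-vector text format: token then space-separated floats."""
    with open(path, "w", encoding="utf-8") as fh:
        for token in sorted(provider.vectors):
            vec = " ".join(f"{v:.6f}" for v in provider.vectors[token])
            fh.write(f"{token} {vec}\n")
        fh.write("<unk> " + " ".join(f"{v:.6f}" for v in provider.unk_vector) + "\n")


def read_word_vectors(path) -> StaticSkipGramEmbedding:
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    dim = len(next(iter(vectors.values())))
    unk = vectors.pop("<unk>", np.zeros(dim))
    return StaticSkipGramEmbedding(vectors, dim, unk)
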