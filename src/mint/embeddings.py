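"""Food-language word embeddings and name / context-sentence vectors.

A small skip-gram model with negative sampling is trained on a
recipe-style corpus; character n-grams (hashed into a fixed bucket table)
give every out-of-vocabulary token a finite, non-degenerate vector.  Name
vectors are the arithmetic mean of the token vectors, so they are
invariant to word order.

Sentence encoders are pluggable: the default backend averages word
vectors from a trained model; heavier contextual encoders can be
registered behind the same ``encode(sentence) -> vector`` contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .errors import EmptyCorpusError, EmptyNameError, UnknownBackendError

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation/whitespace; unicode word chars survive."""
    return _TOKEN_RE.findall(text.lower())


def _fnv1a(s: str) -> int:
    # Python's builtin hash() is salted per process; FNV-1a is stable.
    h = 0xCBF29CE484222325
    for b in s.encode("utf-8"):
        h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def _ngrams(word: str, minn: int, maxn: int) -> list[str]:
    w = f"<{word}>"
    out = []
    for n in range(minn, maxn + 1):
        for i in range(0, len(w) - n + 1):
            out.append(w[i : i + n])
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class FoodEmbeddingModel:
    """Trained word vectors plus a hashed subword table for OOV tokens."""

    dimension: int
    vocab: dict[str, int]
    vectors: np.ndarray          # (V, dimension) in-vocabulary word vectors
    bucket_vectors: np.ndarray   # (n_buckets, dimension) subword table
    n_buckets: int
    minn: int = 3
    maxn: int = 5
    metadata: dict = field(default_factory=dict)

    def token_vector(self, token: str) -> np.ndarray:
        idx = self.vocab.get(token)
        if idx is not None:
            return self.vectors[idx]
        return self.subword_vector(token)

    def subword_vector(self, token: str) -> np.ndarray:
        """Mean of the hashed n-gram bucket vectors for ``token``."""
        grams = _ngrams(token, self.minn, self.maxn)
        if not grams:  # token shorter than minn: hash the marked token itself
            grams = [f"<{token}>"]
        idx = [_fnv1a(g) % self.n_buckets for g in grams]
        return self.bucket_vectors[idx].mean(axis=0)

    def save(self, path: str) -> None:
        words = sorted(self.vocab, key=self.vocab.get)
        np.savez(
            path,
            dimension=self.dimension,
            words=np.array(words, dtype=object),
            vectors=self.vectors,
            bucket_vectors=self.bucket_vectors,
            n_buckets=self.n_buckets,
            minn=self.minn,
            maxn=self.maxn,
        )

    @classmethod
    def load(cls, path: str) -> "FoodEmbeddingModel":
        with np.load(path, allow_pickle=True) as z:
            words = list(z["words"])
            return cls(
                dimension=int(z["dimension"]),
                vocab={w: i for i, w in enumerate(words)},
                vectors=z["vectors"],
                bucket_vectors=z["bucket_vectors"],
                n_buckets=int(z["n_buckets"]),
                minn=int(z["minn"]),
                maxn=int(z["maxn"]),
            )

    def export_word_vectors(self, path: str) -> None:
        """Plain-text export, one ``word v1 v2 …`` line per vocabulary word."""
        with open(path, "w", encoding="utf-8") as fh:
            for w in sorted(self.vocab, key=self.vocab.get):
                vals = " ".join(repr(float(v)) for v in self.vectors[self.vocab[w]])
                fh.write(f"{w} {vals}\n")


def train_embedding_model(
    corpus: list[str],
    dimension: int = 300,
    epochs: int = 5,
    seed: int = 0,
    window: int = 3,
    negatives: int = 5,
    learning_rate: float = 0.05,
    min_count: int = 1,
    n_buckets: int = 20000,
    batch_size: int = 1024,
    subsample: float = 1e-3,
) -> FoodEmbeddingModel:
    """Train skip-gram/negative-sampling vectors on the documents.

    Training is single-threaded and fully seeded, so a fixed
    ``(corpus, seed)`` reproduces the model bit for bit.  After word
    training, each hashed n-gram bucket vector is set to the mean of the
    vectors of the vocabulary words containing it, which lets
    :meth:`FoodEmbeddingModel.subword_vector` compose vectors for unseen
    words from shared subwords.
    """
    docs = [tokenize(d) for d in corpus]
    docs = [d for d in docs if d]
    if not docs:
        raise EmptyCorpusError("no non-empty documents after tokenization")
    if dimension <= 0:
        raise ValueError("dimension must be > 0")

    counts: dict[str, int] = {}
    for d in docs:
        for t in d:
            counts[t] = counts.get(t, 0) + 1
    vocab_words = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab_words:
        raise EmptyCorpusError("vocabulary empty at this min_count")
    vocab = {w: i for i, w in enumerate(vocab_words)}
    V = len(vocab)

    rng = np.random.default_rng(seed)

    # frequent-word subsampling: very common tokens (template filler,
    # connectives) otherwise bridge unrelated words through co-occurrence
    n_tokens = sum(counts[w] for w in vocab_words)
    keep_prob = {}
    for w in vocab_words:
        f = counts[w] / n_tokens
        keep_prob[w] = (
            min(1.0, (np.sqrt(f / subsample) + 1.0) * subsample / f)
            if subsample > 0
            else 1.0
        )

    # (center, context) pairs within the symmetric window
    centers, contexts = [], []
    for d in docs:
        ids = [
            vocab[t]
            for t in d
            if t in vocab and rng.random() < keep_prob[t]
        ]
        for i, c in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers and subsample > 0:
        # tiny corpora can lose every token to subsampling; retry without it
        for d in docs:
            ids = [vocab[t] for t in d if t in vocab]
            for i, c in enumerate(ids):
                for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                    if j != i:
                        centers.append(c)
                        contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise EmptyCorpusError("corpus yields no training pairs")

    W_in = (rng.random((V, dimension)) - 0.5) / dimension
    W_out = np.zeros((V, dimension))

    freq = np.array([counts[w] for w in vocab_words], dtype=float)
    noise = freq**0.75
    noise /= noise.sum()

    for epoch in range(epochs):
        lr = learning_rate * (1.0 - epoch / max(1, epochs))
        lr = max(lr, learning_rate * 0.1)
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c, o = centers[sel], contexts[sel]
            B = len(sel)
            v = W_in[c]                                   # (B, D)
            u_pos = W_out[o]
            g_pos = _sigmoid(np.sum(v * u_pos, axis=1)) - 1.0     # (B,)
            grad_in = g_pos[:, None] * u_pos
            np.add.at(W_out, o, -lr * g_pos[:, None] * v)

            neg = rng.choice(V, size=(B, negatives), p=noise)
            u_neg = W_out[neg]                            # (B, k, D)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))   # (B, k)
            grad_in += np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(
                W_out,
                neg.ravel(),
                (-lr * g_neg[..., None] * v[:, None, :]).reshape(-1, dimension),
            )
            np.add.at(W_in, c, -lr * grad_in)
        logger.debug("embedding epoch %d/%d done (lr=%.4f)", epoch + 1, epochs, lr)

    # subword bucket table: mean of containing-word vectors; untouched
    # buckets get small deterministic noise so any token maps to a
    # finite non-zero vector.
    bucket_rng = np.random.default_rng(seed + 1)
    buckets = bucket_rng.normal(0.0, 1e-3 / dimension, (n_buckets, dimension))
    acc = np.zeros((n_buckets, dimension))
    cnt = np.zeros(n_buckets)
    for w, i in vocab.items():
        for g in _ngrams(w, 3, 5):
            b = _fnv1a(g) % n_buckets
            acc[b] += W_in[i]
            cnt[b] += 1
    hit = cnt > 0
    buckets[hit] = acc[hit] / cnt[hit, None]

    model = FoodEmbeddingModel(
        dimension=dimension,
        vocab=vocab,
        vectors=W_in,
        bucket_vectors=buckets,
        n_buckets=n_buckets,
        metadata={
            "n_documents": len(docs),
            "n_pairs": int(n_pairs),
            "epochs": epochs,
            "seed": seed,
        },
    )
    logger.info(
        "trained embeddings: V=%d dim=%d pairs=%d epochs=%d", V, dimension,
        n_pairs, epochs,
    )
    return model


def embed_name(model: FoodEmbeddingModel, name: str) -> np.ndarray:
    """Mean of the token vectors of the name (order-invariant)."""
    tokens = tokenize(name)
    if not tokens:
        raise EmptyNameError(f"name {name!r} has no tokens after normalization")
    return np.mean([model.token_vector(t) for t in tokens], axis=0)


def embed_names(model: FoodEmbeddingModel, names: list[str]) -> np.ndarray:
    return np.vstack([embed_name(model, n) for n in names])


def build_context_sentence(name: str, ingredients: list[str]) -> str:
    """``"<name> made with <ing1>, <ing2>, …"``; bare name if no ingredients."""
    if not name:
        raise EmptyNameError("name is empty")
    if not ingredients:
        return name
    return f"{name} made with {', '.join(ingredients)}"


class SentenceEncoder(Protocol):
    def encode(self, sentence: str) -> np.ndarray: ...


class WordAverageEncoder:
    """Default backend: mean of word vectors from a trained model."""

    def __init__(self, model: FoodEmbeddingModel):
        self.model = model

    def encode(self, sentence: str) -> np.ndarray:
        return embed_name(self.model, sentence)


_BACKENDS: dict[str, Callable[..., SentenceEncoder]] = {
    "word-average": WordAverageEncoder,
}


def register_backend(name: str, factory: Callable[..., SentenceEncoder]) -> None:
    _BACKENDS[name] = factory


def get_encoder(name: str, *args, **kwargs) -> SentenceEncoder:
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise UnknownBackendError(
            f"unknown encoder backend {name!r}; known: {sorted(_BACKENDS)}"
        ) from None
    return factory(*args, **kwargs)


def embed_context(encoder: SentenceEncoder, sentence: str) -> np.ndarray:
    if not sentence or not tokenize(sentence):
        raise EmptyNameError("context sentence is empty")
    vec = np.asarray(encoder.encode(sentence), dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("encoder produced non-finite components")
    return vec
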