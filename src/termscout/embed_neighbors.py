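"""Word-embedding training and cosine nearest-neighbor term ranking.

A compact word2vec (CBOW and skip-gram with negative sampling) trained
single-threaded for exact reproducibility given (docs, params, seed).
Defaults mirror the common word2vec defaults: CBOW, dim 50, window 5,
5 epochs, min_count 5, 5 negative samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .text_normalize import TokenDoc


class EmbeddingError(Exception):
    pass


@dataclass(frozen=True)
class EmbeddingParams:
    dim: int = 50
    window: int = 5
    epochs: int = 5
    min_count: int = 5
    algorithm: str = "cbow"  # or "skipgram"
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 0.0001

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise EmbeddingError("dim must be >= 2")
        if self.min_count < 1:
            raise EmbeddingError("min_count must be >= 1")
        if self.algorithm not in ("cbow", "skipgram"):
            raise EmbeddingError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class EmbeddingModel:
    """Vocabulary plus one dense vector per token."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim)
    params: EmbeddingParams
    seed: int

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocab):
            raise EmbeddingError("vocab/vector row count mismatch")

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocab[token]]
        except KeyError:
            raise EmbeddingError(f"token {token!r} not in vocabulary") from None

    def tokens(self) -> list[str]:
        out = [""] * len(self.vocab)
        for tok, i in self.vocab.items():
            out[i] = tok
        return out

    # word2vec-text-compatible persistence ---------------------------------

    def save(self, path: str | Path) -> None:
        toks = self.tokens()
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(toks)} {self.dim}\n")
            for tok, row in zip(toks, self.vectors):
                fh.write(tok + " " + " ".join(f"{x:.8f}" for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path, params: EmbeddingParams | None = None) -> "EmbeddingModel":
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab: dict[str, int] = {}
            vectors = np.empty((n, dim), dtype=np.float64)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(vocab, vectors, params or EmbeddingParams(dim=dim), seed=-1)


@dataclass(frozen=True)
class NeighborResult:
    term: str
    similarity: float
    rank: int


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; raises on zero vectors or dim mismatch."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise EmbeddingError("vectors must share dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise EmbeddingError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _build_vocab(docs: Sequence[TokenDoc], min_count: int) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for d in docs:
        for tok in d.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    vocab = {t: i for i, t in enumerate(kept)}
    freqs = np.array([counts[t] for t in kept], dtype=np.float64)
    return vocab, freqs


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(
    docs: Sequence[TokenDoc],
    params: EmbeddingParams | None = None,
    seed: int = 0,
    focal_term: str | None = None,
) -> EmbeddingModel:
    """Train word vectors on token docs.

    Deterministic for fixed (docs, params, seed): single worker, one RNG.
    If ``focal_term`` is given and rarer than ``min_count``, a warning is
    emitted (the model trains regardless).
    """
    params = params or EmbeddingParams()
    if not docs:
        raise EmbeddingError("no documents to train on")
    if not any(len(d.tokens) >= 2 for d in docs):
        raise EmbeddingError("need at least one document with >= 2 tokens")

    vocab, freqs = _build_vocab(docs, params.min_count)
    if not vocab:
        raise EmbeddingError(
            f"empty vocabulary: no token occurs >= min_count ({params.min_count}) times"
        )
    if focal_term is not None and focal_term not in vocab:
        warnings.warn(
            f"focal term {focal_term!r} occurs fewer than min_count "
            f"({params.min_count}) times and is absent from the vocabulary",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    dim = params.dim
    syn0 = (rng.random((len(vocab), dim)) - 0.5) / dim  # input vectors
    syn1 = np.zeros((len(vocab), dim))  # output vectors

    # unigram^0.75 negative-sampling distribution
    noise = freqs ** 0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    # docs as index arrays, out-of-vocab tokens removed
    encoded = [
        np.array([vocab[t] for t in d.tokens if t in vocab], dtype=np.int64) for d in docs
    ]
    encoded = [e for e in encoded if len(e) >= 2]
    if not encoded:
        raise EmbeddingError("no document retains >= 2 in-vocabulary tokens")

    total_words = sum(len(e) for e in encoded) * params.epochs
    processed = 0
    neg = params.negative
    alpha0, min_alpha = params.alpha, params.min_alpha

    for _epoch in range(params.epochs):
        for sent in encoded:
            n = len(sent)
            # dynamic window sizes, as in the reference implementation
            reduced = rng.integers(0, params.window, size=n)
            for pos in range(n):
                alpha = max(min_alpha, alpha0 * (1.0 - processed / max(total_words, 1)))
                processed += 1
                w = params.window - int(reduced[pos])
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if len(ctx) == 0:
                    continue
                center = sent[pos]
                # negative sample targets (center is positive label)
                draws = rng.random(neg)
                negs = np.searchsorted(noise_cdf, draws)
                targets = np.concatenate([[center], negs])
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                if params.algorithm == "cbow":
                    h = syn0[ctx].mean(axis=0)
                    out = syn1[targets]  # (T, dim)
                    g = (labels - _sigmoid(out @ h)) * alpha  # (T,)
                    grad_h = g @ out
                    syn1[targets] += np.outer(g, h)
                    syn0[ctx] += grad_h / len(ctx)
                else:  # skip-gram: center predicts each context word
                    for c in ctx:
                        h = syn0[c]
                        out = syn1[targets]
                        g = (labels - _sigmoid(out @ h)) * alpha
                        grad_h = g @ out
                        syn1[targets] += np.outer(g, h)
                        syn0[c] += grad_h

    return EmbeddingModel(vocab=vocab, vectors=syn0, params=params, seed=seed)


def nearest_neighbors(model: EmbeddingModel, focal: str, k: int) -> list[NeighborResult]:
    """Top-k vocabulary terms by cosine similarity to ``focal``.

    The focal term itself is excluded; ties break lexicographically by term;
    ranks run 1..k.  Raises if the focal term is out of vocabulary.
    """
    if k < 1:
        raise EmbeddingError("k must be >= 1")
    if focal not in model.vocab:
        raise EmbeddingError(f"focal term {focal!r} not in vocabulary")
    fv = model.vector(focal)
    fnorm = np.linalg.norm(fv)
    if fnorm == 0.0:
        raise EmbeddingError(f"focal term {focal!r} has a zero vector")
    norms = np.linalg.norm(model.vectors, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    sims = (model.vectors @ fv) / (safe * fnorm)
    sims = np.clip(sims, -1.0, 1.0)
    toks = model.tokens()
    focal_idx = model.vocab[focal]
    scored = [
        (float(sims[i]), toks[i])
        for i in range(len(toks))
        if i != focal_idx and norms[i] > 0.0
    ]
    scored.sort(key=lambda st: (-st[0], st[1]))
    return [
        NeighborResult(term=t, similarity=s, rank=r)
        for r, (s, t) in enumerate(scored[:k], start=1)
    ]
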