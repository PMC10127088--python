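"""Distributed k-mer representations via skip-gram with negative sampling.

Each window is tiled into overlapping k-mers (step 1), the resulting
token lists form a corpus, and a skip-gram word-embedding model is
trained to predict context k-mers from a center k-mer.  A window is then
represented by the unweighted mean of its k-mer vectors (default
dimension 100).

The trainer is a compact, seeded implementation of skip-gram with
negative sampling: minibatched SGD over the precomputed (center,
context) pair list, fixed symmetric context window, unigram^0.75
negative-sampling distribution, linearly decaying learning rate.  With a
fixed seed it is bit-reproducible (single-threaded numpy throughout).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .encoders import FeatureVector
from .windows import RnaWindow, WindowSet

logger = logging.getLogger(__name__)


@dataclass
class KmerCorpus:
    """One ordered k-mer sentence per window."""

    sentences: list[list[str]]
    k: int
    vocab: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.vocab:
            self.vocab = {tok for s in self.sentences for tok in s}

    def __len__(self) -> int:
        return len(self.sentences)


def build_corpus(ws: WindowSet, k: int) -> KmerCorpus:
    """Tile every window into overlapping k-mers, 5'→3', step 1."""
    if len(ws) and not 2 <= k <= ws.L:
        raise ValueError(f"k={k} outside [2, {ws.L}]")
    sentences = [
        [w.seq[i : i + k] for i in range(len(w.seq) - k + 1)] for w in ws
    ]
    return KmerCorpus(sentences, k)


@dataclass
class EmbeddingModel:
    """Trained k-mer embedding: a vector per vocabulary k-mer."""

    k: int
    dim: int
    window: int
    vectors: dict[str, np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            if len(v) != self.dim:
                raise ValueError(f"vector for {tok!r} has length {len(v)} != {self.dim}")

    def save(self, path: str | Path) -> None:
        """Write vectors as TSV plus a JSON sidecar with hyperparameters."""
        path = Path(path)
        with open(path, "w") as fh:
            for tok in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[tok])
                fh.write(f"{tok}\t{vals}\n")
        sidecar = {"k": self.k, "dim": self.dim, "window": self.window, "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        vectors = {}
        with open(path) as fh:
            for line in fh:
                tok, *vals = line.rstrip("\n").split("\t")
                vectors[tok] = np.array([float(v) for v in vals])
        return cls(vectors=vectors, **meta)


def _scatter_add(W: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """W[idx] += grads with duplicate indices accumulated (fast np.add.at)."""
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(sorted_idx))]
    W[sorted_idx[starts]] += np.add.reduceat(grads[order], starts, axis=0)


def train_skipgram(
    corpus: KmerCorpus,
    dim: int = 100,
    window: int = 4,
    epochs: int = 50,
    negative: int = 5,
    lr: float = 0.05,
    seed: int = 0,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling embeddings on a k-mer corpus.

    Parameters
    ----------
    dim : int
        Embedding dimension (default 100).
    window : int
        Symmetric context size w: tokens up to w positions away count as
        context.
    negative : int
        Negative samples per (center, context) pair, drawn from the
        unigram distribution raised to 3/4.
    """
    if not corpus.sentences or not any(corpus.sentences):
        raise ValueError("cannot train an embedding on an empty corpus")
    if window < 1 or dim < 1 or epochs < 1:
        raise ValueError("window, dim and epochs must all be >= 1")

    vocab = sorted(corpus.vocab)  # deterministic token order
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    counts = np.zeros(V)
    centers, contexts = [], []
    for sent in corpus.sentences:
        ids = [tok2id[t] for t in sent]
        for i, c in enumerate(ids):
            counts[c] += 1
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    n_pairs = len(centers)

    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    batch = 1024
    n_batches_total = epochs * max(1, -(-n_pairs // batch))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for b0 in range(0, n_pairs, batch):
            idx = order[b0 : b0 + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(V, size=(len(idx), negative), p=noise)
            eta = lr * max(1.0 - step / n_batches_total, 1e-2)
            step += 1

            v = W_in[c]  # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+neg)
            u = W_out[targets]  # (B, 1+neg, d)
            score = np.einsum("bd,bnd->bn", v, u)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            g = (label - sig) * eta  # (B, 1+neg)

            grad_v = np.einsum("bn,bnd->bd", g, u)
            grad_u = g[..., None] * v[:, None, :]
            _scatter_add(W_in, c, grad_v)
            _scatter_add(W_out, targets.ravel(), grad_u.reshape(-1, dim))

    vectors = {tok: W_in[i].copy() for tok, i in tok2id.items()}
    return EmbeddingModel(k=corpus.k, dim=dim, window=window, vectors=vectors, seed=seed)


def embed_sequence(win: RnaWindow | str, model: EmbeddingModel) -> FeatureVector:
    """Mean of the window's k-mer vectors; unseen k-mers are skipped.

    If every k-mer is out of vocabulary the zero vector is returned and a
    warning logged.
    """
    seq = win.seq if isinstance(win, RnaWindow) else win
    toks = [seq[i : i + model.k] for i in range(len(seq) - model.k + 1)]
    known = [model.vectors[t] for t in toks if t in model.vectors]
    if known:
        vec = np.mean(known, axis=0)
    else:
        logger.warning("all %d k-mers out of vocabulary; returning zeros", len(toks))
        vec = np.zeros(model.dim)
    names = [f"embed_{i:03d}" for i in range(model.dim)]
    return FeatureVector(names, vec, "embedding")


def embed_matrix(ws: WindowSet, model: EmbeddingModel):
    import pandas as pd

    rows = [embed_sequence(w, model) for w in ws]
    return pd.DataFrame(
        np.vstack([r.values for r in rows]) if rows else np.empty((0, model.dim)),
        index=[w.id for w in ws],
        columns=[f"embed_{i:03d}" for i in range(model.dim)],
    )


def tune_embedding(
    train: WindowSet,
    k_range: Iterable[int],
    w_range: Iterable[int],
    evaluator: Callable[[int, int, EmbeddingModel], float],
    seed: int = 0,
    dim: int = 100,
    epochs: int = 30,
) -> tuple[int, int, EmbeddingModel]:
    """Grid-search embedding hyperparameters (k, w) by CV accuracy.

    ``evaluator(k, w, model)`` must return the cross-validated accuracy
    of the feature matrix built with that candidate model.  Ties prefer
    smaller k, then smaller w.  The winning model (trained on the full
    training set) is returned.
    """
    k_range, w_range = sorted(set(k_range)), sorted(set(w_range))
    if not k_range or not w_range:
        raise ValueError("empty hyperparameter range")
    best: Optional[tuple[float, int, int, EmbeddingModel]] = None
    for k in k_range:
        corpus = build_corpus(train, k)
        for w in w_range:
            model = train_skipgram(corpus, dim=dim, window=w, epochs=epochs, seed=seed)
            acc = evaluator(k, w, model)
            logger.info("embedding grid k=%d w=%d acc=%.4f", k, w, acc)
            if best is None or acc > best[0]:
                best = (acc, k, w, model)
    assert best is not None
    return best[1], best[2], best[3]
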