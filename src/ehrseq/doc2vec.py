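"""Paragraph-vector (doc2vec) patient embeddings.

Implements the two classical training modes with negative sampling and plain
SGD over a unigram^0.75 noise distribution:

* DBOW (distributed bag of words): the document vector alone predicts each
  token of the document — order-free.
* DM (distributed memory): the document vector averaged with the word vectors
  of a +/- ``window`` context predicts the centre token — weakly order-aware
  through the context window.

Model selection uses the identical-sequence criterion: patients who share a
byte-identical token sequence should receive near-identical embeddings, so
the score is the mean cosine similarity over identical-sequence pairs minus
the mean cosine over an equal number of random non-identical pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ehrseq.containers import EmbeddingSet

__all__ = ["Doc2VecConfig", "fit_doc2vec", "identical_sequence_score",
           "select_doc2vec"]

Corpus = dict[str, list[str]]


@dataclass(frozen=True)
class Doc2VecConfig:
    algorithm: str = "dbow"  # "dbow" | "dm"
    dim: int = 100
    window: int = 5  # DM context half-width; DBOW ignores it (order-free)
    learning_rate: float = 0.05
    epochs: int = 20
    negative: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("dbow", "dm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.negative < 1:
            raise ValueError("need at least one negative sample")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def fit_doc2vec(corpus: Corpus, config: Doc2VecConfig) -> EmbeddingSet:
    """Train paragraph vectors; one ``dim``-length vector per patient.

    Deterministic for a given seed (single-threaded SGD with a seeded
    generator; the learning rate decays linearly to 1e-4 of its start over
    the training run).
    """
    ids = list(corpus)
    if any(len(corpus[p]) < 2 for p in ids):
        raise ValueError("every document needs at least 2 tokens")
    vocab = sorted({t for doc in corpus.values() for t in doc})
    vidx = {t: j for j, t in enumerate(vocab)}
    docs = [np.array([vidx[t] for t in corpus[p]]) for p in ids]
    V, D, dim = len(vocab), len(docs), config.dim

    rng = np.random.default_rng(config.seed)
    docvec = (rng.random((D, dim)) - 0.5) / dim
    wordvec = (rng.random((V, dim)) - 0.5) / dim  # DM input vectors
    out = np.zeros((V, dim))  # output (context) matrix

    counts = np.zeros(V)
    for d in docs:
        np.add.at(counts, d, 1.0)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    total_steps = config.epochs * D
    step = 0
    order = np.arange(D)
    for _ in range(config.epochs):
        rng.shuffle(order)
        for di in order:
            lr = config.learning_rate * max(1e-4, 1.0 - step / total_steps)
            step += 1
            doc = docs[di]
            T = len(doc)
            k = config.negative
            # targets: (T, 1+k) with column 0 the positive token
            negs = np.searchsorted(noise_cdf, rng.random((T, k)))
            targets = np.concatenate([doc[:, None], negs], axis=1)
            labels = np.zeros((T, 1 + k))
            labels[:, 0] = 1.0
            if config.algorithm == "dbow":
                h = np.broadcast_to(docvec[di], (T, dim))
            else:
                # mean of doc vector and context word vectors around t
                ctx_sum = np.zeros((T, dim))
                ctx_n = np.zeros(T)
                for off in range(1, config.window + 1):
                    for sgn in (-1, 1):
                        j = np.arange(T) + sgn * off
                        ok = (j >= 0) & (j < T)
                        ctx_sum[ok] += wordvec[doc[j[ok]]]
                        ctx_n[ok] += 1
                h = (docvec[di][None, :] + ctx_sum) / (1.0 + ctx_n)[:, None]
            w = out[targets]  # (T, 1+k, dim)
            logits = np.einsum("td,tkd->tk", h, w)
            g = (labels - _sigmoid(logits)) * lr  # (T, 1+k)
            dh = np.einsum("tk,tkd->td", g, w)
            dw = g[:, :, None] * h[:, None, :]
            np.add.at(out, targets, dw)
            if config.algorithm == "dbow":
                docvec[di] += dh.sum(axis=0)
            else:
                share = dh / (1.0 + ctx_n)[:, None]
                docvec[di] += share.sum(axis=0)
                for off in range(1, config.window + 1):
                    for sgn in (-1, 1):
                        j = np.arange(T) + sgn * off
                        ok = (j >= 0) & (j < T)
                        np.add.at(wordvec, doc[j[ok]], share[ok])
    return EmbeddingSet(ids=ids, X=docvec,
                        method=f"doc2vec-{config.algorithm}",
                        feature_names=None)


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = np.maximum(na * nb, 1e-12)
    return np.einsum("ij,ij->i", a, b) / denom


def identical_sequence_score(embeddings: EmbeddingSet,
                             sequences: Corpus, *, seed: int = 0,
                             max_pairs: int = 10_000) -> float:
    """Paired-minus-random cosine gap over identical-sequence patients.

    Groups patients whose token sequences are byte-identical; the score is
    ``mean cos(identical pairs) - mean cos(random non-identical pairs)`` with
    the random sample matched in size.  1 means identical-sequence patients
    are perfectly aligned while unrelated patients are orthogonal on average;
    0 means the embedding does not distinguish them.
    """
    groups: dict[tuple, list[str]] = {}
    for pid, toks in sequences.items():
        groups.setdefault(tuple(toks), []).append(pid)
    pairs = list(itertools.chain.from_iterable(
        itertools.combinations(m, 2) for m in groups.values() if len(m) >= 2))
    if not pairs:
        raise ValueError(
            "no patients share an identical sequence; simulate duplicate "
            "sequences (or lower the vocabulary size) before scoring")
    rng = np.random.default_rng(seed)
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    ids = embeddings.ids
    a = embeddings.align([p for p, _ in pairs])
    b = embeddings.align([q for _, q in pairs])
    same = float(np.mean(_cosine(a, b)))

    n_rand, rand_pairs = len(pairs), []
    guard = 0
    while len(rand_pairs) < n_rand and guard < 50 * n_rand:
        i, j = rng.integers(len(ids), size=2)
        guard += 1
        if i == j:
            continue
        if tuple(sequences[ids[i]]) == tuple(sequences[ids[j]]):
            continue
        rand_pairs.append((ids[i], ids[j]))
    if not rand_pairs:
        raise ValueError("could not sample non-identical pairs")
    ra = embeddings.align([p for p, _ in rand_pairs])
    rb = embeddings.align([q for _, q in rand_pairs])
    rand = float(np.mean(_cosine(ra, rb)))
    return same - rand


def select_doc2vec(corpus: Corpus, grid: list[Doc2VecConfig], *,
                   seed: int = 0
                   ) -> tuple[Doc2VecConfig, EmbeddingSet, list[dict]]:
    """Grid search maximizing the identical-sequence score.

    Ties favour fewer epochs.  Returns the winning config, its embeddings,
    and the per-config report.
    """
    if not grid:
        raise ValueError("empty selection grid")
    report = []
    best = None
    for cfg in grid:
        emb = fit_doc2vec(corpus, cfg)
        score = identical_sequence_score(emb, corpus, seed=seed)
        report.append({"config": cfg, "score": score})
        cand = (score, -cfg.epochs, cfg, emb)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    return best[2], best[3], report
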