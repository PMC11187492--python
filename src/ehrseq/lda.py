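"""LDA patient representations with perplexity-driven topic-count selection.

Each patient's token sequence is treated as a bag-of-words document; the
fitted per-patient topic proportions are the representation.  The number of
topics is chosen by an 80:20 train/test split, taking the candidate with the
lowest held-out perplexity (ties favour the smaller model), then refitting on
the full corpus with the chosen count.

Perplexity here is ``exp(-L/N)`` where ``L`` is the total held-out log
likelihood under the per-document topic mixture (``p(w|d) = theta_d . phi[:,
w]`` with ``theta_d`` inferred on the held-out document) and ``N`` the token
count.  A model that assigns uniform probability ``1/V`` to every token
therefore has perplexity exactly ``V``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

__all__ = ["TopicModelResult", "fit_lda", "perplexity", "mixture_perplexity",
           "completion_perplexity", "select_n_topics", "corpus_counts"]

Corpus = dict[str, list[str]]


def corpus_counts(corpus: Corpus, vocabulary: list[str] | None = None
                  ) -> tuple[np.ndarray, list[str], list[str]]:
    """Document-term count matrix; returns ``(counts, ids, vocabulary)``."""
    ids = list(corpus)
    if vocabulary is None:
        vocabulary = sorted({t for doc in corpus.values() for t in doc})
    vidx = {t: j for j, t in enumerate(vocabulary)}
    X = np.zeros((len(ids), len(vocabulary)))
    for i, pid in enumerate(ids):
        for t in corpus[pid]:
            j = vidx.get(t)
            if j is None:
                raise ValueError(f"token {t!r} not in vocabulary")
            X[i, j] += 1
    return X, ids, vocabulary


@dataclass
class TopicModelResult:
    """A fitted topic model: row-stochastic topic-word and doc-topic matrices."""

    n_topics: int
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray  # (n_docs, K), rows sum to 1
    ids: list[str]
    vocabulary: list[str]
    seed: int = 0
    heldout_perplexity: float | None = None
    estimator: LatentDirichletAllocation | None = field(default=None,
                                                        repr=False)

    def infer(self, corpus: Corpus) -> np.ndarray:
        """Per-document topic proportions for new documents."""
        if self.n_topics == 1:
            return np.ones((len(corpus), 1))
        if self.estimator is None:
            raise ValueError("no fitted estimator attached; cannot infer")
        X, _, _ = corpus_counts(corpus, self.vocabulary)
        theta = self.estimator.transform(X)
        return theta / theta.sum(axis=1, keepdims=True)

    def embeddings(self):
        from ehrseq.containers import EmbeddingSet
        return EmbeddingSet(ids=self.ids, X=self.doc_topic, method="lda",
                            feature_names=[f"topic{k}"
                                           for k in range(self.n_topics)])


def fit_lda(corpus: Corpus, n_topics: int, *, alpha: float | None = None,
            beta: float = 0.01, seed: int = 0, max_iter: int = 25,
            vocabulary: list[str] | None = None) -> TopicModelResult:
    """Fit LDA with ``n_topics`` topics on a corpus of token lists.

    Priors default to symmetric ``alpha = 1/K`` (document-topic) and ``beta =
    0.01`` (topic-word).  Deterministic for a given seed.
    """
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    X, ids, vocab = corpus_counts(corpus, vocabulary)
    if len(vocab) < n_topics:
        warnings.warn(
            f"vocabulary size {len(vocab)} is smaller than n_topics "
            f"{n_topics}; extra topics will be redundant", stacklevel=2)
    if n_topics == 1:
        # degenerate single-topic model: phi is the corpus unigram MLE
        tot = X.sum(axis=0) + beta
        phi = (tot / tot.sum())[None, :]
        return TopicModelResult(1, phi, np.ones((len(ids), 1)), ids, vocab,
                                seed)
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=alpha if alpha is not None else 1.0 / n_topics,
        topic_word_prior=beta,
        max_iter=max_iter,
        random_state=seed,
        learning_method="batch",
    )
    theta = lda.fit_transform(X)
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModelResult(n_topics, phi, theta, ids, vocab, seed,
                            estimator=lda)


def mixture_perplexity(theta: np.ndarray, phi: np.ndarray,
                       docs: list[list[int]]) -> float:
    """``exp(-loglik/N)`` of token-id documents under per-doc mixtures."""
    total, n_tokens = 0.0, 0
    for d, doc in enumerate(docs):
        if not doc:
            continue
        p = theta[d] @ phi[:, doc]
        total += float(np.log(p).sum())
        n_tokens += len(doc)
    if n_tokens == 0:
        raise ValueError("empty corpus: no tokens to score")
    return float(np.exp(-total / n_tokens))


def perplexity(result: TopicModelResult, corpus: Corpus) -> float:
    """Held-out perplexity of ``corpus`` under a fitted topic model.

    Topic proportions are inferred per held-out document and every token is
    scored under the resulting mixture (``p(w|d) = theta_d . phi[:, w]``).
    """
    if not corpus or all(len(d) == 0 for d in corpus.values()):
        raise ValueError("empty corpus: no tokens to score")
    theta = result.infer(corpus)
    vidx = {t: j for j, t in enumerate(result.vocabulary)}
    docs = [[vidx[t] for t in corpus[pid]] for pid in corpus]
    return mixture_perplexity(theta, result.topic_word, docs)


def completion_perplexity(result: TopicModelResult, corpus: Corpus) -> float:
    """Document-completion perplexity: infer on even-position tokens, score
    odd-position tokens.

    Scoring the same tokens used to infer the document's topic proportions is
    monotonically optimistic in the number of topics (a larger K can always
    adapt ``theta`` to the scored document), so plain held-out perplexity
    keeps improving past the generating K.  Splitting each held-out document
    removes that adaptivity and makes perplexity a usable model-selection
    criterion; this is what :func:`select_n_topics` minimizes.
    """
    if not corpus or all(len(d) == 0 for d in corpus.values()):
        raise ValueError("empty corpus: no tokens to score")
    infer_part = {p: corpus[p][0::2] for p in corpus}
    theta = result.infer(infer_part)
    vidx = {t: j for j, t in enumerate(result.vocabulary)}
    docs = [[vidx[t] for t in corpus[pid][1::2]] for pid in corpus]
    return mixture_perplexity(theta, result.topic_word, docs)


def select_n_topics(corpus: Corpus, candidate_ks: list[int], *,
                    test_frac: float = 0.2, seed: int = 0,
                    alpha: float | None = None, beta: float = 0.01,
                    max_iter: int = 25
                    ) -> tuple[TopicModelResult, dict[int, float]]:
    """Choose the topic count by held-out perplexity, then refit on all data.

    Documents are split 80:20 (by ``test_frac``) with a seeded shuffle; each
    candidate K is fitted on the training split and scored on the test split.
    The argmin K (ties -> smaller K) is refitted on the full corpus.  Returns
    the refitted model and the per-K test perplexities.
    """
    if not candidate_ks:
        raise ValueError("need at least one candidate topic count")
    ids = list(corpus)
    if len(candidate_ks) == 1:
        k = candidate_ks[0]
        model = fit_lda(corpus, k, alpha=alpha, beta=beta, seed=seed,
                        max_iter=max_iter)
        return model, {k: float("nan")}
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_frac * len(ids))))
    test_ids = {ids[i] for i in perm[:n_test]}
    train = {p: corpus[p] for p in ids if p not in test_ids}
    test = {p: corpus[p] for p in ids if p in test_ids}
    vocab = sorted({t for doc in corpus.values() for t in doc})
    scores: dict[int, float] = {}
    for k in sorted(candidate_ks):
        m = fit_lda(train, k, alpha=alpha, beta=beta, seed=seed,
                    max_iter=max_iter, vocabulary=vocab)
        scores[k] = completion_perplexity(m, test)
    best = min(sorted(scores), key=lambda k: scores[k])
    model = fit_lda(corpus, best, alpha=alpha, beta=beta, seed=seed,
                    max_iter=max_iter, vocabulary=vocab)
    model.heldout_perplexity = scores[best]
    return model, scores
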