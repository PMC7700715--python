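"""Synthetic screening corpora and text featurisation.

The generator emulates the one property of a screening corpus that the
criteria and the classifier interact with: relevant and irrelevant
documents draw their tokens from two mixture distributions whose divergence
is tunable.  A ``separability`` of 0 makes the classes indistinguishable
(classifier at chance); larger values concentrate a block of topic words in
the relevant class.  Everything else — identifiers, titles, token order —
is plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

__all__ = ["SyntheticCorpusConfig", "ScreeningDataset", "generate_corpus", "featurize"]


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Parameters of the synthetic corpus generator.

    ``prevalence`` is the exact fraction of relevant documents (the realised
    relevant count is ``round(prevalence * N_total)``).  ``separability``
    scales the log-odds tilt of topic words in the relevant class; 0 means
    the two classes share one token distribution.  ``doc_length`` is the
    mean abstract length in tokens (Poisson, floored at 3).
    """

    N_total: int = 2000
    prevalence: float = 0.10
    separability: float = 1.0
    vocabulary_size: int = 500
    doc_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_total < 2:
            raise ValueError("N_total must be at least 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if round(self.prevalence * self.N_total) < 1:
            raise ValueError("prevalence * N_total must round to at least 1")
        if self.separability < 0:
            raise ValueError("separability must be non-negative")
        if self.vocabulary_size < 10:
            raise ValueError("vocabulary_size must be at least 10")
        if self.doc_length < 3:
            raise ValueError("doc_length must be at least 3")


@dataclass
class ScreeningDataset:
    """A labelled corpus: ids, titles, abstracts and true relevance labels."""

    ids: list[str]
    titles: list[str]
    abstracts: list[str]
    labels: np.ndarray  # int array of 0/1, ground truth

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.titles) == len(self.abstracts) == self.labels.size == n):
            raise ValueError("all fields must have equal length")
        if len(set(self.ids)) != n:
            raise ValueError("document identifiers must be unique")
        if np.any((self.labels != 0) & (self.labels != 1)):
            raise ValueError("labels must be 0/1")

    @property
    def N_total(self) -> int:
        return len(self.ids)

    @property
    def rho_total(self) -> int:
        return int(self.labels.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "title": self.titles,
                "abstract": self.abstracts,
                "label": self.labels,
            }
        )


def _class_distributions(config: SyntheticCorpusConfig) -> tuple[np.ndarray, np.ndarray]:
    """Token distributions for the irrelevant and relevant classes.

    Both start from a Zipf-like base over the shared vocabulary; the
    relevant class multiplies the first tenth of the vocabulary (the topic
    block) by ``exp(separability)`` and renormalises.
    """
    v = config.vocabulary_size
    base = 1.0 / np.arange(1, v + 1)
    base /= base.sum()
    topic = max(1, v // 10)
    tilt = np.ones(v)
    tilt[:topic] = np.exp(config.separability)
    rel = base * tilt
    rel /= rel.sum()
    return base, rel


def generate_corpus(config: SyntheticCorpusConfig) -> ScreeningDataset:
    """Draw a reproducible labelled corpus from the two-class token model."""
    rng = np.random.default_rng(config.seed)
    n_rel = int(round(config.prevalence * config.N_total))
    labels = np.zeros(config.N_total, dtype=np.int64)
    labels[rng.choice(config.N_total, size=n_rel, replace=False)] = 1

    irr_dist, rel_dist = _class_distributions(config)
    vocab = np.array([f"w{i:04d}" for i in range(config.vocabulary_size)])
    lengths = np.maximum(rng.poisson(config.doc_length, size=config.N_total), 3)

    abstracts = []
    for lab, length in zip(labels, lengths):
        dist = rel_dist if lab else irr_dist
        tokens = vocab[rng.choice(config.vocabulary_size, size=length, p=dist)]
        abstracts.append(" ".join(tokens))

    ids = [f"doc{i:05d}" for i in range(config.N_total)]
    titles = [f"Synthetic record {i}" for i in range(config.N_total)]
    return ScreeningDataset(ids=ids, titles=titles, abstracts=abstracts, labels=labels)


def featurize(
    dataset: ScreeningDataset,
    ngram_range: tuple[int, int] = (1, 2),
    weighting: str = "tf",
) -> sparse.csr_matrix:
    """Uni/bigram term counts (or TF-IDF) over the abstracts.

    The vocabulary ordering is deterministic (sorted terms), so two calls on
    the same corpus produce identical matrices.  Documents with empty
    abstracts map to all-zero rows.
    """
    if weighting == "tf":
        vec = CountVectorizer(ngram_range=ngram_range, token_pattern=r"\S+")
    elif weighting == "tfidf":
        vec = TfidfVectorizer(ngram_range=ngram_range, token_pattern=r"\S+")
    else:
        raise ValueError("weighting must be 'tf' or 'tfidf'")
    texts = dataset.abstracts
    if all(not t.strip() for t in texts):
        raise ValueError("corpus has no tokens to featurise")
    X = vec.fit_transform(texts)
    return sparse.csr_matrix(X)
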