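"""Text feature extraction: TF-IDF and paragraph-vector document embeddings.

Features are computed once over the full corpus before a simulation starts
(transductively) and stay fixed while the active-learning loop relabels the
pool, so rankings are comparable across steps and the dimensionality never
changes mid-run.

The paragraph-vector extractor trains distributed bag-of-words (PV-DBOW)
document embeddings with negative sampling directly in numpy: each document
owns a dense vector that is trained to predict the words it contains against
noise words.  Training is single-threaded and fully seeded, so identical
inputs give bit-identical matrices.  Unlike TF-IDF, the resulting matrix
contains negative entries, which matters downstream: multinomial naive Bayes
cannot consume it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import LabeledCorpus

__all__ = [
    "FeatureMatrix",
    "FeatureError",
    "tokenize",
    "extract_tfidf",
    "extract_paragraph_vectors",
    "save_feature_matrix",
    "load_feature_matrix",
]


class FeatureError(Exception):
    """Feature extraction could not produce a usable matrix."""


_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str, min_len: int = 2, lowercase: bool = True) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than min_len."""
    if lowercase:
        text = text.lower()
    return [t for t in _TOKEN.findall(text) if len(t) >= min_len]


@dataclass(frozen=True)
class FeatureMatrix:
    """N x d numeric representation of a corpus, aligned to record order.

    ``nonnegative`` governs classifier compatibility: multinomial naive Bayes
    requires it.  ``values`` is CSR for TF-IDF and a dense ndarray for
    paragraph vectors.
    """

    values: sp.csr_matrix | np.ndarray
    kind: Literal["tfidf", "d2v"]
    nonnegative: bool

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def rows(self, indices: Sequence[int]):
        """Sub-matrix of the given rows, in the given order (repeats allowed)."""
        return self.values[np.asarray(indices, dtype=int)]


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


def extract_tfidf(
    corpus: LabeledCorpus,
    max_features: int | None = None,
    ngram_max: int = 1,
    lowercase: bool = True,
    stop_words: str | list[str] | None = None,
) -> FeatureMatrix:
    """Term frequency x smoothed inverse document frequency, L2-normalized rows.

    idf(t) = ln((1+N)/(1+df(t))) + 1.  The vocabulary is ordered
    lexicographically, so the matrix is deterministic.  Title and abstract are
    concatenated per record.
    """
    if corpus.n == 0:
        raise FeatureError("cannot extract features from an empty corpus")
    texts = corpus.texts()
    vectorizer = TfidfVectorizer(
        tokenizer=lambda doc: tokenize(doc, lowercase=lowercase),
        token_pattern=None,
        lowercase=False,  # handled by the tokenizer
        ngram_range=(1, ngram_max),
        max_features=max_features,
        stop_words=stop_words,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    try:
        values = vectorizer.fit_transform(texts)
    except ValueError as exc:  # empty vocabulary
        raise FeatureError(f"TF-IDF extraction failed: {exc}") from exc
    return FeatureMatrix(values=values.tocsr(), kind="tfidf", nonnegative=True)


# ---------------------------------------------------------------------------
# Paragraph vectors (PV-DBOW with negative sampling)
# ---------------------------------------------------------------------------


def _build_vocab(docs: list[list[str]], min_count: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    # lexicographic ordering for determinism
    vocab = {w: i for i, w in enumerate(sorted(w for w, c in counts.items() if c >= min_count))}
    return vocab


def extract_paragraph_vectors(
    corpus: LabeledCorpus,
    dim: int = 40,
    epochs: int = 20,
    min_count: int = 2,
    window: int = 5,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.05,
) -> FeatureMatrix:
    """Train PV-DBOW document embeddings on the corpus itself.

    Each document's vector is optimized, by SGD with negative sampling, to
    score its own words above noise words drawn from the unigram^0.75
    distribution.  The training-time document vectors are returned for all
    records (no re-inference), so the matrix is deterministic per seed.

    ``window`` is accepted for interface symmetry with distributed-memory
    training but has no effect in the bag-of-words variant.
    """
    del window
    if corpus.n == 0:
        raise FeatureError("cannot extract features from an empty corpus")
    if dim < 2:
        raise FeatureError(f"embedding dim must be >= 2, got {dim}")
    docs = [tokenize(t) for t in corpus.texts()]
    vocab = _build_vocab(docs, min_count)
    if not vocab:
        raise FeatureError(
            f"no token reaches min_count={min_count}; corpus too small or too diverse"
        )
    n_docs, vsize = len(docs), len(vocab)
    doc_ids = [np.array([vocab[t] for t in doc if t in vocab], dtype=np.int64) for doc in docs]

    counts = np.zeros(vsize)
    for ids in doc_ids:
        np.add.at(counts, ids, 1.0)
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    docvecs = (rng.random((n_docs, dim)) - 0.5) / dim
    wordvecs = np.zeros((vsize, dim))

    alpha_min = alpha / 25.0
    for epoch in range(epochs):
        lr = alpha - (alpha - alpha_min) * epoch / max(epochs - 1, 1)
        for i in range(n_docs):
            targets = doc_ids[i]
            if targets.size == 0:
                continue
            negs = rng.choice(vsize, size=(targets.size, negative), p=noise)
            ids = np.concatenate([targets, negs.ravel()])
            labels = np.zeros(ids.size)
            labels[: targets.size] = 1.0
            v = docvecs[i]
            scores = wordvecs[ids] @ v
            g = (labels - 1.0 / (1.0 + np.exp(-scores))) * lr
            grad_v = g @ wordvecs[ids]
            np.add.at(wordvecs, ids, g[:, None] * v[None, :])
            docvecs[i] = v + grad_v
    return FeatureMatrix(values=docvecs, kind="d2v", nonnegative=False)


# ---------------------------------------------------------------------------
# Optional on-disk cache
# ---------------------------------------------------------------------------


def corpus_fingerprint(corpus: LabeledCorpus, params: dict) -> str:
    h = hashlib.sha256()
    for rec in corpus:
        h.update(f"{rec.record_id}\x1f{rec.title}\x1f{rec.abstract}\x1f{rec.label}\x1e".encode())
    h.update(json.dumps(params, sort_keys=True).encode())
    return h.hexdigest()[:16]


def save_feature_matrix(fm: FeatureMatrix, path: str | Path, params: dict | None = None) -> None:
    """Cache a feature matrix (binary container + JSON sidecar of params)."""
    path = Path(path)
    meta = {"kind": fm.kind, "nonnegative": fm.nonnegative, "params": params or {}}
    if sp.issparse(fm.values):
        sp.save_npz(path.with_suffix(".npz"), fm.values.tocsr())
    else:
        np.save(path.with_suffix(".npy"), fm.values)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if path.with_suffix(".npz").exists():
        values = sp.load_npz(path.with_suffix(".npz"))
    else:
        values = np.load(path.with_suffix(".npy"))
    return FeatureMatrix(values=values, kind=meta["kind"], nonnegative=meta["nonnegative"])
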