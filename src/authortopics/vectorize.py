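"""Vocabulary construction and the tf-idf author-term matrix.

The weighting is the smoothed-idf variant with Euclidean row
normalization:

    w(t, d) = count(t, d) * (ln((1 + N) / (1 + df_t)) + 1),

followed by l2-normalizing each author row (rows with no vocabulary terms
are left at zero).  The smoothing keeps idf strictly positive and the row
normalization makes author documents of very different lengths comparable,
which is what the downstream factorization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.preprocessing import normalize

from authortopics.preprocess import AuthorDocument

__all__ = [
    "Vocabulary",
    "DocTermMatrix",
    "build_vocabulary",
    "tfidf",
    "save_matrix",
    "load_matrix",
]


@dataclass
class Vocabulary:
    """Retained terms in lexicographic order with their document frequencies."""

    terms: list[str]
    doc_freq: dict[str, int]
    n_docs: int
    term_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        self.term_index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class DocTermMatrix:
    """Sparse authors-by-terms weight matrix with row/column labels."""

    values: sp.csr_matrix
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")


def _count_matrix(texts: Sequence[str], vocabulary: Sequence[str]) -> sp.csr_matrix:
    cv = CountVectorizer(
        analyzer=str.split, lowercase=False, vocabulary=list(vocabulary)
    )
    return cv.transform(texts).tocsr()


def build_vocabulary(
    docs: Sequence[AuthorDocument],
    min_doc_freq: int = 2,
    max_doc_prop: float = 0.5,
) -> Vocabulary:
    """Collect tokens across documents and apply document-frequency cuts.

    Terms occurring in fewer than ``min_doc_freq`` documents (hapax noise
    at the default) or in more than ``max_doc_prop`` of documents
    (residual ubiquitous words) are dropped; the retained terms are
    ordered lexicographically.
    """
    if not docs:
        raise ValueError("build_vocabulary requires a non-empty document list")
    texts = [d.text for d in docs]
    cv = CountVectorizer(analyzer=str.split, lowercase=False)
    try:
        counts = cv.fit_transform(texts)
    except ValueError as exc:  # empty vocabulary from all-empty docs
        raise ValueError("all terms were filtered; vocabulary is empty") from exc
    terms = cv.get_feature_names_out().tolist()
    df = np.asarray((counts > 0).sum(axis=0)).ravel()
    n = len(docs)
    keep = (df >= min_doc_freq) & (df <= max_doc_prop * n)
    if not keep.any():
        raise ValueError("all terms were filtered; vocabulary is empty")
    kept_terms = [t for t, k in zip(terms, keep) if k]
    doc_freq = {t: int(d) for t, d, k in zip(terms, df, keep) if k}
    return Vocabulary(terms=kept_terms, doc_freq=doc_freq, n_docs=n)


def tfidf(docs: Sequence[AuthorDocument], vocab: Vocabulary) -> DocTermMatrix:
    """Weight term counts by smoothed idf and l2-normalize author rows.

    Document frequencies are recomputed on ``docs`` so the weighting is
    self-consistent with the matrix being built (for the usual case where
    the vocabulary was built on the same corpus they coincide with
    ``vocab.doc_freq``).
    """
    if len(vocab) == 0:
        raise ValueError("tfidf requires a non-empty vocabulary")
    texts = [d.text for d in docs]
    counts = _count_matrix(texts, vocab.terms)
    n = len(docs)
    df = np.asarray((counts > 0).sum(axis=0)).ravel()
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    weighted = counts.multiply(idf[np.newaxis, :]).tocsr()
    weighted = normalize(weighted, norm="l2", axis=1, copy=False)
    return DocTermMatrix(
        values=weighted.tocsr(),
        row_labels=[d.author for d in docs],
        col_labels=list(vocab.terms),
    )


def save_matrix(matrix: DocTermMatrix, prefix: str | Path) -> None:
    """Persist as MatrixMarket coordinate text plus row/column label files."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), matrix.values)
    prefix.with_suffix(".rows.txt").write_text(
        "\n".join(matrix.row_labels) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".cols.txt").write_text(
        "\n".join(matrix.col_labels) + "\n", encoding="utf-8"
    )


def load_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    values = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    rows = prefix.with_suffix(".rows.txt").read_text(encoding="utf-8").splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text(encoding="utf-8").splitlines()
    return DocTermMatrix(values=values, row_labels=rows, col_labels=cols)
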