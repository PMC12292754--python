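"""Embedding providers for the semantic synonym tier.

The semantic tier only depends on the :class:`EmbeddingProvider` contract:
``embed(terms)`` returns one unit-norm vector per term, deterministically
for identical input, with dimension >= 2.  Transformer back-ends (BioBERT,
SentenceTransformers) can be plugged in by wrapping them in this contract;
the built-in default is a deterministic character 3-gram TF-IDF provider
that needs no model download and captures surface-level similarity.
"""

from __future__ import annotations

from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

__all__ = [
    "EmbeddingProvider",
    "ProviderContractError",
    "CharNgramTfidfProvider",
    "validate_embeddings",
]


class ProviderContractError(ValueError):
    """An embedding provider returned vectors violating the contract."""


@runtime_checkable
class EmbeddingProvider(Protocol):
    def embed(self, terms: Sequence[str]) -> np.ndarray:  # pragma: no cover - protocol
        """Return an (n_terms, dim) float array of unit-norm vectors."""
        ...


def validate_embeddings(vectors: np.ndarray, n_terms: int, atol: float = 1e-6) -> np.ndarray:
    """Check the provider contract: shape, dimension >= 2, unit norms."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] != n_terms:
        raise ProviderContractError(
            f"expected ({n_terms}, dim) embedding matrix, got shape {vectors.shape}"
        )
    if vectors.shape[1] < 2:
        raise ProviderContractError("embedding dimension must be >= 2")
    norms = np.linalg.norm(vectors, axis=1)
    if not np.allclose(norms, 1.0, atol=atol):
        worst = float(np.abs(norms - 1.0).max())
        raise ProviderContractError(f"embeddings must be unit-norm (max deviation {worst:.2e})")
    return vectors


class CharNgramTfidfProvider:
    """Deterministic character 3-gram TF-IDF embeddings, L2-normalized.

    The vectorizer is fitted on each input batch, so cosine similarities
    are comparable within one vocabulary (which is how the semantic tier
    consumes them).  Identical input lists yield identical matrices.
    """

    def __init__(self, ngram_range: tuple[int, int] = (3, 3)) -> None:
        self.ngram_range = ngram_range

    def embed(self, terms: Sequence[str]) -> np.ndarray:
        if len(terms) == 0:
            return np.zeros((0, 2))
        vectorizer = TfidfVectorizer(
            analyzer="char_wb", ngram_range=self.ngram_range, norm="l2"
        )
        matrix = vectorizer.fit_transform(terms).toarray()
        if matrix.shape[1] < 2:
            # Degenerate vocabulary (e.g. a single 1-char term): pad a zero
            # column so the dimension contract holds, then re-normalize.
            matrix = np.hstack([matrix, np.zeros((matrix.shape[0], 2 - matrix.shape[1]))])
        norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        zero = norms[:, 0] == 0
        if zero.any():
            # A term with no extractable n-grams gets a deterministic axis vector.
            matrix[zero, 0] = 1.0
            norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        return matrix / norms
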