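"""Core in-memory containers shared by every pipeline stage.

The pipeline moves between three representations:

* :class:`CountMatrix` — raw nonnegative counts of a word (row) against a
  context (column).  Both the cue-by-response tally from a continued free
  association task and generic word-by-context co-occurrence counts live here.
* :class:`WeightedMatrix` — the same shape after PPMI weighting.
* :class:`SimilarityMatrix` — a square, symmetric word-by-word cosine
  similarity matrix over the weighted rows.

Norm ratings (per-word means, optionally per-rater judgments) are held in
:class:`NormTable`.

Word order is fixed lexicographically at construction so that every
downstream artifact is reproducible regardless of input ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: The lexical properties this package models.  Likert-scaled 1-7 except age
#: of acquisition, which is reported in years.
KNOWN_PROPERTIES = ("valence", "arousal", "dominance", "aoa", "concreteness")


def _check_unique(words: Sequence[str], what: str) -> None:
    if len(set(words)) != len(words):
        raise ValueError(f"duplicate tokens in {what} word list")


@dataclass
class AssociationRecord:
    """One participant's responses to one cue in a continued association task.

    Responses are ordered (first, second, third association); missing
    responses are simply absent.  Duplicate responses within a record are
    removed upstream, keeping the earliest position.
    """

    participant_id: str
    cue: str
    responses: list[str]

    def __post_init__(self) -> None:
        if not self.cue:
            raise ValueError("cue must be nonempty")
        if not 1 <= len(self.responses) <= 3:
            raise ValueError("a record carries between 1 and 3 responses")
        if len(set(self.responses)) != len(self.responses):
            raise ValueError("responses within a record must be distinct")


class CountMatrix:
    """Nonnegative integer counts of row words against column contexts.

    Counts are stored sparsely; the association data at full scale are a
    12,566 x 12,566 matrix with a small fraction of nonzero cells.
    """

    def __init__(
        self,
        row_words: Sequence[str],
        col_words: Sequence[str],
        counts: sp.spmatrix | np.ndarray,
    ) -> None:
        _check_unique(row_words, "row")
        _check_unique(col_words, "column")
        m = sp.csr_matrix(counts)
        if m.shape != (len(row_words), len(col_words)):
            raise ValueError(
                f"counts shape {m.shape} does not match "
                f"{len(row_words)} rows x {len(col_words)} cols"
            )
        if m.nnz and m.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.row_words = list(row_words)
        self.col_words = list(col_words)
        self.counts = m.astype(np.int64)
        self._row_index = {w: i for i, w in enumerate(self.row_words)}
        self._col_index = {w: j for j, w in enumerate(self.col_words)}
        n_zero = int((self.row_totals() == 0).sum())
        if n_zero:
            logger.warning("CountMatrix has %d all-zero rows", n_zero)

    # -- basic queries -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def vocabulary(self) -> list[str]:
        """The word vocabulary of this matrix: its row words."""
        return self.row_words

    def row_index(self, word: str) -> int:
        return self._row_index[word]

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def total(self) -> int:
        return int(self.counts.sum())

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def __getitem__(self, key: tuple[str, str]) -> int:
        cue, resp = key
        return int(self.counts[self._row_index[cue], self._col_index[resp]])

    # -- restriction -------------------------------------------------------
    def restrict(self, words: Sequence[str]) -> "CountMatrix":
        """Restrict rows to ``words`` (kept in the given order)."""
        idx = [self._row_index[w] for w in words]
        return CountMatrix(list(words), self.col_words, self.counts[idx, :])

    def restrict_columns(self, words: Sequence[str]) -> "CountMatrix":
        idx = [self._col_index[w] for w in words]
        return CountMatrix(self.row_words, list(words), self.counts[:, idx])

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]}x{self.shape[1]}, total={self.total()})"


class WeightedMatrix:
    """Nonnegative real weights with the same geometry as a CountMatrix."""

    def __init__(
        self,
        row_words: Sequence[str],
        col_words: Sequence[str],
        weights: sp.spmatrix,
    ) -> None:
        _check_unique(row_words, "row")
        _check_unique(col_words, "column")
        w = sp.csr_matrix(weights, dtype=np.float64)
        if w.shape != (len(row_words), len(col_words)):
            raise ValueError("weights shape does not match word lists")
        if w.nnz and w.data.min() < 0:
            raise ValueError("weights must be nonnegative")
        self.row_words = list(row_words)
        self.col_words = list(col_words)
        self.weights = w

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def to_dense(self) -> np.ndarray:
        return self.weights.toarray()


class SimilarityMatrix:
    """Square symmetric cosine similarities in [0, 1].

    Rows whose underlying weight vector had zero norm are flagged in
    ``zero_norm``; such words carry no similarity information and are never
    eligible as nearest neighbors.
    """

    _SYM_TOL = 1e-10

    def __init__(
        self,
        words: Sequence[str],
        values: np.ndarray,
        zero_norm: np.ndarray | None = None,
    ) -> None:
        _check_unique(words, "similarity")
        values = np.asarray(values, dtype=np.float64)
        n = len(words)
        if values.shape != (n, n):
            raise ValueError("similarity matrix must be square over the word list")
        if np.abs(values - values.T).max(initial=0.0) > self._SYM_TOL:
            raise ValueError("similarity matrix must be symmetric")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("cosine similarities over nonnegative vectors lie in [0, 1]")
        self.words = list(words)
        self.values = np.clip(values, 0.0, 1.0)
        if zero_norm is None:
            zero_norm = np.zeros(n, dtype=bool)
        self.zero_norm = np.asarray(zero_norm, dtype=bool)
        self._index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    @property
    def vocabulary(self) -> list[str]:
        return self.words

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def restrict(self, words: Sequence[str]) -> "SimilarityMatrix":
        idx = [self._index[w] for w in words]
        return SimilarityMatrix(
            list(words), self.values[np.ix_(idx, idx)], self.zero_norm[idx]
        )

    def __repr__(self) -> str:
        return f"SimilarityMatrix({len(self.words)} words)"


class NormTable:
    """Per-word mean ratings for one or more lexical properties.

    ``means`` is indexed by word with one column per property.  When the
    per-rater judgments are available, ``rater_matrices[property]`` holds a
    rater x word frame (NaN for missing judgments) whose column means must
    agree with the stored means.
    """

    def __init__(
        self,
        means: pd.DataFrame,
        rater_matrices: Mapping[str, pd.DataFrame] | None = None,
    ) -> None:
        if means.index.has_duplicates:
            raise ValueError("duplicate words in norm table")
        unknown = set(means.columns) - set(KNOWN_PROPERTIES)
        if unknown:
            raise ValueError(f"unknown norm properties: {sorted(unknown)}")
        self.means = means.astype(float)
        self.rater_matrices = dict(rater_matrices or {})
        for prop, mat in self.rater_matrices.items():
            if prop not in self.means.columns:
                raise ValueError(f"rater matrix for absent property {prop!r}")
            cols = mat.columns
            stored = self.means.loc[cols, prop].to_numpy()
            observed = mat.mean(axis=0, skipna=True).to_numpy()
            if np.nanmax(np.abs(stored - observed), initial=0.0) > 1e-9:
                raise ValueError(
                    f"rater-matrix column means disagree with stored means for {prop!r}"
                )

    @classmethod
    def from_raters(cls, rater_matrices: Mapping[str, pd.DataFrame]) -> "NormTable":
        """Build a table whose means are the rater-matrix column means."""
        words = sorted(set().union(*(m.columns for m in rater_matrices.values())))
        means = pd.DataFrame(index=pd.Index(words, name="word"))
        for prop, mat in rater_matrices.items():
            means[prop] = mat.mean(axis=0, skipna=True).reindex(words)
        return cls(means, rater_matrices)

    @property
    def words(self) -> list[str]:
        return list(self.means.index)

    @property
    def vocabulary(self) -> list[str]:
        return self.words

    @property
    def properties(self) -> list[str]:
        return list(self.means.columns)

    def values_for(self, prop: str) -> pd.Series:
        return self.means[prop]

    def restrict(self, words: Sequence[str]) -> "NormTable":
        means = self.means.loc[list(words)]
        raters = {
            prop: mat.loc[:, [w for w in words if w in mat.columns]]
            for prop, mat in self.rater_matrices.items()
        }
        return NormTable(means, raters)

    def __repr__(self) -> str:
        return f"NormTable({len(self.means)} words, properties={self.properties})"


def vocabulary_of(source) -> list[str]:
    """The word vocabulary of a CountMatrix, SimilarityMatrix or NormTable."""
    vocab = getattr(source, "vocabulary", None)
    if vocab is None:
        raise TypeError(f"object of type {type(source).__name__} has no vocabulary")
    return vocab
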