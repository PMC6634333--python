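"""PPMI weighting and cosine similarity between word count vectors.

Raw counts overweight high-frequency words, so each cell is reweighted by
positive pointwise mutual information before cosine similarity is taken:

    PPMI(i, j) = max(0, log[ p_ij / (p_i. * p_.j) ])

with p the empirical joint/marginal probabilities of the count table.
Natural log is used throughout; the base is immaterial because rescaling
all weights by a positive constant leaves every cosine unchanged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .containers import CountMatrix, SimilarityMatrix, WeightedMatrix

logger = logging.getLogger(__name__)


def ppmi_transform(m: CountMatrix) -> WeightedMatrix:
    """Apply positive PMI weighting to a count matrix.

    Zero counts stay zero (PMI of an unobserved pair is treated as
    uninformative), and negative PMI values are clamped to zero.
    """
    n_total = m.total()
    if n_total == 0:
        raise ValueError("cannot PPMI-weight an all-zero count matrix")
    coo = m.counts.tocoo()
    row_tot = m.row_totals().astype(np.float64)
    col_tot = np.asarray(m.counts.sum(axis=0), dtype=np.float64).ravel()
    # PMI on the nonzero cells only: log(c_ij * N / (r_i * c_j))
    vals = np.log(coo.data.astype(np.float64) * n_total / (row_tot[coo.row] * col_tot[coo.col]))
    np.maximum(vals, 0.0, out=vals)
    w = sp.csr_matrix((vals, (coo.row, coo.col)), shape=m.shape)
    w.eliminate_zeros()
    return WeightedMatrix(m.row_words, m.col_words, w)


def cosine_similarity(w: WeightedMatrix) -> SimilarityMatrix:
    """Cosine similarity between the rows of a weighted matrix.

    Rows with zero norm (a word whose every weight was clamped away) get
    zero similarity to everything and are flagged rather than treated as
    errors; they are excluded from neighbor lists downstream.
    """
    sims = _sk_cosine(w.weights)
    sims = np.clip((sims + sims.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    norms = np.sqrt(np.asarray(w.weights.multiply(w.weights).sum(axis=1)).ravel())
    zero = norms == 0
    if zero.any():
        logger.warning("%d words have zero-norm PPMI vectors", int(zero.sum()))
    np.fill_diagonal(sims, 1.0)
    sims[zero, :] = 0.0
    sims[:, zero] = 0.0
    return SimilarityMatrix(w.row_words, sims, zero)


def similarity_from_counts(m: CountMatrix) -> SimilarityMatrix:
    """Convenience composition: PPMI weighting then cosine similarity."""
    return cosine_similarity(ppmi_transform(m))


def top_k_neighbors(
    s: SimilarityMatrix,
    word: str,
    k: int,
    candidates: Iterable[str],
) -> list[str]:
    """The k candidates most similar to ``word``, most similar first.

    The word itself and zero-norm words are never neighbors.  Ties are
    broken deterministically: descending similarity, then lexicographic
    token order.
    """
    if word not in s:
        raise KeyError(f"{word!r} not in similarity matrix")
    if k < 1:
        raise ValueError("k must be a positive integer")
    eligible = sorted(
        c for c in set(candidates) if c != word and not s.zero_norm[s.index(c)]
    )
    if k > len(eligible):
        raise ValueError(
            f"k={k} exceeds the {len(eligible)} eligible candidates for {word!r}"
        )
    sims = s.values[s.index(word), [s.index(c) for c in eligible]]
    order = np.argsort(-sims, kind="stable")  # stable: ties stay lexicographic
    return [eligible[i] for i in order[:k]]


def write_neighbor_lists(
    s: SimilarityMatrix,
    path,
    n: int = 10,
    candidates: Sequence[str] | None = None,
) -> None:
    """Debug writer: word, neighbor, similarity TSV for the top-n lists."""
    cands = list(candidates) if candidates is not None else list(s.words)
    with open(path, "w") as fh:
        fh.write("word\tneighbor\tsimilarity\n")
        for w in s.words:
            if s.zero_norm[s.index(w)]:
                continue
            kk = min(n, len([c for c in cands if c != w]))
            for nb in top_k_neighbors(s, w, kk, cands):
                fh.write(f"{w}\t{nb}\t{s.similarity(w, nb):.6f}\n")
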