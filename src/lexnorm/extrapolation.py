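"""k-nearest-neighbor norm extrapolation with cross-validation.

A word's norm (valence, arousal, ...) is predicted as the unweighted mean
of the norms of its k most similar rated words.  Prediction quality is
assessed by leave-one-out cross-validation within one norm set, or by a
holdout design that trains on one norm set and tests on another, sweeping
k over a grid (1..50 plus 60, 70, 80, 90, 100 by default) and correlating
predictions with the human means at each k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SimilarityMatrix
from .similarity import top_k_neighbors

logger = logging.getLogger(__name__)

#: Default k grid: every integer 1..50, then 60, 70, 80, 90, 100 (55 values).
DEFAULT_K_GRID: tuple[int, ...] = tuple(range(1, 51)) + (60, 70, 80, 90, 100)


@dataclass
class PredictionResult:
    """Cross-validated predictions for one property, one source, one k."""

    property_name: str
    source: str
    k: int
    predictions: pd.Series  # word -> predicted value, rating units
    neighbors: dict[str, tuple[str, ...]] | None = None


@dataclass
class KSweepResult:
    """Per-k prediction-vs-human correlations and the best k."""

    property_name: str
    source: str
    grid: tuple[int, ...]
    correlations: pd.Series  # index k -> Pearson r (NaN if undefined)
    best_k: int
    best_r: float
    predictions_best: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "property": self.property_name,
                "source": self.source,
                "k": self.correlations.index,
                "r": self.correlations.to_numpy(),
            }
        )


def knn_predict(
    s: SimilarityMatrix, train: Mapping[str, float], target: str, k: int
) -> float:
    """Predict one word's norm as the mean of its k nearest rated neighbors."""
    if target in train:
        raise ValueError(f"target {target!r} must not be in the training set")
    if k > len(train):
        raise ValueError(f"k={k} exceeds training-set size {len(train)}")
    nbrs = top_k_neighbors(s, target, k, train.keys())
    return float(np.mean([train[w] for w in nbrs]))


def _neighbor_value_order(
    s: SimilarityMatrix,
    targets: Sequence[str],
    candidates: Mapping[str, float],
):
    """Order every candidate for every target by descending similarity.

    Returns (cand_words, order, ordered_values, n_eligible).  Ties are
    broken lexicographically: candidate columns are sorted, so a stable
    argsort on descending similarity resolves ties by token order, exactly
    as ``top_k_neighbors`` does.  The target itself and zero-norm words are
    pushed past the end via -inf similarity.
    """
    cand_words = sorted(candidates)
    c_idx = np.array([s.index(w) for w in cand_words])
    t_idx = np.array([s.index(w) for w in targets])
    sub = s.values[np.ix_(t_idx, c_idx)].astype(np.float64)
    zero_cols = s.zero_norm[c_idx]
    sub[:, zero_cols] = -np.inf
    cand_pos = {w: j for j, w in enumerate(cand_words)}
    self_mask = np.zeros(len(targets), dtype=bool)
    for i, t in enumerate(targets):
        j = cand_pos.get(t)
        if j is not None:
            sub[i, j] = -np.inf
            self_mask[i] = True
    order = np.argsort(-sub, axis=1, kind="stable")
    values = np.array([candidates[w] for w in cand_words], dtype=np.float64)
    ordered_values = values[order]
    n_eligible = len(cand_words) - int(zero_cols.sum()) - self_mask.astype(int)
    return cand_words, order, ordered_values, n_eligible


def loo_extrapolate(
    s: SimilarityMatrix,
    norms: Mapping[str, float],
    k: int,
    property_name: str = "",
    source: str = "",
    keep_neighbors: bool = True,
) -> PredictionResult:
    """Leave-one-out k-NN: each word predicted from all other rated words."""
    words = sorted(norms)
    missing = [w for w in words if w not in s]
    if missing:
        raise KeyError(f"norm words absent from similarity matrix: {missing[:5]}")
    if k > len(words) - 1:
        raise ValueError(f"k={k} exceeds |norms|-1 = {len(words) - 1}")
    cand_words, order, ordered_values, n_eligible = _neighbor_value_order(s, words, norms)
    low = int(n_eligible.min())
    if k > low:
        worst = words[int(np.argmin(n_eligible))]
        raise ValueError(f"k={k} exceeds the {low} eligible neighbors of {worst!r}")
    preds = ordered_values[:, :k].mean(axis=1)
    neighbors = None
    if keep_neighbors:
        neighbors = {
            w: tuple(cand_words[j] for j in order[i, :k]) for i, w in enumerate(words)
        }
    return PredictionResult(
        property_name, source, k, pd.Series(preds, index=words), neighbors
    )


def holdout_extrapolate(
    s: SimilarityMatrix,
    train_norms: Mapping[str, float],
    test_words: Sequence[str],
    k: int,
    property_name: str = "",
    source: str = "",
    keep_neighbors: bool = True,
) -> PredictionResult:
    """Predict held-out words from a disjoint training norm set."""
    overlap = set(train_norms) & set(test_words)
    if overlap:
        raise ValueError(f"train and test overlap on {len(overlap)} words, e.g. {sorted(overlap)[:3]}")
    words = sorted(test_words)
    for w in list(words) + list(train_norms):
        if w not in s:
            raise KeyError(f"word {w!r} absent from similarity matrix")
    cand_words, order, ordered_values, n_eligible = _neighbor_value_order(
        s, words, dict(train_norms)
    )
    low = int(n_eligible.min())
    if k > low:
        worst = words[int(np.argmin(n_eligible))]
        raise ValueError(f"k={k} exceeds the {low} eligible neighbors of {worst!r}")
    preds = ordered_values[:, :k].mean(axis=1)
    neighbors = None
    if keep_neighbors:
        neighbors = {
            w: tuple(cand_words[j] for j in order[i, :k]) for i, w in enumerate(words)
        }
    return PredictionResult(
        property_name, source, k, pd.Series(preds, index=words), neighbors
    )


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def sweep_k(
    s: SimilarityMatrix,
    norms: Mapping[str, float] | None = None,
    *,
    train: Mapping[str, float] | None = None,
    test: Mapping[str, float] | None = None,
    mode: str = "loo",
    grid: Sequence[int] | None = None,
    property_name: str = "",
    source: str = "",
) -> KSweepResult:
    """Sweep k over a grid, correlating predictions with human means.

    ``mode="loo"`` takes ``norms`` (word -> human mean) and cross-validates
    leave-one-out; ``mode="holdout"`` takes disjoint ``train`` and ``test``
    maps and predicts the test words from the training set only.  A k whose
    predictions are constant (undefined correlation) is recorded as NaN and
    logged.  Ties on the best correlation are broken toward smaller k.
    """
    grid = tuple(grid) if grid is not None else DEFAULT_K_GRID
    if not grid or any(k < 1 for k in grid):
        raise ValueError("k grid must be nonempty positive integers")
    if mode == "loo":
        if norms is None:
            raise ValueError("mode='loo' requires norms")
        targets = sorted(norms)
        candidates = dict(norms)
        human = np.array([norms[w] for w in targets], dtype=np.float64)
    elif mode == "holdout":
        if train is None or test is None:
            raise ValueError("mode='holdout' requires train and test")
        if set(train) & set(test):
            raise ValueError("train and test sets overlap")
        targets = sorted(test)
        candidates = dict(train)
        human = np.array([test[w] for w in targets], dtype=np.float64)
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    _, order, ordered_values, n_eligible = _neighbor_value_order(s, targets, candidates)
    low = int(n_eligible.min())
    if max(grid) > low:
        raise ValueError(
            f"k grid maximum {max(grid)} exceeds the {low} eligible neighbors "
            f"available for some target"
        )
    csum = np.cumsum(ordered_values, axis=1)
    rs: dict[int, float] = {}
    preds_by_k: dict[int, np.ndarray] = {}
    for k in grid:
        preds = csum[:, k - 1] / k
        r = _pearson_or_nan(preds, human)
        if np.isnan(r):
            logger.warning("correlation undefined at k=%d (constant vector)", k)
        rs[k] = r
        preds_by_k[k] = preds
    corr = pd.Series(rs)
    if corr.isna().all():
        raise ValueError("correlation undefined at every k in the grid")
    # ties broken toward smaller k: scan in ascending k order
    best_k = None
    best_r = -np.inf
    for k in sorted(grid):
        r = rs[k]
        if not np.isnan(r) and r > best_r:
            best_r, best_k = r, k
    return KSweepResult(
        property_name,
        source,
        grid,
        corr,
        int(best_k),
        float(best_r),
        pd.Series(preds_by_k[best_k], index=targets),
    )


def write_predictions(results: Sequence[PredictionResult], human: Mapping[str, float], path) -> None:
    """CSV writer: word, property, source, k, predicted, human_mean."""
    rows = []
    for res in results:
        for w, p in res.predictions.items():
            rows.append(
                {
                    "word": w,
                    "property": res.property_name,
                    "source": res.source,
                    "k": res.k,
                    "predicted": p,
                    "human_mean": human.get(w, np.nan),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
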