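"""Readers for association records, co-occurrence triples and norm tables.

The continued free-association format mirrors the Small World of Words
layout: one row per participant x cue, with up to three response columns
(wide) or one response per row (long).  Co-occurrence data arrive as
(word, context, count) triples.  Norm tables are CSV with a word column,
one property column, and optionally one column per rater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    AssociationRecord,
    CountMatrix,
    NormTable,
    SimilarityMatrix,
    vocabulary_of,
)

logger = logging.getLogger(__name__)


@dataclass
class Dialect:
    """File-layout configuration for association files.

    ``fmt`` is ``"wide"`` (participant, cue, R1, R2, R3) or ``"long"``
    (participant, cue, response).  Tokens are case-folded and
    whitespace-trimmed by default; multi-word responses are kept as single
    tokens after trimming.
    """

    sep: str = "\t"
    fmt: str = "wide"
    participant_col: str = "participant"
    cue_col: str = "cue"
    response_cols: tuple[str, ...] = ("R1", "R2", "R3")
    response_col: str = "response"
    case_fold: bool = True
    strip: bool = True

    def normalize(self, token: str) -> str:
        t = token.strip() if self.strip else token
        return t.lower() if self.case_fold else t


def _row_to_record(
    participant: str, cue: str, raw_responses: Iterable[str], dialect: Dialect
) -> AssociationRecord | None:
    if cue is None or (isinstance(cue, float) and np.isnan(cue)):
        return None
    cue = dialect.normalize(str(cue))
    seen: list[str] = []
    for r in raw_responses:
        if r is None or (isinstance(r, float) and np.isnan(r)):
            continue
        tok = dialect.normalize(str(r))
        if tok and tok not in seen:
            seen.append(tok)
    if not cue or not seen:
        return None
    return AssociationRecord(str(participant), cue, seen)


def read_association_file(
    path: str | Path, dialect: Dialect | None = None
) -> list[AssociationRecord]:
    """Parse an association file into one record per participant x cue row.

    Malformed rows (empty cue, no usable responses) are skipped with a
    logged count; an empty file is an error.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"association file {path} contains no rows")
    records: list[AssociationRecord] = []
    n_skipped = 0
    if dialect.fmt == "wide":
        resp_cols = [c for c in dialect.response_cols if c in df.columns]
        if not resp_cols:
            raise ValueError(f"no response columns {dialect.response_cols} in {path}")
        for row in df.itertuples(index=False):
            rec = _row_to_record(
                getattr(row, dialect.participant_col),
                getattr(row, dialect.cue_col),
                [getattr(row, c) for c in resp_cols],
                dialect,
            )
            if rec is None:
                n_skipped += 1
            else:
                records.append(rec)
    elif dialect.fmt == "long":
        grouped = df.groupby(
            [dialect.participant_col, dialect.cue_col], sort=False
        )[dialect.response_col]
        for (pid, cue), responses in grouped:
            rec = _row_to_record(pid, cue, list(responses), dialect)
            if rec is None:
                n_skipped += 1
            else:
                records.append(rec)
    else:
        raise ValueError(f"unknown association format {dialect.fmt!r}")
    if n_skipped:
        logger.warning("skipped %d malformed association rows in %s", n_skipped, path)
    if not records:
        raise ValueError(f"association file {path} yielded no usable records")
    return records


def build_cue_by_response_counts(
    records: Sequence[AssociationRecord],
    position_weights: Sequence[float] | None = None,
) -> CountMatrix:
    """Tally records into a cue-by-response count matrix.

    All response positions are pooled with equal weight by default, so a cue
    answered by 100 participants contributes (up to) 300 response tokens.
    An optional per-position weight vector is accepted for sensitivity
    analyses; weights must be positive integers to keep counts integral.
    """
    if not records:
        raise ValueError("no association records")
    if position_weights is not None:
        w = [int(x) for x in position_weights]
        if list(position_weights) != w or any(x <= 0 for x in w):
            raise ValueError("position weights must be positive integers")
    cues = sorted({r.cue for r in records})
    responses = sorted({tok for r in records for tok in r.responses})
    if not responses:
        raise ValueError("no responses")
    ci = {w_: i for i, w_ in enumerate(cues)}
    rj = {w_: j for j, w_ in enumerate(responses)}
    rows, cols, data = [], [], []
    for rec in records:
        for pos, tok in enumerate(rec.responses):
            rows.append(ci[rec.cue])
            cols.append(rj[tok])
            data.append(position_weights[pos] if position_weights is not None else 1)
    counts = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(cues), len(responses)), dtype=np.int64
    ).tocsr()
    return CountMatrix(cues, responses, counts)


def restrict_to_square(m: CountMatrix) -> CountMatrix:
    """Transform a cue-by-response matrix into a square cue-by-cue matrix.

    Response columns that never served as cues are dropped; the column set
    becomes exactly the row (cue) set, with all-zero columns for cues never
    produced as responses.  Rows left with a zero total after the column
    drop are dropped too (and logged), together with their columns, so the
    result stays square.
    """
    col_set = set(m.col_words)
    if not any(w in col_set for w in m.row_words):
        raise ValueError("no responses coincide with cue words; square restriction empty")
    # re-index surviving columns into the cue vocabulary; absent cues get
    # an all-zero column
    row_pos = {w: i for i, w in enumerate(m.row_words)}
    coo = m.counts.tocoo()
    keep = np.array([m.col_words[j] in row_pos for j in coo.col])
    new_col = np.array(
        [row_pos[m.col_words[j]] for j in coo.col[keep]], dtype=np.int64
    ) if keep.any() else np.array([], dtype=np.int64)
    n = len(m.row_words)
    sq_counts = sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], new_col)), shape=(n, n), dtype=np.int64
    ).tocsr()
    sq = CountMatrix(m.row_words, m.row_words, sq_counts)
    # dropping a zero-total row removes its column too, which can zero out
    # further rows: iterate to a fixed point so the operation is idempotent
    total_dropped = 0
    while True:
        totals = sq.row_totals()
        keep_rows = [w for w, t in zip(sq.row_words, totals) if t > 0]
        if not keep_rows:
            raise ValueError("square restriction dropped every row")
        n_drop = len(sq.row_words) - len(keep_rows)
        if n_drop == 0:
            break
        total_dropped += n_drop
        sq = sq.restrict(keep_rows).restrict_columns(keep_rows)
    if total_dropped:
        logger.info(
            "restrict_to_square dropped %d cue rows with no surviving counts",
            total_dropped,
        )
    return sq


def read_cooccurrence_counts(path: str | Path, sep: str = "\t") -> CountMatrix:
    """Read (word, context, count) triples, summing duplicates."""
    df = pd.read_csv(path, sep=sep, header=None, names=["word", "context", "count"])
    if df.empty:
        raise ValueError(f"co-occurrence file {path} contains no rows")
    if (df["count"] < 0).any():
        raise ValueError("negative co-occurrence count")
    df["word"] = df["word"].astype(str).str.strip().str.lower()
    df["context"] = df["context"].astype(str).str.strip().str.lower()
    agg = df.groupby(["word", "context"], sort=True)["count"].sum()
    rows = sorted(agg.index.get_level_values(0).unique())
    cols = sorted(agg.index.get_level_values(1).unique())
    ri = {w: i for i, w in enumerate(rows)}
    cj = {w: j for j, w in enumerate(cols)}
    counts = sp.coo_matrix(
        (
            agg.to_numpy(),
            (
                [ri[w] for w, _ in agg.index],
                [cj[c] for _, c in agg.index],
            ),
        ),
        shape=(len(rows), len(cols)),
        dtype=np.int64,
    ).tocsr()
    return CountMatrix(rows, cols, counts)


def read_norm_file(
    path: str | Path, property_name: str, sep: str = ","
) -> NormTable:
    """Read a norm CSV: word, <property>[, one column per rater].

    Any column beyond the word and property columns is treated as a rater;
    missing rater judgments are allowed (empty cells).
    """
    df = pd.read_csv(path, sep=sep)
    if "word" not in df.columns or property_name not in df.columns:
        raise ValueError(f"norm file {path} must have 'word' and {property_name!r} columns")
    df["word"] = df["word"].astype(str).str.strip().str.lower()
    df = df.set_index("word").sort_index()
    rater_cols = [c for c in df.columns if c != property_name]
    means = df[[property_name]].astype(float)
    raters = {}
    if rater_cols:
        raters[property_name] = df[rater_cols].astype(float).T
    return NormTable(means, raters)


def align_vocabulary(*sources):
    """Restrict two or more sources to their shared vocabulary.

    Returns the sorted intersection of the vocabularies and a tuple of the
    sources restricted (consistently, in lexicographic order) to it.  The
    result is independent of the order in which sources are given.
    """
    if len(sources) < 2:
        raise ValueError("align_vocabulary needs at least two sources")
    vocabs = [set(vocabulary_of(s)) for s in sources]
    shared = sorted(set.intersection(*vocabs))
    if not shared:
        raise ValueError("vocabularies have empty intersection")
    logger.info(
        "align_vocabulary: %s -> %d shared words",
        " x ".join(str(len(v)) for v in vocabs),
        len(shared),
    )
    return shared, tuple(s.restrict(shared) for s in sources)
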