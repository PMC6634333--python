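"""Synthetic lexicons with the structure the extrapolation analysis assumes.

The generative model places every word in a latent D-dimensional semantic
space (i.i.d. standard normal coordinates).  Each lexical property is a
noisy linear projection of that space onto a unit direction, affinely
mapped onto its rating scale (Likert 1-7; age of acquisition onto 2-16
years).  Two observation channels mimic the empirical data sources:

* association responses — each of P participants per cue produces three
  distinct responses, sampled without replacement with probability
  proportional to exp(beta * cos(cue, response));
* word-context co-occurrence counts — a multinomial over word pairs with
  weights proportional to exp(beta_text * cos), with beta_text typically
  below beta so the text channel carries a weaker semantic signal.

Per-rater Likert judgments add Gaussian noise to the true values and clip
to the scale.  All randomness flows from one seed through named substreams
(lexicon, associations, raters, cooccurrence) so the components can be
regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AssociationRecord, CountMatrix, NormTable
from .corpus_io import build_cue_by_response_counts

_STREAMS = {"lexicon": 0, "associations": 1, "raters": 2, "cooccurrence": 3}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class PropertySpec:
    """One lexical property: its rating scale and projection noise.

    ``noise_sd`` is in latent units (the projection itself has unit
    variance), so it controls how far true norms depart from a perfect
    linear function of the semantic space.
    """

    low: float
    high: float
    noise_sd: float = 0.3


#: Likert 1-7 scales for the affective and concreteness norms; a wider
#: positive scale (years) for age of acquisition, whose deviating behavior
#: the wider range mimics.
DEFAULT_PROPERTIES: dict[str, PropertySpec] = {
    "valence": PropertySpec(1, 7),
    "arousal": PropertySpec(1, 7),
    "dominance": PropertySpec(1, 7),
    "aoa": PropertySpec(2, 16),
    "concreteness": PropertySpec(1, 7),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic lexicon.

    Defaults mirror the empirical setting the pipeline emulates: at least
    100 participants per cue giving three responses each (300 responses per
    cue), a latent space of moderate dimension, and a text channel whose
    semantic sharpness is below the association channel's.
    """

    vocab_size: int = 500
    latent_dim: int = 10
    properties: Mapping[str, PropertySpec] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTIES)
    )
    participants_per_cue: int = 100
    responses_per_participant: int = 3
    assoc_sharpness: float = 6.0  # beta: softmax concentration of responses
    n_raters: int = 20
    rater_noise_sd: float = 1.0  # rating units
    text_sharpness: float = 1.5  # beta_text < beta: weaker text signal
    cooccurrence_budget: int | None = None  # default: matched to 3*P*V tokens
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be at least 10")
        if self.latent_dim < 1 or self.latent_dim < len(self.properties):
            raise ValueError("latent_dim must cover the number of properties")
        if self.assoc_sharpness < 0 or self.text_sharpness < 0:
            raise ValueError("sharpness parameters must be nonnegative")
        if self.rater_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")

    @property
    def budget(self) -> int:
        if self.cooccurrence_budget is not None:
            return self.cooccurrence_budget
        return (
            self.responses_per_participant
            * self.participants_per_cue
            * self.vocab_size
        )


@dataclass
class SyntheticLexicon:
    """A generated lexicon: latent vectors plus true norm values."""

    config: GeneratorConfig
    words: list[str]
    latents: np.ndarray  # V x D
    directions: dict[str, np.ndarray]  # property -> unit vector
    true_norms: pd.DataFrame  # word x property, rating units

    def latent_cosines(self) -> np.ndarray:
        x = self.latents / np.linalg.norm(self.latents, axis=1, keepdims=True)
        return x @ x.T


def generate_lexicon(cfg: GeneratorConfig) -> SyntheticLexicon:
    """Draw latent vectors and project them onto noisy norm values.

    Property directions are mutually orthonormal (QR of a Gaussian draw),
    so distinct properties are independent in the latent population.  Raw
    projections (unit variance plus projection noise) are mapped affinely
    so that +/-3 sd spans the rating scale, then clipped to the scale.
    """
    rng = _stream(cfg.seed, "lexicon")
    V, D = cfg.vocab_size, cfg.latent_dim
    width = len(str(V - 1))
    words = [f"w{i:0{width}d}" for i in range(V)]
    latents = rng.standard_normal((V, D))
    q, _ = np.linalg.qr(rng.standard_normal((D, D)))
    directions = {name: q[:, j].copy() for j, name in enumerate(cfg.properties)}
    norms = {}
    for name, spec in cfg.properties.items():
        raw = latents @ directions[name] + rng.normal(0, spec.noise_sd, V)
        mid = (spec.low + spec.high) / 2
        scale = (spec.high - spec.low) / 6  # +/-3 sd of the unit projection
        norms[name] = np.clip(mid + raw * scale, spec.low, spec.high)
    true_norms = pd.DataFrame(norms, index=pd.Index(words, name="word"))
    return SyntheticLexicon(cfg, words, latents, directions, true_norms)


def _sample_response_indices(lex: SyntheticLexicon) -> np.ndarray:
    """(V, P, 3) response indices: per participant, 3 distinct responses.

    Sampling without replacement proportional to softmax weights uses the
    Gumbel-top-k construction: add Gumbel noise to the log-weights and take
    the top three, which is distributionally identical to sequential
    draws without replacement.
    """
    cfg = lex.config
    rng = _stream(cfg.seed, "associations")
    V, P, R = cfg.vocab_size, cfg.participants_per_cue, cfg.responses_per_participant
    logw = cfg.assoc_sharpness * lex.latent_cosines()
    np.fill_diagonal(logw, -np.inf)  # no self-responses
    out = np.empty((V, P, R), dtype=np.int64)
    for i in range(V):
        g = logw[i][None, :] + rng.gumbel(size=(P, V))
        top = np.argpartition(-g, R - 1, axis=1)[:, :R]
        row_scores = np.take_along_axis(g, top, axis=1)
        order = np.argsort(-row_scores, axis=1)
        out[i] = np.take_along_axis(top, order, axis=1)
    return out


def sample_association_records(lex: SyntheticLexicon) -> list[AssociationRecord]:
    """Participant-level association records (for exercising the I/O layer)."""
    idx = _sample_response_indices(lex)
    words = lex.words
    records = []
    for i, cue in enumerate(words):
        for p in range(idx.shape[1]):
            records.append(
                AssociationRecord(
                    f"p{p:04d}", cue, [words[j] for j in idx[i, p]]
                )
            )
    return records


def sample_association_responses(lex: SyntheticLexicon) -> CountMatrix:
    """Cue-by-response counts tallied from the sampled responses.

    Identical draws to :func:`sample_association_records` (both derive the
    same substream from the lexicon seed), so counts and records agree.
    """
    idx = _sample_response_indices(lex)
    V = len(lex.words)
    flat = idx.reshape(V, -1)
    counts = np.zeros((V, V), dtype=np.int64)
    for i in range(V):
        np.add.at(counts[i], flat[i], 1)
    return CountMatrix(lex.words, lex.words, counts)


def sample_rater_judgments(lex: SyntheticLexicon) -> dict[str, pd.DataFrame]:
    """Per-property rater x word matrices: true value + noise, clipped."""
    cfg = lex.config
    if cfg.n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = _stream(cfg.seed, "raters")
    out = {}
    rater_ids = [f"r{j:03d}" for j in range(cfg.n_raters)]
    for name, spec in cfg.properties.items():
        true = lex.true_norms[name].to_numpy()
        noise = rng.normal(0, cfg.rater_noise_sd, (cfg.n_raters, len(true)))
        mat = np.clip(true[None, :] + noise, spec.low, spec.high)
        out[name] = pd.DataFrame(mat, index=rater_ids, columns=lex.words)
    return out


def rater_norm_table(lex: SyntheticLexicon) -> NormTable:
    """Norm table whose means are the rater means (the observable norms)."""
    return NormTable.from_raters(sample_rater_judgments(lex))


def sample_cooccurrence_counts(lex: SyntheticLexicon) -> CountMatrix:
    """Multinomial word-context counts with softmax-of-cosine weights.

    The diagonal is excluded (a word does not co-occur with itself in a
    dependency relation); total counts equal the budget exactly.
    """
    cfg = lex.config
    budget = cfg.budget
    if budget <= 0:
        raise ValueError("co-occurrence budget must be positive")
    rng = _stream(cfg.seed, "cooccurrence")
    w = np.exp(cfg.text_sharpness * lex.latent_cosines())
    np.fill_diagonal(w, 0.0)
    p = (w / w.sum()).ravel()
    counts = rng.multinomial(budget, p).reshape(w.shape)
    return CountMatrix(lex.words, lex.words, counts)


# -- writers: emit exactly the dialects corpus_io reads ---------------------

def write_association_tsv(records: Sequence[AssociationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("participant\tcue\tR1\tR2\tR3\n")
        for rec in records:
            resp = list(rec.responses) + [""] * (3 - len(rec.responses))
            fh.write(f"{rec.participant_id}\t{rec.cue}\t" + "\t".join(resp) + "\n")


def write_cooccurrence_tsv(m: CountMatrix, path: str | Path) -> None:
    coo = m.counts.tocoo()
    with open(path, "w") as fh:
        for i, j, c in zip(coo.row, coo.col, coo.data):
            fh.write(f"{m.row_words[i]}\t{m.col_words[j]}\t{c}\n")


def write_norms_csv(
    norms: NormTable, property_name: str, path: str | Path
) -> None:
    """CSV: word, <property>[, one column per rater]."""
    df = pd.DataFrame({"word": norms.words, property_name: norms.means[property_name]})
    raters = norms.rater_matrices.get(property_name)
    if raters is not None:
        for rid in raters.index:
            df[rid] = raters.loc[rid, norms.words].to_numpy()
    df.to_csv(path, index=False)
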