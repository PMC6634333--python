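"""Configuration-driven orchestration of a full extrapolation study.

A study takes one or two similarity sources (association counts, optional
word-context co-occurrence counts) plus norm tables, restricts everything
to a shared vocabulary, sweeps k for each property and source under one of
three cross-validation designs, and assembles the complete evaluation
report: per-k correlations, the best-k correlation with its confidence
interval, split-half reliability and the attenuation-corrected correlation
when rater-level data exist, residual incremental R-squared in both
directions, and the dependent-correlation comparison between sources.

Designs:

* ``loo-shared-vocab`` — leave-one-out over every word shared by all inputs;
* ``loo-subset`` — leave-one-out within a random fixed-size subset of the
  shared words (emulating evaluation on a small legacy norm set);
* ``train-test`` — predictions for a held-out test split from a disjoint
  training split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import corpus_io, evaluation, extrapolation, similarity as simmod
from .containers import CountMatrix, NormTable, SimilarityMatrix
from .evaluation import (
    ComparisonReport,
    CorrelationReport,
    ReliabilityReport,
    compare_dependent_correlations,
    disattenuate,
    pearson_with_ci,
    residual_incremental_r2,
    split_half_reliability,
)
from .extrapolation import DEFAULT_K_GRID, KSweepResult, sweep_k
from .synthetic_data import (
    GeneratorConfig,
    generate_lexicon,
    rater_norm_table,
    sample_association_responses,
    sample_cooccurrence_counts,
)

logger = logging.getLogger(__name__)

DESIGNS = ("loo-shared-vocab", "loo-subset", "train-test")


@dataclass
class StudyConfig:
    """Everything needed to (re)run one study deterministically."""

    design: str = "loo-shared-vocab"
    seed: int = 0
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    synthetic: GeneratorConfig | None = None
    association_path: str | None = None
    cooccurrence_path: str | None = None
    norm_paths: dict[str, str] = field(default_factory=dict)
    properties: tuple[str, ...] | None = None
    reliability_randomizations: int = 10_000
    with_reliability: bool = True
    subset_size: int | None = None  # loo-subset
    test_fraction: float = 0.25  # train-test
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        if not self.k_grid:
            raise ValueError("k grid must be nonempty")
        if self.synthetic is None and self.association_path is None:
            raise ValueError("need either a synthetic config or an association file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = GeneratorConfig(**syn)
        if "k_grid" in raw:
            raw["k_grid"] = tuple(int(k) for k in raw["k_grid"])
        if "properties" in raw and raw["properties"] is not None:
            raw["properties"] = tuple(raw["properties"])
        return cls(synthetic=syn, **raw)


@dataclass
class PropertyReport:
    property_name: str
    sweeps: dict[str, KSweepResult]
    correlation: dict[str, CorrelationReport]
    reliability: ReliabilityReport | None = None
    disattenuated: dict[str, float] = field(default_factory=dict)
    residual_r2: dict[str, float] = field(default_factory=dict)
    comparison: ComparisonReport | None = None


@dataclass
class StudyReport:
    config: StudyConfig
    n_shared_words: int
    n_evaluated_words: int
    sources: tuple[str, ...]
    properties: dict[str, PropertyReport]

    def to_dict(self) -> dict[str, Any]:
        return _serialize(self)


def _serialize(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _serialize(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, pd.Series):
        return {str(k): _serialize(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    return obj


def _load_sources(cfg: StudyConfig):
    """Build similarity matrices and the norm table from files or simulation."""
    sims: dict[str, SimilarityMatrix] = {}
    rater_matrices: dict[str, pd.DataFrame] = {}
    if cfg.synthetic is not None:
        lex = generate_lexicon(cfg.synthetic)
        assoc = sample_association_responses(lex)
        norms = rater_norm_table(lex) if cfg.with_reliability else NormTable(lex.true_norms)
        rater_matrices = dict(norms.rater_matrices)
        cooc = sample_cooccurrence_counts(lex)
        sources: dict[str, CountMatrix] = {"associations": assoc, "cooccurrence": cooc}
    else:
        records = corpus_io.read_association_file(cfg.association_path)
        sources = {"associations": corpus_io.build_cue_by_response_counts(records)}
        if cfg.cooccurrence_path:
            sources["cooccurrence"] = corpus_io.read_cooccurrence_counts(
                cfg.cooccurrence_path
            )
        if not cfg.norm_paths:
            raise ValueError("file-based study needs norm_paths")
        tables = [
            corpus_io.read_norm_file(path, prop) for prop, path in cfg.norm_paths.items()
        ]
        means = pd.concat([t.means for t in tables], axis=1)
        for t in tables:
            rater_matrices.update(t.rater_matrices)
        norms = NormTable(means.dropna(), {
            p: m.loc[:, [w for w in means.dropna().index if w in m.columns]]
            for p, m in rater_matrices.items()
        })
    for label, counts in sources.items():
        if label == "associations":
            counts = corpus_io.restrict_to_square(counts)
            logger.info("association matrix square-restricted to %d cues", counts.shape[0])
        sims[label] = simmod.similarity_from_counts(counts)
    return sims, norms


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute a study end to end and (optionally) write its report."""
    try:
        sims, norms = _load_sources(cfg)
    except Exception as exc:
        raise RuntimeError(f"[stage: load] {exc}") from exc
    shared, views = corpus_io.align_vocabulary(*sims.values(), norms)
    sims = dict(zip(sims.keys(), views[:-1]))
    norms = views[-1]
    logger.info("shared vocabulary: %d words", len(shared))

    props = list(cfg.properties) if cfg.properties else norms.properties
    rng = np.random.default_rng(cfg.seed)
    if cfg.design == "loo-subset":
        size = cfg.subset_size or max(10, len(shared) // 4)
        subset = sorted(rng.choice(shared, size=min(size, len(shared)), replace=False))
        eval_words, train_words = subset, None
        logger.info("loo-subset: evaluating within %d words", len(subset))
    elif cfg.design == "train-test":
        n_test = max(1, int(round(cfg.test_fraction * len(shared))))
        test = sorted(rng.choice(shared, size=n_test, replace=False))
        train_words = sorted(set(shared) - set(test))
        eval_words = test
        logger.info("train-test: %d train / %d test words", len(train_words), len(test))
    else:
        eval_words, train_words = shared, None

    reports: dict[str, PropertyReport] = {}
    for prop in props:
        human_all = norms.values_for(prop)
        sweeps: dict[str, KSweepResult] = {}
        correlation: dict[str, CorrelationReport] = {}
        for label, s in sims.items():
            try:
                if cfg.design == "train-test":
                    sweeps[label] = sweep_k(
                        s,
                        train={w: human_all[w] for w in train_words},
                        test={w: human_all[w] for w in eval_words},
                        mode="holdout",
                        grid=cfg.k_grid,
                        property_name=prop,
                        source=label,
                    )
                else:
                    sweeps[label] = sweep_k(
                        s,
                        {w: human_all[w] for w in eval_words},
                        mode="loo",
                        grid=cfg.k_grid,
                        property_name=prop,
                        source=label,
                    )
            except Exception as exc:
                raise RuntimeError(f"[stage: sweep {prop}/{label}] {exc}") from exc
            best = sweeps[label]
            human_eval = human_all.loc[best.predictions_best.index].to_numpy()
            correlation[label] = pearson_with_ci(
                best.predictions_best.to_numpy(), human_eval
            )
        report = PropertyReport(prop, sweeps, correlation)

        if cfg.with_reliability and prop in norms.rater_matrices:
            try:
                report.reliability = split_half_reliability(
                    norms.rater_matrices[prop],
                    cfg.reliability_randomizations,
                    seed=cfg.seed,
                    property_name=prop,
                )
            except Exception as exc:
                raise RuntimeError(f"[stage: reliability {prop}] {exc}") from exc
            for label in sims:
                report.disattenuated[label] = disattenuate(
                    sweeps[label].best_r, report.reliability.reliability
                )

        if len(sims) == 2:
            (la, sa), (lb, sb) = sweeps.items()
            pa = sa.predictions_best.to_numpy()
            pb = sb.predictions_best.to_numpy()
            human_eval = human_all.loc[sa.predictions_best.index].to_numpy()
            report.residual_r2 = {
                f"{la}_residuals_vs_{lb}": residual_incremental_r2(human_eval, pa, pb),
                f"{lb}_residuals_vs_{la}": residual_incremental_r2(human_eval, pb, pa),
            }
            r12 = float(np.corrcoef(pa, pb)[0, 1])
            report.comparison = compare_dependent_correlations(
                sa.best_r, sb.best_r, r12, len(human_eval)
            )
        reports[prop] = report

    study = StudyReport(
        cfg, len(shared), len(eval_words), tuple(sims.keys()), reports
    )
    if cfg.output_dir:
        write_report(study, cfg.output_dir)
    return study


def write_report(study: StudyReport, output_dir: str | Path) -> None:
    """Write report.json plus human-readable CSV tables."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(study.to_dict(), fh, indent=2)
    curves = pd.concat(
        [sw.to_frame() for rep in study.properties.values() for sw in rep.sweeps.values()],
        ignore_index=True,
    )
    curves.to_csv(out / "correlations_by_k.csv", index=False)
    rows = []
    for prop, rep in study.properties.items():
        for label, sw in rep.sweeps.items():
            cr = rep.correlation[label]
            rows.append(
                {
                    "property": prop,
                    "source": label,
                    "n": cr.n,
                    "r": cr.r_rounded,
                    "ci_low": evaluation.round_half_up(cr.ci_low),
                    "ci_high": evaluation.round_half_up(cr.ci_high),
                    "best_k": sw.best_k,
                    "reliability": (
                        evaluation.round_half_up(rep.reliability.reliability)
                        if rep.reliability
                        else None
                    ),
                    "disattenuated_r": (
                        evaluation.round_half_up(rep.disattenuated[label])
                        if label in rep.disattenuated
                        else None
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    preds = []
    for prop, rep in study.properties.items():
        for label, sw in rep.sweeps.items():
            for w, v in sw.predictions_best.items():
                preds.append(
                    {
                        "word": w,
                        "property": prop,
                        "source": label,
                        "k": sw.best_k,
                        "predicted": v,
                    }
                )
    pd.DataFrame(preds).to_csv(out / "predictions.csv", index=False)
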