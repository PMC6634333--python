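"""The statistical evaluation battery for norm-extrapolation studies.

Covers: Pearson correlations with Fisher-z confidence intervals, split-half
reliability with Spearman-Brown correction, correction for attenuation,
residual incremental R-squared between two prediction sources, and tests for
the difference between two correlations — Fisher's z for independent samples
and three published tests for two dependent, overlapping correlations
(Steiger's modified z, Meng-Rosenthal-Rubin, Hittner-May-Silver), of which
the most conservative (largest) p is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how norms papers print values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CorrelationReport:
    r: float
    n: int
    ci_low: float
    ci_high: float

    @property
    def r_rounded(self) -> float:
        return round_half_up(self.r, 2)

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.ci_low <= self.r <= self.ci_high <= 1 + 1e-12):
            raise ValueError("confidence interval must bracket r within [-1, 1]")


@dataclass
class ReliabilityReport:
    property_name: str
    n_randomizations: int
    reliability: float  # mean Spearman-Brown corrected split-half correlation
    values: np.ndarray | None = None  # per-randomization corrected correlations


@dataclass
class ComparisonReport:
    design: str  # "independent" | "dependent-overlapping"
    r1: float
    r2: float
    n: int
    statistics: dict[str, float]  # method name -> z statistic
    p_values: dict[str, float]  # method name -> two-tailed p
    p: float  # the most conservative (largest) p across methods
    n2: int | None = None  # second sample size, independent design only

    @property
    def difference(self) -> float:
        return self.r1 - self.r2


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationReport:
    """Pearson correlation with a Fisher-z confidence interval.

    The CI is atanh(r) +/- z_crit / sqrt(n - 3), back-transformed.  With
    |r| = 1 the interval is degenerate and reported as (r, r).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r = float(stats.pearsonr(x, y).statistic)
    return _fisher_ci_report(r, n, conf)


def _fisher_ci_report(r: float, n: int, conf: float = 0.95) -> CorrelationReport:
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationReport(r, n, r, r)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return CorrelationReport(r, n, float(np.tanh(z - half)), float(np.tanh(z + half)))


def fisher_ci(r: float, n: int, conf: float = 0.95) -> CorrelationReport:
    """Confidence interval for an already-computed correlation."""
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    return _fisher_ci_report(float(r), int(n), conf)


def spearman_brown(r_half: float) -> float:
    """Step up a split-half correlation to full test length: 2r / (1 + r)."""
    if r_half <= -1:
        raise ValueError("Spearman-Brown undefined at r = -1")
    return 2.0 * r_half / (1.0 + r_half)


def split_half_reliability(
    rater_matrix,
    n_randomizations: int = 10_000,
    seed: int = 0,
    property_name: str = "",
    keep_values: bool = False,
) -> ReliabilityReport:
    """Split-half reliability of the mean rating, Spearman-Brown corrected.

    ``rater_matrix`` is raters x words (NaN = missing judgment).  For each
    randomization the raters are split into two random halves (sizes differ
    by one for odd counts); the per-half item means are correlated across
    words and stepped up with the Spearman-Brown formula; the mean over
    randomizations is returned.  Words with an all-missing half are dropped
    for that randomization (logged in aggregate).
    """
    if isinstance(rater_matrix, pd.DataFrame):
        mat = rater_matrix.to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(rater_matrix, dtype=np.float64)
    n_raters, n_words = mat.shape
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if n_words < 4:
        raise ValueError("need at least 4 words")
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    half = n_raters // 2
    out = np.empty(n_randomizations, dtype=np.float64)
    n_dropped = 0
    for i in range(n_randomizations):
        perm = rng.permutation(n_raters)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN halves
            m1 = np.nanmean(mat[perm[:half]], axis=0)
            m2 = np.nanmean(mat[perm[half:]], axis=0)
        ok = ~(np.isnan(m1) | np.isnan(m2))
        n_dropped += int(n_words - ok.sum())
        a, b = m1[ok], m2[ok]
        if len(a) < 4:
            raise ValueError("fewer than 4 words usable in a split")
        if np.std(a) == 0 or np.std(b) == 0:
            # identical raters: halves are equal constants only if the words
            # themselves are constant, which the caller should not feed in
            raise ValueError("undefined split-half correlation: constant half means")
        out[i] = spearman_brown(float(np.corrcoef(a, b)[0, 1]))
    if n_dropped:
        logger.info(
            "split_half_reliability dropped %d word-instances with an all-missing half",
            n_dropped,
        )
    return ReliabilityReport(
        property_name,
        n_randomizations,
        float(out.mean()),
        out if keep_values else None,
    )


def disattenuate(r: float, rel_a: float, rel_b: float = 1.0) -> float:
    """Correct a correlation for attenuation: r / sqrt(rel_a * rel_b).

    For correlations between human ratings and model predictions the
    prediction reliability is conventionally set to one.  Values exceeding 1
    (possible when reliabilities are underestimated) are clipped with a
    warning.
    """
    if not (0 < rel_a <= 1) or not (0 < rel_b <= 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    out = r / np.sqrt(rel_a * rel_b)
    if abs(out) > 1:
        logger.warning("disattenuated correlation %.3f clipped to +/-1", out)
        out = float(np.clip(out, -1.0, 1.0))
    return float(out)


def residual_incremental_r2(human, pred_primary, pred_other) -> float:
    """Variance in the residuals of one source explained by the other.

    Regresses the human means on the primary source's predictions (OLS with
    intercept), then reports the R-squared of the residuals regressed on the
    other source's predictions.
    """
    human = np.asarray(human, dtype=np.float64)
    a = np.asarray(pred_primary, dtype=np.float64)
    b = np.asarray(pred_other, dtype=np.float64)
    if not (human.shape == a.shape == b.shape):
        raise ValueError("inputs must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant predictor")
    resid = sm.OLS(human, sm.add_constant(a)).fit().resid
    return float(sm.OLS(resid, sm.add_constant(b)).fit().rsquared)


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> ComparisonReport:
    """Fisher's z test for correlations from two independent samples."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| = 1 has no Fisher z")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonReport(
        "independent", r1, r2, n1,
        {"fisher_z": float(z)}, {"fisher_z": p}, p, n2=n2,
    )


def _check_psd(r12: float, r13: float, r23: float) -> None:
    corr = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], dtype=float)
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")


def compare_dependent_correlations(
    r_hy1: float, r_hy2: float, r_y1y2: float, n: int
) -> ComparisonReport:
    """Compare two overlapping dependent correlations sharing variable h.

    Tests whether corr(h, y1) differs from corr(h, y2) given corr(y1, y2),
    using three published statistics; the largest (most conservative)
    two-tailed p across them is reported alongside the per-method values.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    for r in (r_hy1, r_hy2, r_y1y2):
        if not -1 <= r <= 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r_hy1) >= 1 or abs(r_hy2) >= 1:
        raise ValueError("|r| = 1 has no Fisher z")
    _check_psd(r_hy1, r_hy2, r_y1y2)
    z1, z2 = np.arctanh(r_hy1), np.arctanh(r_hy2)
    c = r_y1y2

    def _cov_term(rbar_sq: float) -> float:
        # covariance of the two Fisher z's given a pooled squared correlation
        num = c * (1 - 2 * rbar_sq) - 0.5 * rbar_sq * (1 - 2 * rbar_sq - c * c)
        return num / (1 - rbar_sq) ** 2

    stats_out: dict[str, float] = {}
    # Steiger (1980) modified z: pool via the arithmetic mean correlation
    rbar = (r_hy1 + r_hy2) / 2
    s_st = _cov_term(rbar * rbar)
    stats_out["steiger"] = float(
        (z1 - z2) * np.sqrt(n - 3) / np.sqrt(max(2 - 2 * s_st, 1e-12))
    )
    # Hittner-May-Silver: pool via the back-transformed mean Fisher z
    rbar_z = np.tanh((z1 + z2) / 2)
    s_hms = _cov_term(rbar_z * rbar_z)
    stats_out["hittner_may_silver"] = float(
        (z1 - z2) * np.sqrt(n - 3) / np.sqrt(max(2 - 2 * s_hms, 1e-12))
    )
    # Meng-Rosenthal-Rubin
    rsq = (r_hy1 ** 2 + r_hy2 ** 2) / 2
    f = min((1 - c) / (2 * (1 - rsq)), 1.0)
    h = (1 - f * rsq) / (1 - rsq)
    stats_out["meng_rosenthal_rubin"] = float(
        (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - c) * h))
    )
    p_values = {m: float(2 * stats.norm.sf(abs(z))) for m, z in stats_out.items()}
    return ComparisonReport(
        "dependent-overlapping", r_hy1, r_hy2, n,
        stats_out, p_values, max(p_values.values()),
    )
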