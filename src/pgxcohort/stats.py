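"""Nonparametric cohort statistics.

Implements the analysis battery for the pre/post effectiveness
comparison and the genetic-score association:

* paired Wilcoxon signed-rank test with a standardized effect size
  ``r = |Z| / sqrt(N)``, where by default N counts total observations
  (2 x the number of non-zero pairs);
* Spearman rank correlation (mid-ranks for ties, t-approximation p);
* a bootstrap-smoothed ROC curve: per-resample empirical ROC curves
  interpolated onto a fixed FPR grid and averaged, with the AUC taken
  as the trapezoidal area of the averaged curve;
* the descriptive cohort summary table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

#: Effect-size conventions: denominator N in r = |Z| / sqrt(N).
EFFECT_SIZE_CONVENTIONS = ("total_observations", "pairs")

ROC_GRID_POINTS = 101
DEFAULT_N_BOOT = 1000
DEFAULT_ROC_SEED = 20180501
DEFAULT_HIGH_EFFECTIVENESS_THRESHOLD = 8


class DegenerateInputError(ValueError):
    """Input admits no meaningful statistic (all-zero differences,
    constant vector, single-class labels)."""


@dataclass(frozen=True)
class WilcoxonResult:
    n_pairs: int  # non-zero-difference pairs actually ranked
    n_zero_dropped: int
    W_statistic: float
    Z: float
    p_value: float
    effect_size_r: float
    effect_size_convention: str = "total_observations"
    method: str = "approx"

    @property
    def effect_size_label(self) -> str:
        """Cohen's guideline bands 0.1 / 0.3 / 0.5."""
        r = self.effect_size_r
        if r >= 0.5:
            return "large"
        if r >= 0.3:
            return "medium"
        if r >= 0.1:
            return "small"
        return "negligible"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr_grid: tuple[float, ...]
    mean_tpr: tuple[float, ...]
    n_boot: int
    seed: int
    empirical_auc: float


def wilcoxon_paired(
    baseline: Sequence[float],
    followup: Sequence[float],
    effect_size_convention: str = "total_observations",
    method: str = "approx",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on follow-up minus baseline.

    Zero differences are dropped before ranking (signed-rank
    convention, logged). W is the smaller of the positive and negative
    rank sums. In ``approx`` mode Z uses the normal approximation with
    tie-corrected variance and no continuity correction, and the
    two-sided p comes from the normal tail; in ``exact`` mode the p is
    the exact permutation p (no ties supported by the exact null).

    ``effect_size_convention`` selects the denominator of
    r = |Z|/sqrt(N): ``total_observations`` uses N = 2 x pairs,
    ``pairs`` uses N = pairs.
    """
    if effect_size_convention not in EFFECT_SIZE_CONVENTIONS:
        raise ValueError(f"unknown effect size convention {effect_size_convention!r}")
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be equal-length 1-D")
    if len(b) < 5:
        raise ValueError("need at least 5 pairs")
    d = f - b
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d zero-difference pairs", n_dropped)
    d = d[nonzero]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)

    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if sigma2 <= 0:
        raise DegenerateInputError("zero variance after tie correction")
    Z = (W - mu) / math.sqrt(sigma2)

    if method == "exact":
        # exact permutation distribution (valid without ties)
        res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method="exact")
        p = float(res.pvalue)
    elif method == "approx":
        p = float(2.0 * sps.norm.sf(abs(Z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    denom = 2 * n if effect_size_convention == "total_observations" else n
    r = abs(Z) / math.sqrt(denom)
    return WilcoxonResult(
        n_pairs=n,
        n_zero_dropped=n_dropped,
        W_statistic=W,
        Z=Z,
        p_value=min(p, 1.0),
        effect_size_r=r,
        effect_size_convention=effect_size_convention,
        method=method,
    )


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> SpearmanResult:
    """Spearman rank correlation: Pearson on mid-ranks, p from the
    t-approximation with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=len(x))


def empirical_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Empirical AUC of `scores` against binary `labels` (probability
    that a random positive outscores a random negative, ties at 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_bootstrap_smoothed(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_ROC_SEED,
) -> RocResult:
    """Bootstrap-smoothed ROC curve.

    For each of ``n_boot`` class-stratified bootstrap resamples the
    empirical ROC is computed and its TPR interpolated onto a fixed
    101-point FPR grid; the smoothed curve is the pointwise mean and
    the reported AUC is its trapezoidal area. Fully determined by
    ``seed``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("labels contain a single class")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    rng = np.random.default_rng(seed)
    tprs = np.empty((n_boot, ROC_GRID_POINTS))
    for i in range(n_boot):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([bp, bn])
        fpr, tpr, _ = roc_curve(y[idx], s[idx])
        # sample the empirical step function: TPR at the largest
        # achieved FPR <= each grid point
        tprs[i] = tpr[np.searchsorted(fpr, grid, side="right") - 1]
    mean_tpr = tprs.mean(axis=0)
    mean_tpr = np.maximum.accumulate(np.clip(mean_tpr, 0.0, 1.0))
    mean_tpr[-1] = 1.0
    auc = float(np.trapezoid(mean_tpr, grid))
    return RocResult(
        auc=auc,
        fpr_grid=tuple(grid.tolist()),
        mean_tpr=tuple(mean_tpr.tolist()),
        n_boot=n_boot,
        seed=seed,
        empirical_auc=empirical_auc(s, y),
    )


def dichotomize_effectiveness(
    scores: Sequence[float],
    threshold: float = DEFAULT_HIGH_EFFECTIVENESS_THRESHOLD,
) -> np.ndarray:
    """Binary "high effectiveness score" labels: 1 iff score >= threshold."""
    if not 1 <= threshold <= 10:
        raise ValueError("threshold must lie within the score range [1, 10]")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


@dataclass
class CohortSummary:
    """Descriptive summary mirroring the demographics table: counts and
    percentages by sex / ethnicity / profile type, means and SDs (n-1
    denominator) of age, genetic score and effectiveness scores.
    Percentages use the full column denominator, so categories with
    unreported values do not sum to 100%."""

    n: int
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    percents: dict[str, dict[str, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, cats in self.counts.items():
            for cat, cnt in cats.items():
                rows.append((f"{block}: {cat}", f"{cnt} ({self.percents[block][cat]:.1f})"))
        for key, m in self.means.items():
            sd = self.sds.get(key, float("nan"))
            rows.append((f"{key}, mean (SD)", f"{m:.2f} ({sd:.2f})"))
        return pd.DataFrame(rows, columns=["characteristic", "value"])


def summarize_cohort(frame: pd.DataFrame) -> CohortSummary:
    """Summarize a per-patient table with (some of the) columns
    ``sex``, ``ethnicity``, ``profile_type``, ``age``,
    ``genetic_total``, ``baseline_total``, ``followup_total``."""
    n = len(frame)
    summary = CohortSummary(n=n)
    for block in ("sex", "ethnicity", "profile_type"):
        if block in frame.columns:
            counts = frame[block].dropna().value_counts().to_dict()
            summary.counts[block] = {str(k): int(v) for k, v in counts.items()}
            summary.percents[block] = {
                str(k): 100.0 * v / n for k, v in counts.items()
            }
    for key in ("age", "genetic_total", "baseline_total", "followup_total"):
        if key in frame.columns:
            v = frame[key].dropna()
            if v.empty:
                continue
            summary.means[key] = float(v.mean())
            summary.sds[key] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return summary
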