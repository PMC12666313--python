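"""Concordance between organoid sensitivity calls and patient outcomes.

Covers the diagnostic-accuracy toolbox used to compare ex vivo screens with
clinical response: 2x2 contingency summaries with positive/negative
predictive values and Wilson score intervals, empirical ROC curves with
DeLong confidence intervals, Pearson correlation, two/three-group
nonparametric comparisons (rank-sum; Kruskal-Wallis with Dunn-Bonferroni
post hocs), the expected-count rule for choosing Fisher vs chi-square,
simple percent agreement, and enrollment arithmetic under dropout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateLabelsError, DomainError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """PDO call vs patient response: sensitive∧decrease = tp,
    sensitive∧increase = fp, resistant∧decrease = fn, resistant∧increase = tn."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValidationError("contingency table is empty")

    @classmethod
    def from_calls(
        cls, pdo_sensitive: Sequence[bool], patient_decrease: Sequence[bool]
    ) -> "ContingencyTable":
        s = np.asarray(pdo_sensitive, dtype=bool)
        d = np.asarray(patient_decrease, dtype=bool)
        if s.shape != d.shape:
            raise ValidationError("call vectors differ in length")
        return cls(
            tp=int(np.sum(s & d)),
            fp=int(np.sum(s & ~d)),
            fn=int(np.sum(~s & d)),
            tn=int(np.sum(~s & ~d)),
        )


@dataclass(frozen=True)
class DiagnosticPerformance:
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    auroc: float | None
    auroc_ci: tuple[float, float] | None
    n: int


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1:
        raise DomainError("n must be at least 1")
    if not 0 <= k <= n:
        raise DomainError("k must lie in [0, n]")
    low, high = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # the score interval hits the boundary exactly at k = 0 / k = n; keep it
    # free of floating-point dust
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return float(low), float(high)


def diagnostic_performance(
    table: ContingencyTable, conf: float = 0.95
) -> DiagnosticPerformance:
    """PPV and NPV of the sensitivity call, each with a Wilson interval."""
    n_pos = table.tp + table.fp
    n_neg = table.fn + table.tn
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both predicted-positive and predicted-negative margins needed")
    return DiagnosticPerformance(
        ppv=table.tp / n_pos,
        ppv_ci=wilson_interval(table.tp, n_pos, conf),
        npv=table.tn / n_neg,
        npv_ci=wilson_interval(table.tn, n_neg, conf),
        auroc=None,
        auroc_ci=None,
        n=n_pos + n_neg,
    )


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # V10[i] = P(neg < pos_i) with ties at 1/2; V01[j] symmetric
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def empirical_roc(
    scores: Sequence[float], labels: Sequence[int], conf: float = 0.95
) -> dict:
    """Empirical ROC of a sensitivity score against a binary response.

    `scores` are normalized GR_AUC-like values where LOWER means more likely
    responder; they are negated internally so the reported AUROC is the
    Mann-Whitney probability that a responder scores lower than a
    nonresponder (ties counted 1/2). CI by the DeLong method, clipped to
    [0, 1].
    """
    y = np.asarray(labels, dtype=int)
    x = -np.asarray(scores, dtype=float)  # higher = more responder-like
    if x.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("both responder and nonresponder labels required")
    pos, neg = x[y == 1], x[y == 0]
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    auc = float((greater + 0.5 * ties) / (len(pos) * len(neg)))

    # empirical ROC points, one per unique threshold (ties collapsed)
    thresholds = np.unique(x)[::-1]
    tpr = np.concatenate([[0.0], [np.mean(pos >= t) for t in thresholds]])
    fpr = np.concatenate([[0.0], [np.mean(neg >= t) for t in thresholds]])

    se = float(np.sqrt(_delong_variance(x, y, auc)))
    z = stats.norm.ppf(0.5 + conf / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return {"fpr": fpr, "tpr": tpr, "auroc": auc, "auroc_ci": ci, "se": se}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DomainError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> dict[tuple[str, str], float]:
    """Dunn pairwise z-tests on shared ranks, Bonferroni-multiplied p-values."""
    levels = sorted(set(groups.tolist()))
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term of the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    sizes = {g: int(np.sum(groups == g)) for g in levels}
    m = len(levels) * (len(levels) - 1) // 2
    out = {}
    for a, b in combinations(levels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        zstat = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(zstat))
        out[(a, b)] = min(1.0, m * p)
    return out


def group_compare(values: Sequence[float], groups: Sequence[str]) -> dict:
    """Two groups: two-sided Mann-Whitney rank-sum; three or more:
    Kruskal-Wallis (tie-corrected) followed by Dunn-Bonferroni post hocs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise DomainError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise DomainError("every group must be non-empty")
    if len(levels) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {
            "test": "mann-whitney",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "posthoc": {},
        }
    if np.ptp(values) == 0:
        return {"test": "kruskal-wallis", "statistic": 0.0, "p": 1.0, "posthoc": {}}
    res = stats.kruskal(*samples)
    return {
        "test": "kruskal-wallis",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "posthoc": _dunn_posthoc(values, groups),
    }


def categorical_test(table: Sequence[Sequence[int]]) -> dict:
    """Fisher exact for sparse 2x2 tables, chi-square otherwise.

    Expected counts decide: if any expected cell count is below 10 and the
    table is 2x2, the two-sided Fisher exact test is used; otherwise a
    chi-square test without continuity correction. Larger sparse tables fall
    back to chi-square with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise DomainError("table must be a 2-D array of non-negative counts")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise DomainError("table has an empty row or column")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    sparse = bool((expected < 10).any())
    if sparse and t.shape == (2, 2):
        _, p = stats.fisher_exact(t)
        return {"test": "fisher", "p": float(p), "min_expected": float(expected.min())}
    if sparse:
        logger.warning(
            "expected count below 10 in a %dx%d table; Fisher limited to 2x2, "
            "falling back to chi-square",
            *t.shape,
        )
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return {
        "test": "chi-square",
        "statistic": float(chi2),
        "p": float(p),
        "min_expected": float(expected.min()),
    }


def concordance_rate(calls_a: Sequence, calls_b: Sequence) -> float:
    """Percent agreement between two equal-length call vectors."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("call vectors must be non-empty and equal length")
    return float(100.0 * np.mean(a == b))


def required_enrollment(n_evaluable: int, dropout: float) -> int:
    """Enrollment needed for a target evaluable count under a dropout rate,
    rounded to the nearest integer."""
    if not 0.0 <= dropout < 1.0:
        raise DomainError("dropout must lie in [0, 1)")
    if n_evaluable < 1:
        raise DomainError("need at least one evaluable subject")
    return int(round(n_evaluable / (1.0 - dropout)))
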