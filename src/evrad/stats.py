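"""Nonparametric association tests and the univariate ROC with Youden cut-point.

Thin, validated wrappers over the scipy implementations, plus the ROC
summary used throughout the response analyses: the AUC of a single
continuous predictor (identical to the concordance probability
U / (n_pos * n_neg), and to the ROC of a monotone one-covariate logistic
model) together with the cut-point maximizing Youden's J = sensitivity +
specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Mann-Whitney switches to an exact/exhaustive-permutation null at or
#: below this per-group size, and to the tie-corrected normal
#: approximation above it.
EXACT_MAX_N = 10


def mann_whitney_u(
    values_a: np.ndarray, values_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum U statistic (group A) and p-value.

    Exact null (full permutation enumeration when ties are present) for
    groups of at most 10 each; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        if has_ties:
            # scipy's closed-form exact null assumes no ties; enumerate instead
            method = sps.PermutationMethod(n_resamples=np.inf)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(flat).size == 1:
        return 0.0, 1.0  # scipy raises on all-identical values; H is 0 by definition
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of independence, no continuity correction."""
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.number) or (t < 0).any():
        raise ValidationError("table must hold nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("table has an all-zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ROCResult:
    """ROC summary of one continuous predictor against a binary outcome."""

    auc: float
    cutpoint: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int


def univariate_roc(
    predictor: np.ndarray, outcome: np.ndarray, direction: str = "greater"
) -> ROCResult:
    """Full-sweep ROC of a single predictor with the Youden cut-point.

    ``direction='greater'`` means larger predictor values indicate the
    positive class ('less' flips the sign). The AUC equals the
    Mann-Whitney concordance probability U/(n_pos*n_neg); the cut-point
    maximizes sensitivity + specificity - 1 over all observed thresholds
    (prediction rule: positive iff predictor >= cut-point, on the
    oriented scale). Ties in J are broken toward the smallest threshold.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome).astype(int)
    if x.size != y.size:
        raise ValidationError("predictor and outcome lengths differ")
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("outcome must contain both classes (0 and 1)")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    sign = 1.0 if direction == "greater" else -1.0
    xo = sign * x
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)

    # AUC via the rank (concordance) identity
    ranks = sps.rankdata(xo)
    u_stat = float(ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
    auc = u_stat / (n_pos * n_neg)

    thresholds = np.unique(xo)
    best_j, best_thr, best = -np.inf, thresholds[0], (0.0, 0.0, 0.0)
    for thr in thresholds:
        pred = xo >= thr
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_thr = j, thr
            best = (sens, spec, (tp + tn) / y.size)
    return ROCResult(
        auc=float(auc),
        cutpoint=float(sign * best_thr),
        sensitivity=best[0],
        specificity=best[1],
        accuracy=best[2],
        n_pos=n_pos,
        n_neg=n_neg,
    )
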