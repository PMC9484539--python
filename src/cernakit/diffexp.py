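"""Negative-binomial differential expression and dysregulation calls.

The test models counts k_ij ~ NB(mu_ij, alpha_i) with
log mu_ij = log s_j + beta0_i + beta1_i * 1[j in tumor], i.e. a
two-group NB GLM with log link and size-factor offsets. For this
design the likelihood separates per group into a single scalar mean
parameter, so the MLE is found by a vectorised Newton solve of the
score equation

    sum_j (k_j - s_j m) / (1 + alpha s_j m) = 0

per group, and the Wald variance of the log fold change is
1/I_tumor + 1/I_normal with Fisher information
I_g = sum_j mu_j / (1 + alpha mu_j). The per-feature dispersion alpha
is a method-of-moments estimate on normalized counts, pooled within
groups and floored at 1e-8. The Wald statistic is referred to a
t distribution with n - 2 degrees of freedom, the usual small-sample
reference when the dispersion is estimated rather than known.

Dysregulation calls use strict inequalities throughout: a feature is
"up" iff padj < padj_cut and log2fc > log2(fc_cut), "down" iff
padj < padj_cut and log2fc < -log2(fc_cut).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, ValidationError
from .preprocess import size_factors as _size_factors

_DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


def _mom_dispersion(q: np.ndarray, groups: list) -> np.ndarray:
    """Per-feature MoM dispersion from normalized counts, within groups.

    alpha solves var = mu + alpha * mu^2 with the pooled within-group
    variance and the mean of the group means; clipped at the floor.
    """
    n_total = sum(len(g) for g in groups)
    ss = np.zeros(q.shape[0])
    mu_parts = []
    for idx in groups:
        sub = q[:, idx]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        mu_parts.append(m)
    pooled_var = ss / max(n_total - len(groups), 1)
    mu = np.mean(mu_parts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    return np.clip(alpha, _DISPERSION_FLOOR, None)


def _group_mean_mle(k: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                    n_iter: int = 50) -> np.ndarray:
    """Vectorised Newton solve for the per-group NB mean parameter m.

    k: (features, samples) counts of one group; s: (samples,) size
    factors; alpha: (features,) dispersions. Returns m with
    mu_j = s_j * m. The score function is strictly decreasing in m, so
    Newton from the Poisson MLE converges monotonically.
    """
    m = k.sum(axis=1) / s.sum()  # Poisson MLE; exact when alpha=0
    zero = m <= 0
    m = np.where(zero, 1.0, m)  # placeholder, flagged by caller
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * m[:, None]
        denom = 1.0 + a * mu
        f = ((k - mu) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + a * k) / denom**2).sum(axis=1)
        step = f / fp
        m_new = m - step
        m_new = np.where(m_new <= 0, m / 2.0, m_new)
        if np.all(np.abs(m_new - m) <= 1e-12 * np.maximum(m, 1.0)):
            m = m_new
            break
        m = m_new
    return np.where(zero, 0.0, m)


def nb_wald_test(
    matrix: ExpressionMatrix,
    condition: str = "condition",
    group_a: str = "tumor",
    group_b: str = "normal",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group_a vs group_b.

    Returns a DataFrame indexed by feature with columns ``base_mean``,
    ``log2fc`` (group_a over group_b), ``se``, ``p``, ``degenerate``.
    Features with all-zero counts get p=1, log2fc=0 and the degenerate
    flag; features with one all-zero group get a moment-based fold
    change (half-count continuity correction) and are also flagged.
    """
    labels = matrix.sample_meta[condition]
    idx_a = np.flatnonzero((labels == group_a).to_numpy())
    idx_b = np.flatnonzero((labels == group_b).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("need at least 2 samples per group")
    if factors is None:
        factors = _size_factors(matrix)
    s = factors.reindex(matrix.sample_ids).to_numpy(dtype=float)
    k = matrix.values.to_numpy(dtype=float)
    q = k / s[None, :]
    alpha = _mom_dispersion(q, [idx_a, idx_b])

    m_a = _group_mean_mle(k[:, idx_a], s[idx_a], alpha)
    m_b = _group_mean_mle(k[:, idx_b], s[idx_b], alpha)

    zero_a, zero_b = m_a == 0, m_b == 0
    all_zero = zero_a & zero_b
    degenerate = zero_a | zero_b
    # continuity-corrected means for one-sided-zero features
    cc_a = (k[:, idx_a].sum(axis=1) + 0.5) / s[idx_a].sum()
    cc_b = (k[:, idx_b].sum(axis=1) + 0.5) / s[idx_b].sum()
    m_a_eff = np.where(zero_a, cc_a, m_a)
    m_b_eff = np.where(zero_b, cc_b, m_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = (np.log(m_a_eff) - np.log(m_b_eff)) / _LN2
        mu_a = s[idx_a][None, :] * m_a_eff[:, None]
        mu_b = s[idx_b][None, :] * m_b_eff[:, None]
        info_a = (mu_a / (1.0 + alpha[:, None] * mu_a)).sum(axis=1)
        info_b = (mu_b / (1.0 + alpha[:, None] * mu_b)).sum(axis=1)
        var_beta = 1.0 / info_a + 1.0 / info_b
    se = np.sqrt(var_beta) / _LN2
    df_resid = len(idx_a) + len(idx_b) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    p = np.where(degenerate, np.where(all_zero, 1.0, p), p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    return pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "degenerate": degenerate,
        },
        index=matrix.feature_ids,
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_padj(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out


def direction_calls(
    results: pd.DataFrame, padj_cut: float, fc_cut: float
) -> pd.Series:
    """Per-feature direction label: up / down / ns (strict cuts)."""
    if "padj" not in results:
        results = attach_padj(results)
    lfc_cut = np.log2(fc_cut)
    sig = results["padj"] < padj_cut
    up = sig & (results["log2fc"] > lfc_cut)
    down = sig & (results["log2fc"] < -lfc_cut)
    out = pd.Series("ns", index=results.index, name="direction")
    out[up] = "up"
    out[down] = "down"
    return out


def call_dysregulated(
    results: pd.DataFrame, padj_cut: float = 0.1, fc_cut: float = 2.0
) -> tuple:
    """(up set, down set) at strict padj and fold-change cuts."""
    d = direction_calls(results, padj_cut, fc_cut)
    return set(d.index[d == "up"]), set(d.index[d == "down"])


def wilcoxon_two_group(values, labels) -> float:
    """Two-sided rank-sum p-value with mid-rank ties.

    Exact null distribution is used when there are no ties and both
    groups are small; otherwise the normal approximation with tie
    correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValidationError("exactly two group labels required")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)
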