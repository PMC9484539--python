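"""Co-expression gene-set enrichment for a query feature.

Every other gene is ranked by its Pearson correlation with the query
across all samples, and gene sets are scored on that ranking with the
weighted Kolmogorov–Smirnov running-sum statistic: walking down the
list, hits increment the sum by |score|^p / sum_set |score|^p and
misses decrement it by 1/(N - N_hit); the enrichment score (ES) is the
signed maximum deviation from zero, always in [-1, 1].

Significance uses gene-set permutation — random sets of matched size
drawn from the ranked universe — which is the standard preranked
convention (phenotype permutation is undefined when the ranking metric
is a correlation with a single query feature). The p-value is
estimated from the same-sign portion of the null, with add-one
smoothing in both numerator and denominator so it is never zero and
stays uniform under the null; NES divides ES by the mean same-sign
null |ES|; FDR follows the sign-stratified null-ratio convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError


def correlation_rank(
    expression: ExpressionMatrix, query_feature: str
) -> pd.Series:
    """Rank all other genes by Pearson correlation with the query.

    Returns a Series (index gene, values signed correlation) sorted
    descending, ties broken by lexicographic gene id. Zero-variance
    genes score 0; a zero-variance query is an error.
    """
    V = expression.values
    if query_feature not in V.index:
        raise ValidationError(f"query {query_feature!r} not in matrix")
    if V.shape[1] < 4:
        raise ValidationError("correlation ranking needs >= 4 samples")
    q = V.loc[query_feature].to_numpy(dtype=float)
    if q.std() == 0:
        raise ValidationError(f"query {query_feature!r} has zero variance")
    others = V.drop(index=query_feature)
    X = others.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    qc = q - q.mean()
    denom = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((qc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ qc) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    out = pd.DataFrame({"score": r}, index=others.index)
    out = out.sort_values(
        by=["score"], ascending=False, kind="mergesort"
    )
    # stable second key: lexicographic id among equal scores
    out = (
        out.reset_index()
        .sort_values(by=["score", "index"], ascending=[False, True],
                     kind="mergesort")
        .set_index("index")
    )
    return out["score"].rename(None)


def _running_sum(
    scores: np.ndarray, hit: np.ndarray, weight_p: float
) -> np.ndarray:
    n = len(scores)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("gene set has no genes in the ranked list")
    if n_hit == n:
        raise ValidationError(
            "gene set covers the whole ranked list (miss mass undefined)"
        )
    w = np.abs(scores) ** weight_p
    hit_mass = np.where(hit, w, 0.0)
    total = hit_mass.sum()
    if total == 0:
        hit_mass = hit.astype(float)
        total = hit_mass.sum()
    inc = hit_mass / total
    dec = np.where(hit, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(inc - dec)


def enrichment_score(
    ranked: pd.Series, gene_set, weight_p: float = 1.0
) -> tuple:
    """ES, running profile and leading edge for one gene set.

    ``ranked``: ordered Series from :func:`correlation_rank` (or any
    descending score list). The leading edge comprises the set genes at
    or before the extremum for positive ES, and at or after it for
    negative ES.
    """
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    gene_set = set(gene_set)
    hit = np.isin(ids, list(gene_set))
    running = _running_sum(scores, hit, weight_p)
    absr = np.abs(running)
    # earliest extremum within numerical tolerance (deterministic ties)
    i_ext = int(np.flatnonzero(absr >= absr.max() - 1e-12)[0])
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(ids[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(ids[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


@dataclass
class GSEAResult:
    set_id: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list


def gsea_significance(
    ranked: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Permutation significance for many gene sets on one ranking.

    Returns a DataFrame indexed by set id with columns ``es``, ``nes``,
    ``p``, ``fdr``, ``size``, ``leading_edge``. Sets with fewer than
    ``min_size`` genes in the ranked list are skipped with a warning.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n = len(ids)
    id_set = set(ids)

    observed = {}
    leading = {}
    sizes = {}
    for sid, genes in gene_sets.items():
        present = [g for g in genes if g in id_set]
        if len(present) < min_size:
            warnings.warn(
                f"gene set {sid!r}: only {len(present)} genes in the "
                f"ranking (< {min_size}); skipped"
            )
            continue
        es, _, le = enrichment_score(ranked, present, weight_p)
        observed[sid] = es
        leading[sid] = le
        sizes[sid] = len(present)
    if not observed:
        return pd.DataFrame(
            columns=["es", "nes", "p", "fdr", "size", "leading_edge"]
        )

    # one null ensemble per distinct set size
    null_by_size = {}
    for m in sorted(set(sizes.values())):
        es_null = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=m, replace=False)] = True
            running = _running_sum(scores, hit, weight_p)
            es_null[b] = running[np.argmax(np.abs(running))]
        null_by_size[m] = es_null

    rows = []
    all_null_nes = []
    for sid, es in observed.items():
        es_null = null_by_size[sizes[sid]]
        same_sign = es_null[np.sign(es_null) == np.sign(es)] if es != 0 \
            else es_null
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (len(same_sign) + 1.0)
        pos_mean = np.abs(es_null[es_null > 0]).mean() if (es_null > 0).any() else np.nan
        neg_mean = np.abs(es_null[es_null < 0]).mean() if (es_null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null = np.where(
                es_null >= 0, es_null / pos_mean, es_null / neg_mean
            )
        all_null_nes.append(nes_null[np.isfinite(nes_null)])
        rows.append({"set_id": sid, "es": es, "nes": nes, "p": p,
                     "size": sizes[sid], "leading_edge": leading[sid]})

    df = pd.DataFrame(rows).set_index("set_id")
    pooled_null = np.concatenate(all_null_nes)
    obs_nes = df["nes"].to_numpy()
    fdrs = []
    for nes in obs_nes:
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            null_frac = np.mean((pooled_null >= 0) & (pooled_null >= nes)) / \
                max(np.mean(pooled_null >= 0), 1e-12)
            obs_frac = np.mean((obs_nes >= 0) & (obs_nes >= nes)) / \
                max(np.mean(obs_nes >= 0), 1e-12)
        else:
            null_frac = np.mean((pooled_null < 0) & (pooled_null <= nes)) / \
                max(np.mean(pooled_null < 0), 1e-12)
            obs_frac = np.mean((obs_nes < 0) & (obs_nes <= nes)) / \
                max(np.mean(obs_nes < 0), 1e-12)
        fdrs.append(min(null_frac / obs_frac, 1.0) if obs_frac > 0 else np.nan)
    df["fdr"] = fdrs
    return df[["es", "nes", "p", "fdr", "size", "leading_edge"]]
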