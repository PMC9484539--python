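"""Nearest-template prediction (NTP) for single-sample classification.

Each class is a signed signature: a list of (gene, +1/-1) marker
genes. A sample is assigned to the class whose signed template vector
is nearest in cosine distance to the sample's standardized expression
over the template's genes:

    d(sample, class) = 1 - cos(z, t),   z = zscore(expr[genes]),
                                        t = signs in {+1, -1}

Significance is resampling-based: the observed distance to the
predicted class is compared with distances to ``n_perm`` random
templates of the same size and sign pattern drawn from the genes
present in the matrix; p = (1 + #{d_rand <= d_obs}) / (n_perm + 1).
False-discovery rates are Benjamini–Hochberg across samples, and a
call is confident when fdr < the prognosis FDR cut (default 0.05).

Distance is invariant to affine rescaling of the sample vector
(z-scoring plus the cosine); argmin ties break to the first class in
the template list and are never confident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import adjust_bh
from .matrix import ExpressionMatrix, ValidationError


@dataclass
class TemplateSignature:
    """A class label with signed marker genes."""

    class_label: str
    genes: list  # list of (gene_id, sign in {+1, -1})

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValidationError(
                f"template {self.class_label}: needs >= 2 genes"
            )
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"template {self.class_label}: repeated gene"
            )
        for g, s in self.genes:
            if s not in (1, -1):
                raise ValidationError(
                    f"template {self.class_label}: sign for {g} must be +1/-1"
                )


def _cosine_distance(z: np.ndarray, t: np.ndarray) -> float:
    denom = np.linalg.norm(z) * np.linalg.norm(t)
    if denom == 0:
        return np.nan
    return float(1.0 - np.dot(z, t) / denom)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


def ntp_classify(
    matrix: ExpressionMatrix,
    templates: list,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_cut: float = 0.05,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Classify every sample against signed templates.

    Returns a DataFrame indexed by sample with columns ``predicted``,
    ``distance``, ``p``, ``fdr``, ``confident``. Samples with zero
    variance over a template's genes are left unclassified (NaN row)
    with a warning. A template with fewer than ``min_coverage`` of its
    genes present in the matrix is an error.
    """
    if not templates:
        raise ValidationError("no templates supplied")
    rng = np.random.default_rng(seed)
    V = matrix.values
    present_genes = []
    signs = []
    for t in templates:
        pres = [(g, s) for g, s in t.genes if g in V.index]
        if len(pres) < min_coverage * len(t.genes):
            raise ValidationError(
                f"template {t.class_label}: only {len(pres)}/{len(t.genes)} "
                f"genes present (< {min_coverage:.0%})"
            )
        present_genes.append([g for g, _ in pres])
        signs.append(np.array([s for _, s in pres], dtype=float))

    # observed distances: (n_classes, n_samples)
    n_samples = matrix.n_samples
    dist = np.full((len(templates), n_samples), np.nan)
    sample_mats = []
    for ci, (genes, t_vec) in enumerate(zip(present_genes, signs)):
        sub = V.loc[genes].to_numpy()  # (m, n_samples)
        sample_mats.append(sub)
        for j in range(n_samples):
            z = _zscore(sub[:, j])
            if np.isnan(z).any():
                continue
            dist[ci, j] = _cosine_distance(z, t_vec)

    # null distances per class: random same-size signed templates
    all_genes = V.to_numpy()
    n_features = all_genes.shape[0]
    null_dist = []  # per class: (n_perm, n_samples)
    for genes, t_vec in zip(present_genes, signs):
        m = len(genes)
        idx = np.stack(
            [rng.choice(n_features, size=m, replace=False)
             for _ in range(n_perm)]
        )
        sub = all_genes[idx]  # (n_perm, m, n_samples)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (sub - mean) / sd
        num = np.einsum("pms,m->ps", np.nan_to_num(z), t_vec)
        norm_z = np.sqrt(np.nansum(z**2, axis=1))
        norm_t = np.linalg.norm(t_vec)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = num / (norm_z * norm_t)
        null_dist.append(1.0 - cos)

    rows = []
    for j, sample in enumerate(matrix.sample_ids):
        col = dist[:, j]
        if np.isnan(col).all():
            warnings.warn(
                f"sample {sample!r}: zero variance over signature genes; "
                "left unclassified"
            )
            rows.append((sample, None, np.nan, np.nan))
            continue
        ci = int(np.nanargmin(col))
        d_obs = col[ci]
        nd = null_dist[ci][:, j]
        p = (1.0 + np.sum(nd <= d_obs)) / (n_perm + 1.0)
        rows.append((sample, templates[ci].class_label, d_obs, p))

    out = pd.DataFrame(
        rows, columns=["sample_id", "predicted", "distance", "p"]
    ).set_index("sample_id")
    classified = out["p"].notna()
    fdr = pd.Series(np.nan, index=out.index)
    if classified.any():
        fdr[classified] = adjust_bh(out.loc[classified, "p"].to_numpy())
    out["fdr"] = fdr
    out["confident"] = out["fdr"] < fdr_cut
    return out
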