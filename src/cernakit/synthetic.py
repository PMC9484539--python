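"""Ground-truth cohort generation for every pipeline stage.

The generator emulates the statistical structure the analysis assumes
in a paired tumor/normal RNA-seq cohort:

* counts are negative binomial, k ~ NB(mu_i * s_j, alpha), with
  per-sample size factors s_j drawn log-normal(0, 0.2) so that
  median-of-ratios normalization is exercised non-trivially;
* a planted fraction of features per biotype carries a tumor-mean
  shift of +/- log2fc_magnitude (log2 scale);
* sponge modules couple one ncRNA sponge (lncRNA or circRNA,
  alternating), several miRNAs and one mRNA through a shared standard
  normal latent factor L_j added on the log2-mean scale with loading
  +sponge_effect on sponge and mRNA and -sponge_effect on the miRNAs,
  the simplest mechanism producing the sign pattern the ceRNA filters
  assume (miRNA anti-correlated with both, sponge-mRNA positively
  correlated); module members are additionally planted as dysregulated
  (sponge and mRNA up, miRNAs down) so they survive the
  opposite-direction filter;
* tumor samples optionally belong to subclasses whose signed signature
  genes are shifted by +/- subclass_shift;
* tumor samples carry a standard normal prognostic score: a few
  lncRNAs are shifted proportionally to it, and survival times are
  Weibull with log hazard linear in the score; censoring replaces the
  event time with a uniform fraction of it with probability
  censor_rate.

Everything is driven by one seeded generator: identical configs give
bit-identical cohorts. Sequence and annotation substrates derive their
streams from seed+1 and seed+2 so each operation is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circ_annot import CircJunction
from .config import SimulationConfig
from .matrix import ExpressionMatrix
from .ntp import TemplateSignature
from .target_pred import MicroRNA, TargetSite, revcomp

_PREFIX = {"mRNA": "mRNA", "lncRNA": "lnc", "circRNA": "circ", "miRNA": "mir"}
_RNA_BASES = np.array(list("ACGU"))


class SizingError(ValueError):
    """Requested planted structure exceeds the available features."""


@dataclass
class SpongeModule:
    sponge: str
    sponge_class: str
    mirnas: list
    mrna: str

    @property
    def triplets(self) -> list:
        return [(self.sponge, m, self.mrna) for m in self.mirnas]


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix
    truth_de: set  # {(feature_id, 'up'/'down')}
    truth_triplets: list  # [(sponge, mirna, mrna)]
    sponge_modules: list
    truth_subclass: dict  # sample -> label (tumor samples)
    templates: list  # TemplateSignature per subclass
    survival: pd.DataFrame  # index sample; time, event (tumor samples)
    truth_score: pd.Series  # planted prognostic score per tumor sample
    prognostic_features: list
    true_size_factors: pd.Series


def nb_sample(rng: np.random.Generator, mu, alpha: float) -> np.ndarray:
    """NB(mu, alpha) counts with var = mu + alpha mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(r, p)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort with planted ground truth (see module doc)."""
    rng = np.random.default_rng(config.seed)
    nfb = config.n_features_by_biotype

    features, biotypes = [], []
    pools = {}
    for bt in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        ids = [f"{_PREFIX[bt]}_{i:04d}" for i in range(nfb.get(bt, 0))]
        pools[bt] = ids
        features.extend(ids)
        biotypes.extend([bt] * len(ids))
    n_feat = len(features)
    feat_pos = {f: i for i, f in enumerate(features)}

    n = config.n_pairs
    tumors = [f"T{i + 1:02d}" for i in range(n)]
    normals = [f"N{i + 1:02d}" for i in range(n)]
    samples = tumors + normals
    tumor_idx = np.arange(n)

    # sponge modules -------------------------------------------------------
    m_per = config.mirnas_per_triplet
    n_mod = config.n_sponge_triplets
    n_lnc_sponges = (n_mod + 1) // 2
    n_circ_sponges = n_mod // 2
    if n_lnc_sponges > len(pools["lncRNA"]) or n_circ_sponges > len(pools["circRNA"]):
        raise SizingError("not enough lncRNA/circRNA features for sponges")
    if n_mod * m_per > len(pools["miRNA"]):
        raise SizingError("not enough miRNA features for sponge modules")
    if n_mod > len(pools["mRNA"]):
        raise SizingError("not enough mRNA features for sponge modules")
    lnc_pick = rng.choice(len(pools["lncRNA"]), n_lnc_sponges, replace=False)
    circ_pick = rng.choice(len(pools["circRNA"]), n_circ_sponges, replace=False)
    mir_pick = rng.choice(len(pools["miRNA"]), n_mod * m_per, replace=False)
    mrna_pick = rng.choice(len(pools["mRNA"]), n_mod, replace=False)
    modules = []
    li = ci = 0
    for i in range(n_mod):
        if i % 2 == 0:
            sponge = pools["lncRNA"][lnc_pick[li]]
            cls = "lncRNA"
            li += 1
        else:
            sponge = pools["circRNA"][circ_pick[ci]]
            cls = "circRNA"
            ci += 1
        mirnas = [pools["miRNA"][j] for j in mir_pick[i * m_per:(i + 1) * m_per]]
        modules.append(
            SpongeModule(sponge, cls, mirnas, pools["mRNA"][mrna_pick[i]])
        )
    module_members = {
        f for mod in modules for f in [mod.sponge, mod.mrna, *mod.mirnas]
    }

    # baseline means and planted dysregulation -----------------------------
    lo, hi = config.base_log2_mu_range
    base_log2 = rng.uniform(lo, hi, size=n_feat)
    log2mu = np.tile(base_log2[:, None], (1, 2 * n))

    truth_de: set = set()
    if config.de_fraction > 0:
        for bt, ids in pools.items():
            free = [f for f in ids if f not in module_members]
            n_de = int(round(config.de_fraction * len(ids)))
            n_de = min(n_de, len(free))
            if n_de == 0:
                continue
            chosen = rng.choice(len(free), n_de, replace=False)
            dirs = rng.choice([1, -1], n_de)
            for j, d in zip(chosen, dirs):
                f = free[j]
                log2mu[feat_pos[f], :n] += d * config.log2fc_magnitude
                truth_de.add((f, "up" if d > 0 else "down"))
        # module members are dysregulated by construction
        for mod in modules:
            for f in (mod.sponge, mod.mrna):
                log2mu[feat_pos[f], :n] += config.log2fc_magnitude
                truth_de.add((f, "up"))
            for f in mod.mirnas:
                log2mu[feat_pos[f], :n] -= config.log2fc_magnitude
                truth_de.add((f, "down"))

    # shared latent factor per sample (sponge coupling) --------------------
    latent = rng.standard_normal(2 * n)
    for mod in modules:
        log2mu[feat_pos[mod.sponge]] += config.sponge_effect * latent
        log2mu[feat_pos[mod.mrna]] += config.sponge_effect * latent
        for f in mod.mirnas:
            log2mu[feat_pos[f]] -= config.sponge_effect * latent

    # subclasses -----------------------------------------------------------
    truth_subclass: dict = {}
    templates: list = []
    subclass_sizes = config.subclass_sizes or {}
    total_sub = sum(subclass_sizes.values())
    if total_sub > 0:
        if total_sub > n:
            raise SizingError("subclass sizes exceed the tumor sample count")
        order = rng.permutation(n)
        cursor = 0
        sig_pool = [
            f for f in pools["mRNA"]
            if f not in module_members
        ]
        if len(subclass_sizes) * config.n_signature_genes > len(sig_pool):
            raise SizingError("not enough mRNA features for signatures")
        sig_pick = rng.choice(
            len(sig_pool),
            len(subclass_sizes) * config.n_signature_genes,
            replace=False,
        )
        for ci_, (label, size) in enumerate(subclass_sizes.items()):
            members = [tumors[order[cursor + i]] for i in range(size)]
            cursor += size
            genes = [
                sig_pool[j]
                for j in sig_pick[
                    ci_ * config.n_signature_genes:(ci_ + 1) * config.n_signature_genes
                ]
            ]
            signs = rng.choice([1, -1], len(genes))
            templates.append(
                TemplateSignature(label, list(zip(genes, (int(s) for s in signs))))
            )
            for s_name in members:
                truth_subclass[s_name] = label
                col = samples.index(s_name)
                for g, sg in zip(genes, signs):
                    log2mu[feat_pos[g], col] += config.subclass_shift * sg

    # prognostic score and survival ----------------------------------------
    score = rng.standard_normal(n)
    prognostic = []
    if config.n_prognostic > 0:
        free_lnc = [
            f for f in pools["lncRNA"] if f not in module_members
        ]
        if config.n_prognostic > len(free_lnc):
            raise SizingError("not enough lncRNA features for prognostic set")
        picks = rng.choice(len(free_lnc), config.n_prognostic, replace=False)
        prognostic = [free_lnc[j] for j in picks]
        for f in prognostic:
            log2mu[feat_pos[f], tumor_idx] += config.prognostic_coef * score
    shape = config.survival_shape
    e = rng.exponential(1.0, n)
    t_event = config.survival_baseline_scale * (
        e / np.exp(config.survival_effect * score)
    ) ** (1.0 / shape)
    cens = rng.uniform(size=n) < config.censor_rate
    frac = rng.uniform(size=n)
    time = np.where(cens, np.maximum(t_event * frac, 1e-8), t_event)
    event = (~cens).astype(int)
    surv = pd.DataFrame({"time": time, "event": event}, index=tumors)
    surv.index.name = "sample"

    # draw counts ----------------------------------------------------------
    s_true = rng.lognormal(0.0, config.size_factor_sigma, size=2 * n)
    mu = (2.0**log2mu) * s_true[None, :]
    counts = nb_sample(rng, mu, config.nb_dispersion)

    values = pd.DataFrame(counts, index=features, columns=samples)
    feature_meta = pd.DataFrame({"biotype": biotypes}, index=features)
    sample_meta = pd.DataFrame(
        {
            "condition": ["tumor"] * n + ["normal"] * n,
            "pair_id": [f"P{i + 1:02d}" for i in range(n)] * 2,
            "subclass": [truth_subclass.get(s) for s in samples],
        },
        index=samples,
    )
    matrix = ExpressionMatrix(values, feature_meta, sample_meta)
    return SyntheticCohort(
        counts=matrix,
        truth_de=truth_de,
        truth_triplets=[t for mod in modules for t in mod.triplets],
        sponge_modules=modules,
        truth_subclass=truth_subclass,
        templates=templates,
        survival=surv,
        truth_score=pd.Series(score, index=tumors, name="score"),
        prognostic_features=prognostic,
        true_size_factors=pd.Series(s_true, index=samples, name="s"),
    )


# ---------------------------------------------------------------------------
# sequence substrate
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA_BASES, size=length))


def simulate_sequences(config: SimulationConfig, triplets: list) -> tuple:
    """Random-background RNA sequences with planted seed sites.

    For every (sponge, miRNA, mRNA) triplet, the sponge and mRNA
    sequences receive at least one exact 7-nt match to the reverse
    complement of the miRNA seed (positions 2-8) — a 7mer-m8 site, or
    an 8mer when the random base that follows happens to be A.

    Returns (mirna_seqs, target_seqs, truth_sites) where truth_sites
    are :class:`TargetSite` records for every planted site.
    """
    rng = np.random.default_rng(config.seed + 1)
    mirna_ids = sorted({m for _, m, _ in triplets})
    target_ids = sorted(
        {t for t, _, _ in triplets} | {t for _, _, t in triplets}
    )
    mirna_seqs = {
        m: _random_rna(rng, config.mirna_length) for m in mirna_ids
    }
    target_seqs = {
        t: list(_random_rna(rng, config.target_length)) for t in target_ids
    }
    slots = {t: 0 for t in target_ids}
    truth_sites = []
    for sponge, mir, mrna in triplets:
        site = revcomp(mirna_seqs[mir][1:8])  # comp(N8)..comp(N2)
        for tid in (sponge, mrna):
            pos = 20 + 30 * slots[tid]
            slots[tid] += 1
            if pos + len(site) + 1 > config.target_length:
                raise SizingError(
                    f"target {tid}: planted site at {pos} exceeds length "
                    f"{config.target_length}"
                )
            target_seqs[tid][pos:pos + len(site)] = list(site)
            stype = (
                "8mer"
                if target_seqs[tid][pos + len(site)] == "A"
                else "7mer-m8"
            )
            truth_sites.append(TargetSite(tid, mir, pos + 1, stype))
    return (
        mirna_seqs,
        {t: "".join(chars) for t, chars in target_seqs.items()},
        truth_sites,
    )


def mirna_objects(mirna_seqs: dict) -> list:
    return [MicroRNA(mid, seq) for mid, seq in sorted(mirna_seqs.items())]


# ---------------------------------------------------------------------------
# annotation substrate
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> tuple:
    """Non-overlapping gene models plus junctions of known origin.

    Junctions come in three classes — both breakpoints on exon
    boundaries of one gene (exonic), strictly inside one intron
    (intronic), or overlapping no gene (intergenic) — in the
    configured proportions (default emulating the dominant-exonic
    split of back-splice catalogs).

    Returns (genes, junctions, truth_origin) with truth_origin mapping
    circ_id -> label.
    """
    from .io_formats import GeneModel

    rng = np.random.default_rng(config.seed + 2)
    n_junc = config.n_junctions
    p_ex, p_in, p_ig = config.origin_proportions
    total = p_ex + p_in + p_ig
    if total <= 0:
        raise ValueError("origin proportions must sum to a positive value")
    n_ex = int(round(n_junc * p_ex / total))
    n_in = int(round(n_junc * p_in / total))
    n_ig = n_junc - n_ex - n_in

    n_genes = max(20, n_junc // 4)
    genes = []
    cursor = 10_000
    chrom = "chrS"
    for gi in range(n_genes):
        n_exons = int(rng.integers(2, 7))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for xi in range(n_exons):
            length = int(rng.integers(100, 301))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(200, 501))
        genes.append(
            GeneModel(f"G{gi + 1:04d}", chrom, strand, exons, "protein_coding")
        )
        cursor = genes[-1].end + int(rng.integers(5000, 10_001))

    junctions = []
    truth = {}
    jid = 0

    def new_id():
        nonlocal jid
        jid += 1
        return f"bsj_{jid:04d}"

    for _ in range(n_ex):
        g = genes[int(rng.integers(len(genes)))]
        i = int(rng.integers(len(g.exons)))
        j = int(rng.integers(i, len(g.exons)))
        cid = new_id()
        junctions.append(
            CircJunction(cid, chrom, g.exons[i][0], g.exons[j][1],
                         g.strand, int(rng.integers(2, 100)))
        )
        truth[cid] = "exonic"
    intron_genes = [g for g in genes if g.introns]
    for _ in range(n_in):
        g = intron_genes[int(rng.integers(len(intron_genes)))]
        s, e = g.introns[int(rng.integers(len(g.introns)))]
        a = int(rng.integers(1, max((e - s) // 3, 2)))
        b = int(rng.integers(1, max((e - s) // 3, 2)))
        start, end = s + a, e - b
        if start >= end:
            start, end = s + 1, e - 1
        cid = new_id()
        junctions.append(
            CircJunction(cid, chrom, start, end, g.strand,
                         int(rng.integers(2, 100)))
        )
        truth[cid] = "intronic"
    for _ in range(n_ig):
        gi = int(rng.integers(len(genes) - 1))
        gap_start = genes[gi].end + 100
        gap_end = genes[gi + 1].start - 100
        length = int(rng.integers(100, 301))
        start = gap_start + int(rng.integers(0, max(gap_end - gap_start - length, 1)))
        cid = new_id()
        junctions.append(
            CircJunction(cid, chrom, start, start + length,
                         "+" if rng.random() < 0.5 else "-",
                         int(rng.integers(2, 100)))
        )
        truth[cid] = "intergenic"
    return genes, junctions, truth


# ---------------------------------------------------------------------------
# external target-table substrate
# ---------------------------------------------------------------------------

def simulate_target_table(
    config: SimulationConfig,
    modules: list,
    extra_mirnas: list | None = None,
    n_background: int = 50,
) -> pd.DataFrame:
    """Normalised external mRNA–miRNA table containing the planted
    module interactions plus random background rows.

    Emulates the union of a validated and a predicted interaction
    source: planted rows are labelled validated; background rows
    (random miRNA x decoy mRNA combinations) predicted.
    """
    rng = np.random.default_rng(config.seed + 3)
    rows = [
        {
            "mirna_id": m,
            "target_id": mod.mrna,
            "evidence": "validated",
            "source": "synthetic_validated",
        }
        for mod in modules
        for m in mod.mirnas
    ]
    mirna_pool = sorted(
        {m for mod in modules for m in mod.mirnas} | set(extra_mirnas or [])
    )
    n_mrna = config.n_features_by_biotype.get("mRNA", 0)
    for _ in range(n_background):
        rows.append(
            {
                "mirna_id": mirna_pool[int(rng.integers(len(mirna_pool)))],
                "target_id": f"mRNA_{int(rng.integers(n_mrna)):04d}",
                "evidence": "predicted",
                "source": "synthetic_predicted",
            }
        )
    df = pd.DataFrame(rows)
    return df.drop_duplicates(
        subset=["mirna_id", "target_id", "source"]
    ).reset_index(drop=True)
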