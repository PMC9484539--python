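"""End-to-end orchestration: filter -> DE -> subclass -> circRNA origin
-> miRNA targets -> ceRNA network -> (GSEA) -> survival.

The driver runs either on a synthetic cohort (full ground truth, no
input files) or on user-supplied tables. Every enabled stage logs the
counts entering and leaving its filters, outputs are plain TSV next to
a ``provenance.json`` sidecar (config hash, seed, package version),
and a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .cerna_net import assemble_network
from .circ_annot import alt_circularization, classify_origins, origin_fractions, origin_table
from .config import SimulationConfig, Thresholds
from .diffexp import attach_padj, direction_calls, nb_wald_test
from .gsea import correlation_rank, gsea_significance
from .io_formats import (
    read_counts,
    read_gmt,
    read_gtf,
    read_junctions,
    read_signatures,
    read_survival,
    write_counts,
    write_network,
    write_table,
)
from .matrix import BIOTYPES, ValidationError
from .ntp import ntp_classify
from .preprocess import filter_expressed, size_factors, transform
from .survival import prognostic_screen
from .synthetic import (
    mirna_objects,
    simulate_annotation,
    simulate_cohort,
    simulate_sequences,
    simulate_target_table,
)
from .target_pred import build_candidates, filter_pairs, scan_sites


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for one run.

    Either ``simulation`` is set (synthetic mode: all substrates are
    generated with planted truth) or the path fields point at input
    files. Stages lacking their inputs are skipped and noted in the
    report.
    """

    outdir: str = "cernakit_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    counts: str | None = None
    sample_meta: str | None = None
    feature_meta: str | None = None
    gtf: str | None = None
    junctions: str | None = None
    signatures: str | None = None
    target_table: str | None = None
    gmt: str | None = None
    gsea_query: str | None = None
    survival_table: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_perm: int = 1000
    stages: dict = field(
        default_factory=lambda: {
            "de": True,
            "classify": True,
            "annotate": True,
            "targets": True,
            "cerna": True,
            "gsea": True,
            "survival": True,
        }
    )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # hash the analysis, not its location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def intersect_prognostic(
    survival_results: pd.DataFrame,
    class_de: pd.DataFrame,
    fdr_cut: float = 0.05,
    fc_cut: float = 2.0,
) -> pd.DataFrame:
    """Features prognostic by both screens, with both evidence columns.

    ``survival_results`` is a :func:`prognostic_screen` table
    (significant = Cox p below its alpha); ``class_de`` a DE table
    (p/padj/log2fc) from the good-vs-poor contrast, judged at
    padj < fdr_cut and |fold change| > fc_cut. The intersection is a
    subset of each input.
    """
    if "padj" not in class_de:
        class_de = attach_padj(class_de)
    lfc = np.log2(fc_cut)
    de_sig = class_de[
        (class_de["padj"] < fdr_cut) & (class_de["log2fc"].abs() > lfc)
    ]
    surv_sig = survival_results[survival_results["significant"]]
    shared = surv_sig.index.intersection(de_sig.index)
    out = pd.DataFrame(
        {
            "cox_p": surv_sig.loc[shared, "cox_p"],
            "km_p": surv_sig.loc[shared, "km_p"],
            "class_padj": de_sig.loc[shared, "padj"],
            "class_log2fc": de_sig.loc[shared, "log2fc"],
        }
    )
    out.index.name = "feature_id"
    return out.sort_index()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the report.

    The report maps stage names to summary counts and in-memory
    results; files land under ``config.outdir``. Any stage failure
    aborts with the stage name in the exception; partial outputs are
    retained.
    """
    os.makedirs(config.outdir, exist_ok=True)
    th = config.thresholds
    report: dict = {"stages": {}, "results": {}}

    def _stage(name):
        report["stages"][name] = {}
        return report["stages"][name]

    # ------------------------------------------------------------------ load
    info = _stage("load")
    truth = None
    mirna_seqs = target_seqs = None
    templates = None
    genes = junctions = None
    external = None
    survival_df = None
    gene_sets = None
    if config.simulation is not None:
        sim = SimulationConfig(**{**asdict(config.simulation),
                                  "seed": config.seed})
        truth = simulate_cohort(sim)
        matrix = truth.counts
        mirna_seqs, target_seqs, _ = simulate_sequences(
            sim, truth.truth_triplets
        )
        genes, junctions, _ = simulate_annotation(sim)
        external = simulate_target_table(sim, truth.sponge_modules)
        templates = truth.templates or None
        survival_df = truth.survival
    else:
        if config.counts is None:
            raise ValidationError("either simulation or counts must be set")
        matrix = read_counts(config.counts, config.sample_meta,
                             config.feature_meta)
        if config.gtf:
            genes = read_gtf(config.gtf)
        if config.junctions:
            junctions = read_junctions(config.junctions)
        if config.signatures:
            templates = read_signatures(config.signatures)
        if config.target_table:
            from .io_formats import read_target_table

            external = read_target_table(config.target_table)
        if config.survival_table:
            survival_df = read_survival(config.survival_table)
    if config.gmt:
        gene_sets = read_gmt(config.gmt)
    info["n_features"] = matrix.n_features
    info["n_samples"] = matrix.n_samples

    # ------------------------------------------------------------ preprocess
    info = _stage("preprocess")
    info["features_in"] = matrix.n_features
    filtered = filter_expressed(matrix, th.min_count, th.min_sample_frac)
    info["features_out"] = filtered.n_features
    factors = size_factors(filtered)
    logged = transform(filtered, factors)
    write_counts(filtered, os.path.join(config.outdir, "counts_filtered.tsv"))
    write_table(
        logged.values.round(6), os.path.join(config.outdir, "expression_log2.tsv"),
        index_label="feature_id",
    )
    report["results"]["filtered"] = filtered
    report["results"]["transformed"] = logged
    report["results"]["size_factors"] = factors

    # ------------------------------------------------------------------- DE
    de_tables: dict = {}
    de_dirs: dict = {}
    if config.stages.get("de", True):
        info = _stage("de")
        for bt in BIOTYPES:
            sub = filtered.biotype(bt)
            if sub.n_features == 0:
                continue
            res = attach_padj(nb_wald_test(sub, factors=factors))
            res["direction"] = direction_calls(
                res, th.padj_tumorigenesis, th.fc
            )
            de_tables[bt] = res
            de_dirs[bt] = res["direction"]
            info[f"{bt}_tested"] = len(res)
            info[f"{bt}_dysregulated"] = int((res["direction"] != "ns").sum())
            write_table(
                res.round(8), os.path.join(config.outdir, f"de_{bt}.tsv"),
                index_label="feature_id",
            )
        report["results"]["de"] = de_tables

    # -------------------------------------------------------------- classify
    if config.stages.get("classify", True) and templates:
        info = _stage("classify")
        tumor_ids = logged.sample_meta.index[
            logged.sample_meta["condition"] == "tumor"
        ]
        ntp = ntp_classify(
            logged.subset_samples(tumor_ids),
            templates,
            n_perm=config.n_perm,
            seed=config.seed,
            fdr_cut=th.fdr_prognosis,
        )
        info["n_classified"] = int(ntp["predicted"].notna().sum())
        info["n_confident"] = int(ntp["confident"].sum())
        write_table(
            ntp.round(8), os.path.join(config.outdir, "ntp_subclass.tsv"),
            index_label="sample_id",
        )
        report["results"]["ntp"] = ntp

    # -------------------------------------------------------------- annotate
    if config.stages.get("annotate", True) and genes and junctions:
        info = _stage("annotate")
        calls = classify_origins(junctions, genes, slack=0)
        fracs = origin_fractions(calls)
        counts_per_gene, alt_frac = alt_circularization(calls, k=2)
        info["n_junctions"] = len(calls)
        info.update({f"frac_{k}": float(v) for k, v in fracs.items()})
        info["alt_circularization_frac"] = alt_frac
        write_table(
            origin_table(calls), os.path.join(config.outdir, "circ_origin.tsv")
        )
        report["results"]["origin_calls"] = calls
        report["results"]["alt_circ_fraction"] = alt_frac

    # --------------------------------------------------------------- targets
    pairs = None
    if config.stages.get("targets", True) and de_tables:
        info = _stage("targets")
        de_mirnas = {}
        if "miRNA" in de_dirs:
            d = de_dirs["miRNA"]
            de_mirnas = d[d != "ns"].to_dict()
        de_mrnas = {}
        if "mRNA" in de_dirs:
            d = de_dirs["mRNA"]
            de_mrnas = d[d != "ns"].to_dict()
        de_ncrnas = {}
        ncrna_classes = {}
        for bt in ("lncRNA", "circRNA"):
            if bt in de_dirs:
                d = de_dirs[bt]
                for fid, direc in d[d != "ns"].items():
                    de_ncrnas[fid] = direc
                    ncrna_classes[fid] = bt
        sites = []
        if mirna_seqs and target_seqs:
            mirnas = [
                m for m in mirna_objects(mirna_seqs)
                if m.mirna_id in de_mirnas
            ]
            sites = scan_sites(mirnas, target_seqs, strict=True)
        candidates = build_candidates(
            de_mirnas, de_ncrnas, de_mrnas, sites, external, ncrna_classes
        )
        info["candidates"] = len(candidates)
        pairs = filter_pairs(candidates, logged, th)
        info["pairs_pass"] = len(pairs)
        write_table(
            pairs.round(8), os.path.join(config.outdir, "target_pairs.tsv")
        )
        report["results"]["pairs"] = pairs

    # ----------------------------------------------------------------- ceRNA
    if config.stages.get("cerna", True) and pairs is not None:
        info = _stage("cerna")
        edges = assemble_network(pairs, logged, th)
        info["edges"] = len(edges)
        write_network(edges, os.path.join(config.outdir, "cerna_network.tsv"),
                      format="tsv")
        write_network(
            edges, os.path.join(config.outdir, "cerna_network.graphml"),
            format="graphml",
        )
        report["results"]["edges"] = edges

    # ------------------------------------------------------------------ GSEA
    if config.stages.get("gsea", True) and gene_sets and config.gsea_query:
        info = _stage("gsea")
        ranked = correlation_rank(logged, config.gsea_query)
        gres = gsea_significance(
            ranked, gene_sets, n_perm=max(config.n_perm, 100),
            seed=config.seed,
        )
        info["sets_tested"] = len(gres)
        out = gres.copy()
        out["leading_edge"] = out["leading_edge"].map(";".join)
        write_table(
            out.round(8), os.path.join(config.outdir, "gsea.tsv"),
            index_label="set_id",
        )
        report["results"]["gsea"] = gres

    # -------------------------------------------------------------- survival
    if config.stages.get("survival", True) and survival_df is not None:
        info = _stage("survival")
        lnc = logged.biotype("lncRNA")
        tumor_ids = lnc.sample_meta.index[
            lnc.sample_meta["condition"] == "tumor"
        ]
        lnc_t = lnc.subset_samples(tumor_ids)
        screen = prognostic_screen(lnc_t, survival_df,
                                   alpha=th.fdr_prognosis)
        info["features_screened"] = len(screen)
        info["significant"] = int(screen["significant"].sum())
        write_table(
            screen.round(8),
            os.path.join(config.outdir, "prognostic_screen.tsv"),
            index_label="feature_id",
        )
        report["results"]["prognostic"] = screen

    # ----------------------------------------------------------- provenance
    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(
            {
                "config_sha256": config.config_hash(),
                "seed": config.seed,
                "cernakit_version": __version__,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report["stages"], fh, indent=2, sort_keys=True)
    if truth is not None:
        report["results"]["truth"] = truth
    return report
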