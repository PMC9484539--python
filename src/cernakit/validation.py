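"""Self-contained validation studies for every stage of the toolkit.

Each study regenerates its inputs from the synthetic-data module (or
constructs an exact fixture), runs the corresponding method and
returns plain numbers: oracle agreement fractions, Monte-Carlo
calibration rates, ground-truth recovery rates and parameter-recovery
errors. They are used by the acceptance test suite and by
``scripts/acceptance.py``; the study sizes (cohort sizes, feature
counts, permutation counts) are fixed here as the package's reference
validation conditions.
"""

from __future__ import annotations

import hashlib
import math
import os
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cerna_net import assemble_network, hypergeom_tail
from .circ_annot import alt_circularization, classify_origins
from .config import SPONGE_EFFECT_HIGH, SimulationConfig, Thresholds
from .diffexp import attach_padj, direction_calls, nb_wald_test
from .gsea import enrichment_score, gsea_significance
from .matrix import ExpressionMatrix
from .ntp import TemplateSignature, ntp_classify
from .preprocess import filter_expressed, size_factors, transform
from .survival import cox_univariate, grho_test, km_estimate, prognostic_screen
from .synthetic import (
    mirna_objects,
    nb_sample,
    simulate_annotation,
    simulate_cohort,
    simulate_sequences,
    simulate_target_table,
)
from .target_pred import (
    MicroRNA,
    build_candidates,
    filter_pairs,
    revcomp,
    scan_sites,
    seed_sites,
)


# ---------------------------------------------------------------------------
# hypergeometric tail vs exhaustive enumeration
# ---------------------------------------------------------------------------

def hypergeom_study(max_N: int = 12) -> dict:
    """Compare the tail against brute-force enumeration, all N <= max_N."""
    max_err = 0.0
    n_cases = 0
    for N in range(1, max_N + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                total = math.comb(N, n)
                for k in range(min(K, n) + 1):
                    exact = sum(
                        math.comb(K, i) * math.comb(N - K, n - i)
                        for i in range(k, min(K, n) + 1)
                        if n - i <= N - K
                    ) / total
                    got = hypergeom_tail(k, K, n, N)
                    max_err = max(max_err, abs(got - exact))
                    n_cases += 1
    return {
        "max_abs_err": max_err,
        "n_cases": n_cases,
        "worked_case": hypergeom_tail(3, 4, 5, 10),  # 66/252
    }


# ---------------------------------------------------------------------------
# seed matching vs brute-force window scan
# ---------------------------------------------------------------------------

def _brute_force_sites(mirna: MicroRNA, target: str) -> set:
    """Window-scan oracle; positions 1-based, m8-types anchored at the
    m8-pairing base, the rest at the 6mer core."""
    core = revcomp(mirna.sequence[1:7])
    m8c = revcomp(mirna.sequence[1:8])[0]
    found = set()
    for i in range(len(target) - 5):  # i: 0-based core start
        if target[i:i + 6] != core:
            continue
        m8 = i > 0 and target[i - 1] == m8c
        a1 = i + 6 < len(target) and target[i + 6] == "A"
        if m8 and a1:
            found.add((i, "8mer"))
        elif m8:
            found.add((i, "7mer-m8"))
        elif a1:
            found.add((i + 1, "7mer-A1"))
        else:
            found.add((i + 1, "6mer"))
    return found


def seed_match_study(n_random: int = 1000, seed: int = 0,
                     target_len: int = 120) -> dict:
    """Oracle agreement, planted-site recall and the analytic hit rate."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    agree = 0
    strict_hits = 0
    windows = 0
    for i in range(n_random):
        mirna = MicroRNA(f"m{i}", "".join(rng.choice(bases, 22)))
        target = "".join(rng.choice(bases, target_len))
        got = {
            (s.position, s.site_type)
            for s in seed_sites(mirna, target, "t", strict=False)
        }
        expect = _brute_force_sites(mirna, target)
        agree += got == expect
        strict_hits += sum(
            1 for _, t in got if t in ("7mer-m8", "8mer")
        )
        windows += target_len - 6
    expected_rate = 4.0**-7
    expected_hits = windows * expected_rate
    z = (strict_hits - expected_hits) / math.sqrt(expected_hits)

    # planted-site recall on the synthetic sequence substrate
    sim = SimulationConfig(seed=seed)
    cohort = simulate_cohort(sim)
    mseqs, tseqs, truth = simulate_sequences(sim, cohort.truth_triplets)
    mirnas = {m.mirna_id: m for m in mirna_objects(mseqs)}
    recovered = sum(
        any(
            s.position == site.position and s.site_type == site.site_type
            for s in seed_sites(
                mirnas[site.mirna_id], tseqs[site.target_id], site.target_id
            )
        )
        for site in truth
    )
    return {
        "oracle_agreement": agree / n_random,
        "planted_recall": recovered / len(truth),
        "n_planted": len(truth),
        "hit_rate_z": z,
        "observed_hit_rate": strict_hits / windows,
        "expected_hit_rate": expected_rate,
    }


# ---------------------------------------------------------------------------
# differential-expression calibration and fold-change recovery
# ---------------------------------------------------------------------------

def de_calibration_study(seed: int = 0, n_features: int = 2000,
                         n_per_group: int = 8, mu: float = 100.0,
                         alpha: float = 0.1) -> dict:
    """Null type-I error at 0.05 and recovery of a planted 4-fold shift."""
    rng = np.random.default_rng(seed)
    cols = [f"T{i}" for i in range(n_per_group)] + [
        f"N{i}" for i in range(n_per_group)
    ]
    meta = pd.DataFrame(
        {"condition": ["tumor"] * n_per_group + ["normal"] * n_per_group},
        index=cols,
    )
    ones = pd.Series(1.0, index=cols)

    null_counts = nb_sample(
        rng, np.full((n_features, 2 * n_per_group), mu), alpha
    )
    m0 = ExpressionMatrix(
        pd.DataFrame(null_counts, columns=cols), sample_meta=meta
    )
    res0 = nb_wald_test(m0, factors=ones)
    fpr = float((res0["p"] < 0.05).mean())

    planted = null_counts.copy()
    planted[:, :n_per_group] = nb_sample(
        rng, np.full((n_features, n_per_group), 4.0 * mu), alpha
    )
    m1 = ExpressionMatrix(
        pd.DataFrame(planted, columns=cols), sample_meta=meta
    )
    res1 = nb_wald_test(m1, factors=ones)
    med_err = float(np.median(np.abs(res1["log2fc"] - 2.0)))
    return {
        "null_fpr_at_0.05": fpr,
        "median_abs_log2fc_error": med_err,
        "n_features": n_features,
    }


# ---------------------------------------------------------------------------
# ceRNA pipeline recovery
# ---------------------------------------------------------------------------

def _run_target_stages(sim: SimulationConfig, cohort, logged, factors,
                       filtered, thresholds: Thresholds):
    de_dirs = {}
    for bt in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        res = attach_padj(nb_wald_test(filtered.biotype(bt), factors=factors))
        de_dirs[bt] = direction_calls(
            res, thresholds.padj_tumorigenesis, thresholds.fc
        )

    def dmap(bt):
        d = de_dirs[bt]
        return d[d != "ns"].to_dict()

    de_nc = {**dmap("lncRNA"), **dmap("circRNA")}
    classes = {
        fid: bt for bt in ("lncRNA", "circRNA") for fid in dmap(bt)
    }
    mseqs, tseqs, _ = simulate_sequences(sim, cohort.truth_triplets)
    mirnas = [
        m for m in mirna_objects(mseqs) if m.mirna_id in dmap("miRNA")
    ]
    sites = scan_sites(mirnas, tseqs, strict=True)
    external = simulate_target_table(sim, cohort.sponge_modules)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_candidates(
            dmap("miRNA"), de_nc, dmap("mRNA"), sites, external, classes
        )


def cerna_recovery_study(seed: int = 1, n_pairs: int = 32) -> dict:
    """Recall of planted sponge modules at the quoted edge criteria, and
    the permuted-cohort negative control (correlations destroyed)."""
    sim = SimulationConfig(
        n_pairs=n_pairs, sponge_effect=SPONGE_EFFECT_HIGH, seed=seed
    )
    cohort = simulate_cohort(sim)
    th = Thresholds()
    filtered = filter_expressed(cohort.counts)
    factors = size_factors(filtered)
    logged = transform(filtered, factors)
    candidates = _run_target_stages(sim, cohort, logged, factors, filtered, th)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = filter_pairs(candidates, logged, th)
    edges = assemble_network(pairs, logged, th)
    planted = {(m.sponge, m.mrna) for m in cohort.sponge_modules}
    found = {(e.cerna_id, e.mrna_id) for e in edges}

    # negative control: permute each feature's samples independently
    rng = np.random.default_rng(seed + 10_000)
    vp = logged.values.copy()
    arr = vp.to_numpy()
    for i in range(arr.shape[0]):
        arr[i] = rng.permutation(arr[i])
    permuted = ExpressionMatrix(
        pd.DataFrame(arr, index=vp.index, columns=vp.columns),
        logged.feature_meta, logged.sample_meta, transformed=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs_p = filter_pairs(candidates, permuted, th)
    edges_p = assemble_network(pairs_p, permuted, th)
    return {
        "recall": len(planted & found) / len(planted),
        "n_planted": len(planted),
        "false_edges": len(found - planted),
        "permuted_edges": len(edges_p),
    }


# ---------------------------------------------------------------------------
# NTP recovery and null calibration
# ---------------------------------------------------------------------------

def ntp_study(seed: int = 1, n_perm: int = 1000) -> dict:
    """Label recovery on separated templates; confident-call rate under
    a null cohort; exactness on a template-equal sample."""
    sim = SimulationConfig(seed=seed)
    cohort = simulate_cohort(sim)
    filtered = filter_expressed(cohort.counts)
    logged = transform(filtered, size_factors(filtered))
    tumor = logged.subset_samples(
        [s for s in logged.sample_ids if s.startswith("T")]
    )
    res = ntp_classify(tumor, cohort.templates, n_perm=n_perm, seed=seed)
    recovered = np.mean(
        [res.loc[s, "predicted"] == lab
         for s, lab in cohort.truth_subclass.items()]
    )

    null_sim = SimulationConfig(
        n_pairs=30,
        subclass_sizes={"S1": 10, "S2": 10, "S3": 10},
        subclass_shift=0.0,
        seed=seed + 1,
    )
    null_cohort = simulate_cohort(null_sim)
    nf = filter_expressed(null_cohort.counts)
    nl = transform(nf, size_factors(nf))
    nt = nl.subset_samples([s for s in nl.sample_ids if s.startswith("T")])
    null_res = ntp_classify(nt, null_cohort.templates, n_perm=n_perm,
                            seed=seed + 1)
    null_confident = float(null_res["confident"].mean())

    # exact fixture: a sample that IS the signed template
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(8)]
    signs = [1, 1, 1, 1, -1, -1, -1, -1]
    template = TemplateSignature("A", list(zip(genes, signs)))
    other = TemplateSignature("B", list(zip(genes, [-s for s in signs])))
    vals = np.vstack(
        [np.array(signs, float)[:, None], rng.normal(size=(40, 1))]
    )
    m = ExpressionMatrix(
        pd.DataFrame(
            vals, index=genes + [f"bg{i}" for i in range(40)], columns=["s"]
        ),
        transformed=True,
    )
    fix = ntp_classify(m, [template, other], n_perm=n_perm, seed=seed)
    return {
        "planted_recovery": float(recovered),
        "n_subclassed": len(cohort.truth_subclass),
        "null_confident_fraction": null_confident,
        "n_null_samples": len(null_res),
        "template_equal_distance": float(fix.loc["s", "distance"]),
        "template_equal_p": float(fix.loc["s", "p"]),
        "min_possible_p": 1.0 / (n_perm + 1),
    }


# ---------------------------------------------------------------------------
# GSEA oracle agreement and null uniformity
# ---------------------------------------------------------------------------

def _es_oracle(scores, hit, weight_p=1.0) -> float:
    n = len(scores)
    n_hit = int(np.sum(hit))
    denom = sum(abs(s) ** weight_p for s, h in zip(scores, hit) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, hit):
        if h:
            running += (abs(s) ** weight_p) / denom if denom else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best) + 1e-12:
            best = running
    return best


def gsea_study(seed: int = 0, n_oracle: int = 500, n_reps: int = 200,
               n_perm: int = 200) -> dict:
    """Running-sum oracle agreement, the hand fixture, null uniformity."""
    ranked = pd.Series([3, 2, 1, 0.5], index=["g1", "g2", "g3", "g4"])
    fixture_es, _, _ = enrichment_score(ranked, {"g1", "g3"})

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_oracle):
        n = int(rng.integers(8, 50))
        scores = np.sort(rng.normal(size=n))[::-1]
        r = pd.Series(scores, index=[f"g{i}" for i in range(n)])
        m = int(rng.integers(1, n))
        genes = set(rng.choice(r.index, m, replace=False))
        hit = np.array([g in genes for g in r.index])
        es, _, _ = enrichment_score(r, genes)
        agree += abs(es - _es_oracle(scores, hit)) < 1e-9

    ps = []
    for rep in range(n_reps):
        n = 200
        scores = np.sort(rng.uniform(-1, 1, n))[::-1]
        r = pd.Series(scores, index=[f"g{i}" for i in range(n)])
        gs = {"s": list(rng.choice(r.index, 15, replace=False))}
        res = gsea_significance(r, gs, n_perm=n_perm, seed=seed + rep)
        ps.append(float(res["p"].iloc[0]))
    ks_p = float(stats.kstest(ps, "uniform").pvalue)
    return {
        "fixture_es": float(fixture_es),
        "oracle_agreement": agree / n_oracle,
        "n_oracle": n_oracle,
        "null_ks_p": ks_p,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# survival analysis studies
# ---------------------------------------------------------------------------

def survival_study(seed: int = 4, n_cox: int = 300) -> dict:
    """Hand-tabulated log-rank fixture, KM fixtures, Cox slope recovery
    and the permuted-survival screen calibration."""
    time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
    event = np.array([1, 1, 0, 1, 1, 1])
    group = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
    res = grho_test(time, event, group, rho=0)
    logrank_err = abs(res.statistic - 32 / 433)  # hand tabulation

    s = km_estimate([1.0, 2.0], [1, 1])
    km_err = max(abs(s.loc[1.0] - 0.5), abs(s.loc[2.0] - 0.0))
    flat = km_estimate([2.0, 3.0], [0, 0])
    km_err = max(km_err, float(np.max(np.abs(flat.to_numpy() - 1.0))))

    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_cox)
    shape = 1.5
    t = 10.0 * (rng.exponential(1, n_cox) / np.exp(0.7 * x)) ** (1 / shape)
    cox = cox_univariate(t, np.ones(n_cox, dtype=int), x)

    # null screen: expression unrelated to survival
    n, n_feat = 80, 100
    score = rng.normal(size=n)
    ts = 10.0 * (rng.exponential(1, n) / np.exp(0.9 * score)) ** (1 / shape)
    ev = (rng.random(n) < 0.8).astype(int)
    vals = rng.normal(size=(n_feat, n))
    samples = [f"T{i}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"f{i}" for i in range(n_feat)],
                     columns=samples),
        transformed=True,
    )
    surv = pd.DataFrame({"time": ts, "event": ev}, index=samples)
    screen = prognostic_screen(expr, surv, alpha=0.05)
    return {
        "logrank_fixture_abs_err": float(logrank_err),
        "km_fixture_abs_err": float(km_err),
        "cox_slope_estimate": float(cox.beta),
        "cox_true_slope": 0.7,
        "n_cox": n_cox,
        "null_screen_significant_fraction": float(
            screen["significant"].mean()
        ),
        "n_screen_features": n_feat,
    }


# ---------------------------------------------------------------------------
# circRNA origin agreement
# ---------------------------------------------------------------------------

def origin_study(seed: int = 0) -> dict:
    sim = SimulationConfig(seed=seed, n_junctions=400)
    genes, junctions, truth = simulate_annotation(sim)
    calls = classify_origins(junctions, genes, slack=0)
    agree = np.mean([c.origin == truth[c.circ_id] for c in calls])
    exhaustive = all(
        c.origin in ("exonic", "intronic", "intergenic") for c in calls
    )
    _, alt_frac = alt_circularization(calls, k=2)
    return {
        "truth_agreement": float(agree),
        "n_junctions": len(calls),
        "partition_ok": bool(exhaustive and len(calls) == len(junctions)),
        "alt_circularization_fraction": float(alt_frac),
    }


# ---------------------------------------------------------------------------
# threshold boundary fixtures
# ---------------------------------------------------------------------------

def boundary_study() -> dict:
    """Every quoted strict-inequality boundary behaves as printed."""
    checks = []
    # expression filter: > 5 in >= ceil(0.2 * 16) = 4 samples
    cols = [f"s{j}" for j in range(16)]
    rows = {
        "keep": [6] * 4 + [0] * 12,
        "edge_count": [5] * 16,
        "edge_samples": [6] * 3 + [0] * 13,
        "anchor": [10] * 16,
    }
    m = ExpressionMatrix(pd.DataFrame(rows, index=cols).T)
    kept = set(filter_expressed(m, 5, 0.2).feature_ids)
    checks.append("keep" in kept)
    checks.append("edge_count" not in kept)
    checks.append("edge_samples" not in kept)

    # dysregulation cuts
    de = pd.DataFrame(
        {
            "log2fc": [1.5, 0.5, 3.0, 1.0],
            "p": [0.05, 0.05, 0.15, 0.05],
            "padj": [0.05, 0.05, 0.15, 0.05],
        },
        index=["a", "b", "c", "d"],
    )
    d1 = direction_calls(de, 0.1, 2.0)
    d2 = direction_calls(de, 0.25, 2.0)
    checks += [
        d1["a"] == "up",
        d1["b"] == "ns",          # fold change below 2
        d1["c"] == "ns",          # padj above tumorigenesis cut
        d2["c"] == "up",          # passes the subclass cut
        d1["d"] == "ns",          # log2fc == log2(2) exactly: strict >
    ]

    # pair filter: opposite directions and PCC <= -0.4 inclusive
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    y = -0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=20)
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([x, y, x * 0.1 + rng.normal(size=20)]),
            index=["mir", "tgt", "weak"],
            columns=[f"s{j}" for j in range(20)],
        ),
        transformed=True,
    )

    def pair(target, mdir, tdir):
        return pd.DataFrame(
            [{"mirna_id": "mir", "target_id": target,
              "target_class": "lncRNA", "evidence": "seed",
              "mirna_dir": mdir, "target_dir": tdir}]
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        checks.append(len(filter_pairs(pair("tgt", "up", "up"), expr)) == 0)
        checks.append(len(filter_pairs(pair("tgt", "down", "up"), expr)) == 1)
        checks.append(len(filter_pairs(pair("weak", "down", "up"), expr)) == 0)

    # network: k = 4 shared fails strict > 4; k = 5 with small p passes
    mirnas5 = [f"mir{i}" for i in range(5)]

    def network_pairs(mirnas):
        rows = []
        for mid in mirnas:
            for tid, cls in (("lncA", "lncRNA"), ("geneB", "mRNA")):
                rows.append(
                    {"mirna_id": mid, "target_id": tid, "target_class": cls,
                     "evidence": "seed", "mirna_dir": "down",
                     "target_dir": "up"}
                )
        return pd.DataFrame(rows)

    xg = rng.normal(size=30)
    yg = 0.9 * xg + np.sqrt(1 - 0.81) * rng.normal(size=30)
    net_expr = ExpressionMatrix(
        pd.DataFrame(np.vstack([xg, yg]), index=["lncA", "geneB"],
                     columns=[f"s{j}" for j in range(30)]),
        transformed=True,
    )
    universe = set(mirnas5) | {f"bg{i}" for i in range(45)}
    th = Thresholds()
    checks.append(
        len(assemble_network(network_pairs(mirnas5), net_expr, th, universe))
        == 1
    )
    checks.append(
        len(assemble_network(network_pairs(mirnas5[:4]), net_expr, th,
                             universe)) == 0
    )
    return {
        "fraction_passed": float(np.mean(checks)),
        "n_checks": len(checks),
    }


# ---------------------------------------------------------------------------
# end-to-end determinism
# ---------------------------------------------------------------------------

def pipeline_determinism_study(workdir: str, seed: int = 5) -> dict:
    """Two full runs with one config: byte-identical outputs expected."""
    from .pipeline import PipelineConfig, run_pipeline

    sim = SimulationConfig(
        n_pairs=8,
        n_features_by_biotype={"mRNA": 150, "lncRNA": 50, "circRNA": 30,
                               "miRNA": 120},
        n_sponge_triplets=3,
        n_junctions=60,
        subclass_sizes={"S1": 3, "S2": 3, "S3": 2},
        n_signature_genes=15,
    )
    sums = []
    for name in ("run_a", "run_b"):
        outdir = os.path.join(workdir, name)
        cfg = PipelineConfig(outdir=outdir, seed=seed, simulation=sim,
                             n_perm=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(cfg)
        digest = {}
        for fn in sorted(os.listdir(outdir)):
            with open(os.path.join(outdir, fn), "rb") as fh:
                digest[fn] = hashlib.sha256(fh.read()).hexdigest()
        sums.append(digest)
    return {
        "identical": float(sums[0] == sums[1]),
        "n_files": len(sums[0]),
    }
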