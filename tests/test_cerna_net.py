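import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernakit.cerna_net import (
    assemble_network,
    cis_pairs,
    hypergeom_tail,
)
from cernakit.config import Thresholds
from cernakit.matrix import ExpressionMatrix, ValidationError


def hypergeom_oracle(k, K, n, N):
    """Exact tail by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total


class TestHypergeomTail:
    def test_worked_case(self):
        """P(X >= 3) with N=10, K=4, n=5 is 66/252."""
        assert hypergeom_tail(3, 4, 5, 10) == pytest.approx(66 / 252)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 4, 5, 10) == 1.0

    def test_forced_complete_overlap(self):
        assert hypergeom_tail(6, 6, 6, 6) == pytest.approx(1.0)

    def test_exhaustive_against_enumeration(self):
        """All valid (k, K, n, N) with N <= 12 match the oracle."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        if n - k > N - K and k == 0:
                            continue
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            hypergeom_oracle(k, K, n, N), rel=1e-9, abs=1e-12
                        ), (k, K, n, N)

    def test_bounds_enforced(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(5, 4, 5, 10)
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 11, 5, 10)


def _network_inputs(pcc_target=0.9, k_shared=5, n_universe=50):
    """One ceRNA and one mRNA sharing k miRNAs, tunable correlation."""
    mirnas = [f"mir{i}" for i in range(k_shared)]
    rows = []
    for m in mirnas:
        rows.append({"mirna_id": m, "target_id": "lncA",
                     "target_class": "lncRNA", "evidence": "seed",
                     "mirna_dir": "down", "target_dir": "up", "pcc": -0.8})
        rows.append({"mirna_id": m, "target_id": "geneB",
                     "target_class": "mRNA", "evidence": "validated_db",
                     "mirna_dir": "down", "target_dir": "up", "pcc": -0.8})
    pairs = pd.DataFrame(rows)
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    y = pcc_target * x + np.sqrt(max(1 - pcc_target**2, 1e-9)) * rng.normal(size=30)
    values = pd.DataFrame(
        np.vstack([x, y]), index=["lncA", "geneB"],
        columns=[f"s{j}" for j in range(30)],
    )
    expr = ExpressionMatrix(values, transformed=True)
    universe = set(mirnas) | {f"bg{i}" for i in range(n_universe - k_shared)}
    return pairs, expr, universe


class TestAssembleNetwork:
    def test_edge_emitted_when_all_criteria_met(self):
        pairs, expr, universe = _network_inputs()
        edges = assemble_network(pairs, expr, Thresholds(), universe)
        assert len(edges) == 1
        e = edges[0]
        assert e.k == 5 and e.p_hyper < 1e-6 and e.pcc > 0.6
        assert e.shared_mirnas == sorted(f"mir{i}" for i in range(5))

    def test_k_equal_four_rejected_strict(self):
        """Exactly 4 shared miRNAs fails the strict > 4 criterion."""
        pairs, expr, universe = _network_inputs(k_shared=4)
        assert assemble_network(pairs, expr, Thresholds(), universe) == []

    def test_low_pcc_rejected(self):
        pairs, expr, universe = _network_inputs(pcc_target=0.5)
        assert assemble_network(pairs, expr, Thresholds(), universe) == []

    def test_pcc_at_boundary_rejected(self):
        """PCC exactly 0.6 fails the strict > 0.6 criterion."""
        pairs, expr, universe = _network_inputs()
        x = expr.values.loc["lncA"].to_numpy()
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        rng = np.random.default_rng(9)
        o = rng.normal(size=len(x))
        o = o - o.mean()
        o = o - (o @ xc) * xc
        o /= np.linalg.norm(o)
        expr.values.loc["geneB"] = 0.6 * xc + 0.8 * o
        pcc = float(
            np.corrcoef(expr.values.loc["lncA"], expr.values.loc["geneB"])[0, 1]
        )
        assert pcc == pytest.approx(0.6, abs=1e-12)
        # pin the cut to the realised correlation: strict > must reject
        th = Thresholds(pcc_cerna_mrna=pcc)
        assert assemble_network(pairs, expr, th, universe) == []

    def test_large_p_rejected(self):
        # tiny universe makes sharing unsurprising
        pairs, expr, _ = _network_inputs()
        assert assemble_network(pairs, expr, Thresholds(), set(
            f"mir{i}" for i in range(6)
        )) == []

    def test_input_order_invariance(self):
        pairs, expr, universe = _network_inputs()
        shuffled = pairs.sample(frac=1, random_state=5).reset_index(drop=True)
        e1 = assemble_network(pairs, expr, Thresholds(), universe)
        e2 = assemble_network(shuffled, expr, Thresholds(), universe)
        assert [(e.cerna_id, e.mrna_id, e.p_hyper) for e in e1] == [
            (e.cerna_id, e.mrna_id, e.p_hyper) for e in e2
        ]

    def test_empty_pairs_empty_network(self):
        pairs, expr, _ = _network_inputs()
        assert assemble_network(pairs.iloc[:0], expr, Thresholds()) == []


class TestCisPairs:
    def _expr(self, pcc):
        rng = np.random.default_rng(11)
        x = rng.normal(size=24)
        y = pcc * x + np.sqrt(max(1 - pcc**2, 1e-12)) * rng.normal(size=24)
        values = pd.DataFrame(
            np.vstack([x, y, rng.normal(size=24)]),
            index=["lncAS", "geneS", "geneFar"],
            columns=[f"s{j}" for j in range(24)],
        )
        feature_meta = pd.DataFrame(
            {
                "biotype": ["lncRNA", "mRNA", "mRNA"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [1000, 2500, 900_000],
                "end": [2000, 3500, 901_000],
            },
            index=values.index,
        )
        return ExpressionMatrix(values, feature_meta, transformed=True)

    def test_perfectly_correlated_neighbour_reported(self):
        expr = self._expr(1.0)
        out = cis_pairs(expr, pcc_cut=0.8, max_distance=10_000)
        assert len(out) == 1
        assert out.iloc[0]["gene_id"] == "geneS"
        assert out.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_weak_correlation_not_reported(self):
        out = cis_pairs(self._expr(0.5), pcc_cut=0.8, max_distance=10_000)
        assert len(out) == 0

    def test_distant_gene_gated_by_distance(self):
        expr = self._expr(1.0)
        expr.values.loc["geneFar"] = expr.values.loc["lncAS"]
        out = cis_pairs(expr, pcc_cut=0.8, max_distance=10_000)
        assert set(out["gene_id"]) == {"geneS"}
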