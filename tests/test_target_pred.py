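import numpy as np
import pandas as pd
import pytest

from cernakit.config import SimulationConfig, Thresholds
from cernakit.matrix import ValidationError
from cernakit.synthetic import mirna_objects, simulate_sequences
from cernakit.target_pred import (
    MicroRNA,
    build_candidates,
    filter_pairs,
    revcomp,
    seed_sites,
)

LET7 = MicroRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


def brute_force_sites(mirna: MicroRNA, target: str):
    """Independent oracle: test every 7-nt window against the seed
    complement, classifying m8/A1 context by direct base comparison."""
    found = []
    core = revcomp(mirna.sequence[1:7])
    m8c = revcomp(mirna.sequence[1:8])[0]
    for i in range(len(target) - 5):
        if target[i:i + 6] != core:
            continue
        m8 = i > 0 and target[i - 1] == m8c
        a1 = i + 6 < len(target) and target[i + 6] == "A"
        if m8 and a1:
            found.append((i, "8mer"))
        elif m8:
            found.append((i - 1 + 1, "7mer-m8"))
        elif a1:
            found.append((i + 1, "7mer-A1"))
        else:
            found.append((i + 1, "6mer"))
    # normalise 8mer position to the m8 base like the implementation
    return [
        (i if t != "8mer" else i, t) if t != "8mer" else (i, t)
        for i, t in found
    ]


class TestSeedSites:
    def test_let7_site_is_reverse_complement_of_seed(self):
        """CUACCUC is the reverse complement of let-7 positions 2-8."""
        assert revcomp(LET7.seed7) == "CUACCUC"
        target = "GGGG" + "CUACCUC" + "GGGG"
        sites = seed_sites(LET7, target, "t")
        assert len(sites) == 1
        assert sites[0].site_type == "7mer-m8"
        assert sites[0].position == 5

    def test_full_complement_reports_seed_site(self):
        target = revcomp(LET7.sequence)
        sites = seed_sites(LET7, target, "t")
        assert len(sites) == 1
        # seed complement sits at the 3' end of the reverse complement
        assert sites[0].position == len(target) - 7

    def test_eight_mer_requires_trailing_A(self):
        sites = seed_sites(LET7, "GG" + "CUACCUC" + "A" + "GG", "t")
        assert sites[0].site_type == "8mer"

    def test_a1_only_site_excluded_in_strict_mode(self):
        target = "GG" + "UACCUC" + "A" + "GG"  # 6mer core + A, no m8
        assert seed_sites(LET7, target, "t", strict=True) == []
        lax = seed_sites(LET7, target, "t", strict=False)
        assert [s.site_type for s in lax] == ["7mer-A1"]

    def test_no_complement_no_sites(self):
        assert seed_sites(LET7, "A" * 60, "t") == []

    def test_rejects_dna_alphabet_with_ambiguity_codes(self):
        with pytest.raises(ValidationError):
            seed_sites(LET7, "ACGUN", "t")

    def test_agrees_with_brute_force_on_random_pairs(self):
        """1,000 random miRNA/target pairs against the window oracle."""
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGU"))
        mismatches = 0
        for i in range(1000):
            mirna = MicroRNA(
                f"m{i}", "".join(rng.choice(bases, 22))
            )
            target = "".join(rng.choice(bases, 120))
            got = {
                (s.position, s.site_type)
                for s in seed_sites(mirna, target, "t", strict=False)
            }
            expect = set(brute_force_sites(mirna, target))
            if got != expect:
                mismatches += 1
        assert mismatches == 0

    def test_planted_synthetic_sites_all_recovered(self, small_sim):
        triplets = [("lnc_0001", "mir_0001", "mRNA_0001"),
                    ("circ_0002", "mir_0002", "mRNA_0003")]
        mseqs, tseqs, truth = simulate_sequences(small_sim, triplets)
        mirnas = {m.mirna_id: m for m in mirna_objects(mseqs)}
        for site in truth:
            found = seed_sites(
                mirnas[site.mirna_id], tseqs[site.target_id], site.target_id
            )
            assert any(
                s.position == site.position and s.site_type == site.site_type
                for s in found
            )


def _expr_for_pairs(matrix_factory, mirna_col, target_col):
    vals = np.vstack([mirna_col, target_col]).astype(float)
    m = matrix_factory(vals, transformed=True)
    return m.values.rename(index={"f0": "mir", "f1": "tgt"}).pipe(
        lambda df: df
    )


class TestPairFilters:
    def _pairs(self, mirna_dir, target_dir):
        return pd.DataFrame(
            [
                {
                    "mirna_id": "mir",
                    "target_id": "tgt",
                    "target_class": "lncRNA",
                    "evidence": "seed",
                    "mirna_dir": mirna_dir,
                    "target_dir": target_dir,
                }
            ]
        )

    def _expr(self, matrix_factory, rho):
        """Two features with a chosen sample correlation sign/strength."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        noise = rng.normal(size=20)
        y = rho * x + np.sqrt(max(1 - rho**2, 0)) * noise
        m = matrix_factory(np.vstack([x, y]), transformed=True)
        m.values.index = ["mir", "tgt"]
        m.feature_meta.index = ["mir", "tgt"]
        return m

    def test_same_direction_dropped_regardless_of_pcc(self, matrix_factory):
        m = self._expr(matrix_factory, -0.99)
        out = filter_pairs(self._pairs("up", "up"), m)
        assert len(out) == 0

    @pytest.mark.parametrize("rho, kept", [(-0.95, True), (-0.1, False)])
    def test_anticorrelation_threshold(self, matrix_factory, rho, kept):
        m = self._expr(matrix_factory, rho)
        out = filter_pairs(self._pairs("down", "up"), m)
        assert (len(out) == 1) is kept

    def test_inclusive_boundary_at_threshold(self, matrix_factory):
        """PCC exactly at -0.4 is retained (inclusive boundary)."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        # construct y with exact PCC -0.4 against x
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        orth = np.array([1.0, -1.0, -1.0, 1.0])
        orth = orth - orth @ xc * xc
        orth /= np.linalg.norm(orth)
        y = -0.4 * xc + np.sqrt(1 - 0.16) * orth
        m = self._expr(matrix_factory, 0)
        m.values.loc["mir"] = np.tile(x, 5)[:20]
        m.values.loc["tgt"] = np.tile(y, 5)[:20]
        pcc = float(np.corrcoef(m.values.loc["mir"], m.values.loc["tgt"])[0, 1])
        assert pcc == pytest.approx(-0.4, abs=1e-12)
        # pin the cut to the realised correlation: inclusive keeps,
        # exclusive drops the exact-boundary pair
        out = filter_pairs(
            self._pairs("down", "up"), m,
            thresholds=Thresholds(pcc_mirna_target=pcc),
        )
        assert len(out) == 1
        strict = filter_pairs(
            self._pairs("down", "up"), m,
            thresholds=Thresholds(pcc_mirna_target=pcc,
                                  pcc_mirna_target_inclusive=False),
        )
        assert len(strict) == 0

    def test_too_few_samples_dropped(self, matrix_factory):
        m = matrix_factory(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
                           transformed=True)
        m.values.index = ["mir", "tgt"]
        m.feature_meta.index = ["mir", "tgt"]
        with pytest.warns(UserWarning, match="dropped"):
            out = filter_pairs(self._pairs("down", "up"), m)
        assert len(out) == 0


class TestBuildCandidates:
    def test_empty_inputs_empty_output(self):
        out = build_candidates({}, {}, {}, [], None)
        assert len(out) == 0

    def test_seed_pair_construction(self):
        from cernakit.target_pred import TargetSite

        sites = [TargetSite("lncA", "mirX", 10, "7mer-m8")]
        out = build_candidates(
            {"mirX": "down"}, {"lncA": "up"}, {}, sites, None,
            {"lncA": "lncRNA"},
        )
        assert len(out) == 1
        assert out.iloc[0]["evidence"] == "seed"
        assert out.iloc[0]["target_class"] == "lncRNA"

    def test_database_dialects_merge_evidence(self):
        external = pd.DataFrame(
            [
                {"mirna_id": "mirX", "target_id": "geneY",
                 "evidence": "validated", "source": "a"},
                {"mirna_id": "mirX", "target_id": "geneY",
                 "evidence": "predicted", "source": "b"},
            ]
        )
        out = build_candidates(
            {"mirX": "up"}, {}, {"geneY": "down"}, [], external
        )
        assert len(out) == 1
        assert out.iloc[0]["evidence"] == "predicted_db+validated_db"

    def test_missing_de_call_dropped_with_warning(self):
        from cernakit.target_pred import TargetSite

        sites = [TargetSite("lncA", "mirX", 10, "7mer-m8")]
        with pytest.warns(UserWarning, match="dysregulation"):
            out = build_candidates({}, {"lncA": "up"}, {}, sites, None)
        assert len(out) == 0
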