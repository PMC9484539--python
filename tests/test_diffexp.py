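import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from cernakit.diffexp import (
    adjust_bh,
    call_dysregulated,
    direction_calls,
    nb_wald_test,
    wilcoxon_two_group,
    _mom_dispersion,
)
from cernakit.matrix import ValidationError
from cernakit.synthetic import nb_sample


def _two_group(values, n_per_group):
    cols = ["tumor"] * n_per_group + ["normal"] * n_per_group
    return values, cols


class TestNBWald:
    def test_identical_groups_zero_log2fc(self, matrix_factory):
        vals = np.tile([[5, 9, 13, 20]], (3, 1))
        vals = np.hstack([vals, vals])  # tumor block == normal block
        m = matrix_factory(vals, conditions=["tumor"] * 4 + ["normal"] * 4)
        res = nb_wald_test(m, factors=pd.Series(1.0, index=m.sample_ids))
        assert (res["log2fc"] == 0).all()

    def test_all_zero_feature_degenerate(self, matrix_factory):
        vals = np.vstack([[0] * 8, [10] * 8])
        m = matrix_factory(vals, conditions=["tumor"] * 4 + ["normal"] * 4)
        res = nb_wald_test(m, factors=pd.Series(1.0, index=m.sample_ids))
        assert res.loc["f0", "p"] == 1.0
        assert res.loc["f0", "log2fc"] == 0.0
        assert bool(res.loc["f0", "degenerate"])

    def test_matches_statsmodels_glm_oracle(self, matrix_factory):
        """Our separable Newton MLE equals a GLM fit at the same dispersion."""
        rng = np.random.default_rng(42)
        n = 8
        mu = np.concatenate([np.full(n, 400.0), np.full(n, 100.0)])
        counts = nb_sample(rng, np.tile(mu, (5, 1)), 0.1)
        s = rng.lognormal(0, 0.2, 2 * n)
        m = matrix_factory(counts, conditions=["tumor"] * n + ["normal"] * n)
        factors = pd.Series(s, index=m.sample_ids)
        res = nb_wald_test(m, factors=factors)
        alpha = _mom_dispersion(
            counts / s[None, :], [np.arange(n), np.arange(n, 2 * n)]
        )
        X = np.column_stack([np.ones(2 * n), [1] * n + [0] * n])
        for i in range(5):
            glm = sm.GLM(
                counts[i],
                X,
                family=sm.families.NegativeBinomial(alpha=alpha[i]),
                offset=np.log(s),
            ).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(
                glm.params[1] / np.log(2), abs=1e-5
            )

    def test_power_monotone_in_effect_size(self, matrix_factory):
        """Bigger planted shifts are detected more often (matched seeds)."""
        powers = []
        for lfc in (0.5, 1.0, 2.0):
            rng = np.random.default_rng(7)
            n_feat, n = 300, 8
            mu_n = np.full((n_feat, n), 100.0)
            mu_t = mu_n * 2.0**lfc
            counts = np.hstack(
                [nb_sample(rng, mu_t, 0.1), nb_sample(rng, mu_n, 0.1)]
            )
            m = matrix_factory(
                counts, conditions=["tumor"] * n + ["normal"] * n
            )
            res = nb_wald_test(m, factors=pd.Series(1.0, index=m.sample_ids))
            powers.append((res["p"] < 0.05).mean())
        assert powers[0] < powers[1] < powers[2]

    def test_requires_two_samples_per_group(self, matrix_factory):
        m = matrix_factory([[1, 2, 3]], conditions=["tumor", "normal", "normal"])
        with pytest.raises(ValidationError):
            nb_wald_test(m)


class TestBenjaminiHochberg:
    def test_hand_computed_case(self):
        padj = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert padj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3]) == pytest.approx([0.3])

    def test_order_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert adjust_bh(p)[perm] == pytest.approx(adjust_bh(p[perm]))

    @staticmethod
    def _bh_oracle(p):
        """Literal step-up definition: padj_i = min over j>=rank(i) of m*p(j)/j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            adj[i] = min(running, 1.0)
        return adj

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=100,
        )
    )
    def test_matches_stepup_oracle(self, p):
        assert adjust_bh(p) == pytest.approx(self._bh_oracle(p), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])


class TestDysregulationCalls:
    @pytest.mark.parametrize(
        "padj, log2fc, padj_cut, expected",
        [
            (0.05, 1.5, 0.1, "up"),
            (0.05, 0.5, 0.1, "ns"),   # |fc| < 2
            (0.15, 3.0, 0.1, "ns"),   # padj above tumorigenesis cut
            (0.15, 3.0, 0.25, "up"),  # same feature passes the subclass cut
            (0.05, -1.5, 0.1, "down"),
            (0.1, 1.5, 0.1, "ns"),    # strict: padj == cut fails
            (0.05, 1.0, 0.1, "ns"),   # strict: log2fc == log2(2) fails
        ],
    )
    def test_threshold_boundaries(self, padj, log2fc, padj_cut, expected):
        res = pd.DataFrame(
            {"log2fc": [log2fc], "p": [padj], "padj": [padj]}, index=["f"]
        )
        d = direction_calls(res, padj_cut, 2.0)
        assert d["f"] == expected

    def test_returns_disjoint_sets(self):
        res = pd.DataFrame(
            {
                "log2fc": [2.0, -2.0, 0.1],
                "p": [0.001, 0.001, 0.9],
                "padj": [0.01, 0.01, 0.9],
            },
            index=["a", "b", "c"],
        )
        up, down = call_dysregulated(res, 0.1, 2.0)
        assert up == {"a"} and down == {"b"}


class TestWilcoxon:
    def test_exact_small_sample_p(self):
        p = wilcoxon_two_group(
            [1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3
        )
        assert p == pytest.approx(0.1)  # 2/C(6,3) enumerations

    def test_monotone_transform_invariance(self):
        x = [1.0, 4.0, 2.5, 9.0, 7.0, 6.0]
        labels = ["a", "a", "a", "b", "b", "b"]
        assert wilcoxon_two_group(x, labels) == pytest.approx(
            wilcoxon_two_group(np.exp(x), labels)
        )

    def test_mirror_symmetric_data_p_one(self):
        p = wilcoxon_two_group([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_two_group([1, 2, 3], ["a", "a", "a"])
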