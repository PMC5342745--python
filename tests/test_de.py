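import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tamsig.de import (bh_fdr, de_table, equalize_depth,
                       estimate_common_dispersion, nb_exact_test, seed_genes)


def conv_split_pvalue(a, b, phi):
    """Independent oracle: conditional split distribution obtained by
    numerically convolving per-sample NB pmfs (no size-additivity)."""
    a, b = np.asarray(a), np.asarray(b)
    total = int(a.sum() + b.sum())
    mu = total / (len(a) + len(b))

    def group_pmf(n):
        if phi < 1e-10:
            single = stats.poisson.pmf(np.arange(total + 1), mu)
        else:
            size = 1.0 / phi
            single = stats.nbinom.pmf(np.arange(total + 1), size, size / (size + mu))
        out = np.zeros(total + 1)
        out[0] = 1.0
        for _ in range(n):
            out = np.convolve(out, single)[: total + 1]
        return out

    joint = group_pmf(len(a)) * group_pmf(len(b))[::-1]
    obs = joint[int(a.sum())]
    return joint[joint <= obs * (1 + 1e-9)].sum() / joint.sum()


class TestExactTest:
    def test_balanced_identical_sums_give_p_one(self):
        assert nb_exact_test([3, 3], [3, 3], 0.1) == 1.0

    def test_empty_total_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.1) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nb_exact_test([-1, 2], [3, 4], 0.1)

    def test_worked_small_instance_matches_enumeration(self):
        p = nb_exact_test([0, 0], [5, 6], 0.01)
        assert p == pytest.approx(conv_split_pvalue([0, 0], [5, 6], 0.01), rel=1e-9)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_convolution_oracle_small_totals(self, trial):
        rng = np.random.default_rng(100 + trial)
        na, nb = rng.integers(2, 5, size=2)
        a = rng.integers(0, 8, size=na)
        b = rng.integers(0, 8, size=nb)
        if a.sum() + b.sum() == 0:
            a[0] = 1
        phi = float(rng.choice([0.01, 0.1, 0.5]))
        assert nb_exact_test(a, b, phi) == pytest.approx(
            conv_split_pvalue(a, b, phi), rel=1e-9)

    def test_poisson_limit_matches_conditional_binomial(self):
        def binom_two_sided(a, b):
            total = int(np.sum(a) + np.sum(b))
            pr = len(a) / (len(a) + len(b))
            pm = stats.binom.pmf(np.arange(total + 1), total, pr)
            obs = pm[int(np.sum(a))]
            return pm[pm <= obs * (1 + 1e-9)].sum()

        for a, b in [([3, 4, 5], [9, 10]), ([0, 1], [7, 8, 9]), ([20, 25], [15, 30])]:
            assert nb_exact_test(a, b, 1e-12) == pytest.approx(
                binom_two_sided(a, b), rel=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.lists(st.integers(0, 20), min_size=2, max_size=4),
           b=st.lists(st.integers(0, 20), min_size=2, max_size=4),
           phi=st.sampled_from([0.01, 0.1, 0.3]))
    def test_symmetric_in_group_labels(self, a, b, phi):
        assert nb_exact_test(a, b, phi) == pytest.approx(
            nb_exact_test(b, a, phi), rel=1e-12)


class TestDispersion:
    def _counts(self, rng, phi, n_genes=2000, n=10):
        mu = rng.uniform(50, 500, n_genes)
        if phi == 0:
            c = rng.poisson(mu[:, None], (n_genes, n))
        else:
            p = 1 / (1 + phi * mu[:, None])
            c = rng.negative_binomial(1 / phi, np.broadcast_to(p, (n_genes, n)))
        counts = pd.DataFrame(c, columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({"cell_type": ["TAM"] * 5 + ["pMPH"] * 5,
                                "batch": "b1"}, index=counts.columns)
        return counts, samples

    def test_poisson_data_estimates_near_zero(self):
        counts, samples = self._counts(np.random.default_rng(0), 0.0)
        assert estimate_common_dispersion(counts, samples) <= 0.01

    def test_recovers_planted_dispersion(self):
        counts, samples = self._counts(np.random.default_rng(1), 0.2)
        assert 0.1 <= estimate_common_dispersion(counts, samples) <= 0.3

    def test_single_sample_groups_fall_back_to_floor(self):
        counts = pd.DataFrame([[5, 9], [3, 2]], columns=["s0", "s1"])
        samples = pd.DataFrame({"cell_type": ["TAM", "pMPH"], "batch": "b1"},
                               index=counts.columns)
        phi = estimate_common_dispersion(counts, samples)
        assert np.isfinite(phi) and phi == 1e-8


class TestBhFdr:
    def test_identical_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.04] * 10), 0.04)

    def test_hand_computed_stepup(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_single_pvalue_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_dominates_p_and_is_monotone(self, pvals):
        q = bh_fdr(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSeedSelection:
    def test_empty_results_empty_seed(self):
        table = pd.DataFrame({"q": []})
        assert len(seed_genes(table)) == 0

    def test_boundary_q_included(self):
        table = pd.DataFrame({"q": [0.19, 0.2, 0.21]}, index=["a", "b", "c"])
        assert list(seed_genes(table, 0.2)) == ["a", "b"]

    def test_planted_effects_reach_seed(self, default_run):
        """Strong planted effects are significant at FDR 0.2 in the
        end-to-end run."""
        results, _, _ = default_run
        truth = results["truth"]
        table = results["tables"]["TAM_vs_pMPH"]
        seeds = set(seed_genes(table, 0.2))
        planted = set(truth.up_gene_ids) | set(truth.down_gene_ids)
        assert planted <= seeds


def test_equalize_depth_matches_geometric_mean():
    counts = pd.DataFrame({"s0": [10, 10], "s1": [40, 40]})
    eq = equalize_depth(counts)
    assert eq["s0"].sum() == eq["s1"].sum() == 40  # geometric mean of 20, 80


def test_de_table_orientation():
    """A gene with higher counts in the TAM group gets a positive fold
    change and a small p-value."""
    rng = np.random.default_rng(3)
    n = 8
    base = rng.poisson(200, size=(40, n))
    base[0, :4] *= 12
    counts = pd.DataFrame(base, index=[f"g{i}" for i in range(40)],
                          columns=[f"s{i}" for i in range(n)])
    samples = pd.DataFrame({"cell_type": ["TAM"] * 4 + ["pMPH"] * 4,
                            "batch": "b1"}, index=counts.columns)
    lengths = pd.Series(1000, index=counts.index)
    from tamsig.expression import compute_tpm
    table = de_table(counts, compute_tpm(counts, lengths), samples)
    assert table.loc["g0", "log2_fc"] > 2
    assert table.loc["g0", "q"] < 0.05
    assert (table["q"] >= table["p"] - 1e-12).all()
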