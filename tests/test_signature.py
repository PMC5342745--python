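import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tamsig.signature import (SignatureResult, classify_fold_change,
                              extend_signature, max_seed_correlation,
                              quartile_nonoverlap, venn_overlap)


class TestSeedCorrelation:
    def _mat(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=[f"TAM{i}" for i in range(len(rows[0]))])

    def test_candidate_identical_to_seed(self):
        x = self._mat([[1, 2, 3, 4], [1, 2, 3, 4]])
        r = max_seed_correlation(x, ["g0"])
        assert r["g1"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = self._mat([[1, 2, 3, 4], [7, 9, 11, 13]])  # 2*seed + 5
        assert max_seed_correlation(x, ["g0"])["g1"] == pytest.approx(1.0)

    def test_matches_pearson_formula(self):
        cand, seed = [1, 2, 3, 4], [1, 2, 3, 5]
        x = self._mat([seed, cand])
        expected = stats.pearsonr(cand, seed).statistic
        assert max_seed_correlation(x, ["g0"])["g1"] == pytest.approx(expected)

    def test_max_over_seeds(self):
        x = self._mat([[1, 2, 3, 4], [4, 3, 2, 1], [1.1, 2.2, 2.9, 4.3]])
        r = max_seed_correlation(x, ["g0", "g1"])
        assert r["g2"] > 0.99  # best seed is g0, not the anticorrelated g1

    def test_centroid_mode_is_stricter_than_any_seed(self):
        rng = np.random.default_rng(1)
        seed_a = rng.normal(size=8)
        seed_b = rng.normal(size=8)
        cand = seed_a + rng.normal(0, 0.1, 8)   # tracks one seed gene only
        x = self._mat([seed_a, seed_b, cand])
        any_r = max_seed_correlation(x, ["g0", "g1"], mode="any-seed")["g2"]
        cen_r = max_seed_correlation(x, ["g0", "g1"], mode="centroid")["g2"]
        assert any_r > 0.95 > cen_r

    def test_unknown_mode_rejected(self):
        x = self._mat([[1, 2, 3, 4]])
        with pytest.raises(ValueError, match="mode"):
            max_seed_correlation(x, ["g0"], mode="median")

    def test_flat_candidate_excluded_not_nan(self):
        x = self._mat([[1, 2, 3, 4], [5, 5, 5, 5]])
        r = max_seed_correlation(x, ["g0"])
        assert r["g1"] == -np.inf

    def test_too_few_samples_rejected(self):
        x = self._mat([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match=">= 3 TAM samples"):
            max_seed_correlation(x, ["g0"])


class TestQuartileRule:
    def test_identical_distributions_false(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert not quartile_nonoverlap(v, v, "up")

    def test_separated_groups_true(self):
        # Q1(TAM) = 10.75 > Q3(ref) = 3.25 under type-7 quantiles
        assert quartile_nonoverlap([10, 11, 12, 13], [1, 2, 3, 4], "up")

    def test_single_outlier_does_not_separate(self):
        # Q1(TAM) = 1.75 < Q3(ref) = 4.25
        assert not quartile_nonoverlap([1, 2, 3, 50], [2, 3, 4, 5], "up")

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            quartile_nonoverlap([1, 2], [3, 4], "sideways")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
           b=st.lists(st.floats(-50, 50), min_size=2, max_size=10))
    def test_antisymmetric(self, a, b):
        assert quartile_nonoverlap(a, b, "up") == quartile_nonoverlap(b, a, "down")


class TestFoldChange:
    @pytest.mark.parametrize("tam,ref,expected", [
        (30.0, 10.0, "none"),    # boundary is strict
        (31.0, 10.0, "up"),
        (10.0, 31.0, "down"),
        (5.0, 0.0, "up"),        # expression from nothing
        (0.0, 5.0, "down"),
        (0.0, 0.0, "none"),
    ])
    def test_classification(self, tam, ref, expected):
        assert classify_fold_change(tam, ref, 3.0) == expected

    def test_negative_median_rejected(self):
        with pytest.raises(ValueError):
            classify_fold_change(-1.0, 2.0)


def _toy_cohort(log_rows, samples_spec, genes=None):
    genes = genes or [f"g{i}" for i in range(len(log_rows))]
    cols = [f"{ct}{i}" for ct, n in samples_spec for i in range(n)]
    log_x = pd.DataFrame(log_rows, index=genes, columns=cols, dtype=float)
    tpm = (2.0 ** log_x - 1).clip(lower=0)
    samples = pd.DataFrame(
        {"cell_type": np.repeat([ct for ct, _ in samples_spec],
                                [n for _, n in samples_spec]),
         "batch": "b1"}, index=cols)
    return tpm, log_x, samples


class TestExtendSignature:
    def test_empty_seed_rejected(self):
        tpm, log_x, samples = _toy_cohort([[1] * 6], [("TAM", 4), ("pMPH", 2)])
        with pytest.raises(ValueError, match="seed set is empty"):
            extend_signature(tpm, log_x, samples, [])

    def test_seed_only_signature_is_fold_change_classified_seed(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.05, (3, 6))
        rows = np.array([[8, 8, 8, 8, 3, 3],     # seed, clearly up
                         [3, 3, 3, 3, 8, 8],     # seed, clearly down
                         [5, 5, 5, 5, 5, 5]]) + noise
        tpm, log_x, samples = _toy_cohort(rows, [("TAM", 4), ("pMPH", 2)])
        sig = extend_signature(tpm, log_x, samples, ["g0", "g1"])
        assert sig.up == ["g0"] and sig.down == ["g1"]

    def test_correlated_candidate_with_quartile_overlap_excluded(self):
        seed_tam = [1.0, 2.0, 30.0, 32.0]
        cand_tam = [1.0, 2.0, 30.0, 31.0]      # r ~ 1 to the seed
        rows = [seed_tam + [0.1, 0.1, 0.1, 0.1],
                cand_tam + [0.0, 0.0, 3.0, 3.0]]  # ref quartiles overlap TAM's
        tpm, log_x, samples = _toy_cohort(rows, [("TAM", 4), ("pMPH", 4)])
        sig = extend_signature(tpm, log_x, samples, ["g0"])
        assert "g1" not in sig.up
        assert sig.table.loc["g1", "max_seed_r"] > 0.9
        assert sig.table.loc["g1", "reason"] == "quartile overlap"

    def test_seed_gene_failing_fold_change_reported_not_dropped(self):
        rows = [[5.0, 5.1, 4.9, 5.0, 4.8, 5.2]]
        tpm, log_x, samples = _toy_cohort(rows, [("TAM", 4), ("pMPH", 2)])
        sig = extend_signature(tpm, log_x, samples, ["g0"])
        assert sig.up == [] and sig.down == []
        assert "fold-change" in sig.table.loc["g0", "reason"]

    def test_threshold_monotonicity(self, clean_cohort):
        """Raising r, fold-change or expression thresholds never enlarges
        the signature."""
        from tamsig.expression import compute_tpm, log_transform

        counts, lengths, samples, truth = clean_cohort
        tpm = compute_tpm(counts, lengths)
        log_x = log_transform(tpm)
        seed = truth.up_gene_ids[:10] + truth.down_gene_ids
        base = extend_signature(tpm, log_x, samples, seed)
        for kw in ({"r_threshold": 0.95}, {"fc_threshold": 5.0}, {"min_tpm": 30.0}):
            tight = extend_signature(tpm, log_x, samples, seed, **kw)
            assert set(tight.up) <= set(base.up)
            assert set(tight.down) <= set(base.down)


class TestVenn:
    def _sig(self, up):
        return SignatureResult("x", [], list(up), [], pd.DataFrame())

    def test_identical_sets(self):
        assert venn_overlap(self._sig("abc"), self._sig("abc")) == (0, 3, 0)

    def test_disjoint_sets(self):
        assert venn_overlap(self._sig("abc"), self._sig("defgh")) == (3, 0, 5)

    def test_partial_overlap(self):
        assert venn_overlap(self._sig("abcd"), self._sig("cdef")) == (2, 2, 2)
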