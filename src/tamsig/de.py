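"""Negative-binomial exact test and BH-FDR seed selection.

The significance stage mirrors the classic exact NB test for two-group
count data: libraries are first equalized to a common depth, a common
dispersion phi (variance mu + phi*mu^2) is estimated by pooled method of
moments, and each gene's two-group split of the total count is compared
with its conditional distribution.  Group sums are sufficient under equal
depths: the sum of n i.i.d. NB(mean mu, size 1/phi) variables is
NB(mean n*mu, size n/phi).

The two-sided p-value is the conditional probability of all splits of the
total that are at most as probable as the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

PHI_FLOOR = 1e-8
#: Below this dispersion the NB is numerically Poisson.
POISSON_PHI = 1e-10
#: Relative log-probability tolerance when collecting equiprobable splits.
TIE_TOL = 1e-10


def equalize_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the geometric-mean library size and round.

    A documented simplification of TMM-style normalization: adequate when
    library sizes are within a small factor of each other, as in the
    simulated cohorts.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    target = np.exp(np.log(lib).mean())
    return counts.mul(target / lib, axis=1).round().astype(np.int64)


def estimate_common_dispersion(counts: pd.DataFrame, samples: pd.DataFrame) -> float:
    """Pooled method-of-moments common dispersion on depth-equalized counts.

    Moments are pooled within cell-type x batch cells (so per-gene batch
    shifts do not masquerade as dispersion), giving a per-gene estimate
    phi_g from sum(s2 - mu) = phi * sum(mu^2) over a gene's cells; the
    common value is the median of phi_g across genes, which a handful of
    strongly (co-)regulated genes cannot dominate.  Floored at 1e-8.
    """
    eq = equalize_depth(counts)
    meta = samples.loc[eq.columns]
    keys = ["cell_type", "batch"] if "batch" in meta.columns else ["cell_type"]
    num = np.zeros(eq.shape[0])
    den = np.zeros(eq.shape[0])
    for _, ids in meta.groupby(keys).groups.items():
        ids = eq.columns.intersection(ids)
        if len(ids) < 2:
            continue
        sub = eq[ids].to_numpy(dtype=float)
        num += sub.var(axis=1, ddof=1) - sub.mean(axis=1)
        den += sub.mean(axis=1) ** 2
    ok = den > 0
    if not ok.any():
        return PHI_FLOOR
    return max(float(np.median(num[ok] / den[ok])), PHI_FLOOR)


def _group_sum_logpmf(total: int, n_samples: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of ``n_samples`` NB(mu, phi) counts, on 0..total."""
    s = np.arange(total + 1)
    if phi < POISSON_PHI:
        return stats.poisson.logpmf(s, n_samples * mu)
    size = n_samples / phi
    p = size / (size + n_samples * mu)
    return stats.nbinom.logpmf(s, size, p)


def nb_exact_test(counts_a, counts_b, phi: float) -> float:
    """Two-sided conditional exact test of equal means for two NB groups.

    ``counts_a``/``counts_b`` are depth-equalized integer count vectors.
    Returns the conditional probability, given the total, of all splits
    with probability at most that of the observed split.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    sa, sb = int(a.sum()), int(b.sum())
    total = sa + sb
    if total == 0:
        return 1.0
    mu = total / (len(a) + len(b))
    lpa = _group_sum_logpmf(total, len(a), mu, phi)
    lpb = _group_sum_logpmf(total, len(b), mu, phi)
    joint = lpa + lpb[::-1]          # joint[s] = P(SA=s) P(SB=total-s)
    norm = logsumexp(joint)
    obs = joint[sa]
    keep = joint <= obs + TIE_TOL * max(1.0, abs(obs))
    p = float(np.exp(logsumexp(joint[keep]) - norm))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(counts: pd.DataFrame, tpm: pd.DataFrame, samples: pd.DataFrame,
             group_a: str = "TAM", group_b: str = "pMPH",
             phi: float | None = None) -> pd.DataFrame:
    """Per-gene exact-test table for one two-group comparison.

    ``counts`` should already be restricted to the genes under test (the
    purity-filtered universe).  Medians and fold changes are computed on
    the TPM matrix.  Returns a DataFrame with columns median_a, median_b,
    log2_fc, p, q indexed by gene.
    """
    ids_a = samples.index[samples["cell_type"] == group_a].intersection(counts.columns)
    ids_b = samples.index[samples["cell_type"] == group_b].intersection(counts.columns)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"missing samples for comparison {group_a} vs {group_b}")
    eq = equalize_depth(counts[list(ids_a) + list(ids_b)])
    if phi is None:
        phi = estimate_common_dispersion(counts, samples)
    A = eq[ids_a].to_numpy()
    B = eq[ids_b].to_numpy()
    pvals = np.array([nb_exact_test(A[i], B[i], phi) for i in range(eq.shape[0])])
    med_a = tpm.loc[eq.index, ids_a].median(axis=1)
    med_b = tpm.loc[eq.index, ids_b].median(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(med_a.to_numpy()) - np.log2(med_b.to_numpy())
    return pd.DataFrame({
        f"median_{group_a}": med_a,
        f"median_{group_b}": med_b,
        "log2_fc": log2fc,
        "p": pvals,
        "q": bh_fdr(pvals),
    }, index=eq.index)


def seed_genes(table: pd.DataFrame, fdr_threshold: float = 0.2) -> pd.Index:
    """Genes significant at the given BH-FDR (boundary inclusive)."""
    return table.index[table["q"] <= fdr_threshold]
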