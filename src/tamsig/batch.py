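"""Variance pre-filter and empirical-Bayes location/scale batch adjustment.

The adjustment follows the parametric ComBat procedure: per-gene
standardization, per-(gene, batch) location (gamma) and scale (delta^2)
estimates, shrinkage of both toward batch-level normal / inverse-gamma
priors fitted by method of moments, then back-transformation.  No covariate
design is modelled; batches are assumed balanced with respect to biology.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EB_TOL = 1e-4
EB_MAX_ITER = 100


def variance_filter(x: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Drop genes whose sample variance (n-1 denominator) is below
    ``threshold`` on the input scale; gene order is preserved."""
    if x.shape[1] < 2:
        raise ValueError("variance filter needs >= 2 samples")
    var = x.var(axis=1, ddof=1)
    keep = var >= threshold
    out = x.loc[keep]
    log.info("variance_filter: kept %d / %d genes (threshold %g)",
             keep.sum(), len(keep), threshold)
    if keep.sum() == 0:
        log.warning("variance_filter removed every gene")
    out.attrs.update(x.attrs)
    return out


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def combat_adjust(x: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Empirical-Bayes batch adjustment of a log-scale expression matrix.

    ``samples`` must carry a ``batch`` column covering every column of
    ``x``.  With a single batch the matrix is returned unchanged.  A batch
    with one sample is rejected (its scale cannot be estimated).
    """
    batches = samples.loc[x.columns, "batch"]
    labels = batches.unique().tolist()
    if x.shape[0] == 0:
        log.warning("combat_adjust: empty matrix, nothing to correct")
        return x.copy()
    if len(labels) == 1:
        log.info("combat_adjust: single batch %r, nothing to correct", labels[0])
        out = x.copy()
        out.attrs.update(x.attrs)
        return out
    sizes = batches.value_counts()
    for b in labels:
        if sizes[b] < 2:
            raise ValueError(f"batch {b!r} has a single sample; cannot estimate its scale")

    Y = x.to_numpy(dtype=float)
    n_genes, n = Y.shape
    idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in labels}

    # Standardize: grand mean is the batch-size-weighted mean of batch
    # means; pooled variance is the mean squared residual around batch means.
    batch_mean = {b: Y[:, idx[b]].mean(axis=1) for b in labels}
    grand = sum(sizes[b] / n * batch_mean[b] for b in labels)
    resid = np.empty_like(Y)
    for b in labels:
        resid[:, idx[b]] = Y[:, idx[b]] - batch_mean[b][:, None]
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    Z = (Y - grand[:, None]) / sd[:, None]

    Zadj = np.empty_like(Z)
    for b in labels:
        cols = idx[b]
        nb = len(cols)
        g_hat = Z[:, cols].mean(axis=1)
        d_hat = Z[:, cols].var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        t2 = max(t2, 1e-12)
        a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)

        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(EB_MAX_ITER):
            g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
            ss = ((Z[:, cols] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_pr + 0.5 * ss) / (nb / 2.0 + a_pr - 1.0)
            change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < EB_TOL:
                break
        Zadj[:, cols] = (Z[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = pd.DataFrame(Zadj * sd[:, None] + grand[:, None],
                       index=x.index, columns=x.columns)
    out.attrs.update(x.attrs)
    return out


def batch_variance_fraction(x: pd.DataFrame, samples: pd.DataFrame) -> float:
    """Mean (over genes) fraction of total variance explained by batch —
    the diagnostic used to judge the adjustment."""
    batches = samples.loc[x.columns, "batch"]
    Y = x.to_numpy(dtype=float)
    total = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    between = np.zeros(Y.shape[0])
    for b in batches.unique():
        cols = np.flatnonzero((batches == b).to_numpy())
        between += len(cols) * (Y[:, cols].mean(axis=1) - Y.mean(axis=1)) ** 2
    ok = total > 0
    return float((between[ok] / total[ok]).mean())
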