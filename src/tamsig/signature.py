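"""Signature extension: the seed-and-extend core of the analysis.

A small seed of significance-selected genes is extended to every gene that
(i) is tightly co-expressed with a seed gene across TAM samples
(Pearson r above a threshold on the log2 scale), (ii) shows quartile
non-overlap between the TAM and reference groups, and (iii) clears a
median fold-change threshold.  Seed genes themselves only need the fold
change.  Quartiles use the linear-interpolation (type-7) definition —
with four reference samples the rule is sensitive to this choice, so it is
fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SignatureResult:
    """Result of one comparison (e.g. TAM_vs_pMPH)."""

    label: str
    seed: list
    up: list
    down: list
    table: pd.DataFrame          # per-gene diagnostics
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (f"{self.label}: seed={len(self.seed)} "
                f"up={len(self.up)} down={len(self.down)}")


def max_seed_correlation(log_tam: pd.DataFrame, seed,
                         mode: str = "any-seed") -> pd.Series:
    """Pearson r of every gene against the seed set across TAM samples.

    mode="any-seed" (default): the max r against any individual seed gene
    — the most permissive reading of "correlated with the seed set".
    mode="centroid": r against the mean seed profile (stricter).

    Zero-variance genes (candidate or seed) are excluded from the
    correlation rather than producing NaN: a flat candidate gets r = -inf,
    a flat seed gene simply cannot anchor anything.
    """
    if log_tam.shape[1] < 3:
        raise ValueError("need >= 3 TAM samples for seed correlations")
    if mode not in ("any-seed", "centroid"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    seed = [g for g in seed if g in log_tam.index]
    if not seed:
        raise ValueError("no seed genes present in the matrix")
    X = log_tam.to_numpy(dtype=float)
    sd = X.std(axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = Xc / np.where(sd > 0, sd, np.nan)[:, None]
    seed_pos = log_tam.index.get_indexer(pd.Index(seed).drop_duplicates())
    if mode == "centroid":
        cen = log_tam.iloc[seed_pos].mean(axis=0).to_numpy()
        cen = cen - cen.mean()
        csd = cen.std()
        if csd == 0:
            raise ValueError("seed centroid has zero variance")
        best = Xn @ (cen / csd) / log_tam.shape[1]
        best = np.where(np.isnan(best), -np.inf, best)
    else:
        R = Xn @ Xn[seed_pos].T / log_tam.shape[1]
        R = np.where(np.isnan(R), -np.inf, R)
        best = R.max(axis=1)
    best[~(sd > 0)] = -np.inf
    return pd.Series(best, index=log_tam.index, name="max_seed_r")


def quartile_nonoverlap(tam_values, ref_values, direction: str) -> bool:
    """Quartile non-overlap rule between the TAM and reference samples.

    direction="up": the TAM lower quartile must exceed the reference upper
    quartile; mirrored for "down".
    """
    tam = np.asarray(tam_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if tam.size < 2 or ref.size < 2:
        raise ValueError("need >= 2 values per group for quartiles")
    if direction == "up":
        return bool(np.percentile(tam, 25) > np.percentile(ref, 75))
    if direction == "down":
        return bool(np.percentile(tam, 75) < np.percentile(ref, 25))
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def classify_fold_change(median_tam: float, median_ref: float,
                         fc_threshold: float = 3.0) -> str:
    """'up' / 'down' / 'none' by strict median fold change.

    A zero reference median with nonzero TAM median counts as up (and
    mirrored): expression appearing from nothing is maximal regulation.
    """
    if median_tam < 0 or median_ref < 0:
        raise ValueError("medians must be non-negative")
    if median_tam > fc_threshold * median_ref and median_tam > 0:
        return "up"
    if median_ref > fc_threshold * median_tam and median_ref > 0:
        return "down"
    return "none"


def extend_signature(tpm: pd.DataFrame, log_x: pd.DataFrame,
                     samples: pd.DataFrame, seed, *,
                     ref_type: str = "pMPH", label: str | None = None,
                     r_threshold: float = 0.9, fc_threshold: float = 3.0,
                     min_tpm: float = 1.5,
                     correlation_mode: str = "any-seed") -> SignatureResult:
    """Extend a seed set into the full up/down signature for one comparison.

    ``tpm`` supplies group medians and fold changes (purity-adjusted TPM
    scale); ``log_x`` supplies the correlation and quartile values (log2,
    batch-corrected — typically only the variance-filtered genes, which
    therefore delimit the extension candidates).  A gene enters the up-set
    iff it is a seed gene with an up fold-change, or it correlates with
    some seed gene above ``r_threshold`` and passes the quartile
    non-overlap and fold-change rules; mirrored for down.  Candidates must
    have a median TPM above ``min_tpm`` in the higher group.  Seed genes
    failing the fold change are reported with a reason, never dropped
    silently.
    """
    seed = list(seed)
    if not seed:
        raise ValueError("seed set is empty — run the significance stage first")
    label = label or f"TAM_vs_{ref_type}"
    tam_ids = samples.index[samples["cell_type"] == "TAM"].intersection(log_x.columns)
    ref_ids = samples.index[samples["cell_type"] == ref_type].intersection(log_x.columns)
    if len(tam_ids) == 0 or len(ref_ids) == 0:
        raise ValueError(f"missing TAM or {ref_type} samples")

    seed_in_x = [g for g in seed if g in log_x.index]
    r = (max_seed_correlation(log_x[tam_ids], seed_in_x, mode=correlation_mode)
         if seed_in_x else None)

    med_tam = tpm.loc[:, tpm.columns.intersection(
        samples.index[samples["cell_type"] == "TAM"])].median(axis=1)
    med_ref = tpm.loc[:, tpm.columns.intersection(
        samples.index[samples["cell_type"] == ref_type])].median(axis=1)

    records = []
    universe = log_x.index.union(pd.Index(seed))
    for g in universe:
        in_seed = g in seed
        mt = float(med_tam.get(g, 0.0))
        mr = float(med_ref.get(g, 0.0))
        fc_class = classify_fold_change(mt, mr, fc_threshold)
        rg = float(r.get(g, -np.inf)) if r is not None else -np.inf
        expressed = max(mt, mr) > min_tpm
        quart = False
        status, reason = "none", ""
        if in_seed:
            if fc_class == "up":
                status = "up"
            elif fc_class == "down":
                status = "down"
            else:
                reason = "seed gene failed fold-change classification"
        elif g in log_x.index and fc_class != "none" and expressed:
            if rg > r_threshold:
                quart = quartile_nonoverlap(log_x.loc[g, tam_ids],
                                            log_x.loc[g, ref_ids], fc_class)
                if quart:
                    status = fc_class
                else:
                    reason = "quartile overlap"
            else:
                reason = "below correlation threshold"
        elif not expressed and fc_class != "none":
            reason = f"median TPM below {min_tpm}"
        records.append({"gene": g, "in_seed": in_seed, "max_seed_r": rg,
                        "fc_class": fc_class, "quartile_ok": quart,
                        "median_tam": mt, f"median_{ref_type.lower()}": mr,
                        "status": status, "reason": reason})
    table = pd.DataFrame(records).set_index("gene")
    up = sorted(table.index[table["status"] == "up"])
    down = sorted(table.index[table["status"] == "down"])
    return SignatureResult(
        label=label, seed=sorted(seed), up=up, down=down, table=table,
        params={"ref_type": ref_type, "r_threshold": r_threshold,
                "fc_threshold": fc_threshold, "min_tpm": min_tpm,
                "correlation_mode": correlation_mode})


def venn_overlap(sig_a: SignatureResult, sig_b: SignatureResult):
    """(|A only|, |A and B|, |B only|) over the upregulated sets."""
    a, b = set(sig_a.up), set(sig_b.up)
    return (len(a - b), len(a & b), len(b - a))
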