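"""Expression-matrix containers, I/O, TPM normalization and pre-filters.

Matrices are plain pandas DataFrames: rows are genes (index = gene IDs),
columns are samples.  TPM matrices carry ``df.attrs["scale"]`` so that a
double log transform is caught.  Sample metadata is a DataFrame indexed by
sample ID with columns ``cell_type``, ``batch`` and (optionally) ``patient``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Closed vocabulary of cell types handled by the pipeline.
CELL_TYPES = frozenset({"TAM", "pMPH", "MDM", "TAT", "TU"})

TPM_SUM = 1_000_000.0


# ---------------------------------------------------------------------------
# I/O — tab-separated files with a gene-ID first column and sample-ID header
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples tab-separated matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_ids(df)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_lengths(path) -> pd.Series:
    """Read a two-column (gene, length-in-bases) table."""
    s = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    if (s <= 0).any():
        bad = s.index[s <= 0][0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    return s


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_frame().to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    validate_sample_table(samples)
    return samples


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


def validate_sample_table(samples: pd.DataFrame) -> None:
    for col in ("cell_type", "batch"):
        if col not in samples.columns:
            raise ValueError(f"sample table lacks required column {col!r}")
    unknown = set(samples["cell_type"]) - CELL_TYPES
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample IDs in sample table")


def _check_ids(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in matrix")


# ---------------------------------------------------------------------------
# TPM and pre-filters
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length- and depth-normalize read counts to transcripts per million.

    TPM_gs = 1e6 * (c_gs / l_g) / sum_j (c_js / l_j); every column sums to
    1e6.  ``lengths`` must cover every gene of ``counts``.
    """
    _check_ids(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"gene lengths missing for {len(missing)} genes "
                         f"(e.g. {missing[0]!r})")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has no counts; cannot compute TPM")
    tpm = rate.div(colsum, axis=1) * TPM_SUM
    tpm.attrs["scale"] = "tpm"
    return tpm


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1); refuses to transform an already-log matrix."""
    if tpm.attrs.get("scale") == "log2":
        raise ValueError("matrix is already log-transformed")
    out = np.log2(tpm + 1.0)
    out.attrs["scale"] = "log2"
    return out


def purity_filter(tpm: pd.DataFrame, samples: pd.DataFrame,
                  min_tpm: float = 3.0, min_ratio: float = 0.1) -> pd.Index:
    """Expression/purity pre-filter on the TPM matrix.

    Keeps genes with median TAM TPM >= ``min_tpm`` whose TAM median is not
    dwarfed by the contamination references: median(TAM)/median(TAT) and
    median(TAM)/median(TU) must both exceed ``min_ratio``.  A zero reference
    median passes the ratio (no evidence of that contamination source).
    """
    groups = {}
    for ct in ("TAM", "TAT", "TU"):
        ids = samples.index[samples["cell_type"] == ct]
        ids = ids.intersection(tpm.columns)
        if len(ids) == 0:
            raise ValueError(f"purity filter requires {ct} samples")
        groups[ct] = tpm[ids].median(axis=1)
    med_tam, med_tat, med_tu = groups["TAM"], groups["TAT"], groups["TU"]
    keep = med_tam >= min_tpm
    for ref in (med_tat, med_tu):
        ratio_ok = (ref == 0) | (med_tam > min_ratio * ref)
        keep &= ratio_ok
    return tpm.index[keep]


def median_profile(x: pd.DataFrame, samples: pd.DataFrame, cell_type: str) -> pd.Series:
    """Per-gene median across the samples of one cell type."""
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    ids = samples.index[samples["cell_type"] == cell_type].intersection(x.columns)
    if len(ids) == 0:
        raise ValueError(f"no {cell_type} samples in matrix")
    return x[ids].median(axis=1)
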