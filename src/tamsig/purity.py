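"""In-silico purification of TAM expression profiles.

TAM samples from ascites carry residual tumor cells (TU) and tumor-associated
T cells (TAT).  A linear two-component mixture model is assumed:

    observed = (1 - f_tu - f_tat) * pure + f_tu * tu_ref + f_tat * tat_ref

Fractions are estimated from marker genes expressed in the contaminating
type and silent in macrophages: for such a marker m, observed[m]/ref[m] is
the contamination fraction, and the median over markers is robust to
sampling noise.  Profiles are then un-mixed and renormalized to TPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import TPM_SUM

#: A sample whose estimated foreign fraction exceeds this is a QC failure,
#: not an adjustment case; estimates are clipped here.
MAX_FRACTION = 0.5


@dataclass
class ContaminationEstimate:
    sample_id: str
    f_tu: float
    f_tat: float
    n_tu_markers: int
    n_tat_markers: int


def _marker_fraction(profile: pd.Series, ref: pd.Series, markers) -> tuple[float, int]:
    markers = [m for m in markers if m in ref.index and m in profile.index]
    usable = [m for m in markers if ref[m] > 0]
    if not usable:
        raise ValueError("no usable markers: all absent from the reference profile")
    ratios = np.array([profile[m] / ref[m] for m in usable])
    f = float(np.clip(np.median(ratios), 0.0, MAX_FRACTION))
    return f, len(usable)


def estimate_fractions(tam_profile: pd.Series, tu_ref: pd.Series,
                       tat_ref: pd.Series, tu_markers, tat_markers,
                       sample_id: str = "") -> ContaminationEstimate:
    """Estimate tumor and T-cell fractions of one TAM sample from markers."""
    f_tu, n_tu = _marker_fraction(tam_profile, tu_ref, tu_markers)
    f_tat, n_tat = _marker_fraction(tam_profile, tat_ref, tat_markers)
    return ContaminationEstimate(sample_id, f_tu, f_tat, n_tu, n_tat)


def adjust_profile(tam_profile: pd.Series, tu_ref: pd.Series, tat_ref: pd.Series,
                   est: ContaminationEstimate) -> pd.Series:
    """Remove the estimated contamination and renormalize to TPM.

    adjusted = (observed - f_tu*tu_ref - f_tat*tat_ref) / (1 - f_tu - f_tat),
    clipped at zero.
    """
    if est.f_tu < 0 or est.f_tat < 0:
        raise ValueError("negative contamination fractions")
    if est.f_tu + est.f_tat >= 1:
        raise ValueError("contamination fractions sum to >= 1")
    adj = (tam_profile - est.f_tu * tu_ref - est.f_tat * tat_ref) / (
        1.0 - est.f_tu - est.f_tat)
    adj = adj.clip(lower=0.0)
    total = adj.sum()
    if total == 0:
        raise ValueError("adjusted profile is identically zero")
    return adj / total * TPM_SUM


def adjust_matrix(tpm: pd.DataFrame, samples: pd.DataFrame,
                  tu_markers, tat_markers):
    """Adjust every TAM column of a TPM matrix.

    References are the median TU and TAT profiles of the same matrix.
    Returns the adjusted matrix (non-TAM columns untouched) and a QC report
    (sample, f_tu, f_tat, marker counts).
    """
    from .expression import median_profile

    tu_ref = median_profile(tpm, samples, "TU")
    tat_ref = median_profile(tpm, samples, "TAT")
    out = tpm.copy()
    rows = []
    for sid in samples.index[samples["cell_type"] == "TAM"]:
        if sid not in tpm.columns:
            continue
        est = estimate_fractions(tpm[sid], tu_ref, tat_ref,
                                 tu_markers, tat_markers, sample_id=sid)
        out[sid] = adjust_profile(tpm[sid], tu_ref, tat_ref, est)
        rows.append({"sample_id": sid, "f_tu": est.f_tu, "f_tat": est.f_tat,
                     "n_tu_markers": est.n_tu_markers,
                     "n_tat_markers": est.n_tat_markers})
    report = pd.DataFrame(rows).set_index("sample_id")
    out.attrs["scale"] = "tpm"
    return out, report
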