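"""Synthetic bulk RNA-seq cohorts with planted TAM-selective structure.

The generator emits a count matrix with the statistical structure the
analysis pipeline assumes and a ground-truth record for scoring recovery:

* negative-binomial counts per gene (variance mu + phi*mu^2) around
  group-specific expected TPM profiles,
* a small cohort (default 17 TAM, 4 pMPH, 3 MDM, 3 TAT, 3 TU),
* planted TAM-selective up/down genes of configurable fold change, of which
  a configurable subset is also elevated against MDMs,
* one co-expressed module among the planted up-genes, driven by a single
  standard-normal latent factor per TAM sample with loadings calibrated to
  a target pairwise Pearson r on the log2 scale,
* additive (location) and multiplicative (scale) batch effects on the log2
  expected-expression scale, mirroring the location/scale model the batch
  correction assumes,
* optional convex-mixture contamination of TAM samples with the tumor (TU)
  and T-cell (TAT) reference profiles, plus marker genes expressed only in
  the contaminating type so the purity stage can estimate fractions.

Counts are derived from TPM-scale means through a configured library size
and gene length, so TPM computation approximately inverts the generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import TPM_SUM

LN2_SQ = np.log(2.0) ** 2

_DEFAULT_GROUP_SIZES = {"TAM": 17, "pMPH": 4, "MDM": 3, "TAT": 3, "TU": 3}
_DEFAULT_CONTAMINATION = {
    "TAM01": (0.15, 0.05),
    "TAM02": (0.05, 0.10),
    "TAM03": (0.10, 0.10),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the pipeline is validated
    against: a 17/4/3 macrophage cohort with 30 planted up-regulated and 4
    planted down-regulated genes at 8-fold, a 19-gene co-expressed module
    at target pairwise r = 0.95, and 20 of the up-genes shared with the
    TAM-vs-MDM comparison.
    """

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    baseline_mean_log2_range: tuple = (2.0, 9.0)
    dispersion: float = 0.05
    n_up_planted: int = 30
    n_down_planted: int = 4
    planted_fc: float = 8.0
    module_size: int = 19
    module_corr: float = 0.95
    n_up_vs_mdm_subset: int = 20
    batch_assignment: dict | None = None   # sample -> batch; None = balanced 2 batches
    batch_shift_sd: float = 0.5            # log2 additive shift per gene x batch
    batch_scale_sd: float = 0.1            # sd of log2 scale factor per gene x batch
    bio_noise_sd: float = 0.15             # per gene x sample log2 biological noise
    contamination: dict | None = None      # TAM sample -> (f_tu, f_tat); None = default
    n_tu_markers: int = 15
    n_tat_markers: int = 15
    marker_tpm: float = 500.0
    library_size_range: tuple = (1.5e6, 2.5e6)
    gene_length_range: tuple = (300, 10_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must be > 1")
        if not 0 < self.module_corr < 1:
            raise ValueError("module_corr must be in (0, 1)")
        if self.module_size > self.n_up_planted:
            raise ValueError("module_size cannot exceed n_up_planted")
        if self.n_up_vs_mdm_subset > self.n_up_planted:
            raise ValueError("n_up_vs_mdm_subset cannot exceed n_up_planted")
        if self.n_up_planted + self.n_down_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        for g in ("TAM", "pMPH", "MDM"):
            if self.group_sizes.get(g, 0) < 2:
                raise ValueError(
                    f"group {g} needs >= 2 samples for quartile statistics")
        for s, (ftu, ftat) in (self.contamination or {}).items():
            if ftu < 0 or ftat < 0 or ftu + ftat >= 1:
                raise ValueError(f"invalid contamination fractions for {s}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery scoring."""

    up_gene_ids: list
    down_gene_ids: list
    module_gene_ids: list
    up_vs_mdm_gene_ids: list
    tu_marker_ids: list
    tat_marker_ids: list
    batch_params: dict
    contamination_params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def mix_contamination(pure: pd.Series, tu_ref: pd.Series, tat_ref: pd.Series,
                      f_tu: float, f_tat: float) -> pd.Series:
    """Convex mixture of a pure profile with tumor and T-cell references.

    result = (1-f_tu-f_tat)*pure + f_tu*tu_ref + f_tat*tat_ref, renormalized
    to the TPM sum convention.
    """
    if f_tu < 0 or f_tat < 0:
        raise ValueError("contamination fractions must be non-negative")
    if f_tu + f_tat >= 1:
        raise ValueError("contamination fractions must sum to < 1")
    mixed = (1.0 - f_tu - f_tat) * pure + f_tu * tu_ref + f_tat * tat_ref
    return mixed / mixed.sum() * TPM_SUM


def _sample_names(group_sizes: dict) -> list:
    names = []
    for ct, n in group_sizes.items():
        names += [f"{ct}{i + 1:02d}" for i in range(n)]
    return names


def _default_batches(samples: pd.DataFrame, n_batches: int = 2) -> pd.Series:
    """Round-robin batches within each cell type, so batch is balanced
    within group (the adjustment assumes batch is not confounded with
    biology)."""
    labels = pd.Series(index=samples.index, dtype=object)
    for ct, ids in samples.groupby("cell_type").groups.items():
        for i, s in enumerate(ids):
            labels[s] = f"b{i % n_batches + 1}"
    return labels


def generate_cohort(config: SimulationConfig):
    """Generate (counts, gene lengths, sample table, truth).

    Identical config + seed gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    phi = config.dispersion
    lo, hi = config.baseline_mean_log2_range

    n_up, n_down = config.n_up_planted, config.n_down_planted
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    tu_markers = [f"TUmark{i + 1:02d}" for i in range(config.n_tu_markers)]
    tat_markers = [f"TATmark{i + 1:02d}" for i in range(config.n_tat_markers)]
    all_genes = gene_ids + tu_markers + tat_markers
    n_total = len(all_genes)

    # --- expected TPM-scale mean per gene and cell type -------------------
    base = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    # Down-planted genes keep their TAM mean (baseline / fc) comfortably
    # above the TPM>=3 purity threshold by drawing from the upper range.
    down_lo = max(lo, np.log2(config.planted_fc * 3.0) + 1.5)
    down_slice = slice(n_up, n_up + n_down)
    base[down_slice] = 2.0 ** rng.uniform(down_lo, max(hi, down_lo + 1.0), n_down)

    means = {ct: base.copy() for ct in ("TAM", "pMPH", "MDM")}
    # TAT/TU are distinct cell types: independent baseline profiles, so the
    # purity ratio filter has genuine work to do on null genes.
    means["TAT"] = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    means["TU"] = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)

    up_idx = np.arange(n_up)
    down_idx = np.arange(n_up, n_up + n_down)
    shared_idx = up_idx[: config.n_up_vs_mdm_subset]
    module_idx = up_idx[: config.module_size]

    means["TAM"][up_idx] = base[up_idx] * config.planted_fc
    # Up-genes not in the MDM-shared subset are elevated in MDMs too, so
    # they are TAM-selective only against pMPHs.
    not_shared = np.setdiff1d(up_idx, shared_idx)
    means["MDM"][not_shared] = means["TAM"][not_shared]
    means["TAM"][down_idx] = base[down_idx] / config.planted_fc
    # Planted genes are macrophage genes, not tumor/T-cell derived: pin the
    # reference means so the purity ratio filter keeps them by construction
    # (at baseline for up-genes, i.e. well below TAM; at the TAM level for
    # down-genes, whose TAM side is the low one).
    means["TAT"][up_idx] = base[up_idx]
    means["TU"][up_idx] = base[up_idx]
    means["TAT"][down_idx] = means["TAM"][down_idx]
    means["TU"][down_idx] = means["TAM"][down_idx]

    # Marker genes: expressed only in their contaminating cell type.
    marker_block = {ct: np.zeros(config.n_tu_markers + config.n_tat_markers)
                    for ct in means}
    marker_block["TU"][: config.n_tu_markers] = config.marker_tpm
    marker_block["TAT"][config.n_tu_markers:] = config.marker_tpm
    profiles = {}
    for ct in means:
        prof = np.concatenate([means[ct], marker_block[ct]])
        profiles[ct] = prof / prof.sum() * TPM_SUM

    # --- cohort layout ----------------------------------------------------
    samples = pd.DataFrame({
        "cell_type": np.repeat(list(config.group_sizes),
                               list(config.group_sizes.values())),
    }, index=pd.Index(_sample_names(config.group_sizes), name="sample_id"))
    if config.batch_assignment is None:
        samples["batch"] = _default_batches(samples)
    else:
        samples["batch"] = pd.Series(config.batch_assignment).reindex(samples.index)
        if samples["batch"].isna().any():
            raise ValueError("batch_assignment does not cover every sample")
    samples["patient"] = [f"P{i + 1:02d}" for i in range(len(samples))]

    contamination = (dict(_DEFAULT_CONTAMINATION)
                     if config.contamination is None else dict(config.contamination))
    contamination = {s: f for s, f in contamination.items() if s in samples.index}
    for s, (ftu, ftat) in contamination.items():
        if ftu < 0 or ftat < 0 or ftu + ftat >= 1:
            raise ValueError(f"invalid contamination fractions for {s}")

    # --- nuisance parameters ---------------------------------------------
    batches = sorted(samples["batch"].unique())
    gamma = {b: rng.normal(0.0, config.batch_shift_sd, size=n_total) for b in batches}
    scale = {b: 2.0 ** rng.normal(0.0, config.batch_scale_sd, size=n_total)
             for b in batches}

    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1],
                     size=n_total),
        index=all_genes, name="length")
    lib_sizes = rng.uniform(*config.library_size_range, size=len(samples))

    # Module loadings: pairwise log2-scale correlation a^2/(a^2+v) =
    # module_corr, with v the residual log2 variance (biological noise plus
    # the NB sampling noise at the gene's expected count).
    mean_lib = float(np.mean(config.library_size_range))
    tam_prof = profiles["TAM"]
    rate = tam_prof * lengths.to_numpy()
    mu_count = mean_lib * rate / rate.sum()
    v_resid = config.bio_noise_sd ** 2 + (1.0 / np.maximum(mu_count, 1e-9) + phi) / LN2_SQ
    loadings = np.zeros(n_total)
    ratio = config.module_corr / (1.0 - config.module_corr)
    if len(module_idx):
        a0 = np.sqrt(ratio * v_resid[module_idx])
        # TPM renormalization couples module genes to their own latent
        # factor through the per-sample denominator (when the factor is
        # high the module inflates the library share and every TPM is
        # deflated), attenuating the realized log-scale slope by roughly
        # the module's factor-weighted expression share.  Solve the share
        # by fixed point and inflate the loadings to compensate.
        s0 = float(tam_prof[module_idx].sum() / TPM_SUM)
        a_bar = float(a0.mean())
        for _ in range(25):
            infl = np.exp((a_bar * np.log(2.0)) ** 2 / 2.0)
            share = min(s0 * infl / (1.0 - s0 + s0 * infl), 0.5)
            a_bar = float(a0.mean()) / (1.0 - share)
        loadings[module_idx] = a0 / (1.0 - share)
    tam_ids = samples.index[samples["cell_type"] == "TAM"]
    latent = pd.Series(rng.normal(0.0, 1.0, size=len(tam_ids)), index=tam_ids)

    # --- per-sample expected profiles and NB sampling ---------------------
    counts = np.zeros((n_total, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        ct, b = row["cell_type"], row["batch"]
        prof = pd.Series(profiles[ct], index=all_genes)
        if sid in contamination:
            ftu, ftat = contamination[sid]
            prof = mix_contamination(prof,
                                     pd.Series(profiles["TU"], index=all_genes),
                                     pd.Series(profiles["TAT"], index=all_genes),
                                     ftu, ftat)
        log2mu = np.log2(np.maximum(prof.to_numpy(), 1e-300))
        log2mu = log2mu + gamma[b] + scale[b] * rng.normal(0.0, config.bio_noise_sd,
                                                           size=n_total)
        if sid in latent.index:
            log2mu = log2mu + loadings * latent[sid]
        expr = np.where(prof.to_numpy() > 0, 2.0 ** log2mu, 0.0)
        rate = expr * lengths.to_numpy()
        mu = lib_sizes[j] * rate / rate.sum()
        if phi > 0:
            p = 1.0 / (1.0 + phi * mu)
            counts[:, j] = np.where(mu > 0,
                                    rng.negative_binomial(1.0 / phi, np.maximum(p, 1e-12)),
                                    0)
        else:
            counts[:, j] = rng.poisson(mu)

    count_df = pd.DataFrame(counts, index=all_genes, columns=samples.index)
    truth = SyntheticTruth(
        up_gene_ids=[gene_ids[i] for i in up_idx],
        down_gene_ids=[gene_ids[i] for i in down_idx],
        module_gene_ids=[gene_ids[i] for i in module_idx],
        up_vs_mdm_gene_ids=[gene_ids[i] for i in shared_idx],
        tu_marker_ids=tu_markers,
        tat_marker_ids=tat_markers,
        batch_params={b: {"shift_sd": config.batch_shift_sd,
                          "scale_sd": config.batch_scale_sd} for b in batches},
        contamination_params={s: list(f) for s, f in contamination.items()},
    )
    return count_df, lengths, samples, truth


def truth_gmt(truth: SyntheticTruth, gene_universe, rng=None, n_random: int = 5,
              random_size: int = 25) -> dict:
    """Small gene-set collection derived from the planted truth, for
    exercising the enrichment stage end-to-end without external annotation."""
    rng = np.random.default_rng(0) if rng is None else rng
    universe = list(gene_universe)
    sets = {
        "PLANTED_UP": list(truth.up_gene_ids),
        "PLANTED_DOWN": list(truth.down_gene_ids),
        "PLANTED_MODULE": list(truth.module_gene_ids),
    }
    for i in range(n_random):
        sets[f"RANDOM_{i + 1}"] = list(
            rng.choice(universe, size=min(random_size, len(universe)), replace=False))
    return {k: v for k, v in sets.items() if v}
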