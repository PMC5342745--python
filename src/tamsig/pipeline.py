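"""End-to-end orchestration of the signature pipeline.

Stage order: (simulate | load) -> TPM -> purity adjust -> purity filter ->
log -> variance filter -> batch correct -> per-comparison exact-test seed
and correlation extension -> Venn -> module clustering -> enrichment ->
similarity/PCA report.  Every stage writes a tab-separated or JSON
artifact; a manifest records content hashes so identical config + seed
gives an identical run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, batch, de, enrichment, expression, purity, signature
from . import simulate as sim
from . import structure

log = logging.getLogger("tamsig.pipeline")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the analysis, with the published defaults."""

    min_tpm_purity: float = 3.0
    min_ratio: float = 0.1
    variance_threshold: float = 1.0
    fdr_threshold: float = 0.2
    r_threshold: float = 0.9
    fc_threshold: float = 3.0        # the 2-fold variant is config, not code
    min_tpm_signature: float = 1.5
    correlation_mode: str = "any-seed"   # or "centroid"
    cut_height: float = 0.5
    comparisons: list = field(default_factory=lambda: ["pMPH", "MDM"])
    tu_markers: list = field(default_factory=list)
    tat_markers: list = field(default_factory=list)
    gmt: str | None = None
    seed: int = 0
    simulate: bool = True
    counts: str | None = None
    lengths: str | None = None
    samples: str | None = None
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [-1, 1]")
        for name in ("min_tpm_purity", "min_ratio", "variance_threshold",
                     "min_tpm_signature", "cut_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.correlation_mode not in ("any-seed", "centroid"):
            raise ValueError("correlation_mode must be 'any-seed' or 'centroid'")
        if not self.simulate:
            for name in ("counts", "lengths", "samples"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} path required when not simulating")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage into ``outdir`` and return the in-memory results.

    Artifacts: counts/lengths/samples (simulated or copied-through inputs),
    tpm, purity QC, filtered log matrix, batch-corrected matrix, per
    comparison a DE table + signature diagnostics + JSON summary, venn.json,
    modules.json + tree.nwk, enrichment table, sample-correlation matrix and
    PCA coordinates, and manifest.json with content hashes.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        sim_cfg = sim.SimulationConfig(**{"seed": config.seed,
                                          **config.sim_overrides})
        counts, lengths, samples, truth = sim.generate_cohort(sim_cfg)
        truth.to_json(outdir / "truth.json")
        tu_markers = config.tu_markers or truth.tu_marker_ids
        tat_markers = config.tat_markers or truth.tat_marker_ids
        log.info("simulate: %d genes x %d samples", *counts.shape)
    else:
        counts = expression.read_matrix(config.counts)
        lengths = expression.read_lengths(config.lengths)
        samples = expression.read_sample_table(config.samples)
        truth = None
        tu_markers, tat_markers = config.tu_markers, config.tat_markers
    expression.write_matrix(counts, outdir / "counts.tsv")
    expression.write_lengths(lengths, outdir / "lengths.tsv")
    expression.write_sample_table(samples, outdir / "samples.tsv")

    # ---- expression and purity ------------------------------------------
    tpm = expression.compute_tpm(counts, lengths)
    expression.write_matrix(tpm, outdir / "tpm.tsv")
    if tu_markers and tat_markers:
        tpm_adj, qc = purity.adjust_matrix(tpm, samples, tu_markers, tat_markers)
        qc.to_csv(outdir / "purity_qc.tsv", sep="\t", float_format="%.6g")
        log.info("purity: adjusted %d TAM samples", len(qc))
    else:
        tpm_adj, qc = tpm, pd.DataFrame()
        log.info("purity: no markers configured, adjustment skipped")
    expression.write_matrix(tpm_adj, outdir / "tpm_adjusted.tsv")

    purity_genes = expression.purity_filter(
        tpm_adj, samples, config.min_tpm_purity, config.min_ratio)
    log.info("purity_filter: kept %d / %d genes", len(purity_genes), len(tpm_adj))
    (outdir / "purity_genes.txt").write_text("\n".join(purity_genes) + "\n")

    # ---- log, variance filter, batch correction -------------------------
    log_x = expression.log_transform(tpm_adj.loc[purity_genes])
    filtered = batch.variance_filter(log_x, config.variance_threshold)
    corrected = batch.combat_adjust(filtered, samples)
    expression.write_matrix(corrected, outdir / "log_corrected.tsv")

    # Once batch effects are removed, every downstream median / fold change
    # uses the corrected data (back-transformed to the TPM scale); genes
    # dropped by the variance filter keep their adjusted-TPM medians so
    # that seed genes are never silently lost.
    tpm_corrected = tpm_adj.copy()
    tpm_corrected.loc[corrected.index, corrected.columns] = (
        2.0 ** corrected - 1.0).clip(lower=0.0)

    # ---- per-comparison DE seed and extension ----------------------------
    counts_f = counts.loc[purity_genes]
    results: dict = {"signatures": {}, "tables": {}}
    for ref in config.comparisons:
        comp = f"TAM_vs_{ref}"
        table = de.de_table(counts_f, tpm_adj, samples, "TAM", ref)
        table.to_csv(outdir / f"de_{comp}.tsv", sep="\t", float_format="%.6g")
        seed = de.seed_genes(table, config.fdr_threshold)
        log.info("%s: %d seed genes at FDR <= %g", comp, len(seed),
                 config.fdr_threshold)
        if len(seed) == 0:
            log.warning("%s: no significant genes; empty signature", comp)
            sig = signature.SignatureResult(
                label=comp, seed=[], up=[], down=[], table=pd.DataFrame(),
                params={"ref_type": ref, "r_threshold": config.r_threshold,
                        "fc_threshold": config.fc_threshold,
                        "min_tpm": config.min_tpm_signature})
        else:
            sig = signature.extend_signature(
                tpm_corrected, corrected, samples, seed, ref_type=ref, label=comp,
                r_threshold=config.r_threshold, fc_threshold=config.fc_threshold,
                min_tpm=config.min_tpm_signature,
                correlation_mode=config.correlation_mode)
        sig.table.to_csv(outdir / f"signature_{comp}.tsv", sep="\t",
                         float_format="%.6g")
        with open(outdir / f"signature_{comp}.json", "w") as fh:
            json.dump({"label": comp, "seed": sig.seed, "up": sig.up,
                       "down": sig.down, "params": sig.params}, fh, indent=1)
        log.info("%s", sig.summary())
        results["signatures"][comp] = sig
        results["tables"][comp] = table

    # ---- Venn over the first two comparisons -----------------------------
    sigs = list(results["signatures"].values())
    if len(sigs) >= 2:
        venn = signature.venn_overlap(sigs[0], sigs[1])
        results["venn"] = venn
        with open(outdir / "venn.json", "w") as fh:
            json.dump({"a": sigs[0].label, "b": sigs[1].label,
                       "a_only": venn[0], "both": venn[1], "b_only": venn[2]},
                      fh, indent=1)
        log.info("venn %s vs %s: %s", sigs[0].label, sigs[1].label, venn)

    # ---- module extraction on the primary up-set -------------------------
    primary = sigs[0]
    tam_ids = samples.index[samples["cell_type"] == "TAM"].intersection(
        corrected.columns)
    up_in_x = [g for g in primary.up if g in corrected.index]
    results["modules"] = []
    if len(up_in_x) >= 2:
        tree = structure.hcluster(corrected.loc[up_in_x, tam_ids])
        modules = structure.extract_modules(tree, config.cut_height)
        results["modules"] = modules
        (outdir / "tree.nwk").write_text(tree.to_newick())
        with open(outdir / "modules.json", "w") as fh:
            json.dump({"cut_height": config.cut_height,
                       "sizes": [len(m) for m in modules],
                       "modules": modules}, fh, indent=1)
        log.info("modules at cut %.2f: sizes %s", config.cut_height,
                 [len(m) for m in modules])

    # ---- enrichment ------------------------------------------------------
    if config.gmt:
        sets = enrichment.read_gmt(config.gmt)
    elif truth is not None:
        sets = sim.truth_gmt(truth, purity_genes,
                             rng=np.random.default_rng(config.seed))
        enrichment.write_gmt(sets, outdir / "annotations.gmt")
    else:
        sets = {}
    if sets and primary.up:
        query = [g for g in primary.up if g in set(purity_genes)]
        enr = enrichment.hypergeom_enrich(query, purity_genes, sets)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
        results["enrichment"] = enr

    # ---- similarity / PCA report ----------------------------------------
    corr = structure.pearson_matrix(log_x, axis="samples")
    expression.write_matrix(corr, outdir / "sample_correlation.tsv")
    med_corr = {}
    tam_med = expression.median_profile(log_x, samples, "TAM")
    for ct in ("pMPH", "MDM", "TAT", "TU"):
        try:
            other = expression.median_profile(log_x, samples, ct)
        except ValueError:
            continue
        med_corr[f"TAM_vs_{ct}"] = float(np.corrcoef(tam_med, other)[0, 1])
    with open(outdir / "median_profile_correlation.json", "w") as fh:
        json.dump(med_corr, fh, indent=1)
    macro = samples.index[samples["cell_type"].isin(["TAM", "pMPH", "MDM"])]
    pca_input = corrected if corrected.shape[0] >= 2 else log_x
    coords, evr = structure.pca(pca_input[macro.intersection(pca_input.columns)])
    coords.to_csv(outdir / "pca.tsv", sep="\t", float_format="%.10g")
    results["median_profile_correlation"] = med_corr
    results["pca_evr"] = evr

    # ---- manifest --------------------------------------------------------
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    artifacts = sorted(p for p in outdir.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(cfg_path),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    results["truth"] = truth
    results["purity_genes"] = purity_genes
    return results


def _prf(found, true) -> dict:
    found, true = set(found), set(true)
    tp = len(found & true)
    precision = tp / len(found) if found else (1.0 if not true else 0.0)
    recall = tp / len(true) if true else 1.0
    return {"n_found": len(found), "n_true": len(true), "tp": tp,
            "precision": precision, "recall": recall}


def score_recovery(results: dict, truth: sim.SyntheticTruth) -> dict:
    """Exact set comparison of the recovered signature against the planted
    truth: per-category precision/recall."""
    primary = list(results["signatures"].values())[0]
    report = {
        "up": _prf(primary.up, truth.up_gene_ids),
        "down": _prf(primary.down, truth.down_gene_ids),
    }
    if results.get("modules"):
        report["module"] = _prf(results["modules"][0], truth.module_gene_ids)
    if "venn" in results and len(results["signatures"]) >= 2:
        sigs = list(results["signatures"].values())
        shared = set(sigs[0].up) & set(sigs[1].up)
        report["shared_up"] = _prf(shared, truth.up_vs_mdm_gene_ids)
    return report
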