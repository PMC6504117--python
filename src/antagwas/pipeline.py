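"""End-to-end orchestration of the antagonism GWAS chain.

Runs simulate -> genotype QC -> fitness QC -> quantitative genetics ->
GWAS -> windows/clumping -> partitioning -> balancing-selection tests on a
single configuration, writing TSV/JSON outputs and a reproducibility
manifest.  Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from antagwas import __version__, simdata
from antagwas import assoc, balsel, fitness_qc, geno_qc, partition, quantgen, vcfio

log = logging.getLogger("antagwas.pipeline")


@dataclass
class PipelineConfig:
    """Pipeline thresholds (defaults are the study's analysis settings)."""

    outdir: str = "antagwas_out"
    seed: int = 42
    # synthetic-study scale
    sim: dict = field(default_factory=dict)
    # QC thresholds
    min_depth: int = 10
    min_gq: int = 30
    max_missing: float = 0.15
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    prune_r2: float = 0.2
    prune_window_bp: int = 10_000
    pca_sd_threshold: float = 6.0
    # association
    alpha: float = -0.25
    q_snp: float = 0.3
    q_window: float = 0.1
    window_bp: int = 1000
    window_step: int = 500
    clump_p: float = 0.00093
    clump_r2: float = 0.4
    clump_dist_bp: int = 10_000
    n_perm: int = 1000
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "qc", "fitness", "quantgen", "gwas", "windows",
        "clump", "partition", "balsel",
    )

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages; returns (and writes) the report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {**asdict(config), "stages": list(config.stages)},
                    "versions": {"antagwas": __version__,
                                 "python": platform.python_version(),
                                 "numpy": np.__version__,
                                 "pandas": pd.__version__}}
    sim_cfg = simdata.SimConfig(**{"seed": config.seed, **config.sim})
    panel = None
    if "simulate" in config.stages:
        log.info("stage simulate")
        panel = simdata.simulate_genotypes(sim_cfg)
        assays, truth = simdata.simulate_fitness(panel, sim_cfg)
        annot = simdata.simulate_annotations(panel, sim_cfg)
        vcfio.write_panel_vcf(panel, out / "panel.vcf")
        vcfio.write_assay_table(assays, out / "assays.tsv")
        vcfio.write_linked_selection(annot.linked_selection, out / "linked_selection.tsv")
        report["simulate"] = {"n_lines": panel.n_lines, "n_sites": panel.n_sites,
                              "vcf_sha": _hash_file(out / "panel.vcf")}
    else:
        raise ValueError("pipeline currently requires the simulate stage "
                         "(external inputs go through the library API)")

    if "qc" in config.stages:
        log.info("stage qc")
        panel_qc, qc_report = geno_qc.run_qc(
            panel, config.min_depth, config.min_gq, config.max_missing,
            config.min_call_rate, config.min_maf)
        _, outlier = geno_qc.pca_outliers(panel_qc, sd_threshold=config.pca_sd_threshold)
        if outlier.any():
            panel_qc = panel_qc.take_lines(np.flatnonzero(~outlier))
            qc_report.individuals_removed_pca = int(outlier.sum())
            qc_report.final_individuals = panel_qc.n_lines
        (out / "qc_report.json").write_text(qc_report.to_json())
        report["qc"] = json.loads(qc_report.to_json())
    else:
        panel_qc = panel

    if "fitness" in config.stages:
        log.info("stage fitness")
        line_fit, normed = fitness_qc.fitness_pipeline(
            assays, flies_per_vial=sim_cfg.flies_per_vial)
        line_fit.to_csv(out / "line_fitness.tsv", sep="\t", index=False)
        keep = [l for l in panel_qc.lines if l in set(line_fit["line"])]
        panel_qc = panel_qc.take_lines(
            np.array([panel_qc.lines.index(l) for l in keep]))
        line_fit = line_fit.set_index("line").loc[keep].reset_index()
        report["fitness"] = {"n_lines": len(line_fit)}

    if "quantgen" in config.stages:
        log.info("stage quantgen")
        normed_kept = normed[normed["line"].isin(set(line_fit["line"]))]
        est = quantgen.fit_bivariate_model(normed_kept, seed=config.seed,
                                           n_iter=4000, burn_in=1000, thin=5)
        report["quantgen"] = {
            "h2_m": est.h2_m, "h2_f": est.h2_f, "r_mf": est.r_mf,
            "intervals": {k: list(v) for k, v in est.intervals.items()},
        }

    if "gwas" in config.stages:
        log.info("stage gwas")
        y = line_fit["antagonism_index"].to_numpy()
        w = assoc.ld_weights(panel_qc)
        kin = assoc.kinship(panel_qc, w, alpha=config.alpha)
        res = assoc.gwas_lmm(y, panel_qc, kin, q_candidate=config.q_snp)
        res.to_csv(out / "assoc.tsv", sep="\t", index=False)
        report["gwas"] = {
            "n_snps": int(len(res)),
            "n_candidates": int(res["candidate"].sum()),
            "lambda_median": assoc.inflation_factor(res["p"].to_numpy()),
            "h2_snp_antagonism": float(res.attrs["h2_snp"]),
            "bonferroni_threshold": assoc.bonferroni_threshold(0.05, len(res)),
        }

    if "windows" in config.stages:
        log.info("stage windows")
        wres = assoc.window_set_test(y, panel_qc, kin, window=config.window_bp,
                                     step=config.window_step, q_flag=config.q_window)
        wres.to_csv(out / "windows.tsv", sep="\t", index=False)
        report["windows"] = {"n_windows": int(len(wres)),
                             "n_antagonistic": int(wres["antagonistic"].sum())
                             if len(wres) else 0}

    if "clump" in config.stages:
        log.info("stage clump")
        clumped = assoc.clump(res, panel_qc, p_index_max=config.clump_p,
                              r2_min=config.clump_r2, dist_bp=config.clump_dist_bp)
        clumped.to_csv(out / "clumped.tsv", sep="\t", index=False)
        report["clump"] = {"n_clusters": int(clumped["is_index"].sum())}

    if "partition" in config.stages:
        log.info("stage partition")
        labels = np.where(panel_qc.sites["arm"] == "X", "X", "autosome")
        part = partition.partition_h2(y, panel_qc, labels, w, alpha=config.alpha)
        part.to_csv(out / "partition_xa.tsv", sep="\t", index=False)
        report["partition"] = {
            row["class"]: {"observed_share": row["observed_share"],
                           "expected_share": row["expected_share"],
                           "p": row["p"]}
            for _, row in part.iterrows()}

    if "balsel" in config.stages:
        log.info("stage balsel")
        key = panel_qc.sites.set_index(["arm", "pos"]).index
        full_key = panel.sites.set_index(["arm", "pos"]).index
        site_idx = np.flatnonzero(full_key.isin(key))
        truth_flags = np.zeros(panel.n_sites, dtype=bool)
        truth_flags[truth.causal_idx_antagonistic] = True
        comp = simdata.simulate_comparison_panel(panel, sim_cfg, truth_flags)
        cmaf = balsel.comparison_maf(panel.sites, comp)[site_idx]
        ls_track = annot.linked_selection
        ls_by_window = {(r.arm, int(r.start)): r.value for r in ls_track.itertuples()}
        site_ls = np.array([
            ls_by_window.get((a, (p_ // 1000) * 1000), np.nan)
            for a, p_ in zip(panel_qc.sites["arm"], panel_qc.sites["pos"])])
        site_ls = np.nan_to_num(site_ls, nan=float(np.nanmean(site_ls)))
        cand = res["candidate"].to_numpy()
        if cand.sum() >= 5:
            mres = balsel.analysis_A_matched_null(
                cand, panel_qc.maf(), site_ls, cmaf,
                n_sets=config.n_perm, seed=config.seed)
            report["balsel_A"] = {"observed_mean_maf": mres.observed_mean,
                                  "p": mres.p,
                                  "naive_null_mean": mres.naive_null_mean}
        bres = balsel.analysis_B_persistence_logit(
            (cmaf > 0).astype(float), np.abs(res["beta"].to_numpy()),
            panel_qc.maf(), site_ls)
        report["balsel_B"] = {k: v for k, v in bres.items() if k != "ci"}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float, sort_keys=True))
    log.info("report written to %s", report_path)
    return report
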