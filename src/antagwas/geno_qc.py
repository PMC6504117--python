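"""Genotype quality-control funnel and population-structure screening.

Filter order follows the study design: call-level filters (depth, genotype
quality), then individuals by missingness, then sites (call rate, MAF,
biallelic), then LD pruning and PCA outlier screening against a reference
panel.  All thresholds are exclusive in the direction the wording forces
(DP < 10 removed, missingness > 15% removed, MAF > 0.05 retained, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from antagwas._util import r2_vector
from antagwas.panel import GenotypePanel


@dataclass
class QCReport:
    """Counts at each stage of the funnel; removed + retained = input."""

    thresholds: dict = field(default_factory=dict)
    input_sites: int = 0
    input_individuals: int = 0
    calls_removed: int = 0
    individuals_removed_missingness: int = 0
    sites_removed_call_rate: int = 0
    sites_removed_maf: int = 0
    sites_removed_not_biallelic: int = 0
    individuals_removed_pca: int = 0
    final_sites: int = 0
    final_individuals: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_calls(panel: GenotypePanel, min_depth: int = 10, min_gq: int = 30,
                 report: QCReport | None = None) -> GenotypePanel:
    """Set individual calls with DP < min_depth or GQ < min_gq to missing."""
    if panel.dp is None or panel.gq is None:
        missing = "DP" if panel.dp is None else "GQ"
        raise ValueError(f"panel lacks per-call FORMAT field {missing}; cannot apply call filter")
    bad = (panel.dp < min_depth) | (panel.gq < min_gq)
    g = panel.genotypes.copy()
    newly = bad & ~np.isnan(g)
    g[bad] = np.nan
    if report is not None:
        report.calls_removed += int(newly.sum())
        report.thresholds.update({"min_depth": min_depth, "min_gq": min_gq})
    return GenotypePanel(panel.lines, panel.sites.copy(), g, panel.dp, panel.gq)


def filter_individuals(panel: GenotypePanel, max_missing: float = 0.15,
                       report: QCReport | None = None) -> GenotypePanel:
    """Drop individuals with missing fraction strictly above ``max_missing``."""
    frac = panel.missing_fraction_per_line()
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValueError("individual missingness filter removed every individual")
    if report is not None:
        report.individuals_removed_missingness += panel.n_lines - keep.size
        report.thresholds["max_missing"] = max_missing
    return panel.take_lines(keep)


def filter_sites(panel: GenotypePanel, min_call_rate: float = 0.95,
                 min_maf: float = 0.05, biallelic_only: bool = True,
                 report: QCReport | None = None) -> GenotypePanel:
    """Retain sites with call rate >= min_call_rate and MAF strictly > min_maf.

    Call rate is computed across the retained individuals, so the
    individual filter must be applied first.  Monomorphic sites fail the
    MAF criterion.  Non-ACGT / multi-base alleles fail the biallelic check.
    """
    call = panel.call_rate_per_site()
    maf = panel.maf()
    ok_call = call >= min_call_rate
    ok_maf = np.nan_to_num(maf) > min_maf
    if biallelic_only:
        ok_bi = np.array([
            len(str(r)) == 1 and len(str(a)) == 1 and str(a) in "ACGT" and str(r) in "ACGT"
            for r, a in zip(panel.sites["ref"], panel.sites["alt"])
        ])
    else:
        ok_bi = np.ones(panel.n_sites, dtype=bool)
    keep = ok_call & ok_maf & ok_bi
    if report is not None:
        report.sites_removed_call_rate += int((~ok_call).sum())
        report.sites_removed_maf += int((ok_call & ~ok_maf).sum())
        report.sites_removed_not_biallelic += int((ok_call & ok_maf & ~ok_bi).sum())
        report.thresholds.update({"min_call_rate": min_call_rate, "min_maf": min_maf})
    if not keep.any():
        raise ValueError("site filters removed every site")
    return panel.take_sites(np.flatnonzero(keep))


def ld_prune(panel: GenotypePanel, r2_max: float = 0.2,
             window_bp: int = 10_000) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Scans each arm in positional order; a site is kept only if its r² with
    every already-kept site within ``window_bp`` is <= ``r2_max``.  Returns
    the indices (into ``panel.sites``) of retained sites; the retained set
    satisfies the pairwise condition by construction.
    """
    g = panel.imputed()
    keep: list[int] = []
    for arm, grp in panel.sites.groupby("arm", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        kept_idx: list[int] = []
        kept_pos: list[int] = []
        for k, j in enumerate(idx):
            lo = pos[k] - window_bp
            near = [m for m, q in zip(kept_idx, kept_pos) if q >= lo]
            if near:
                r2 = r2_vector(g[:, j], g[:, near])
                if np.any(r2 > r2_max):
                    continue
            kept_idx.append(j)
            kept_pos.append(pos[k])
        keep.extend(kept_idx)
    return np.array(sorted(keep))


def pca_outliers(panel: GenotypePanel, reference_panel: GenotypePanel | None = None,
                 n_pcs: int = 2, sd_threshold: float = 6.0):
    """PC scores of the centred genotype matrix and outlier flags.

    The PCA is fit on focal + reference individuals over the shared site
    set (reference optional); outliers are focal individuals whose score
    exceeds ``sd_threshold`` focal-panel SDs on any of the first
    ``n_pcs`` axes.
    """
    if panel.n_lines < n_pcs + 1:
        raise ValueError("fewer individuals than requested principal components")
    g_focal = panel.imputed()
    if reference_panel is not None:
        key = panel.sites.set_index(["arm", "pos"]).index
        ref_key = reference_panel.sites.set_index(["arm", "pos"]).index
        shared = key.intersection(ref_key)
        f_idx = np.flatnonzero(key.isin(shared))
        r_idx = np.flatnonzero(ref_key.isin(shared))
        mat = np.vstack([g_focal[:, f_idx], reference_panel.imputed()[:, r_idx]])
    else:
        mat = g_focal
    mat = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    scores_all = u[:, :n_pcs] * s[:n_pcs]
    scores = scores_all[: panel.n_lines]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    flags = np.any(np.abs(scores) > sd_threshold * sd, axis=1)
    return scores, flags


def run_qc(panel: GenotypePanel, min_depth: int = 10, min_gq: int = 30,
           max_missing: float = 0.15, min_call_rate: float = 0.95,
           min_maf: float = 0.05) -> tuple[GenotypePanel, QCReport]:
    """Full funnel: calls -> individuals -> sites (call rate, MAF, biallelic)."""
    report = QCReport(input_sites=panel.n_sites, input_individuals=panel.n_lines)
    p = filter_calls(panel, min_depth, min_gq, report)
    p = filter_individuals(p, max_missing, report)
    p = filter_sites(p, min_call_rate, min_maf, report=report)
    report.final_sites = p.n_sites
    report.final_individuals = p.n_lines
    return p, report
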