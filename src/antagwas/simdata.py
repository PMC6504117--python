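"""Synthetic hemiclone study generator.

Emulates the statistical structure the downstream analyses assume: a panel
of ~200 haploid hemiclonal genomes over five chromosome arms with LD that
decays within ~1 kb, vial-replicated male/female fitness assays with a
specified sex-specific genetic (co)variance matrix, comparison populations
that drift away from the focal population except at balanced sites, and
functional annotation tables.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from antagwas._util import check_psd_2x2, psd_inv_sqrt, psd_sqrt
from antagwas.panel import ComparisonPanel, GenotypePanel

ARMS_DEFAULT = ("2L", "2R", "3L", "3R", "X")

# default functional-category mix, loosely Drosophila-like
CATEGORY_PROPORTIONS = {
    "missense": 0.05,
    "synonymous": 0.07,
    "intron": 0.33,
    "5'UTR": 0.02,
    "3'UTR": 0.03,
    "upstream": 0.10,
    "downstream": 0.10,
    "splice_region": 0.01,
    "intergenic": 0.29,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Genetic (co)variances are on the scale of normalised (Box-Cox + z-scored)
    fitness; defaults target h²_f = 2*0.27/1.27 ≈ 0.42, h²_m ≈ 0.16 and
    r_mf ≈ 0.15, i.e. the magnitudes reported for the real hemiclone panel.
    """

    n_lines: int = 200
    snps_per_arm: int = 400
    arms: tuple[str, ...] = ARMS_DEFAULT
    ld_block_bp: float = 1000.0
    target_maf_range: tuple[float, float] = (0.05, 0.5)
    n_antagonistic_causal: int = 40
    n_concordant_causal: int = 40
    sigma2_Gm: float = 0.087
    sigma2_Gf: float = 0.27
    cov_Gmf: float = 0.023
    sigma2_Rm: float = 1.0
    sigma2_Rf: float = 1.0
    sigma2_block: float = 0.1
    n_blocks: int = 5
    vials_per_block: int = 5
    flies_per_vial: int = 5
    qc_fail_rate: float = 0.05
    balanced_fraction: float = 1.0
    balancing_strength: float = 0.05
    balancing_eq_freq: float = 0.5
    drift_generations: int = 500
    pop_size: int = 1000
    panel_size: int = 100
    allele_mismatch_rate: float = 0.02
    n_founders: int = 8
    site_spacing_bp: float = 100.0
    mean_depth: float = 40.0
    n_tissues: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        lo, hi = self.target_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < min <= max <= 0.5")
        for name in ("n_lines", "snps_per_arm", "n_blocks", "vials_per_block", "flies_per_vial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        check_psd_2x2(self.g_matrix())
        if self.sigma2_Rm < 0 or self.sigma2_Rf < 0:
            raise ValueError("residual variances must be non-negative")

    def g_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_Gm, self.cov_Gmf], [self.cov_Gmf, self.sigma2_Gf]]
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        d["target_maf_range"] = list(self.target_maf_range)
        return d


@dataclass
class FitnessTruth:
    """Ground truth recorded by :func:`simulate_fitness` for recovery tests."""

    causal_idx_antagonistic: np.ndarray
    causal_idx_concordant: np.ndarray
    line_values_male: np.ndarray
    line_values_female: np.ndarray


@dataclass
class AnnotationSet:
    """Synthetic stand-in for functional/expression annotation inputs."""

    site_category: pd.Series  # one category per site
    site_gene: pd.Series  # gene id per site ('' for intergenic)
    genes: pd.DataFrame  # gene, arm, start, end, sex_bias, sex_bias_sig, ppi, adult_expressed
    tissue_expression: pd.DataFrame  # genes x tissues, non-negative
    linked_selection: pd.DataFrame  # arm, start, end, value (0-based half-open)


def _copying_paths(rng: np.random.Generator, n_lines: int, positions: np.ndarray,
                   n_founders: int, ld_block_bp: float) -> np.ndarray:
    """Founder index per (line, site) under a haplotype-copying walk.

    The copied founder switches between adjacent sites with probability
    1 - exp(-d / ld_block_bp); ld_block_bp == 0 makes every site an
    independent copy (no LD).
    """
    n_sites = positions.size
    if ld_block_bp <= 0:
        return rng.integers(0, n_founders, size=(n_lines, n_sites))
    d = np.diff(positions.astype(float))
    p_switch = 1.0 - np.exp(-d / ld_block_bp)
    paths = np.empty((n_lines, n_sites), dtype=np.int64)
    paths[:, 0] = rng.integers(0, n_founders, size=n_lines)
    switches = rng.random((n_lines, n_sites - 1)) < p_switch[None, :]
    new = rng.integers(0, n_founders, size=(n_lines, n_sites - 1))
    for j in range(1, n_sites):
        paths[:, j] = np.where(switches[:, j - 1], new[:, j - 1], paths[:, j - 1])
    return paths


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Generate a haploid genotype panel with block-wise LD.

    Sites live on ``config.arms`` at ~``site_spacing_bp`` mean spacing; the
    realised minor-allele frequency of every retained site lies within
    ``target_maf_range``.  Per-call DP/GQ values are attached so the QC
    funnel has something to filter.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.target_maf_range
    bases = np.array(list("ACGT"))
    frames, genos, dps, gqs = [], [], [], []
    for arm in config.arms:
        kept_pos: list[np.ndarray] = []
        kept_geno: list[np.ndarray] = []
        n_kept = 0
        attempt = 0
        # oversample until enough sites fall in the MAF window
        while n_kept < config.snps_per_arm and attempt < 20:
            attempt += 1
            n_try = 2 * config.snps_per_arm
            arm_len = int(config.snps_per_arm * config.site_spacing_bp * 2)
            offset = (attempt - 1) * arm_len
            positions = offset + np.sort(
                rng.choice(np.arange(1, arm_len), size=n_try, replace=False)
            )
            founder_freq = rng.uniform(0.15, 0.85, size=n_try)
            founders = (rng.random((config.n_founders, n_try)) < founder_freq).astype(float)
            paths = _copying_paths(
                rng, config.n_lines, positions, config.n_founders, config.ld_block_bp
            )
            g = founders[paths, np.arange(n_try)]
            p = g.mean(axis=0)
            maf = np.minimum(p, 1 - p)
            ok = (maf >= lo) & (maf <= hi)
            kept_pos.append(positions[ok])
            kept_geno.append(g[:, ok])
            n_kept += int(ok.sum())
        if n_kept < config.snps_per_arm:
            raise RuntimeError(f"could not generate enough in-range sites on arm {arm}")
        pos = np.concatenate(kept_pos)[: config.snps_per_arm]
        g = np.concatenate(kept_geno, axis=1)[:, : config.snps_per_arm]
        ref = bases[rng.integers(0, 4, size=config.snps_per_arm)]
        alt = np.array(
            [bases[rng.choice([b for b in range(4) if bases[b] != r])] for r in ref]
        )
        frames.append(pd.DataFrame({"arm": arm, "pos": pos, "ref": ref, "alt": alt}))
        genos.append(g)
        n = (config.n_lines, config.snps_per_arm)
        dp = rng.poisson(config.mean_depth, size=n)
        gq = np.minimum(99, rng.poisson(60, size=n))
        # a sprinkling of low-quality calls so the call filter has work to do
        low = rng.random(n) < config.qc_fail_rate / 2
        dp[low] = rng.integers(0, 10, size=int(low.sum()))
        low_gq = rng.random(n) < config.qc_fail_rate / 2
        gq[low_gq] = rng.integers(0, 30, size=int(low_gq.sum()))
        dps.append(dp)
        gqs.append(gq)
    sites = pd.concat(frames, ignore_index=True)
    lines = [f"L{i:03d}" for i in range(config.n_lines)]
    return GenotypePanel(
        lines=lines,
        sites=sites,
        genotypes=np.concatenate(genos, axis=1),
        dp=np.concatenate(dps, axis=1),
        gq=np.concatenate(gqs, axis=1),
    )


def _line_genetic_values(panel: GenotypePanel, config: SimConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, FitnessTruth]:
    n_ant, n_con = config.n_antagonistic_causal, config.n_concordant_causal
    if n_ant + n_con > panel.n_sites:
        raise ValueError("more causal sites requested than sites in the panel")
    g = config.g_matrix()
    zero_var = [g[0, 0] <= 0, g[1, 1] <= 0]
    if any(zero_var) and config.cov_Gmf != 0:
        raise ValueError("zero genetic variance with nonzero cross-sex covariance")
    n = panel.n_lines
    if n_ant + n_con == 0 or (zero_var[0] and zero_var[1]):
        zeros = np.zeros(n)
        truth = FitnessTruth(np.array([], int), np.array([], int), zeros, zeros.copy())
        return zeros, zeros.copy(), truth
    idx = rng.choice(panel.n_sites, size=n_ant + n_con, replace=False)
    idx_ant, idx_con = idx[:n_ant], idx[n_ant:]
    x = panel.imputed()
    b_ant = rng.standard_normal(n_ant)
    b_con = rng.standard_normal(n_con)
    ant = x[:, idx_ant] @ b_ant if n_ant else np.zeros(n)
    con = x[:, idx_con] @ b_con if n_con else np.zeros(n)
    raw = np.column_stack([ant + con, -ant + con])  # male, female
    raw -= raw.mean(axis=0)
    emp = raw.T @ raw / (n - 1)
    if np.linalg.matrix_rank(emp, tol=1e-10) < 2 and not any(zero_var):
        raise ValueError(
            "degenerate causal architecture: need at least one antagonistic and "
            "one concordant causal site to realise a full-rank G"
        )
    # recolour so the realised line-level (co)variance equals the target G
    vals = raw @ psd_inv_sqrt(emp) @ psd_sqrt(g)
    gm, gf = vals[:, 0], vals[:, 1]
    truth = FitnessTruth(idx_ant, idx_con, gm, gf)
    return gm, gf, truth


def simulate_fitness(panel: GenotypePanel, config: SimConfig) -> tuple[pd.DataFrame, FitnessTruth]:
    """Vial-level male/female fitness assays for each line.

    Line genetic values are additive over causal sites and rescaled exactly
    to the target G; each vial observation adds a block effect and residual
    noise.  Male values are proportions of wild-type progeny around the
    empirical competitor share (0.464); female values are egg counts.  A
    fraction ``qc_fail_rate`` of vials is injected with QC failures
    (missing focal males, <2 eggs, dead females).
    """
    rng = np.random.default_rng(config.seed + 1)
    gm, gf, truth = _line_genetic_values(panel, config, rng)
    rows = []
    block_eff = rng.normal(0.0, np.sqrt(config.sigma2_block),
                           size=(config.n_blocks, 2))
    sd_r = {"M": np.sqrt(config.sigma2_Rm), "F": np.sqrt(config.sigma2_Rf)}
    gval = {"M": gm, "F": gf}
    for sex_i, sex in enumerate(("M", "F")):
        for block in range(1, config.n_blocks + 1):
            for vial in range(1, config.vials_per_block + 1):
                latent = (
                    gval[sex]
                    + block_eff[block - 1, sex_i]
                    + rng.normal(0.0, sd_r[sex], size=panel.n_lines)
                )
                fail = rng.random(panel.n_lines) < config.qc_fail_rate
                if sex == "M":
                    value = np.clip(0.464 + 0.08 * latent, 0.005, 0.995)
                    alive = np.where(fail, rng.integers(0, config.flies_per_vial,
                                                        size=panel.n_lines),
                                     config.flies_per_vial)
                    for i, line in enumerate(panel.lines):
                        rows.append((line, sex, block, vial, float(value[i]),
                                     int(alive[i]), np.nan, False))
                else:
                    eggs = np.maximum(0, np.round(30.0 + 8.0 * latent)).astype(int)
                    dead = fail & (rng.random(panel.n_lines) < 0.5)
                    few = fail & ~dead
                    eggs = np.where(few, rng.integers(0, 2, size=panel.n_lines), eggs)
                    for i, line in enumerate(panel.lines):
                        rows.append((line, sex, block, vial, float(eggs[i]),
                                     config.flies_per_vial, int(eggs[i]), bool(dead[i])))
    table = pd.DataFrame(
        rows,
        columns=["line", "sex", "block", "vial", "value",
                 "n_focal_alive", "n_eggs", "female_dead"],
    )
    return table, truth


def simulate_comparison_panel(
    panel: GenotypePanel,
    config: SimConfig,
    antagonistic_truth: np.ndarray | None = None,
    population: str = "COMP",
    strength: float | None = None,
    drift_generations: int | None = None,
    seed_offset: int = 2,
) -> ComparisonPanel:
    """Evolve the focal allele frequencies into an independent panel.

    Neutral sites drift by Wright-Fisher binomial sampling for
    ``drift_generations`` at haploid size ``pop_size``; balanced sites are
    deterministically pulled toward ``balancing_eq_freq`` with strength
    ``balancing_strength`` each generation before sampling.  Some neutral
    sites fix; a small fraction of drifted polymorphic sites is given a
    mismatching alternate allele to emulate non-shared variants.
    """
    if drift_generations is None:
        drift_generations = config.drift_generations
    if drift_generations < 0:
        raise ValueError("drift_generations must be >= 0")
    s = config.balancing_strength if strength is None else strength
    rng = np.random.default_rng(config.seed + seed_offset)
    p = panel.alt_freq().copy()
    p[np.isnan(p)] = 0.0
    n_sites = p.size
    if antagonistic_truth is None:
        antagonistic_truth = np.zeros(n_sites, dtype=bool)
    balanced = antagonistic_truth & (rng.random(n_sites) < config.balanced_fraction)
    p_eq = np.where(p > 0.5, 1.0 - config.balancing_eq_freq, config.balancing_eq_freq)
    n_pop = config.pop_size
    for _ in range(drift_generations):
        p = np.where(balanced, p + s * (p_eq - p), p)
        p = rng.binomial(n_pop, p) / n_pop
    if drift_generations > 0:
        haps = (rng.random((config.panel_size, n_sites)) < p[None, :]).astype(np.int8)
    else:
        # degenerate case: the panel is the focal panel itself
        haps = np.nan_to_num(panel.genotypes).astype(np.int8)
    freq = haps.mean(axis=0)
    sites = panel.sites[["arm", "pos", "ref", "alt"]].copy().reset_index(drop=True)
    if drift_generations > 0 and config.allele_mismatch_rate > 0:
        poly = (freq > 0) & (freq < 1) & ~balanced
        swap = poly & (rng.random(n_sites) < config.allele_mismatch_rate)
        bases = np.array(list("ACGT"))
        for j in np.flatnonzero(swap):
            choices = [b for b in bases if b not in (sites.at[j, "ref"], sites.at[j, "alt"])]
            sites.at[j, "alt"] = choices[rng.integers(0, len(choices))]
    return ComparisonPanel(
        population=population,
        sites=sites,
        freq=freq.astype(float),
        haplotypes=haps,
        call_count=np.full(n_sites, haps.shape[0]),
        balanced_truth=balanced,
    )


def simulate_annotations(
    panel: GenotypePanel,
    config: SimConfig,
    category_proportions: dict[str, float] | None = None,
) -> AnnotationSet:
    """Functional categories, genes, sex-bias, tissue expression, PPI counts
    and a spatially autocorrelated linked-selection track."""
    rng = np.random.default_rng(config.seed + 3)
    props = dict(CATEGORY_PROPORTIONS if category_proportions is None else category_proportions)
    cats = list(props)
    pvec = np.array([props[c] for c in cats], dtype=float)
    pvec = pvec / pvec.sum()
    site_cat = pd.Series(
        np.array(cats)[rng.choice(len(cats), size=panel.n_sites, p=pvec)],
        name="category",
    )
    # genes tile each arm in 5-kb slots; genic sites map to the overlapping gene
    gene_rows = []
    site_gene = np.full(panel.n_sites, "", dtype=object)
    gene_len = 5000
    for arm, grp in panel.sites.groupby("arm", sort=False):
        pos = grp["pos"].to_numpy()
        for slot in np.unique(pos // gene_len):
            gid = f"FBgn_{arm}_{slot:05d}"
            start = int(slot * gene_len + 1)
            gene_rows.append((gid, arm, start, start + gene_len - 1))
        slots = pos // gene_len
        names = np.array([f"FBgn_{arm}_{s:05d}" for s in slots], dtype=object)
        genic = site_cat.iloc[grp.index].to_numpy() != "intergenic"
        site_gene[grp.index.to_numpy()] = np.where(genic, names, "")
    genes = pd.DataFrame(gene_rows, columns=["gene", "arm", "start", "end"])
    n_genes = len(genes)
    biased = rng.random(n_genes) < 0.3
    sex_bias = np.where(biased, rng.normal(0.0, 2.0, n_genes), rng.normal(0.0, 0.2, n_genes))
    genes["sex_bias"] = sex_bias
    genes["sex_bias_sig"] = biased & (np.abs(sex_bias) > 0.5)
    genes["ppi"] = rng.negative_binomial(2, 0.2, size=n_genes)
    genes["adult_expressed"] = rng.random(n_genes) < 0.9
    expr = rng.gamma(1.5, 10.0, size=(n_genes, config.n_tissues))
    tissue_expr = pd.DataFrame(
        expr, index=genes["gene"],
        columns=[f"tissue_{t}" for t in range(config.n_tissues)],
    )
    # AR(1)-smoothed positive linked-selection values over 1-kb windows
    ls_rows = []
    for arm in config.arms:
        pos = panel.sites.loc[panel.sites["arm"] == arm, "pos"]
        if pos.empty:
            continue
        hi = int(pos.max()) + 1000
        starts = np.arange(0, hi, 1000)
        ar = np.empty(starts.size)
        ar[0] = rng.standard_normal()
        for i in range(1, starts.size):
            ar[i] = 0.9 * ar[i - 1] + np.sqrt(1 - 0.81) * rng.standard_normal()
        vals = 0.8 + 0.15 * ar
        for st, v in zip(starts, vals):
            ls_rows.append((arm, int(st), int(st + 1000), float(v)))
    linked = pd.DataFrame(ls_rows, columns=["arm", "start", "end", "value"])
    return AnnotationSet(
        site_category=site_cat,
        site_gene=pd.Series(site_gene, name="gene"),
        genes=genes,
        tissue_expression=tissue_expr,
        linked_selection=linked,
    )
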