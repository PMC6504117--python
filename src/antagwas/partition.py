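"""Heritability partitioning and gene-level enrichment analyses.

Partitions SNP heritability of the antagonism index across chromosomal or
functional classes of SNPs via multi-component REML (one kinship per
class), with circular-permutation nulls that preserve LD and annotation
order; plus candidate-proportion Z-tests, sex-bias analyses, the
tissue-specificity index tau, PPI count regression and gene-set overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from antagwas.panel import GenotypePanel


# ---------------------------------------------------------------- REML core

def _build_class_kinships(panel: GenotypePanel, labels: np.ndarray,
                          weights: np.ndarray | None, alpha: float) -> tuple[list, list]:
    g = panel.imputed()
    p = g.mean(axis=0)
    ok = (p > 0) & (p < 1)
    if weights is None:
        weights = np.ones(panel.n_sites)
    z = np.zeros_like(g)
    z[:, ok] = (np.sqrt(weights[ok]) * (g[:, ok] - p[ok])
                * (p[ok] * (1 - p[ok])) ** (alpha / 2.0))
    classes = [c for c in pd.unique(labels)]
    mats = []
    for c in classes:
        sel = (labels == c) & ok
        zk = z[:, sel]
        K = zk @ zk.T
        d = np.mean(np.diag(K))
        if d <= 0:
            raise ValueError(f"class {c!r} yields a degenerate kinship")
        mats.append(K / d)
    return classes, mats


def _multi_reml(y: np.ndarray, mats: list[np.ndarray]) -> tuple[np.ndarray, float, np.ndarray, float]:
    """ML fit of y ~ N(0, sum_c sc² Kc + se² I) on the centred phenotype.

    Returns (component variances, residual variance, covariance matrix of
    the variance estimates from the expected information, logL).
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    n = y.size
    comps = mats + [np.eye(n)]
    vary = float(y.var())

    def nll(log_v: np.ndarray) -> float:
        v = np.exp(log_v)
        V = sum(vi * Ki for vi, Ki in zip(v, comps))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        alpha_ = np.linalg.solve(L, y)
        logdet = 2 * np.sum(np.log(np.diag(L)))
        return 0.5 * (n * np.log(2 * np.pi) + logdet + alpha_ @ alpha_)

    x0 = np.log(np.full(len(comps), vary / len(comps)))
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(np.log(1e-8 * vary), np.log(10 * vary))] * len(comps))
    v = np.exp(res.x)
    V = sum(vi * Ki for vi, Ki in zip(v, comps))
    Vi = np.linalg.inv(V)
    info = np.empty((len(comps), len(comps)))
    prods = [Vi @ Ki for Ki in comps]
    for i in range(len(comps)):
        for j in range(i, len(comps)):
            info[i, j] = info[j, i] = 0.5 * np.trace(prods[i] @ prods[j])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return v[:-1], float(v[-1]), cov, -res.fun


def partition_h2(y: np.ndarray, panel: GenotypePanel, labels: np.ndarray,
                 weights: np.ndarray | None = None, alpha: float = -0.25,
                 min_class_snps: int = 10) -> pd.DataFrame:
    """Partition SNP heritability across a complete SNP classification.

    Observed share = class variance component / total genetic variance;
    expected share = the class's fraction of the LD-weight mass; Z-test of
    observed vs expected using the delta-method SE of the share.  Classes
    with fewer than ``min_class_snps`` SNPs are flagged unstable.
    """
    labels = np.asarray(labels)
    if labels.size != panel.n_sites:
        raise ValueError("labels must cover every SNP")
    if weights is None:
        weights = np.ones(panel.n_sites)
    classes, mats = _build_class_kinships(panel, labels, weights, alpha)
    v, ve, cov, _ = _multi_reml(y, mats)
    total = v.sum()
    shares = v / total if total > 0 else np.full(len(v), np.nan)
    wmass = np.array([weights[labels == c].sum() for c in classes])
    expected = wmass / wmass.sum()
    # delta method: d share_i / d v_j = (delta_ij total - v_i) / total²
    nc = len(v)
    jac = (np.eye(nc) * total - v[:, None]) / total**2
    share_cov = jac @ cov[:nc, :nc] @ jac.T
    se = np.sqrt(np.clip(np.diag(share_cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = (shares - expected) / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    counts = np.array([(labels == c).sum() for c in classes])
    return pd.DataFrame({
        "class": classes, "n_snps": counts, "variance": v,
        "observed_share": shares, "expected_share": expected,
        "share_se": se, "z": zstat, "p": pvals,
        "unstable": counts < min_class_snps,
    })


def circular_permutation_null(labels: np.ndarray, y: np.ndarray,
                              panel: GenotypePanel,
                              weights: np.ndarray | None = None,
                              alpha: float = -0.25, n_perm: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Circular-genome permutation null for per-class heritability shares.

    Each permutation rotates the annotation vector by a random offset along
    the genome-ordered SNPs (preserving annotation order, class counts and
    LD) and recomputes the partition.  Two-tailed empirical p per class from
    the permuted shares' deviations around their mean.
    """
    rng = np.random.default_rng(seed)
    obs = partition_h2(y, panel, labels, weights, alpha)
    classes = obs["class"].tolist()
    perm_shares = np.full((n_perm, len(classes)), np.nan)
    for b in range(n_perm):
        off = int(rng.integers(0, len(labels)))
        rot = np.roll(labels, off)
        try:
            res = partition_h2(y, panel, rot, weights, alpha)
        except ValueError:
            continue
        res = res.set_index("class")
        for i, c in enumerate(classes):
            if c in res.index:
                perm_shares[b, i] = res.loc[c, "observed_share"]
    out = obs.copy()
    pvals = []
    for i, c in enumerate(classes):
        null = perm_shares[:, i]
        null = null[~np.isnan(null)]
        if null.size == 0:
            pvals.append(np.nan)
            continue
        center = null.mean()
        k = np.sum(np.abs(null - center) >= abs(obs["observed_share"].iloc[i] - center))
        pvals.append((1 + k) / (1 + null.size))
    out["perm_p"] = pvals
    return out


# ----------------------------------------------------- enrichment & genes

def category_enrichment_z(candidate: np.ndarray, category: np.ndarray) -> pd.DataFrame:
    """Two-proportion Z-test per category: candidates vs all SNPs."""
    candidate = np.asarray(candidate, dtype=bool)
    category = np.asarray(category)
    n_cand = candidate.sum()
    n_all = category.size
    rows = []
    for c in pd.unique(category):
        x1 = int((candidate & (category == c)).sum())
        x2 = int((category == c).sum())
        p1 = x1 / n_cand if n_cand else np.nan
        p2 = x2 / n_all
        pool = (x1 + x2) / (n_cand + n_all)
        se = np.sqrt(pool * (1 - pool) * (1 / n_cand + 1 / n_all))
        z = (p1 - p2) / se if se > 0 else 0.0
        rows.append((c, p1, p2, z, 2 * stats.norm.sf(abs(z))))
    return pd.DataFrame(rows, columns=["category", "obs_prop", "exp_prop", "z", "p"])


def sexbias_class_test(genes: pd.DataFrame, antag_col: str = "antagonistic",
                       sig_col: str = "sex_bias_sig") -> dict:
    """Deficit/excess of significantly sex-biased genes among antagonistic genes.

    Expected count = background sex-biased fraction x number of antagonistic
    genes; 1-df χ² on the (biased, unbiased) cells of the antagonistic
    genes; deficit% = 100 (E - O) / E.
    """
    antag = genes[antag_col].astype(bool)
    sig = genes[sig_col].astype(bool)
    n_a = int(antag.sum())
    frac_bg = float(sig[~antag].mean())
    obs = int((antag & sig).sum())
    exp = frac_bg * n_a
    exp2 = (1 - frac_bg) * n_a
    obs2 = n_a - obs
    chi2 = (obs - exp) ** 2 / exp + (obs2 - exp2) ** 2 / exp2
    return {
        "observed": obs, "expected": exp,
        "deficit_percent": 100.0 * (exp - obs) / exp,
        "chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1)),
    }


def sexbias_quantitative(genes: pd.DataFrame, antag_col: str = "antagonistic",
                         bias_col: str = "sex_bias") -> dict:
    """Quantitative sex-bias analyses of antagonistic status.

    Wilcoxon rank-sum on |sex bias| between antagonistic and other genes;
    logistic GLMs of antagonistic status on polynomials of sex bias, with
    LRTs of quadratic-vs-linear (peak at zero bias) and quartic-vs-quadratic
    ('Twin Peaks') shapes.
    """
    y = genes[antag_col].astype(int).to_numpy()
    x = genes[bias_col].to_numpy(dtype=float)
    absb = np.abs(x)
    a, b = absb[y == 1], absb[y == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both antagonistic and nonantagonistic genes required")
    w = stats.mannwhitneyu(a, b, alternative="two-sided")

    def fit_poly(deg: int):
        cols = [x**k for k in range(1, deg + 1)]
        X = sm.add_constant(np.column_stack(cols))
        return sm.GLM(y, X, family=sm.families.Binomial()).fit()

    m1, m2, m4 = fit_poly(1), fit_poly(2), fit_poly(4)
    lrt_quad = 2 * (m2.llf - m1.llf)
    lrt_quart = 2 * (m4.llf - m2.llf)
    return {
        "wilcoxon_w": float(w.statistic), "wilcoxon_p": float(w.pvalue),
        "quadratic_chi2": float(lrt_quad),
        "quadratic_p": float(stats.chi2.sf(max(lrt_quad, 0), 1)),
        "quartic_chi2": float(lrt_quart),
        "quartic_p": float(stats.chi2.sf(max(lrt_quart, 0), 2)),
    }


def tau(expression: np.ndarray) -> float:
    """Tissue-specificity index tau = sum(1 - x_i/max) / (n - 1).

    0 for uniform expression, 1 for single-tissue expression; NaN (flagged
    undefined) for an all-zero row.  Invariant to positive rescaling.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 tissues")
    m = x.max()
    if m <= 0:
        return np.nan
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def trim_sex_limited(genes: pd.DataFrame, bias_col: str = "sex_bias",
                     quantile: float = 0.05) -> pd.DataFrame:
    """Drop genes in the most extreme quantiles of the sex-bias distribution
    (a proxy for sex-limited expression) before tissue-specificity tests."""
    lo = genes[bias_col].quantile(quantile)
    hi = genes[bias_col].quantile(1 - quantile)
    return genes[(genes[bias_col] >= lo) & (genes[bias_col] <= hi)]


def ppi_glm(ppi_counts: np.ndarray, antagonistic: np.ndarray) -> dict:
    """Quasi-Poisson regression of PPI counts on antagonistic status.

    Log-link count GLM with a free dispersion (Pearson χ²/df); the flag is
    tested with a dispersion-adjusted F test.
    """
    yv = np.asarray(ppi_counts, dtype=float)
    flag = np.asarray(antagonistic, dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("zero-variance PPI counts")
    X1 = sm.add_constant(flag)
    fit1 = sm.GLM(yv, X1, family=sm.families.Poisson()).fit()
    fit0 = sm.GLM(yv, np.ones_like(yv), family=sm.families.Poisson()).fit()
    phi = fit1.pearson_chi2 / fit1.df_resid
    f = (fit0.deviance - fit1.deviance) / phi
    p = float(stats.f.sf(f, 1, fit1.df_resid))
    return {"coef": float(fit1.params[1]), "dispersion": float(phi),
            "f": float(f), "p": p}


def overlap_chisq(set_a: np.ndarray, set_b: np.ndarray) -> dict:
    """Overlap of two gene sets against their common background.

    ``set_a``/``set_b`` are boolean masks over the background; expected
    overlap = |A||B|/|background|; 2x2 χ² without continuity correction.
    """
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    n = a.size
    obs = int((a & b).sum())
    exp = a.sum() * b.sum() / n
    table = np.array([
        [obs, int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"observed": obs, "expected": float(exp),
            "chi2": float(chi2), "p": float(p)}


def assign_genes(sites: pd.DataFrame, genes: pd.DataFrame,
                 flank_bp: int = 5000) -> pd.DataFrame:
    """Flag genes with >= 1 candidate SNP within +/- ``flank_bp`` of the
    gene's 1-based inclusive coordinates.  ``sites`` needs arm/pos plus a
    boolean ``candidate`` column."""
    out = genes.copy()
    out["antagonistic"] = False
    cand = sites[sites["candidate"].astype(bool)]
    for arm, grp in cand.groupby("arm"):
        pos = grp["pos"].to_numpy()
        sel = out["arm"] == arm
        starts = out.loc[sel, "start"].to_numpy() - flank_bp
        ends = out.loc[sel, "end"].to_numpy() + flank_bp
        hit = np.array([np.any((pos >= s) & (pos <= e)) for s, e in zip(starts, ends)])
        out.loc[sel, "antagonistic"] = hit
    return out
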