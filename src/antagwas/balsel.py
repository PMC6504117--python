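"""Balancing-selection signatures at candidate antagonistic sites.

Tests the prediction that sexually antagonistic polymorphisms are held at
elevated frequency in independent populations: matched Monte-Carlo
minor-allele-frequency nulls (analysis A), polymorphism-persistence
logistic regressions (analysis B), binned effect-size/MAF rank
correlations (analysis C), sliding-window diversity (pi, Watterson's
theta, Tajima's D) and differentiation (Hudson F_ST) with
linked-selection residualisation, LD pair-class comparisons, and
trans-specific polymorphism flags for sister-species panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from antagwas._util import empirical_pvalue
from antagwas.panel import ComparisonPanel, GenotypePanel


# ------------------------------------------------------------- regressions

def residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of an OLS regression of ``values`` on ``covariate``."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def comparison_maf(lhm_sites: pd.DataFrame, comp: ComparisonPanel) -> np.ndarray:
    """Comparison-population MAF with the allele-identity rule applied.

    Sites monomorphic in the comparison population, and sites where the
    comparison population segregates alleles other than those segregating
    in the focal population, are assigned MAF = 0.
    """
    maf = comp.maf().copy()
    match = (
        (lhm_sites["ref"].to_numpy() == comp.sites["ref"].to_numpy())
        & (lhm_sites["alt"].to_numpy() == comp.sites["alt"].to_numpy())
    )
    maf[~match] = 0.0
    mono = (comp.freq <= 0) | (comp.freq >= 1)
    maf[mono] = 0.0
    return maf


# ------------------------------------------------------ analysis A (null)

@dataclass
class MatchedNullResult:
    observed_mean: float
    null_means: np.ndarray
    p: float
    naive_null_mean: float
    n_candidates: int
    n_bins: int

    @property
    def empirical_p(self) -> float:
        return self.p


def analysis_A_matched_null(
    candidate: np.ndarray,
    lhm_maf: np.ndarray,
    linked_sel: np.ndarray,
    comp_maf: np.ndarray,
    n_sets: int = 1000,
    n_bins: int = 20,
    seed: int = 0,
    tail: str = "ge",
) -> MatchedNullResult:
    """Matched Monte-Carlo null for candidate-site polymorphism.

    Focal MAF is residualised on linked selection; control sites are
    stratified into ``n_bins`` quantile bins of residual MAF; each of
    ``n_sets`` null sets draws (without replacement within a set) control
    sites reproducing the candidates' bin histogram exactly, and records
    the mean comparison-population MAF.  One-sided empirical p by default
    (elevated MAF at candidates); two-sided via ``tail='two'``.
    """
    candidate = np.asarray(candidate, dtype=bool)
    resid = residualize(lhm_maf, linked_sel)
    cand_idx = np.flatnonzero(candidate)
    ctrl_idx = np.flatnonzero(~candidate)
    if cand_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("need both candidate and control sites")
    edges = np.quantile(resid[ctrl_idx], np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    cand_bin = np.digitize(resid[cand_idx], edges[1:-1])
    ctrl_bin = np.digitize(resid[ctrl_idx], edges[1:-1])
    rng = np.random.default_rng(seed)
    null_means = np.zeros(n_sets)
    comp_maf = np.asarray(comp_maf, dtype=float)
    counts = np.bincount(cand_bin, minlength=n_bins)
    per_bin_ctrl = [ctrl_idx[ctrl_bin == b] for b in range(n_bins)]
    for b in range(n_bins):
        if counts[b] > 0 and per_bin_ctrl[b].size == 0:
            raise ValueError(f"residual-MAF bin {b} has candidates but no controls")
        if counts[b] > per_bin_ctrl[b].size:
            raise ValueError(f"residual-MAF bin {b} has too few controls to match")
    total = counts.sum()
    for s in range(n_sets):
        acc = 0.0
        for b in range(n_bins):
            if counts[b] == 0:
                continue
            pick = rng.choice(per_bin_ctrl[b], size=counts[b], replace=False)
            acc += comp_maf[pick].sum()
        null_means[s] = acc / total
    observed = float(comp_maf[cand_idx].mean())
    return MatchedNullResult(
        observed_mean=observed,
        null_means=null_means,
        p=empirical_pvalue(null_means, observed, tail),
        naive_null_mean=float(comp_maf[ctrl_idx].mean()),
        n_candidates=int(cand_idx.size),
        n_bins=n_bins,
    )


# -------------------------------------------------- analysis B (logistic)

def analysis_B_persistence_logit(poly_flag: np.ndarray, abs_beta: np.ndarray,
                                 lhm_maf: np.ndarray,
                                 linked_sel: np.ndarray) -> dict:
    """Does polymorphism persistence increase with antagonistic effect size?

    Logistic regression of the binary 'polymorphic in the comparison
    population' flag on |GWAS effect|, with focal MAF and linked selection
    as covariates; significance by an LRT (1 df) against the model without
    the effect-size term.  OR > 1 means larger-effect sites stay
    polymorphic more often.
    """
    yv = np.asarray(poly_flag, dtype=float)
    if np.all(yv == yv[0]):
        return {"separation": True, "or_per_unit": np.nan, "p": np.nan,
                "chi2": np.nan, "ci": (np.nan, np.nan)}
    X1 = sm.add_constant(np.column_stack([abs_beta, lhm_maf, linked_sel]))
    X0 = sm.add_constant(np.column_stack([lhm_maf, linked_sel]))
    try:
        fit1 = sm.Logit(yv, X1).fit(disp=0)
        fit0 = sm.Logit(yv, X0).fit(disp=0)
    except Exception:
        return {"separation": True, "or_per_unit": np.nan, "p": np.nan,
                "chi2": np.nan, "ci": (np.nan, np.nan)}
    lrt = 2 * (fit1.llf - fit0.llf)
    ci = fit1.conf_int()[1]
    return {
        "separation": False,
        "or_per_unit": float(np.exp(fit1.params[1])),
        "log_odds_slope": float(fit1.params[1]),
        "ci": (float(np.exp(ci[0])), float(np.exp(ci[1]))),
        "chi2": float(lrt),
        "p": float(stats.chi2.sf(max(lrt, 0), 1)),
    }


# --------------------------------------------------- analysis C (spearman)

def analysis_C_binned_spearman(comp_maf: np.ndarray, abs_beta: np.ndarray,
                               resid_lhm_maf: np.ndarray, maf_bins: int = 20,
                               beta_bins: int = 100, seed: int = 0) -> dict:
    """Rank correlation of comparison MAF with effect size over a balanced draw.

    Sites are binned on a (residual focal MAF) x (effect size) quantile
    grid (default 20 x 100 = 2,000 bins); one site is drawn uniformly from
    each non-empty bin and Spearman's rho of comparison MAF vs |effect|
    is computed over the drawn sites.
    """
    rng = np.random.default_rng(seed)
    maf_q = pd.qcut(resid_lhm_maf, maf_bins, labels=False, duplicates="drop")
    beta_q = pd.qcut(abs_beta, beta_bins, labels=False, duplicates="drop")
    cell = maf_q * beta_bins + beta_q
    drawn = []
    cells = pd.unique(cell[~pd.isna(cell)])
    for c in cells:
        members = np.flatnonzero(cell == c)
        drawn.append(int(rng.choice(members)))
    n_total = maf_bins * beta_bins
    if len(cells) < 0.8 * n_total:
        warnings.warn(f"{n_total - len(cells)} of {n_total} MAF/effect bins are empty")
    drawn = np.asarray(drawn)
    rho, p = stats.spearmanr(np.asarray(comp_maf)[drawn], np.asarray(abs_beta)[drawn])
    return {"rho": float(rho), "p": float(p), "n_drawn": int(drawn.size),
            "n_bins_total": n_total}


# ------------------------------------------------------- window diversity

def tajima_constants(n: int) -> dict:
    """Standard Tajima normalising constants for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajima_d(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """(pi, theta_W, D) from derived-allele counts of segregating sites.

    ``counts`` are per-site minor (or derived) allele counts among ``n``
    haplotypes; monomorphic entries are ignored.  D is NaN when S = 0.
    """
    counts = np.asarray(counts, dtype=float)
    seg = (counts > 0) & (counts < n)
    c = counts[seg]
    s = int(c.size)
    const = tajima_constants(n)
    pi = float(np.sum(2.0 * c * (n - c) / (n * (n - 1))))
    theta_w = s / const["a1"]
    if s == 0:
        return pi, theta_w, np.nan
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    return pi, theta_w, float((pi - theta_w) / np.sqrt(var))


def window_diversity(haplotypes: np.ndarray, positions: np.ndarray,
                     arms: np.ndarray | None = None, window: int = 1000,
                     step: int = 500) -> pd.DataFrame:
    """Sliding-window S, pi, theta_W and Tajima's D from a haplotype panel."""
    haplotypes = np.asarray(haplotypes)
    n = haplotypes.shape[0]
    if n < 4:
        raise ValueError("need >= 4 haplotypes for window diversity")
    positions = np.asarray(positions)
    if arms is None:
        arms = np.array(["chr"] * positions.size)
    counts = haplotypes.sum(axis=0)
    rows = []
    for arm in pd.unique(arms):
        mask = arms == arm
        pos_a = positions[mask]
        cnt_a = counts[mask]
        last = int(pos_a.max())
        for start in range(0, last + 1, step):
            end = start + window
            sel = (pos_a > start) & (pos_a <= end)
            if not sel.any():
                rows.append((arm, start, end, 0, 0.0, 0.0, np.nan))
                continue
            pi, tw, d = tajima_d(cnt_a[sel], n)
            s = int(np.sum((cnt_a[sel] > 0) & (cnt_a[sel] < n)))
            rows.append((arm, start, end, s, pi, tw, d))
    return pd.DataFrame(rows, columns=["arm", "start", "end", "S", "pi",
                                       "theta_w", "tajima_d"])


def window_diversity_test(d_values: np.ndarray, antagonistic: np.ndarray,
                          linked_sel: np.ndarray) -> dict:
    """Gaussian GLM of linked-selection-residualised Tajima's D on window class."""
    d = np.asarray(d_values, dtype=float)
    flag = np.asarray(antagonistic, dtype=float)
    ls = np.asarray(linked_sel, dtype=float)
    ok = ~np.isnan(d)
    d, flag, ls = d[ok], flag[ok], ls[ok]
    if len(set(flag)) < 2:
        raise ValueError("need both antagonistic and nonantagonistic windows")
    resid = residualize(d, ls)
    X = sm.add_constant(flag)
    fit = sm.OLS(resid, X).fit()
    f = float(fit.tvalues[1] ** 2)
    return {"coef": float(fit.params[1]), "f": f,
            "p": float(fit.pvalues[1]), "df_resid": int(fit.df_resid)}


# ------------------------------------------------------------- Hudson Fst

def hudson_fst_site(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator with sample-size correction."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Window F_ST as the ratio of averages over sites (Hudson estimator)."""
    num, den = hudson_fst_site(p1, p2, n1, n2)
    ok = den > 0
    if not ok.any():
        return np.nan
    return float(num[ok].sum() / den[ok].sum())


def fst_windows(freq1: np.ndarray, freq2: np.ndarray, n1: int, n2: int,
                positions: np.ndarray, arms: np.ndarray | None = None,
                window: int = 1000, step: int = 500) -> pd.DataFrame:
    """Sliding-window Hudson F_ST between two populations."""
    positions = np.asarray(positions)
    if arms is None:
        arms = np.array(["chr"] * positions.size)
    rows = []
    for arm in pd.unique(arms):
        mask = arms == arm
        pos_a = positions[mask]
        f1, f2 = np.asarray(freq1)[mask], np.asarray(freq2)[mask]
        last = int(pos_a.max())
        for start in range(0, last + 1, step):
            sel = (pos_a > start) & (pos_a <= start + window)
            fst = hudson_fst(f1[sel], f2[sel], n1, n2) if sel.any() else np.nan
            rows.append((arm, start, start + window, int(sel.sum()), fst))
    return pd.DataFrame(rows, columns=["arm", "start", "end", "n_snps", "fst"])


def fst_window_test(fst: np.ndarray, antagonistic: np.ndarray,
                    linked_sel: np.ndarray) -> dict:
    """Wilcoxon rank-sum on linked-selection-residualised window F_ST."""
    fst = np.asarray(fst, dtype=float)
    flag = np.asarray(antagonistic, dtype=bool)
    ok = ~np.isnan(fst)
    resid = residualize(fst[ok], np.asarray(linked_sel, dtype=float)[ok])
    flag = flag[ok]
    if flag.all() or not flag.any():
        raise ValueError("need both window classes")
    w = stats.mannwhitneyu(resid[flag], resid[~flag], alternative="two-sided")
    return {"w": float(w.statistic), "p": float(w.pvalue),
            "mean_antag": float(resid[flag].mean()),
            "mean_control": float(resid[~flag].mean())}


# ------------------------------------------------------------ LD classes

def _exp_decay(d, a, b, c):
    return a * np.exp(-d / b) + c


def ld_class_comparison(haplotypes: np.ndarray, positions: np.ndarray,
                        candidate: np.ndarray, arms: np.ndarray | None = None,
                        max_dist: int = 1000, bin_bp: int = 25,
                        min_pairs: int = 10) -> dict:
    """Pairwise r² within ``max_dist``, split by site-pair class.

    Pair classes: candidate/candidate, control/control and mixed.  r² is
    modelled as a declining exponential in distance over all pairs
    (a·exp(-d/b)+c, least squares, analytically seeded); class differences
    are assessed by Wilcoxon rank-sum tests on the residuals.  Also returns
    distance-binned mean r² per class.
    """
    haplotypes = np.asarray(haplotypes, dtype=float)
    positions = np.asarray(positions)
    candidate = np.asarray(candidate, dtype=bool)
    if arms is None:
        arms = np.array(["chr"] * positions.size)
    hc = haplotypes - haplotypes.mean(axis=0)
    sd = hc.std(axis=0)
    dists, r2s, classes = [], [], []
    for arm in pd.unique(arms):
        idx = np.flatnonzero(arms == arm)
        pos_a = positions[idx]
        for ii, j in enumerate(idx):
            close = idx[(positions[idx] > pos_a[ii]) & (positions[idx] - pos_a[ii] <= max_dist)]
            for m in close:
                if sd[j] == 0 or sd[m] == 0:
                    continue
                r = (hc[:, j] @ hc[:, m]) / (haplotypes.shape[0] * sd[j] * sd[m])
                dists.append(positions[m] - pos_a[ii])
                r2s.append(r**2)
                if candidate[j] and candidate[m]:
                    classes.append("cand/cand")
                elif candidate[j] or candidate[m]:
                    classes.append("mixed")
                else:
                    classes.append("control/control")
    dists = np.asarray(dists, dtype=float)
    r2s = np.asarray(r2s)
    classes = np.asarray(classes)
    if dists.size == 0:
        raise ValueError("no site pairs within max_dist")
    bins = (dists // bin_bp).astype(int)
    binned = {}
    for cls in ("cand/cand", "control/control", "mixed"):
        sel = classes == cls
        binned[cls] = pd.DataFrame({
            "bin_bp": [b * bin_bp for b in np.unique(bins[sel])],
            "mean_r2": [r2s[sel][bins[sel] == b].mean() for b in np.unique(bins[sel])],
        })
    a0 = float(np.clip(r2s[dists <= bin_bp].mean() if (dists <= bin_bp).any()
                       else r2s.mean(), 1e-3, 1))
    c0 = float(r2s[dists >= dists.max() - bin_bp].mean())
    b0 = max_dist / 2.0
    try:
        popt, _ = optimize.curve_fit(_exp_decay, dists, r2s, p0=(a0, b0, c0),
                                     maxfev=10_000)
    except RuntimeError:
        popt = (a0, b0, c0)
    resid = r2s - _exp_decay(dists, *popt)
    tests = {}
    counts = {cls: int((classes == cls).sum())
              for cls in ("cand/cand", "control/control", "mixed")}
    for other in ("control/control", "mixed"):
        a = resid[classes == "cand/cand"]
        b = resid[classes == other]
        if a.size < min_pairs or b.size < min_pairs:
            tests[other] = {"w": np.nan, "p": np.nan, "flagged_few_pairs": True}
            continue
        w = stats.mannwhitneyu(a, b, alternative="two-sided")
        tests[other] = {"w": float(w.statistic), "p": float(w.pvalue),
                        "flagged_few_pairs": False,
                        "mean_resid_cand": float(a.mean()),
                        "mean_resid_other": float(b.mean())}
    return {"fit": {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
            "binned": binned, "tests": tests, "pair_counts": counts}


# -------------------------------------------------------- trans-specific

def trans_specific_flags(lhm_sites: pd.DataFrame, lhm_maf: np.ndarray,
                         species: ComparisonPanel) -> np.ndarray:
    """True where a site is polymorphic in both the focal population and the
    species panel for the same allele pair."""
    lhm_poly = np.asarray(lhm_maf) > 0
    sp_poly = (species.freq > 0) & (species.freq < 1)
    match = (
        (lhm_sites["ref"].to_numpy() == species.sites["ref"].to_numpy())
        & (lhm_sites["alt"].to_numpy() == species.sites["alt"].to_numpy())
    )
    return lhm_poly & sp_poly & match
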