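"""Kinship construction, SNP-heritability REML and mixed-model GWAS.

The association chain mirrors an LDAK-style analysis: per-SNP LD weights
(down-weighting SNPs in strong local LD), a MAF^alpha-scaled kinship
matrix, single-component REML for SNP heritability with phenotype-label
permutations for significance, an EMMAX-style mixed-model Wald test per
SNP, whitening permutations for empirical p-values, Benjamini-Hochberg
FDR, window set-tests, LD clumping and positional clustering tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from antagwas._util import bh_qvalues, empirical_pvalue, pairwise_r2
from antagwas.panel import GenotypePanel

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)


@dataclass
class KinshipModel:
    K: np.ndarray
    ld_weights: np.ndarray
    alpha: float = -0.25


def ld_weights(panel: GenotypePanel, window_bp: int = 100_000) -> np.ndarray:
    """weight_j = 1 / (1 + sum of r² with neighbours within ``window_bp``).

    An isolated SNP gets weight 1; k perfectly correlated copies each get
    weight 1/k.  Weights lie in (0, 1].
    """
    g = panel.imputed()
    w = np.ones(panel.n_sites)
    for arm, grp in panel.sites.groupby("arm", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        r2 = pairwise_r2(g[:, idx])
        near = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        np.fill_diagonal(near, False)
        w[idx] = 1.0 / (1.0 + np.sum(r2 * near, axis=1))
    return w


def kinship(panel: GenotypePanel, weights: np.ndarray | None = None,
            alpha: float = -0.25) -> KinshipModel:
    """MAF^alpha-scaled, LD-weighted kinship with mean diagonal 1.

    Column j of Z is w_j^{1/2} (x_j - p_j) [p_j(1-p_j)]^{alpha/2}; K = ZZᵀ/c
    with c chosen so mean(diag K) = 1.  Missing genotypes must have been
    mean-imputed (handled by the panel).
    """
    g = panel.imputed()
    p = g.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic column in kinship input")
    if weights is None:
        weights = np.ones(panel.n_sites)
    z = np.sqrt(weights) * (g - p) * (p * (1 - p)) ** (alpha / 2.0)
    K = z @ z.T
    c = np.mean(np.diag(K))
    if c <= 0:
        raise ValueError("degenerate kinship (zero diagonal)")
    return KinshipModel(K=K / c, ld_weights=np.asarray(weights), alpha=alpha)


def _profile_loglik(h: float, s: np.ndarray, y2: np.ndarray) -> float:
    """Profile Gaussian log-likelihood of y ~ N(0, sp²(hS + (1-h)I))."""
    n = s.size
    d = h * s + (1 - h)
    sp2 = np.mean(y2 / d)
    if sp2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sp2) + np.sum(np.log(d)) + n)


def reml_h2(y: np.ndarray, K: np.ndarray,
            eig: tuple[np.ndarray, np.ndarray] | None = None,
            tol: float = 1e-10) -> tuple[float, float, float, float]:
    """REML estimate of h²_SNP for y ~ N(0, σ²_SNP K + σ²_e I).

    Maximises the profile likelihood over the variance ratio via the
    eigendecomposition of K (the phenotype carries no fixed effects beyond
    centring, so ML on the centred data is the restricted likelihood).
    Returns (h2_snp, sigma2_snp, sigma2_e, logL).
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    if eig is None:
        s, u = np.linalg.eigh(K)
        if s.min() < -1e-6 * max(s.max(), 1.0):
            raise ValueError("kinship matrix is not PSD")
        s = np.clip(s, 0.0, None)
    else:
        s, u = eig
    y2 = (u.T @ y) ** 2
    obj = lambda h: -_profile_loglik(h, s, y2)
    res = optimize.minimize_scalar(obj, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                   options={"xatol": tol})
    cands = [(obj(0.0), 0.0), (res.fun, float(res.x))]
    fval, h = min(cands)
    d = h * s + (1 - h)
    sp2 = float(np.mean(y2 / d))
    return h, h * sp2, (1 - h) * sp2, -fval


def permutation_pvalue_h2(y: np.ndarray, K: np.ndarray, n_perm: int = 1000,
                          seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of h²_SNP.

    p = (1 + #{permuted ĥ² >= observed}) / (1 + n_perm).
    Returns (p, observed h², null h² values).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s, u = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    eig = (s, u)
    obs = reml_h2(y, K, eig=eig)[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = np.asarray(y, dtype=float)
    for b in range(n_perm):
        null[b] = reml_h2(rng.permutation(y), K, eig=eig)[0]
    return empirical_pvalue(null, obs, "ge"), obs, null


def _whitener(K: np.ndarray, sigma2_g: float, sigma2_e: float) -> np.ndarray:
    """A^{-1} with V = σg² K + σe² I = A², via eigendecomposition."""
    s, u = np.linalg.eigh(K)
    d = sigma2_g * np.clip(s, 0.0, None) + sigma2_e
    if np.any(d <= 0):
        raise ValueError("singular phenotypic covariance V")
    return (u / np.sqrt(d)) @ u.T


def gwas_lmm(y: np.ndarray, panel: GenotypePanel, kin: KinshipModel,
             q_candidate: float = 0.3) -> pd.DataFrame:
    """EMMAX-style mixed-model association scan.

    Variance components are estimated once under the null; each SNP is then
    tested by GLS with V = σ²g K + σ²e I fixed, giving a per-SNP effect,
    SE and 1-df Wald χ².  Constant SNPs are skipped (NaN results, logged).
    Adds BH q-values and the candidate flag (q < ``q_candidate``).
    """
    y = np.asarray(y, dtype=float)
    h2, sg, se_var, _ = reml_h2(y, kin.K)
    # guard: a whitener needs a strictly positive residual component
    se_var = max(se_var, 1e-8 * max(sg, 1.0))
    ainv = _whitener(kin.K, sg, se_var)
    yt = ainv @ (y - y.mean())
    one_t = ainv @ np.ones_like(y)
    # project the transformed intercept out of phenotype and genotypes
    one_n = one_t / np.linalg.norm(one_t)
    yt = yt - one_n * (one_n @ yt)
    g = panel.imputed()
    beta = np.full(panel.n_sites, np.nan)
    se = np.full(panel.n_sites, np.nan)
    const = g.std(axis=0) == 0
    if const.any():
        log.info("skipping %d constant SNP(s) in association scan", int(const.sum()))
    gt = ainv @ g[:, ~const]
    gt = gt - np.outer(one_n, one_n @ gt)
    denom = np.sum(gt**2, axis=0)
    beta[~const] = (gt.T @ yt) / denom
    se[~const] = 1.0 / np.sqrt(denom)
    chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, 1)
    out = panel.sites[["arm", "pos", "ref", "alt"]].copy()
    out["maf"] = panel.maf()
    out["beta"] = beta
    out["se"] = se
    out["wald_chi2"] = chi2
    out["p"] = p
    ok = ~np.isnan(p)
    q = np.full(panel.n_sites, np.nan)
    q[ok] = bh_qvalues(p[ok])
    out["q"] = q
    out["candidate"] = q < q_candidate
    out.attrs["h2_snp"] = h2
    out.attrs["sigma2_g"] = sg
    out.attrs["sigma2_e"] = se_var
    return out


def inflation_factor(p: np.ndarray) -> float:
    """Genomic inflation λ = median(χ²_obs) / median(χ²_1)."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_MEDIAN_1DF)


def whitening_permutation(y: np.ndarray, panel: GenotypePanel, kin: KinshipModel,
                          n_perm: int = 10_000, seed: int = 0,
                          block: int = 2000) -> np.ndarray:
    """Empirical per-SNP p-values from permutations of the whitened phenotype.

    V = σ²g K + σ²e I is fitted under the null; A = V^{1/2}; the transformed
    phenotype z = A⁻¹y has identity covariance, so its entries are
    exchangeable and the mixed model becomes per-SNP OLS on the transformed
    genotypes.  p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm); the
    smallest attainable value is 1/(n_perm+1).
    """
    y = np.asarray(y, dtype=float)
    _, sg, se_var, _ = reml_h2(y, kin.K)
    se_var = max(se_var, 1e-8 * max(sg, 1.0))
    ainv = _whitener(kin.K, sg, se_var)
    z = ainv @ (y - y.mean())
    one_t = ainv @ np.ones_like(y)
    one_n = one_t / np.linalg.norm(one_t)
    g = panel.imputed()
    gt = ainv @ g
    gt = gt - np.outer(one_n, one_n @ gt)
    norms = np.sqrt(np.sum(gt**2, axis=0))
    norms[norms == 0] = np.inf
    gu = gt / norms
    zp = z - one_n * (one_n @ z)
    stat_obs = np.abs(gu.T @ zp)
    rng = np.random.default_rng(seed)
    count = np.zeros(panel.n_sites, dtype=np.int64)
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        zperm = np.empty((len(y), nb))
        for b in range(nb):
            zperm[:, b] = rng.permutation(z)
        zperm -= np.outer(one_n, one_n @ zperm)
        stats_perm = np.abs(gu.T @ zperm)
        count += np.sum(stats_perm >= stat_obs[:, None], axis=1)
        done += nb
    return (1 + count) / (1 + n_perm)


def _window_loglik(h: float, lam: np.ndarray, u2: np.ndarray,
                   rest2: float, n: int) -> float:
    """Profile log-likelihood for z ~ N(0, sp²(h Kw + (1-h) I)) with Kw of
    low rank: ``lam`` are its nonzero eigenvalues, ``u2`` the squared
    projections of z onto those eigenvectors, ``rest2`` the residual squared
    norm in the orthogonal complement."""
    d = h * lam + (1 - h)
    if np.any(d <= 0) or (1 - h) <= 0:
        return -np.inf
    quad = np.sum(u2 / d) + rest2 / (1 - h)
    sp2 = quad / n
    if sp2 <= 0:
        return -np.inf
    logdet = np.sum(np.log(d)) + (n - lam.size) * np.log(1 - h)
    return -0.5 * (n * np.log(2 * np.pi * sp2) + logdet + n)


def window_set_test(y: np.ndarray, panel: GenotypePanel, kin: KinshipModel,
                    window: int = 1000, step: int = 500,
                    q_flag: float = 0.1) -> pd.DataFrame:
    """Set-based association of 1-kb sliding windows (500-bp step).

    The phenotype is whitened by the null background model (σ²g K + σ²e I);
    each window's SNPs then form a local kinship whose variance component
    is tested by REML + a boundary LRT (0.5χ²₀ + 0.5χ²₁ mixture).  Windows
    with fewer than two SNPs are skipped.  BH q-values across tested
    windows; antagonistic flag at q < ``q_flag``.
    """
    y = np.asarray(y, dtype=float)
    _, sg, se_var, _ = reml_h2(y, kin.K)
    se_var = max(se_var, 1e-8 * max(sg, 1.0))
    ainv = _whitener(kin.K, sg, se_var)
    z = ainv @ (y - y.mean())
    z = z - z.mean()
    n = z.size
    g = panel.imputed()
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    sd[sd == 0] = 1.0
    gs = gc / sd
    rows = []
    for arm, grp in panel.sites.groupby("arm", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        last = int(pos.max())
        for start in range(0, last + 1, step):
            end = start + window
            sel = idx[(pos > start) & (pos <= end)]
            if sel.size < 2:
                continue
            zw = (ainv @ gs[:, sel]) / np.sqrt(sel.size)
            uu, sv, _ = np.linalg.svd(zw, full_matrices=False)
            lam = sv**2
            keep = lam > 1e-12 * lam.max()
            lam = lam[keep]
            proj = uu[:, keep].T @ z
            u2 = proj**2
            rest2 = float(z @ z - u2.sum())
            ll0 = _window_loglik(0.0, lam, u2, rest2, n)
            res = optimize.minimize_scalar(
                lambda h: -_window_loglik(h, lam, u2, rest2, n),
                bounds=(0.0, 1.0 - 1e-9), method="bounded")
            ll1 = max(ll0, -res.fun)
            h_w = 0.0 if ll1 <= ll0 else float(res.x)
            lrt = 2 * (ll1 - ll0)
            p = 1.0 if lrt <= 0 else 0.5 * stats.chi2.sf(lrt, 1)
            rows.append((arm, start, end, sel.size, h_w, lrt, p))
    out = pd.DataFrame(rows, columns=["arm", "start", "end", "n_snps",
                                      "h2_window", "lrt", "lrt_p"])
    if len(out):
        out["q"] = bh_qvalues(out["lrt_p"].to_numpy())
        out["antagonistic"] = out["q"] < q_flag
    return out


def clump(assoc: pd.DataFrame, panel: GenotypePanel,
          p_index_max: float = 0.00093, r2_min: float = 0.4,
          dist_bp: int = 10_000) -> pd.DataFrame:
    """Greedy LD clumping of association results.

    Repeatedly takes the best remaining SNP with p <= ``p_index_max`` as an
    index SNP and assigns every unclaimed SNP within ``dist_bp`` on the same
    arm with r² > ``r2_min`` to its cluster.  Returns the association table
    with ``cluster`` (index of cluster, -1 if unclaimed) and ``is_index``.
    """
    g = panel.imputed()
    p = assoc["p"].to_numpy(dtype=float)
    arm = assoc["arm"].to_numpy()
    pos = assoc["pos"].to_numpy()
    cluster = np.full(len(assoc), -1, dtype=int)
    is_index = np.zeros(len(assoc), dtype=bool)
    claimed = np.zeros(len(assoc), dtype=bool)
    order = np.argsort(p, kind="mergesort")
    cid = 0
    for j in order:
        if claimed[j] or np.isnan(p[j]) or p[j] > p_index_max:
            continue
        near = np.flatnonzero((arm == arm[j]) & (np.abs(pos - pos[j]) <= dist_bp)
                              & ~claimed)
        r2 = np.array([1.0 if m == j else
                       float(np.corrcoef(g[:, j], g[:, m])[0, 1] ** 2)
                       for m in near])
        members = near[(r2 > r2_min) | (near == j)]
        cluster[members] = cid
        claimed[members] = True
        is_index[j] = True
        cid += 1
    out = assoc.copy()
    out["cluster"] = cluster
    out["is_index"] = is_index
    return out


def cluster_permutation_test(sites: pd.DataFrame, candidate: np.ndarray,
                             n_perm: int = 1000, seed: int = 0,
                             strata: dict[str, list[str]] | None = None) -> dict:
    """Positional clustering of candidate SNPs via label permutation.

    For each stratum (default: autosomes vs X), the statistic is the median
    distance between adjacent candidate SNPs along arms; candidate labels
    are permuted among all stratum SNPs; p is the proportion of permuted
    medians <= the observed one.  Strata with < 2 candidates are flagged
    undefined.
    """
    if strata is None:
        arms = sites["arm"].unique()
        strata = {"autosome": [a for a in arms if a != "X"],
                  "X": [a for a in arms if a == "X"]}
    rng = np.random.default_rng(seed)
    candidate = np.asarray(candidate, dtype=bool)
    results = {}
    for name, arm_list in strata.items():
        mask = sites["arm"].isin(arm_list).to_numpy()
        sub_arm = sites["arm"].to_numpy()[mask]
        sub_pos = sites["pos"].to_numpy()[mask]
        flags = candidate[mask]
        def median_adjacent(f: np.ndarray) -> float:
            dists = []
            for a in arm_list:
                on_arm = sub_arm == a
                pp = np.sort(sub_pos[on_arm][f[on_arm]])
                if pp.size >= 2:
                    dists.append(np.diff(pp))
            if not dists:
                return np.nan
            return float(np.median(np.concatenate(dists)))
        if flags.sum() < 2:
            results[name] = {"median_bp": np.nan, "p": np.nan, "defined": False}
            continue
        obs = median_adjacent(flags)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = median_adjacent(rng.permutation(flags))
        null = null[~np.isnan(null)]
        pval = float(np.mean(null <= obs)) if null.size else np.nan
        results[name] = {"median_bp": obs, "p": pval, "defined": True,
                         "n_candidates": int(flags.sum())}
    return results


def bonferroni_threshold(alpha_fw: float, m: int) -> float:
    """Family-wise Bonferroni per-test threshold alpha_fw / m."""
    return alpha_fw / m
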