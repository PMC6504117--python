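"""Bivariate line model for sex-specific genetic (co)variances.

The model is Y_ijk = X_ij + e_ijk where Y_ijk is the normalised fitness of
individual k of line j in sex i, X_j = (X_mj, X_fj) ~ N(0, G) is the
sex-specific genotypic effect with G the 2x2 genetic variance-covariance
matrix across sexes, and e_ijk ~ N(0, sigma2_R_i) are sex-specific residuals
uncorrelated across sexes.  A Gibbs sampler with weakly informative
inverse-Wishart / inverse-gamma priors yields the posterior over
(G, residual variances); heritabilities use the hemiclone factor-2 formula
h2_i = 2*sigma2_G_i / (sigma2_G_i + sigma2_R_i), reflecting that assayed
individuals share half their genome (the hemiclonal haplotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from antagwas._util import hpd_interval


def h2_formula(sigma2_g: float, sigma2_r: float) -> float:
    """Hemiclone heritability: h² = 2σ²G / (σ²G + σ²R)."""
    total = sigma2_g + sigma2_r
    if total <= 0:
        raise ValueError("zero total variance: heritability undefined")
    return 2.0 * sigma2_g / total


def rmf_formula(cov_gmf: float, sigma2_gm: float, sigma2_gf: float) -> float:
    """Intersexual genetic correlation r_mf = Cov / sqrt(σ²G,m σ²G,f)."""
    denom = np.sqrt(sigma2_gm * sigma2_gf)
    if denom <= 0:
        return np.nan
    return cov_gmf / denom


@dataclass
class GMatrixEstimate:
    """Posterior summary of the bivariate line model."""

    sigma2_Gm: float
    sigma2_Gf: float
    cov_Gmf: float
    sigma2_Rm: float
    sigma2_Rf: float
    h2_m: float
    h2_f: float
    r_mf: float
    intervals: dict = field(default_factory=dict)  # 95% HPD per derived quantity
    n_draws: int = 0
    ess: dict = field(default_factory=dict)
    r_mf_defined: bool = True
    draws: pd.DataFrame | None = None

    def h2_flags(self) -> dict:
        return {"h2_m_gt_1": self.h2_m > 1.0, "h2_f_gt_1": self.h2_f > 1.0}


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    if np.allclose(xc, 0):
        return float(n)
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] < 0.05:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def fit_bivariate_model(
    table: pd.DataFrame,
    value_col: str = "norm_value",
    n_iter: int = 13_000,
    burn_in: int = 3_000,
    thin: int = 10,
    seed: int = 0,
    prior_nu: float = 3.0,
    prior_v: float = 0.1,
    prior_ig: tuple[float, float] = (0.001, 0.001),
    min_ess: float = 100.0,
) -> GMatrixEstimate:
    """Gibbs sampler over (line effects, G, residual variances).

    ``table`` holds individual-level normalised fitness with columns
    ``line``, ``sex`` ('M'/'F') and ``value_col``.  Point estimates are
    posterior means; intervals are 95% highest-posterior-density.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lines = sorted(table["line"].unique())
    j_of = {l: j for j, l in enumerate(lines)}
    n_lines = len(lines)
    stats_per = {}
    for sex_i, sex in enumerate(("M", "F")):
        sub = table[table["sex"] == sex]
        n = np.zeros(n_lines)
        s = np.zeros(n_lines)
        ss = 0.0
        for l, grp in sub.groupby("line"):
            v = grp[value_col].to_numpy(dtype=float)
            n[j_of[l]] = v.size
            s[j_of[l]] = v.sum()
            ss += float(np.sum(v**2))
        stats_per[sex] = (n, s, ss)
    both = np.sum((stats_per["M"][0] > 0) & (stats_per["F"][0] > 0))
    if both < 2:
        raise ValueError("need >= 2 lines with observations in both sexes")

    G = np.eye(2) * 0.5
    sr = np.array([1.0, 1.0])  # residual variances (M, F)
    x = np.zeros((n_lines, 2))
    a0, b0 = prior_ig
    v0 = np.eye(2) * prior_v
    keep = []
    for it in range(n_iter):
        # line effects: posterior precision P_j = G^-1 + diag(n_mj/sr_m, n_fj/sr_f)
        gi = np.linalg.inv(G)
        d_m = stats_per["M"][0] / sr[0]
        d_f = stats_per["F"][0] / sr[1]
        a = gi[0, 0] + d_m
        b = np.full(n_lines, gi[0, 1])
        c = gi[1, 1] + d_f
        det = a * c - b**2
        rhs_m = stats_per["M"][1] / sr[0]
        rhs_f = stats_per["F"][1] / sr[1]
        mu_m = (c * rhs_m - b * rhs_f) / det
        mu_f = (-b * rhs_m + a * rhs_f) / det
        # sample from N(mu, P^-1) via 2x2 Cholesky of the covariance
        s11 = c / det
        s12 = -b / det
        s22 = a / det
        l11 = np.sqrt(s11)
        l21 = s12 / l11
        l22 = np.sqrt(np.maximum(s22 - l21**2, 1e-300))
        z = rng.standard_normal((n_lines, 2))
        x[:, 0] = mu_m + l11 * z[:, 0]
        x[:, 1] = mu_f + l21 * z[:, 0] + l22 * z[:, 1]
        # G | x ~ inverse-Wishart
        sc = v0 + x.T @ x
        G = stats.invwishart.rvs(df=prior_nu + n_lines, scale=sc, random_state=rng)
        # residual variances | x ~ inverse-gamma
        for k, sex in enumerate(("M", "F")):
            n, s, ss = stats_per[sex]
            ssr = ss - 2 * np.sum(x[:, k] * s) + np.sum(n * x[:, k] ** 2)
            shape = a0 + n.sum() / 2.0
            scale = b0 + ssr / 2.0
            sr[k] = scale / rng.gamma(shape, 1.0)
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep.append((G[0, 0], G[1, 1], G[0, 1], sr[0], sr[1]))
    draws = pd.DataFrame(keep, columns=["sigma2_Gm", "sigma2_Gf", "cov_Gmf",
                                        "sigma2_Rm", "sigma2_Rf"])
    draws["h2_m"] = 2 * draws.sigma2_Gm / (draws.sigma2_Gm + draws.sigma2_Rm)
    draws["h2_f"] = 2 * draws.sigma2_Gf / (draws.sigma2_Gf + draws.sigma2_Rf)
    draws["r_mf"] = draws.cov_Gmf / np.sqrt(draws.sigma2_Gm * draws.sigma2_Gf)
    post = draws.mean()
    intervals = {c: hpd_interval(draws[c].to_numpy()) for c in
                 ("h2_m", "h2_f", "r_mf", "sigma2_Gm", "sigma2_Gf", "cov_Gmf")}
    ess = {c: _ess(draws[c].to_numpy()) for c in ("h2_m", "h2_f", "r_mf")}
    if min(ess.values()) < min_ess:
        warnings.warn(f"sampler effective size below {min_ess}: {ess}")
    defined = post.sigma2_Gm > 1e-8 and post.sigma2_Gf > 1e-8
    return GMatrixEstimate(
        sigma2_Gm=float(post.sigma2_Gm), sigma2_Gf=float(post.sigma2_Gf),
        cov_Gmf=float(post.cov_Gmf), sigma2_Rm=float(post.sigma2_Rm),
        sigma2_Rf=float(post.sigma2_Rf), h2_m=float(post.h2_m),
        h2_f=float(post.h2_f), r_mf=float(post.r_mf) if defined else np.nan,
        intervals=intervals, n_draws=len(draws), ess=ess,
        r_mf_defined=bool(defined), draws=draws,
    )


def heritability(est: GMatrixEstimate) -> dict:
    """Per-sex h² applied per posterior draw, with HPD intervals."""
    if est.draws is None:
        return {
            "h2_m": h2_formula(est.sigma2_Gm, est.sigma2_Rm),
            "h2_f": h2_formula(est.sigma2_Gf, est.sigma2_Rf),
        }
    return {
        "h2_m": float(est.draws["h2_m"].mean()),
        "h2_f": float(est.draws["h2_f"].mean()),
        "h2_m_hpd": hpd_interval(est.draws["h2_m"].to_numpy()),
        "h2_f_hpd": hpd_interval(est.draws["h2_f"].to_numpy()),
    }


def genetic_correlation(est: GMatrixEstimate) -> dict:
    """r_mf per posterior draw with HPD interval; flags near-zero variances."""
    if not est.r_mf_defined:
        return {"r_mf": np.nan, "defined": False}
    if est.draws is None:
        return {"r_mf": rmf_formula(est.cov_Gmf, est.sigma2_Gm, est.sigma2_Gf),
                "defined": True}
    return {
        "r_mf": float(est.draws["r_mf"].mean()),
        "r_mf_hpd": hpd_interval(est.draws["r_mf"].to_numpy()),
        "defined": True,
    }
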