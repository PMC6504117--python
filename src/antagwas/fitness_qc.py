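"""Assay vial QC, Box-Cox normalisation, line means and index rotation.

Male fitness is the proportion of wild-type progeny in a competition vial;
female fitness is an egg count.  Vials failing assay QC are dropped, values
are Box-Cox transformed to normality within each experimental block, then
scaled and centred, averaged into one estimate per line and sex, and
finally rotated onto the antagonism / concordant axes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

# 45-degree rotation of the (male, female) fitness plane; row 1 is the
# concordant axis (negated downstream so beneficial is positive), row 2 the
# antagonistic axis (female-beneficial positive).
ROTATION = np.array([
    [-1 / np.sqrt(2), -1 / np.sqrt(2)],
    [-1 / np.sqrt(2), 1 / np.sqrt(2)],
])


def qc_vials(raw: pd.DataFrame, flies_per_vial: int = 5,
             min_eggs: int = 2) -> pd.DataFrame:
    """Drop failing vials.

    Male vials are removed when not all focal males survived
    (``n_focal_alive < flies_per_vial``); female vials when fewer than
    ``min_eggs`` eggs were present or the female died.
    """
    male = raw["sex"] == "M"
    ok_male = male & (raw["n_focal_alive"] >= flies_per_vial)
    female = raw["sex"] == "F"
    ok_female = female & (raw["n_eggs"] >= min_eggs) & (~raw["female_dead"].astype(bool))
    out = raw[ok_male | ok_female].reset_index(drop=True)
    lost = set(raw["line"]) - set(out["line"])
    if lost:
        warnings.warn(f"{len(lost)} line(s) lost all vials during assay QC: {sorted(lost)[:5]}...")
    return out


def boxcox_lambda(values: np.ndarray, grid_step: float = 0.01,
                  grid_range: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Profile-likelihood Box-Cox lambda on a bounded grid."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(values) == 0:
        raise ValueError("constant values within block: Box-Cox lambda undefined")
    grid = np.arange(grid_range[0], grid_range[1] + grid_step / 2, grid_step)
    # vectorised profile log-likelihood: (λ-1)Σlog y - n/2 log var(y^(λ))
    logy = np.log(values)
    n = values.size
    with np.errstate(over="ignore", invalid="ignore"):
        mat = np.exp(np.outer(logy, grid))  # y**λ
        nz = grid != 0
        t = np.empty_like(mat)
        t[:, nz] = (mat[:, nz] - 1.0) / grid[nz]
        t[:, ~nz] = logy[:, None]
        var = t.var(axis=0, ddof=0)
    ll = (grid - 1.0) * logy.sum() - 0.5 * n * np.log(var)
    ll[~np.isfinite(ll)] = -np.inf
    return float(grid[np.argmax(ll)])


def boxcox_scale_block(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Box-Cox transform within (sex, block), then scale and centre.

    Values equal to zero are offset by half the smallest nonzero value in
    the block before transforming.  Adds a ``norm_value`` column with mean
    0, SD 1 within each (sex, block).
    """
    out = table.copy()
    out["norm_value"] = np.nan
    for (sex, block), grp in table.groupby(["sex", "block"]):
        v = grp[value_col].to_numpy(dtype=float)
        if np.any(v <= 0):
            nz = v[v > 0]
            if nz.size == 0:
                raise ValueError(f"all values non-positive in block {block} sex {sex}")
            v = v + nz.min() / 2.0
        lam = boxcox_lambda(v)
        t = stats.boxcox(v, lmbda=lam)
        t = (t - t.mean()) / t.std(ddof=0)
        out.loc[grp.index, "norm_value"] = t
    return out


def line_means(table: pd.DataFrame, value_col: str = "norm_value") -> pd.DataFrame:
    """Unweighted mean of surviving normalised observations per line and sex.

    Lines missing one sex entirely are flagged ``incomplete`` (and carry
    NaN for that sex's mean).
    """
    means = (
        table.groupby(["line", "sex"])[value_col].mean().unstack("sex")
        .rename(columns={"M": "mean_male", "F": "mean_female"})
    )
    for col in ("mean_male", "mean_female"):
        if col not in means:
            means[col] = np.nan
    means["incomplete"] = means["mean_male"].isna() | means["mean_female"].isna()
    if means["incomplete"].any():
        warnings.warn(
            f"{int(means['incomplete'].sum())} line(s) lack observations for one sex"
        )
    return means.reset_index()[["line", "mean_male", "mean_female", "incomplete"]]


def rotate_indices(means: pd.DataFrame) -> pd.DataFrame:
    """Antagonism and concordant indices from line-mean (male, female) fitness.

    The rotation maps (m, f) to (-(m+f)/sqrt(2), (f-m)/sqrt(2)); component 2
    is reported as ``antagonism_index`` (female-beneficial positive) and
    component 1 is negated into ``concordant_index`` (beneficial positive).
    The rotation is an isometry: index norms equal fitness norms per line.
    """
    mf = means[["mean_male", "mean_female"]].to_numpy(dtype=float)
    rot = mf @ ROTATION.T
    out = means.copy()
    out["concordant_index"] = -rot[:, 0]
    out["antagonism_index"] = rot[:, 1]
    return out


def fitness_pipeline(raw: pd.DataFrame, flies_per_vial: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qc_vials -> boxcox_scale_block -> line_means -> rotate_indices.

    Returns (per-line table with indices, QC'd normalised vial table).
    """
    qcd = qc_vials(raw, flies_per_vial=flies_per_vial)
    normed = boxcox_scale_block(qcd)
    means = line_means(normed)
    complete = means[~means["incomplete"]].reset_index(drop=True)
    return rotate_indices(complete), normed
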