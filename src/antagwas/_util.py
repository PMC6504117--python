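"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns of a genotype matrix.

    Monomorphic columns yield r² = 0 against everything (they carry no
    linkage information).
    """
    g = np.asarray(g, dtype=float)
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    ok = sd > 0
    gn = np.zeros_like(gc)
    gn[:, ok] = gc[:, ok] / sd[ok]
    r = gn.T @ gn / g.shape[0]
    return r**2


def r2_vector(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """r² between one genotype column and each column of ``g``."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    sx = xc.std()
    if sx == 0:
        return np.zeros(g.shape[1])
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    ok = sd > 0
    out = np.zeros(g.shape[1])
    out[ok] = (xc @ gc[:, ok] / (len(x) * sx * sd[ok])) ** 2
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the posterior draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def psd_sqrt(a: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition."""
    w, v = np.linalg.eigh(np.asarray(a, dtype=float))
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T

def psd_inv_sqrt(a: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Pseudo-inverse square root of a symmetric PSD matrix."""
    w, v = np.linalg.eigh(np.asarray(a, dtype=float))
    tol = rcond * max(w.max(), 0.0)
    inv = np.where(w > tol, 1.0 / np.sqrt(np.clip(w, tol, None)), 0.0)
    return (v * inv) @ v.T


def empirical_pvalue(null: np.ndarray, observed: float, tail: str = "ge") -> float:
    """Permutation p with the +1 correction; never exactly zero."""
    null = np.asarray(null, dtype=float)
    if tail == "ge":
        k = int(np.sum(null >= observed))
    elif tail == "le":
        k = int(np.sum(null <= observed))
    elif tail == "two":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + null.size)


def check_psd_2x2(g: np.ndarray) -> None:
    g = np.asarray(g, dtype=float)
    if g[0, 0] < 0 or g[1, 1] < 0 or g[0, 1] != g[1, 0]:
        raise ValueError("G matrix must be symmetric with non-negative variances")
    if g[0, 0] * g[1, 1] - g[0, 1] ** 2 < -1e-12 * max(1.0, g[0, 0] * g[1, 1]):
        raise ValueError("G matrix is not positive semi-definite")
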