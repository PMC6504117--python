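"""In-memory genotype container for haploid hemiclonal panels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["arm", "pos", "ref", "alt"]


@dataclass
class GenotypePanel:
    """Haploid 0/1 genotype matrix with site metadata.

    Attributes
    ----------
    lines:
        Line identifiers, one per matrix row.
    sites:
        DataFrame with columns ``arm`` (chromosome arm), ``pos``
        (1-based bp, strictly increasing within an arm), ``ref``, ``alt``.
    genotypes:
        float array of shape (n_lines, n_sites); values 0.0, 1.0 or NaN
        (missing call).
    dp, gq:
        Optional per-call depth and genotype-quality arrays (same shape
        as ``genotypes``), used to exercise call-level QC.
    """

    lines: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.lines), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.lines)} lines x {len(self.sites)} sites"
            )
        for arm, grp in self.sites.groupby("arm", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on arm {arm}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per site (minor count / called alleles)."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction_per_line(self) -> np.ndarray:
        return np.mean(np.isnan(self.genotypes), axis=1)

    def call_rate_per_site(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=0)

    def take_sites(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            lines=list(self.lines),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            lines=[self.lines[i] for i in idx],
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx],
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def imputed(self) -> np.ndarray:
        """Genotypes with missing calls mean-imputed per site."""
        g = self.genotypes.copy()
        p = self.alt_freq()
        nan = np.isnan(g)
        g[nan] = np.broadcast_to(p, g.shape)[nan]
        return g

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.lines == other.lines
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.genotypes, other.genotypes, equal_nan=True)
        )


@dataclass
class ComparisonPanel:
    """Allele-frequency / haplotype panel from an independent population.

    ``balanced_truth`` carries simulation ground truth (which sites were
    held polymorphic by balancing selection); it is None for real panels.
    """

    population: str
    sites: pd.DataFrame  # arm, pos, ref, alt (alleles as observed in this panel)
    freq: np.ndarray  # alt-allele frequency per site
    haplotypes: np.ndarray  # (n_haplotypes, n_sites) 0/1
    call_count: np.ndarray  # called alleles per site
    balanced_truth: np.ndarray | None = None

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def maf(self) -> np.ndarray:
        return np.minimum(self.freq, 1.0 - self.freq)
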