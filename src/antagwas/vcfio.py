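"""VCF and TSV input/output for genotype panels and pipeline tables.

VCF v4.2 with haploid GT calls and per-call DP/GQ, read and written through
pysam so the call-level QC filters are exercisable from files on disk.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from antagwas.panel import GenotypePanel


def write_panel_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write a panel as VCF v4.2 (haploid GT, DP and GQ per call)."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line('##source=antagwas')
    for arm in panel.sites["arm"].unique():
        length = int(panel.sites.loc[panel.sites["arm"] == arm, "pos"].max()) + 1000
        header.add_line(f"##contig=<ID={arm},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for line in panel.lines:
        header.add_sample(line)
    dp = panel.dp if panel.dp is not None else np.full(panel.genotypes.shape, 99, int)
    gq = panel.gq if panel.gq is not None else np.full(panel.genotypes.shape, 99, int)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, site in panel.sites.iterrows():
            rec = vcf.new_record(
                contig=site["arm"], start=int(site["pos"]) - 1,
                stop=int(site["pos"]), alleles=(site["ref"], site["alt"]),
            )
            rec.id = f"{site['arm']}_{site['pos']}"
            for i, sample in enumerate(panel.lines):
                g = panel.genotypes[i, j]
                rec.samples[sample]["GT"] = (None,) if np.isnan(g) else (int(g),)
                rec.samples[sample]["DP"] = int(dp[i, j])
                rec.samples[sample]["GQ"] = int(gq[i, j])
            vcf.write(rec)


def read_panel_vcf(path: str | os.PathLike) -> GenotypePanel:
    """Read a haploid VCF back into a :class:`GenotypePanel`."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        arms, pos, ref, alt = [], [], [], []
        geno_rows, dp_rows, gq_rows = [], [], []
        for rec in vcf:
            fmt = set(rec.format.keys())
            for needed in ("GT",):
                if needed not in fmt:
                    raise ValueError(f"VCF record at {rec.chrom}:{rec.pos} lacks FORMAT field {needed}")
            arms.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0] if rec.alts else ".")
            g = np.empty(len(samples))
            d = np.empty(len(samples), dtype=int)
            q = np.empty(len(samples), dtype=int)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                allele = call["GT"][0] if call.get("GT") else None
                g[i] = np.nan if allele is None else float(allele)
                d[i] = call.get("DP") if call.get("DP") is not None else -1
                q[i] = call.get("GQ") if call.get("GQ") is not None else -1
            geno_rows.append(g)
            dp_rows.append(d)
            gq_rows.append(q)
    sites = pd.DataFrame({"arm": arms, "pos": pos, "ref": ref, "alt": alt})
    return GenotypePanel(
        lines=samples,
        sites=sites,
        genotypes=np.array(geno_rows).T if geno_rows else np.empty((len(samples), 0)),
        dp=np.array(dp_rows).T if dp_rows else None,
        gq=np.array(gq_rows).T if gq_rows else None,
    )


def write_assay_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_assay_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_linked_selection(track: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED-like TSV: arm, start, end (0-based half-open), value."""
    track[["arm", "start", "end", "value"]].to_csv(path, sep="\t", index=False)


def read_linked_selection(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
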