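"""Genotype QC funnel: call-level filters, individuals, sites, LD pruning.

Thresholds follow the study design: calls with DP<10 or GQ<30 are set
missing, individuals with >15% missingness are dropped, sites need a
>=95% call rate and MAF>0.05, and LD pruning enforces r²<=0.2 in 10 kb.
"""

from antagwas import geno_qc, simdata

cfg = simdata.SimConfig(n_lines=100, snps_per_arm=200, seed=42)
panel = simdata.simulate_genotypes(cfg)

clean, report = geno_qc.run_qc(panel)
print(f"input: {report.input_individuals} individuals x {report.input_sites} sites")
print(f"calls set missing (DP<10 or GQ<30): {report.calls_removed}")
print(f"individuals dropped (>15% missing): {report.individuals_removed_missingness}")
print(f"sites dropped: call rate {report.sites_removed_call_rate}, "
      f"MAF {report.sites_removed_maf}")
print(f"final: {report.final_individuals} x {report.final_sites}")

kept = geno_qc.ld_prune(clean, r2_max=0.2, window_bp=10_000)
print(f"LD pruning retains {len(kept)} of {clean.n_sites} sites "
      "(no retained pair within 10 kb has r² > 0.2)")

scores, outliers = geno_qc.pca_outliers(clean, sd_threshold=6)
print(f"PCA outliers at 6 SD on the leading PCs: {int(outliers.sum())}")
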