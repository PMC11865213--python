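"""SNP quality control and the VanRaden genomic relationship matrix.

Filters the simulated panel (call rate > 0.9, MAF > 0.02, HWE p > 0.001),
builds G = ZZ' / 2*sum(p(1-p)) on the genotyped fish and derives the two
principal components used later as GWAS covariates.
"""

import numpy as np

import salmofat as sf

cfg = sf.SimulationConfig(seed=1)
ped = sf.simulate_pedigree(cfg)
geno = sf.simulate_genotypes(ped, cfg)

kept, report = sf.apply_qc(geno)
print(f"QC: {geno.n_snps} SNPs in, {kept.n_snps} kept")
print(f"  removed by call rate: {report.removed_call_rate}")
print(f"  removed by MAF:       {report.removed_maf}")
print(f"  removed by HWE:       {report.removed_hwe}")
print(f"  removed in total:     {report.removed_total} "
      "(a SNP can fail several filters)\n")

genotyped = kept.subset_samples(ped.loc[ped["genotyped"], "individual_id"])
grm = sf.compute_grm(genotyped)
diag = np.diag(grm.values)
fam = ped.set_index("individual_id").loc[grm.sample_ids, "family_id"].to_numpy()
sibs = (fam[:, None] == fam[None, :]) & ~np.eye(len(fam), dtype=bool)
print(f"GRM: {grm.n_samples} fish, {grm.n_snps} SNPs")
print(f"  mean diagonal            {diag.mean():.3f}  (~1 for a well-scaled G)")
print(f"  mean full-sib off-diag   {grm.values[sibs].mean():.3f}  (~0.5 expected)")
print(f"  mean non-sib off-diag    {grm.values[~sibs & ~np.eye(len(fam), dtype=bool)].mean():.3f}")

pcs = sf.grm_pca(grm, 2)
print(f"  PC coordinates: {pcs.shape[0]} x {pcs.shape[1]}, "
      f"PC1 span {pcs['PC1'].min():.2f}..{pcs['PC1'].max():.2f}")
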