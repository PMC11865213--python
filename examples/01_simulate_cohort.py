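"""Simulate the default salmon cohort and summarise its phenotypes.

Builds the full synthetic population — 634 fish from 39 sires x 48 dams,
610 genotyped on a 5,000-SNP panel, 48 selected for RNA-seq — and prints
the descriptive statistics the generator is calibrated to (liver fat mean
near 7.6 % with a ~4 % floor, HSI near 0.8).
"""

import salmofat as sf

cfg = sf.SimulationConfig(seed=1)
ped = sf.simulate_pedigree(cfg)
geno = sf.simulate_genotypes(ped, cfg)
phen = sf.simulate_phenotypes(geno, ped, cfg)

print(f"pedigree: {len(ped)} offspring, {ped['family_id'].nunique()} full-sib "
      f"families, {ped['genotyped'].sum()} genotyped, "
      f"{ped['expression'].sum()} in the RNA-seq subset")
print(f"genotypes: {geno.n_samples} x {geno.n_snps} dosages on "
      f"{geno.snp_map['chrom'].nunique()} chromosomes\n")

table = sf.descriptive_stats(
    phen, ["liver_fat", "muscle_fat", "body_weight", "hsi", "liver_score"]
)
print(table.round(2).to_string(index=False))
print("\nEach row gives n, mean, SD and range over the simulated fish; the "
      "liver-fat floor near 4% produces the right-skew seen in real cohorts.")
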