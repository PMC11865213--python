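"""Generator behaviour: pedigree structure, Mendelian gene dropping,
phenotype calibration, expression coupling, fatty-acid closure, annotation."""

import numpy as np
import pandas as pd
import pytest

import salmofat as sf
from salmofat.config import TraitSpec
from salmofat.errors import InvalidConfigError


class TestPedigree:
    def test_default_population_structure(self):
        cfg = sf.SimulationConfig(seed=1)
        ped = sf.simulate_pedigree(cfg)
        assert len(ped) == 634
        assert ped["genotyped"].sum() == 610
        assert ped["expression"].sum() == 48
        assert ped["family_id"].nunique() <= 48
        assert ped["sire_id"].nunique() <= 39
        # expression subset drawn from the genotyped fish
        assert (ped.loc[ped["expression"], "genotyped"]).all()
        # parent ids disjoint from offspring ids
        assert not (set(ped["sire_id"]) | set(ped["dam_id"])) & set(ped["individual_id"])

    def test_single_cross_gives_one_family(self):
        cfg = sf.SimulationConfig(
            n_individuals=20, n_genotyped=20, n_expression=5, n_sires=1, n_dams=1,
            n_snps=50, n_chromosomes=2, qc_spike=(0, 0, 0), seed=2,
        )
        ped = sf.simulate_pedigree(cfg)
        assert ped["family_id"].nunique() == 1

    def test_family_constant_within_sire_dam_pair(self, cohort):
        ped = cohort["ped"]
        assert (ped.groupby(["sire_id", "dam_id"])["family_id"].nunique() == 1).all()

    def test_oversized_expression_subset_rejected(self):
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(n_individuals=10, n_genotyped=10, n_expression=11)


class TestGenotypes:
    def test_mendelian_transmission(self, cohort):
        """No offspring dosage is unreachable from its parents' dosages."""
        gm, ped = cohort["gm"], cohort["ped"]
        founder_row = {f: i for i, f in enumerate(gm.founder_ids)}
        si = np.array([founder_row[s] for s in ped["sire_id"]])
        di = np.array([founder_row[d] for d in ped["dam_id"]])
        clean = gm.snp_map["qc_spike"].to_numpy() == ""
        off = gm.dosages[:, clean]
        sire = gm.founder_dosages[si][:, clean]
        dam = gm.founder_dosages[di][:, clean]
        # each parent transmits at least floor(g/2)=g-1 (g>=1) and at most min(g,1)... encode bounds
        lo = (sire == 2).astype(int) + (dam == 2).astype(int)
        hi = 2 - (sire == 0).astype(int) - (dam == 0).astype(int)
        assert ((off >= lo) & (off <= hi)).all()

    def test_founder_allele_frequency_binomial(self):
        """Founder frequency at p=0.3 lands within 3 binomial SEs."""
        cfg = sf.SimulationConfig(
            n_individuals=10_000, n_genotyped=10_000, n_expression=5,
            n_sires=5000, n_dams=5000, n_snps=5, n_chromosomes=1,
            maf_range=(0.3, 0.3), qc_spike=(0, 0, 0), seed=4,
        )
        ped = sf.simulate_pedigree(cfg)
        gm = sf.simulate_genotypes(ped, cfg)
        freq = gm.founder_dosages.mean(axis=0) / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 10_000))
        assert (np.abs(freq - 0.3) < 3 * se).all()

    def test_qc_spikes_are_guaranteed_violations(self, cohort):
        gm, report = cohort["gm"], cohort["report"]
        n_spiked = sum(cohort["cfg"].qc_spike)
        assert report.removed_total >= n_spiked
        spiked = gm.snp_map["qc_spike"].to_numpy() != ""
        metrics = report.metrics
        assert not metrics.loc[spiked, "pass"].any()

    def test_seed_determinism(self, small_cfg):
        ped1 = sf.simulate_pedigree(small_cfg)
        gm1 = sf.simulate_genotypes(ped1, small_cfg)
        ph1 = sf.simulate_phenotypes(gm1, ped1, small_cfg)
        ped2 = sf.simulate_pedigree(small_cfg)
        gm2 = sf.simulate_genotypes(ped2, small_cfg)
        ph2 = sf.simulate_phenotypes(gm2, ped2, small_cfg)
        pd.testing.assert_frame_equal(ped1, ped2)
        np.testing.assert_array_equal(gm1.dosages, gm2.dosages)
        pd.testing.assert_frame_equal(ph1, ph2)

    def test_empty_maf_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(maf_range=(0.4, 0.1))

    def test_vcf_round_trip(self, cohort, tmp_path):
        gm = cohort["gq"].subset_snps(cohort["gq"].snp_ids[:40])
        path = str(tmp_path / "panel.vcf")
        gm.to_vcf(path)
        back = sf.GenotypeMatrix.from_vcf(path)
        np.testing.assert_array_equal(back.dosages, gm.dosages)
        assert list(back.snp_ids) == list(gm.snp_ids)

    def test_dosage_tsv_round_trip(self, cohort, tmp_path):
        gm = cohort["gm"].subset_snps(cohort["gm"].snp_ids[:30])
        gm.to_tsv(str(tmp_path / "panel"))
        back = sf.GenotypeMatrix.from_tsv(str(tmp_path / "panel"))
        np.testing.assert_allclose(back.dosages, gm.dosages)


class TestPhenotypes:
    def test_liver_fat_calibration(self, default_cohort):
        """Default cohort: mean liver fat near 7.6 % with a ~4 % floor."""
        fat = default_cohort["phen"]["liver_fat"]
        assert abs(fat.mean() - 7.6) < 0.3
        assert fat.min() > 3.5
        assert fat.skew() > 0  # right tail

    def test_realized_genetic_variance_matches_target(self):
        """Across 20 seeds the variance of simulated breeding values stays
        within 10% of sigma2_g."""
        vars_ = []
        for seed in range(20):
            cfg = sf.paired_trait_config(seed=seed, n_individuals=400, n_snps=800)
            ped = sf.simulate_pedigree(cfg)
            gm = sf.simulate_genotypes(ped, cfg)
            phen = sf.simulate_phenotypes(gm, ped, cfg)
            vars_.append(phen["u_liver_fat"].var(ddof=1))
        assert abs(np.mean(vars_) - 2.59) / 2.59 < 0.10

    def test_null_heritability_truth(self):
        cfg = sf.paired_trait_config(var_g_first=0.0, var_e_first=6.78,
                                     n_individuals=150, n_snps=300, seed=9)
        ped = sf.simulate_pedigree(cfg)
        gm = sf.simulate_genotypes(ped, cfg)
        phen = sf.simulate_phenotypes(gm, ped, cfg)
        assert phen["u_liver_fat"].abs().max() == 0.0

    def test_liver_score_reversal_fields(self, default_cohort):
        phen = default_cohort["phen"]
        assert ((phen["liver_score"] + phen["liver_score_raw"]) == 6).all()
        # reversed score correlates positively with liver fat
        rho, _ = sf.spearman_correlation(phen["liver_fat"], phen["liver_score"])
        assert rho > 0.2

    def test_nonpsd_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.99], [0.99, 1.0]])
        bad[0, 1] = 1.5
        bad[1, 0] = 1.5
        with pytest.raises(InvalidConfigError):
            sf.paired_trait_config(genetic_correlations=bad)


class TestExpression:
    def test_zero_count_gene_is_filtered(self, cohort):
        em, truth = sf.simulate_expression(cohort["phen"], cohort["cfg"])
        zero = em.counts.sum(axis=1) == 0
        assert zero.sum() >= 2
        emn = sf.normalize_expression(em.counts, em.lengths)
        keep = sf.filter_genes(emn)
        assert not keep[zero.to_numpy()].any()
        assert not truth.loc[zero.to_numpy(), "associated"].any()

    def test_strong_coupling_recovered_across_replicates(self):
        """A gene with large positive coupling yields a positive significant
        slope in nearly every replicate."""
        hits = 0
        for seed in range(20):
            cfg = sf.SimulationConfig(
                n_individuals=120, n_genotyped=120, n_expression=48, n_snps=60,
                n_chromosomes=2, n_genes=40, qc_spike=(0, 0, 0), n_zero_genes=0,
                assoc_gene_fraction=1.0, assoc_effect_sd=0.4, seed=seed,
            )
            ped = sf.simulate_pedigree(cfg)
            gm = sf.simulate_genotypes(ped, cfg)
            phen = sf.simulate_phenotypes(gm, ped, cfg)
            em, truth = sf.simulate_expression(phen, cfg)
            gene = truth.loc[truth["coef"].idxmax(), "gene_id"]
            assert truth["coef"].max() > 0.2
            emn = sf.normalize_expression(em.counts, em.lengths)
            scan = sf.run_association_scan(emn, phen)
            rec = scan[scan["gene_id"] == gene]
            if len(rec) and rec["beta1"].iloc[0] > 0 and rec["significant"].iloc[0]:
                hits += 1
        assert hits >= 19

    def test_bad_association_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(assoc_gene_fraction=1.2)


class TestFattyAcids:
    def test_rows_close_to_exactly_100(self, default_cohort):
        fa = sf.simulate_fatty_acids(default_cohort["phen"], default_cohort["cfg"])
        sums = fa.drop(columns="individual_id").sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)
        assert (fa.drop(columns="individual_id") >= 0).all().all()

    def test_oleic_acid_mean_calibration(self, default_cohort):
        fa = sf.simulate_fatty_acids(default_cohort["phen"], default_cohort["cfg"])
        assert len(fa) == 48
        assert abs(fa["18:1n-9"].mean() - 22.4) < 2.0

    def test_signed_coupling_to_liver_fat(self, default_cohort):
        phen = default_cohort["phen"]
        fa = sf.simulate_fatty_acids(phen, default_cohort["cfg"])
        sub = phen.set_index("individual_id").loc[fa["individual_id"]]
        for name, sign in [("18:1n-9", 1), ("22:6n-3", -1)]:
            rho, _ = sf.spearman_correlation(sub["liver_fat"], fa[name])
            assert np.sign(rho) == sign and abs(rho) > 0.25

    def test_decoupled_generator(self, default_cohort):
        cfg = sf.SimulationConfig(
            seed=3, fa_sign_map={k: 0 for k in sf.SimulationConfig().fa_sign_map}
        )
        phen = default_cohort["phen"]
        fa = sf.simulate_fatty_acids(phen, cfg)
        sub = phen.set_index("individual_id").loc[fa["individual_id"]]
        rho, _ = sf.spearman_correlation(sub["liver_fat"], fa["18:1n-9"])
        assert abs(rho) < 0.3

    def test_overfull_means_rejected(self):
        fat = {k: (20.0, 1.0) for k in "abcdef"}
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(fatty_acid_means_sds=fat)


class TestAnnotation:
    def test_every_chromosome_gets_genes(self, small_cfg):
        ann, _ = sf.simulate_annotation_and_terms(small_cfg)
        per_chr = ann.genes.groupby("chrom").size()
        assert len(per_chr) == small_cfg.n_chromosomes
        assert (per_chr >= 1).all()
        # non-overlapping within chromosome
        for _, sub in ann.genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_gff3_round_trip(self, small_cfg, tmp_path):
        ann, _ = sf.simulate_annotation_and_terms(small_cfg)
        path = str(tmp_path / "genes.gff3")
        ann.to_gff3(path)
        back = sf.AnnotationIndex.from_gff3(path)
        pd.testing.assert_frame_equal(
            back.genes.astype({"start": int, "end": int}),
            ann.genes.astype({"start": int, "end": int}),
        )

    def test_constructed_term_enrichment_detected(self, cohort):
        em, truth = sf.simulate_expression(cohort["phen"], cohort["cfg"])
        _, tmap = sf.simulate_annotation_and_terms(cohort["cfg"], truth)
        # pretend the truth labels are the significant set: the loaded terms
        # must come out enriched
        bg = truth["gene_id"].tolist()
        sig = truth.loc[truth["associated"], "gene_id"].tolist()
        enr = sf.enrich_terms(sig, bg, tmap)
        loaded = enr[enr["term_id"].isin(["TERM0001", "TERM0002", "TERM0003"])]
        assert loaded["enriched"].all()
        assert (loaded["direction"] == 1).all()
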