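"""Mixed-model association: thresholds, inflation factor, GLS oracle,
LOCO construction, candidate-gene windows, plot exports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import salmofat as sf
from salmofat.errors import InvalidConfigError, UndefinedStatisticError


@pytest.fixture(scope="module")
def gwas_cohort():
    cfg = sf.SimulationConfig(
        n_individuals=300, n_genotyped=300, n_expression=30, n_snps=600,
        n_chromosomes=6, qc_spike=(0, 0, 0), seed=31,
    )
    ped = sf.simulate_pedigree(cfg)
    gm = sf.simulate_genotypes(ped, cfg)
    phen = sf.simulate_phenotypes(gm, ped, cfg)
    gq, _ = sf.apply_qc(gm)
    grm = sf.compute_grm(gq)
    pcs = sf.grm_pca(grm, 2)
    design = sf.build_design(phen, "liver_fat", pcs=pcs)
    result = sf.mlma_loco(design, gq, grm_full=grm)
    return {"cfg": cfg, "phen": phen, "gq": gq, "grm": grm, "pcs": pcs,
            "design": design, "result": result}


class TestThresholds:
    def test_published_panel_cutoffs(self):
        th = sf.bonferroni_thresholds(52_925, 1_825)
        assert float(f"{th.genome_wide_p:.1e}") == pytest.approx(9.4e-7)
        assert round(th.genome_wide_neglog10, 1) == 6.0
        assert float(f"{th.chromosome_wide_p:.1e}") == pytest.approx(2.7e-5)
        assert round(th.chromosome_wide_neglog10, 1) == 4.6

    def test_single_test_keeps_alpha(self):
        th = sf.bonferroni_thresholds(1, 1)
        assert th.genome_wide_p == 0.05 and th.chromosome_wide_p == 0.05

    def test_monotone_in_test_count(self):
        ps = [sf.bonferroni_thresholds(n).genome_wide_p for n in (10, 100, 1000, 52925)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidConfigError):
            sf.bonferroni_thresholds(0)


class TestInflationFactor:
    def test_definitional_unit_case(self):
        assert sf.inflation_factor(np.array([0.1, 0.455, 3.0])) == pytest.approx(1.0)

    def test_published_magnitude(self):
        chi2 = np.array([0.5369])
        assert round(sf.inflation_factor(chi2), 2) == 1.18

    def test_uniform_p_values_give_lambda_one(self):
        rng = np.random.default_rng(0)
        lam = sf.inflation_factor(p_values=rng.random(10_000))
        assert abs(lam - 1.0) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            sf.inflation_factor(np.array([]))


class TestMlmaLoco:
    def test_matches_direct_gls_oracle(self, gwas_cohort):
        """alpha, SE and p equal an explicit dense-V GLS fit per SNP."""
        gq = gwas_cohort["gq"].subset_snps(gwas_cohort["gq"].snp_ids[:200])
        design = gwas_cohort["design"]
        res = sf.mlma_loco(design, gq)
        vc = res.vc
        gm = gq.subset_samples(design.sample_ids)
        p = gm.allele_freq()
        z = np.where(np.isnan(gm.dosages), 2 * p, gm.dosages) - 2 * p
        het = 2 * p * (1 - p)
        chroms = gm.snp_map["chrom"].astype(str).to_numpy()
        y, x = design.y, design.X
        n = y.size
        for j in range(0, gm.n_snps, 23):
            off = chroms != chroms[j]
            g_loco = (z[:, off] @ z[:, off].T) / (2 * het[off].sum())
            v = vc.sigma2_g * g_loco + vc.sigma2_e * np.eye(n)
            vinv = np.linalg.inv(v)
            xa = np.column_stack([x, z[:, j]])
            cov = np.linalg.inv(xa.T @ vinv @ xa)
            beta = cov @ xa.T @ vinv @ y
            alpha, se = beta[-1], np.sqrt(cov[-1, -1])
            row = res.table.iloc[j]
            assert row["alpha"] == pytest.approx(alpha, abs=1e-8)
            assert row["se_alpha"] == pytest.approx(se, abs=1e-8)
            assert row["p_value"] == pytest.approx(
                stats.chi2.sf((alpha / se) ** 2, 1), abs=1e-8
            )

    def test_loco_grm_ignores_own_chromosome(self, gwas_cohort):
        """A SNP's test is unchanged when every *other* SNP on its own
        chromosome is corrupted: G(-c) never includes chromosome c."""
        gq = gwas_cohort["gq"]
        design = gwas_cohort["design"]
        vc = gwas_cohort["result"].vc
        res = sf.mlma_loco(design, gq, vc=vc)
        chroms = gq.snp_map["chrom"].astype(str).to_numpy()
        on_t = np.flatnonzero(chroms == "2")
        target_snp, others = on_t[0], on_t[1:]
        swap = gq.dosages.copy()
        rng = np.random.default_rng(5)
        swap[:, others] = rng.permutation(swap[:, others], axis=0)
        gq2 = sf.GenotypeMatrix(gq.sample_ids, swap, gq.snp_map.copy())
        res2 = sf.mlma_loco(design, gq2, vc=vc)
        for col in ("alpha", "se_alpha", "p_value"):
            assert res2.table.loc[target_snp, col] == pytest.approx(
                res.table.loc[target_snp, col], rel=1e-10
            )
        # sanity: SNPs on other chromosomes do see the corruption via G(-c)
        off_t = chroms != "2"
        assert not np.allclose(
            res2.table.loc[off_t, "alpha"], res.table.loc[off_t, "alpha"]
        )

    def test_large_qtl_tops_the_scan(self):
        """A SNP explaining ~20% of variance attains the smallest p in at
        least 9 of 10 replicates."""
        wins = 0
        for seed in range(10):
            cfg = sf.SimulationConfig(
                n_individuals=200, n_genotyped=200, n_expression=10, n_snps=300,
                n_chromosomes=5, qc_spike=(0, 0, 0), gaussian_traits=True,
                seed=seed + 50,
            )
            ped = sf.simulate_pedigree(cfg)
            gm = sf.simulate_genotypes(ped, cfg)
            phen = sf.simulate_phenotypes(gm, ped, cfg)
            gq, _ = sf.apply_qc(gm)
            rng = np.random.default_rng(seed)
            j = int(rng.integers(gq.n_snps))
            s = gq.dosages[:, j]
            s = np.where(np.isnan(s), np.nanmean(s), s)
            y = phen["liver_fat"].to_numpy()
            beta = np.sqrt(0.20 * y.var() / s.var())
            phen = phen.copy()
            phen["liver_fat"] = y + beta * (s - s.mean())
            res = sf.mlma_loco(sf.build_design(phen, "liver_fat"), gq)
            if res.table["p_value"].idxmin() == j:
                wins += 1
        assert wins >= 9

    def test_unmapped_stratum_reported(self, gwas_cohort):
        gq = gwas_cohort["gq"]
        snp_map = gq.snp_map.copy()
        snp_map.loc[snp_map.index[:20], "chrom"] = "0"
        gm = sf.GenotypeMatrix(gq.sample_ids, gq.dosages, snp_map)
        res = sf.mlma_loco(gwas_cohort["design"], gm)
        tab = res.table
        assert (tab["stratum"] == "unmapped").sum() == 20
        assert tab.loc[tab["stratum"] == "unmapped", "p_value"].notna().all()

    def test_single_chromosome_panel_rejected(self, gwas_cohort):
        gq = gwas_cohort["gq"]
        snp_map = gq.snp_map.copy()
        snp_map["chrom"] = "1"
        gm = sf.GenotypeMatrix(gq.sample_ids, gq.dosages, snp_map)
        with pytest.raises(InvalidConfigError):
            sf.mlma_loco(gwas_cohort["design"], gm)

    def test_permuted_phenotype_lambda_near_one(self, gwas_cohort):
        rng = np.random.default_rng(1)
        phen = gwas_cohort["phen"].copy()
        phen["liver_fat"] = rng.permutation(phen["liver_fat"].to_numpy())
        design = sf.build_design(phen, "liver_fat", pcs=gwas_cohort["pcs"])
        res = sf.mlma_loco(design, gwas_cohort["gq"], grm_full=gwas_cohort["grm"])
        assert abs(res.lambda_ - 1.0) < 0.3


class TestCandidateGeneScan:
    def _toy_result(self, rows):
        tab = pd.DataFrame(
            rows, columns=["snp_id", "chrom", "pos", "p_value"]
        ).assign(freq=0.3, alpha=0.1, se_alpha=0.05, wald_chi2=1.0, stratum="mapped")
        th = sf.bonferroni_thresholds(len(tab), len(tab))
        return sf.GwasResult(table=tab, lambda_=1.0, thresholds=th, vc=None)

    def _toy_annotation(self):
        return sf.AnnotationIndex(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2", "g3"],
                    "name": ["inside", "other_chrom", "edge"],
                    "chrom": ["1", "2", "1"],
                    "start": [64_850_000, 64_850_000, 64_600_000],
                    "end": [64_900_000, 64_900_000, 64_800_000],
                }
            )
        )

    def test_window_containment_and_chromosome_match(self):
        res = self._toy_result([["snp1", "1", 65_000_000, 1e-8]])
        hits = sf.candidate_gene_scan(res, self._toy_annotation(), top_k=1)
        genes = set(hits["gene_id"].dropna())
        assert "g1" in genes  # inside the +/-200 kb window
        assert "g2" not in genes  # same coordinates, other chromosome
        assert "g3" in genes  # ends exactly at pos - 200,000: closed interval

    def test_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(8)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "name": [f"g{i}" for i in range(60)],
                "chrom": rng.choice(["1", "2"], 60),
                "start": rng.integers(1, 5_000_000, 60),
            }
        )
        genes["end"] = genes["start"] + rng.integers(1_000, 50_000, 60)
        ann = sf.AnnotationIndex(genes)
        snps = [
            [f"s{i}", str(rng.choice(["1", "2"])), int(rng.integers(1, 5_000_000)),
             float(rng.random())]
            for i in range(15)
        ]
        res = self._toy_result(snps)
        hits = sf.candidate_gene_scan(res, ann, top_k=10, window=200_000)
        top = res.table.sort_values(["p_value", "chrom", "pos", "snp_id"]).head(10)
        for _, snp in top.iterrows():
            expected = {
                g["gene_id"]
                for _, g in genes.iterrows()
                if g["chrom"] == snp["chrom"]
                and g["start"] <= snp["pos"] + 200_000
                and g["end"] >= max(1, snp["pos"] - 200_000)
            }
            got = set(
                hits.loc[hits["snp_id"] == snp["snp_id"], "gene_id"].dropna()
            )
            assert got == expected


class TestPlotExports:
    def test_single_snp_expected_quantile(self):
        res = TestCandidateGeneScan()._toy_result([["s1", "1", 100, 0.2]])
        _, qq = sf.export_plots_data(res)
        assert qq["expected_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_observed_column_is_sorted_input(self, gwas_cohort):
        _, qq = sf.export_plots_data(gwas_cohort["result"])
        obs = qq["observed_neglog10_p"].to_numpy()
        raw = -np.log10(gwas_cohort["result"].table["p_value"].dropna().to_numpy())
        np.testing.assert_allclose(obs, np.sort(raw)[::-1])

    def test_uniform_p_qq_slope_near_one(self):
        rng = np.random.default_rng(4)
        m = 5000
        tab = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1),
                "p_value": rng.random(m),
                "stratum": "mapped",
            }
        )
        res = sf.GwasResult(tab, 1.0, sf.bonferroni_thresholds(m, m), None)
        _, qq = sf.export_plots_data(res)
        x = qq["expected_neglog10_p"].to_numpy()
        y = qq["observed_neglog10_p"].to_numpy()
        slope = (x @ y) / (x @ x)
        assert abs(slope - 1.0) < 0.1

    def test_manhattan_offsets_monotone_within_chromosome(self, gwas_cohort):
        man, _ = sf.export_plots_data(gwas_cohort["result"])
        for _, sub in man.groupby("chrom"):
            assert sub.sort_values("pos")["cumulative_pos"].is_monotonic_increasing
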