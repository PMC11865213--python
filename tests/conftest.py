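import numpy as np
import pytest

import salmofat as sf


@pytest.fixture(scope="session")
def small_cfg():
    """A down-scaled cohort that keeps every structural feature of the
    default configuration (families, QC spikes, expression subset)."""
    return sf.SimulationConfig(
        n_individuals=200,
        n_genotyped=200,
        n_expression=40,
        n_snps=600,
        n_chromosomes=5,
        n_genes=300,
        qc_spike=(10, 10, 10),
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(small_cfg):
    ped = sf.simulate_pedigree(small_cfg)
    gm = sf.simulate_genotypes(ped, small_cfg)
    phen = sf.simulate_phenotypes(gm, ped, small_cfg)
    gq, report = sf.apply_qc(gm)
    grm = sf.compute_grm(gq)
    pcs = sf.grm_pca(grm, 2)
    return {
        "cfg": small_cfg,
        "ped": ped,
        "gm": gm,
        "phen": phen,
        "gq": gq,
        "report": report,
        "grm": grm,
        "pcs": pcs,
    }


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the default calibration (n=634, 5,000 SNPs)."""
    cfg = sf.SimulationConfig(seed=3)
    ped = sf.simulate_pedigree(cfg)
    gm = sf.simulate_genotypes(ped, cfg)
    phen = sf.simulate_phenotypes(gm, ped, cfg)
    return {"cfg": cfg, "ped": ped, "gm": gm, "phen": phen}


@pytest.fixture(scope="session")
def unrelated_genotypes():
    """500 unrelated individuals in Hardy-Weinberg proportions, 2,000 SNPs."""
    import pandas as pd

    rng = np.random.default_rng(77)
    n, m = 500, 2000
    p = rng.uniform(0.1, 0.5, m)
    dos = rng.binomial(2, p[None, :], (n, m)).astype(float)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"u{j}" for j in range(m)],
            "chrom": np.repeat(np.arange(1, 11), m // 10).astype(str),
            "pos": np.tile(np.arange(1, m // 10 + 1) * 1000, 10),
            "a1": "A",
            "a2": "B",
        }
    )
    ids = np.array([f"ind{k}" for k in range(n)], object)
    return sf.GenotypeMatrix(ids, dos, snp_map)
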