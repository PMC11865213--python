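"""Synthetic cohort generator.

Emulates the study population the downstream analyses assume: a pedigreed
batch of full-sib salmon families, array genotypes propagated from founders
by Mendelian gene dropping, multi-trait polygenic phenotypes with the
published variance components and genetic correlations, a trait-coupled
liver transcriptome for the RNA-seq subset, compositional liver fatty-acid
panels, and gene annotation with term maps carrying built-in enrichment.

The additive architecture is infinitesimal: every clean SNP is causal with
i.i.d. normal effects on the allele-count scale, scaled so the additive
covariance equals sigma2_g times the VanRaden relationship matrix — exactly
the model GREML fits downstream. Trait truth (the realised additive values)
is written into the phenotype table as ``u_<trait>`` columns so recovery
tests can compare estimates against generative truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import roots_hermitenorm

from .annotation import AnnotationIndex
from .config import SimulationConfig
from .errors import InvalidConfigError
from .expression import ExpressionMatrix
from .genotypes import GenotypeMatrix

SPIKE_NONE, SPIKE_CALL_RATE, SPIKE_MAF, SPIKE_HWE = "", "call_rate", "maf", "hwe"


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Offspring of n_sires x n_dams matings.

    Each dam is mated to one sire (sires cycle when outnumbered), giving
    n_dams full-sib families; offspring are spread evenly over families.
    Exactly ``n_genotyped`` fish are flagged genotyped and ``n_expression``
    of those flagged for RNA-seq.
    """
    if config.n_expression > config.n_individuals:
        raise InvalidConfigError("n_expression must not exceed n_individuals")
    rng = config.rng("pedigree")
    n = config.n_individuals
    sire_of_dam = np.arange(config.n_dams) % config.n_sires
    fam = rng.permutation(np.arange(n) % config.n_dams)
    sex = np.where(rng.random(n) < config.sex_fraction_male, "M", "F")
    genotyped = np.zeros(n, bool)
    genotyped[rng.choice(n, config.n_genotyped, replace=False)] = True
    expression = np.zeros(n, bool)
    geno_idx = np.flatnonzero(genotyped)
    expression[rng.choice(geno_idx, config.n_expression, replace=False)] = True
    return pd.DataFrame(
        {
            "individual_id": [f"F{i + 1:05d}" for i in range(n)],
            "sire_id": [f"S{sire_of_dam[d] + 1:03d}" for d in fam],
            "dam_id": [f"D{d + 1:03d}" for d in fam],
            "family_id": [f"FAM{d + 1:03d}" for d in fam],
            "sex": sex,
            "genotyped": genotyped,
            "expression": expression,
        }
    )


# ---------------------------------------------------------------------------
# genotypes


def _transmit(parent_dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry: homozygotes transmit deterministically,
    heterozygotes a fair coin."""
    het = parent_dosages == 1
    allele = (parent_dosages == 2).astype(float)
    allele[het] = rng.integers(0, 2, het.sum())
    return allele


def simulate_genotypes(
    pedigree: pd.DataFrame, config: SimulationConfig
) -> GenotypeMatrix:
    """Gene-dropped SNP dosages for every pedigree offspring.

    Founder dosages are Hardy-Weinberg draws at per-SNP frequencies from
    ``maf_range``; offspring receive one allele from each parent. The
    configured numbers of QC-violating SNPs (low call rate, rare, and
    heterozygote-depleted) are injected and labelled in the SNP map's
    ``qc_spike`` column; clean SNPs are fully called.
    """
    lo, hi = config.maf_range
    if lo > hi:
        raise InvalidConfigError("empty maf_range")
    rng = config.rng("genotypes")
    m = config.n_snps
    n = len(pedigree)

    p = rng.uniform(lo, hi, m)
    sires = sorted(pedigree["sire_id"].unique())
    dams = sorted(pedigree["dam_id"].unique())
    founder_ids = np.array(sires + dams, dtype=object)
    founder_dosages = rng.binomial(2, p[None, :], (len(founder_ids), m)).astype(float)
    founder_row = {fid: i for i, fid in enumerate(founder_ids)}
    si = np.array([founder_row[s] for s in pedigree["sire_id"]])
    di = np.array([founder_row[d] for d in pedigree["dam_id"]])
    dosages = _transmit(founder_dosages[si], rng) + _transmit(founder_dosages[di], rng)

    spike = np.full(m, SPIKE_NONE, object)
    n_cr, n_maf, n_hwe = config.qc_spike
    order = rng.permutation(m)
    cr_idx = order[:n_cr]
    maf_idx = order[n_cr : n_cr + n_maf]
    hwe_idx = order[n_cr + n_maf : n_cr + n_maf + n_hwe]
    spike[cr_idx], spike[maf_idx], spike[hwe_idx] = (
        SPIKE_CALL_RATE,
        SPIKE_MAF,
        SPIKE_HWE,
    )
    # call-rate violation: 12% of calls missing (call rate 0.88 <= 0.9)
    n_missing = int(np.ceil(0.12 * n))
    for j in cr_idx:
        dosages[rng.choice(n, n_missing, replace=False), j] = np.nan
    # MAF violation: a handful of heterozygote carriers only
    n_carriers = max(1, round(0.01 * n))
    for j in maf_idx:
        dosages[:, j] = 0.0
        dosages[rng.choice(n, n_carriers, replace=False), j] = 1.0
    # HWE violation: common SNP with no heterozygotes (chi2 ~ n)
    for j in hwe_idx:
        dosages[:, j] = 2.0 * rng.integers(0, 2, n)

    snps_per_chr = np.full(config.n_chromosomes, m // config.n_chromosomes)
    snps_per_chr[: m % config.n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), snps_per_chr)
    def draw_positions(k):
        pos = np.unique(rng.integers(1, config.chromosome_length, k))
        while pos.size < k:  # top up after dedup (collisions are rare)
            extra = rng.integers(1, config.chromosome_length, k - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        return np.sort(pos)

    pos = np.concatenate([draw_positions(k) for k in snps_per_chr])
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"SNP{i + 1:06d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "a1": "A",
            "a2": "B",
            "qc_spike": spike,
        }
    )
    return GenotypeMatrix(
        pedigree["individual_id"].to_numpy(object),
        dosages,
        snp_map,
        founder_ids=founder_ids,
        founder_dosages=founder_dosages,
    )


# ---------------------------------------------------------------------------
# phenotypes


def _soft_floor(x: np.ndarray, floor: float, softness: float) -> np.ndarray:
    """Smooth rectification: ~identity far above the floor, asymptotes to
    the floor below it, producing the observed right-skew with a minimum
    near the floor."""
    z = (x - floor) / softness
    return floor + softness * np.logaddexp(0.0, z)


def _solve_floor_latent_mean(
    target_mean: float, sd: float, floor: float, softness: float
) -> float:
    """Latent mean mu0 such that E[soft_floor(N(mu0, sd^2))] = target_mean
    (Gauss-Hermite quadrature + root bracketing)."""
    nodes, weights = roots_hermitenorm(80)
    weights = weights / weights.sum()

    def expected(mu):
        return np.sum(weights * _soft_floor(mu + sd * nodes, floor, softness))

    return optimize.brentq(
        lambda mu: expected(mu) - target_mean, floor - 10 * sd, target_mean + 10 * sd
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix, pedigree: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Multi-trait polygenic phenotypes for every pedigree individual.

    Additive values come from i.i.d. normal effects on all clean
    polymorphic SNPs (allele-count scale, VanRaden-consistent), with
    cross-trait covariance set by the configured genetic correlation
    matrix; residuals are multivariate normal; a centred sex effect is
    added. Unless ``gaussian_traits`` is
    set, liver fat is passed through the soft 4 %-floor rectification,
    scores are discretised to 1..5, and the hepatosomatic index is
    re-derived from simulated liver and body weights.
    """
    ids = pedigree["individual_id"].to_numpy(object)
    missing = set(ids) - set(genotypes.sample_ids)
    if missing:
        raise InvalidConfigError("genotypes must cover all pedigree individuals")
    rng = config.rng("phenotypes")
    traits = config.traits
    names = config.trait_names
    t = len(names)
    rg = config.genetic_correlation_matrix()
    if np.linalg.eigvalsh(rg).min() < -1e-8:
        raise InvalidConfigError("genetic correlation matrix not positive semidefinite")
    re = config.residual_correlation_matrix()
    sg = np.array([np.sqrt(traits[k].var_g) for k in names])
    se = np.array([np.sqrt(traits[k].var_e) for k in names])
    cg = rg * np.outer(sg, sg)
    ce = re * np.outer(se, se)

    gm = genotypes.subset_samples(ids) if list(genotypes.sample_ids) != list(ids) else genotypes
    clean = (
        gm.snp_map["qc_spike"].to_numpy() == SPIKE_NONE
        if "qc_spike" in gm.snp_map
        else np.ones(gm.n_snps, bool)
    )
    dos = gm.dosages[:, clean]
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    dos = np.where(np.isnan(dos), 2 * p, dos)[:, poly]
    p = p[poly]
    zc = dos - 2 * p  # centred allele counts
    m_causal = zc.shape[1]

    def chol_psd(a):
        w, v = np.linalg.eigh(a)
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))

    # i.i.d. per-SNP effects on the allele-count scale, scaled so that
    # Cov(u) = G_VanRaden * Cg exactly — the infinitesimal architecture the
    # GREML model assumes (mean diagonal of G is ~1, so realised additive
    # variance matches sigma2_g)
    denom = np.sqrt(2.0 * np.sum(p * (1 - p)))
    effects = rng.standard_normal((m_causal, t)) @ chol_psd(cg).T / denom
    u = zc @ effects
    eps = rng.standard_normal((len(ids), t)) @ chol_psd(ce).T
    male = (pedigree["sex"].to_numpy() == "M").astype(float)
    sex_shift = np.column_stack(
        [traits[k].sex_effect * (male - config.sex_fraction_male) for k in names]
    )
    latent = (
        np.array([traits[k].mean for k in names])[None, :] + u + eps + sex_shift
    )

    out = pedigree.copy()
    for j, k in enumerate(names):
        out[f"u_{k}"] = u[:, j]
    if config.gaussian_traits:
        for j, k in enumerate(names):
            out[k] = latent[:, j]
        return out

    for j, k in enumerate(names):
        spec = traits[k]
        x = latent[:, j]
        if spec.kind == "floored":
            sd = np.sqrt(spec.var_g + spec.var_e)
            mu0 = _solve_floor_latent_mean(
                spec.mean, sd, config.liver_fat_floor, config.floor_softness
            )
            out[k] = _soft_floor(
                x - spec.mean + mu0, config.liver_fat_floor, config.floor_softness
            )
        elif spec.kind == "score":
            out[k] = np.clip(np.rint(x), 1, 5).astype(int)
        else:
            out[k] = x
    if "liver_score" in out:
        # stored score is fattier-is-higher; the raw field scale is reversed
        out["liver_score_raw"] = 6 - out["liver_score"]
    if {"hsi", "body_weight"} <= set(out.columns):
        out["hsi"] = np.clip(out["hsi"], 0.05, None)
        out["body_weight"] = np.clip(out["body_weight"], 0.3, None)
        out["liver_weight_g"] = out["hsi"] / 100.0 * out["body_weight"] * 1000.0
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    phenotypes: pd.DataFrame, config: SimulationConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Trait-coupled fragment counts for the RNA-seq subset.

    Per-gene log2 abundance is log-normal; for the configured fraction of
    genes it is linearly coupled to liver fat with a coefficient drawn at
    ``assoc_effect_sd`` (log2 units per % liver fat). Sex and full-sib
    family intercepts are added, then counts are Poisson draws at the
    implied FPKM given gene length and library size, so FPKM can be
    recomputed downstream. Returns the matrix and the truth labels.
    """
    if not (0.0 <= config.assoc_gene_fraction <= 1.0):
        raise InvalidConfigError("assoc_gene_fraction must lie in [0, 1]")
    sub = phenotypes[phenotypes["expression"]]
    if sub.empty:
        raise InvalidConfigError("no expression-flagged individuals")
    rng = config.rng("expression")
    n_s, n_g = len(sub), config.n_genes
    fat = sub["liver_fat"].to_numpy(float)
    fat_c = fat - fat.mean()
    male = (sub["sex"].to_numpy() == "M").astype(float)
    fam_codes, _ = pd.factorize(sub["family_id"].to_numpy())

    lengths = rng.integers(400, 8000, n_g).astype(float)
    mu = rng.normal(4.0, 1.5, n_g)
    n_assoc = round(config.assoc_gene_fraction * n_g)
    assoc = np.zeros(n_g, bool)
    assoc[rng.choice(n_g, n_assoc, replace=False)] = True
    coef = np.zeros(n_g)
    coef[assoc] = rng.normal(0.0, config.assoc_effect_sd, n_assoc)
    sex_eff = rng.normal(0.0, config.expr_sex_effect_sd, n_g)
    fam_eff = rng.normal(
        0.0, np.sqrt(config.family_variance_expr), (n_g, fam_codes.max() + 1)
    )

    log2e = (
        mu[:, None]
        + coef[:, None] * fat_c[None, :]
        + sex_eff[:, None] * (male - male.mean())[None, :]
        + fam_eff[:, fam_codes]
        + rng.normal(0.0, config.expr_noise_sd, (n_g, n_s))
    )
    fpkm_true = np.clip(2.0**log2e - 1.0, 0.0, None)
    lib = rng.normal(2e6, 2e5, n_s).clip(5e5)
    expected = fpkm_true * lengths[:, None] / 1e3 * lib[None, :] / 1e6
    counts = rng.poisson(expected).astype(np.int64)
    if config.n_zero_genes:
        zero_idx = rng.choice(n_g, min(config.n_zero_genes, n_g), replace=False)
        counts[zero_idx] = 0
        assoc[zero_idx] = False
        coef[zero_idx] = 0.0

    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_g)]
    em = ExpressionMatrix(
        counts=pd.DataFrame(
            counts, index=gene_ids, columns=sub["individual_id"].to_numpy(object)
        ),
        lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "associated": assoc, "coef": coef}
    )
    return em, truth


# ---------------------------------------------------------------------------
# fatty acids


def simulate_fatty_acids(
    phenotypes: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Compositional liver fatty-acid panel for the analysed subset.

    Each named acid is drawn at its configured mean/SD with the configured
    sign of correlation to liver fat; the row is closed to exactly 100 %
    through an ``other`` pool.
    """
    if "liver_fat" not in phenotypes:
        raise InvalidConfigError("phenotypes must contain liver_fat")
    if sum(m for m, _ in config.fatty_acid_means_sds.values()) > 100.0:
        raise InvalidConfigError("fatty-acid means exceed 100% in total")
    sub = phenotypes[phenotypes["expression"]] if phenotypes["expression"].any() else phenotypes
    rng = config.rng("fatty_acids")
    n = len(sub)
    fat = sub["liver_fat"].to_numpy(float)
    z = (fat - fat.mean()) / (fat.std(ddof=0) or 1.0)
    rho = config.fa_coupling
    table = {"individual_id": sub["individual_id"].to_numpy(object)}
    for name, (mean, sd) in config.fatty_acid_means_sds.items():
        sign = config.fa_sign_map.get(name, 0)
        if sign == 0:
            x = mean + sd * rng.standard_normal(n)
        else:
            x = mean + sd * (
                sign * rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            )
        table[name] = np.clip(x, 0.01, None)
    df = pd.DataFrame(table)
    named = df.drop(columns="individual_id")
    total = named.sum(axis=1).to_numpy()
    over = total > 99.5
    if over.any():
        named.loc[over] = named.loc[over].mul(99.5 / total[over], axis=0)
        total = named.sum(axis=1).to_numpy()
        df[named.columns] = named
    df["other"] = 100.0 - total
    return df


# ---------------------------------------------------------------------------
# annotation and terms


def simulate_annotation_and_terms(
    config: SimulationConfig, truth: pd.DataFrame | None = None
) -> tuple[AnnotationIndex, pd.DataFrame]:
    """Non-overlapping gene intervals per chromosome plus a gene-to-term map.

    When expression truth labels are supplied, ``n_enriched_terms`` terms
    are loaded with trait-associated genes so downstream enrichment has
    positives by construction.
    """
    if config.n_chromosomes < 1:
        raise InvalidConfigError("n_chromosomes must be >= 1")
    rng = config.rng("annotation")
    n_g = config.n_genes
    gene_ids = (
        truth["gene_id"].to_numpy(object)
        if truth is not None
        else np.array([f"GENE{i + 1:05d}" for i in range(n_g)], object)
    )
    n_g = len(gene_ids)
    chrom = (np.arange(n_g) % config.n_chromosomes) + 1
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        members = np.flatnonzero(chrom == c)
        cursor = 1
        for i in members:
            gap = int(rng.integers(5_000, 200_000))
            length = int(rng.integers(2_000, 20_000))
            start = cursor + gap
            rows.append((gene_ids[i], f"gene_{gene_ids[i]}", str(c), start, start + length))
            cursor = start + length
    ann = AnnotationIndex(
        pd.DataFrame(rows, columns=["gene_id", "name", "chrom", "start", "end"])
    )

    assoc_genes = (
        truth.loc[truth["associated"], "gene_id"].to_numpy(object)
        if truth is not None
        else np.array([], object)
    )
    pairs = []
    for k in range(config.n_terms):
        term = f"TERM{k + 1:04d}"
        size = int(rng.integers(3, 60))
        if k < config.n_enriched_terms and len(assoc_genes) >= 5:
            size = max(size, 12)
            n_from_assoc = int(np.ceil(0.8 * size))
            chosen = list(
                rng.choice(assoc_genes, min(n_from_assoc, len(assoc_genes)), replace=False)
            )
            rest = rng.choice(gene_ids, size - len(chosen), replace=False)
            chosen.extend(rest)
        else:
            chosen = rng.choice(gene_ids, size, replace=False)
        pairs.extend((g, term) for g in dict.fromkeys(chosen))
    term_map = pd.DataFrame(pairs, columns=["gene_id", "term_id"])
    return ann, term_map
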