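"""Mixed-linear-model association with leave-one-chromosome-out GRMs.

Each SNP is tested under y = mu + Xb + S alpha + u + e, where the polygenic
term uses a GRM built from every chromosome except the SNP's own (LOCO),
avoiding proximal contamination. Variance components are estimated once
genome-wide and reused for every LOCO chromosome (re-estimation per
chromosome is available behind a flag). The per-SNP allele-substitution
effect and its standard error come from generalised least squares under
V(-c); p-values are 1-df Wald chi-square. SNPs without genome placement are
tested against the full-genome GRM and reported as a separate stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .annotation import AnnotationIndex, manhattan_offsets
from .errors import InvalidConfigError, UndefinedStatisticError
from .genotypes import GenotypeMatrix
from .grm import GRMatrix, compute_grm
from .reml import ModelDesign, REMLOptions, VarianceComponents, fit_greml_univariate

#: null median of a 1-df chi-square, as conventionally printed
LAMBDA_NULL_MEDIAN = 0.455

UNMAPPED_LABELS = ("0", "Un", "un", "unknown", "NA")


@dataclass
class GwasThresholds:
    genome_wide_p: float | None
    chromosome_wide_p: float | None
    genome_wide_neglog10: float | None
    chromosome_wide_neglog10: float | None
    alpha: float
    n_tests_genome: int | None
    n_tests_chromosome: int | None


def bonferroni_thresholds(
    n_snps_total: int | None = None,
    avg_snps_per_chr: int | None = None,
    alpha: float = 0.05,
) -> GwasThresholds:
    """Genome-wide (alpha / total SNPs) and chromosome-wide (alpha / average
    SNPs per chromosome) Bonferroni cutoffs with their -log10 equivalents."""
    for name, n in [("n_snps_total", n_snps_total), ("avg_snps_per_chr", avg_snps_per_chr)]:
        if n is not None and n < 1:
            raise InvalidConfigError(f"{name} must be >= 1")
    pg = alpha / n_snps_total if n_snps_total else None
    pc = alpha / avg_snps_per_chr if avg_snps_per_chr else None
    return GwasThresholds(
        genome_wide_p=pg,
        chromosome_wide_p=pc,
        genome_wide_neglog10=-np.log10(pg) if pg else None,
        chromosome_wide_neglog10=-np.log10(pc) if pc else None,
        alpha=alpha,
        n_tests_genome=n_snps_total,
        n_tests_chromosome=avg_snps_per_chr,
    )


def inflation_factor(
    chi2_values: np.ndarray | None = None, p_values: np.ndarray | None = None
) -> float:
    """Genomic inflation factor lambda = median(chi2) / 0.455."""
    if chi2_values is None:
        if p_values is None:
            raise UndefinedStatisticError("provide chi2_values or p_values")
        chi2_values = stats.chi2.isf(np.asarray(p_values, float), df=1)
    chi2_values = np.asarray(chi2_values, float)
    if chi2_values.size == 0:
        raise UndefinedStatisticError("empty chi-square vector")
    return float(np.median(chi2_values) / LAMBDA_NULL_MEDIAN)


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp_id, chrom, pos, freq, alpha, se_alpha, wald_chi2, p_value, stratum
    lambda_: float
    thresholds: GwasThresholds
    vc: VarianceComponents


def _gls_scan(s_cols: np.ndarray, py: np.ndarray, p_mat: np.ndarray):
    """alpha, SE, chi2, p for each column of S under a fixed projection P."""
    ps = p_mat @ s_cols
    sps = np.einsum("ij,ij->j", s_cols, ps)
    spy = s_cols.T @ py
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = spy / sps
        se = 1.0 / np.sqrt(sps)
        chi2 = spy**2 / sps
    p = stats.chi2.sf(chi2, df=1)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return alpha, se, chi2, p


def _projection(v: np.ndarray, x: np.ndarray, y: np.ndarray):
    """P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv and Py, via Cholesky."""
    c = cho_factor(v)
    vinv_x = cho_solve(c, x)
    vinv_y = cho_solve(c, y)
    xtvx = x.T @ vinv_x
    beta_part = np.linalg.solve(xtvx, vinv_x.T)
    py = vinv_y - vinv_x @ (beta_part @ y)
    vinv = cho_solve(c, np.eye(v.shape[0]))
    p_mat = vinv - vinv_x @ beta_part
    return p_mat, py


def mlma_loco(
    design: ModelDesign,
    genotypes: GenotypeMatrix,
    grm_full: GRMatrix | None = None,
    vc: VarianceComponents | None = None,
    per_chromosome_vc: bool = False,
    alpha_level: float = 0.05,
    unmapped_labels: tuple[str, ...] = UNMAPPED_LABELS,
    reml_options: REMLOptions = REMLOptions(),
) -> GwasResult:
    """Leave-one-chromosome-out mixed-model association scan.

    ``design`` should carry the intercept, sex and the two GRM principal
    components as fixed covariates. ``grm_full`` / ``vc`` can be supplied to
    reuse an existing full-genome GRM and variance-component fit; both are
    recomputed from the genotypes otherwise.
    """
    gm = genotypes.subset_samples(design.sample_ids)
    chrom = gm.snp_map["chrom"].astype(str).to_numpy()
    mapped = ~np.isin(chrom, unmapped_labels)
    mapped_chroms = pd.unique(chrom[mapped])
    if len(mapped_chroms) < 2 and mapped.any():
        raise InvalidConfigError(
            "LOCO needs SNPs on at least two chromosomes; a single chromosome "
            "would leave G(-c) empty"
        )

    p_freq = gm.allele_freq()
    dos = np.where(np.isnan(gm.dosages), 2 * p_freq, gm.dosages)
    z = dos - 2 * p_freq
    het = 2 * p_freq * (1 - p_freq)
    zz_full = z @ z.T
    denom_full = het.sum()
    if grm_full is None:
        grm_full = GRMatrix(gm.sample_ids.copy(), zz_full / (2 * denom_full), gm.n_snps)
    else:
        grm_full = grm_full.subset(design.sample_ids)
    if vc is None:
        vc = fit_greml_univariate(design, grm_full, reml_options)

    y = np.asarray(design.y, float)
    x = design.X
    n = y.size
    out = {
        k: np.full(gm.n_snps, np.nan)
        for k in ("alpha", "se_alpha", "wald_chi2", "p_value")
    }
    stratum = np.where(mapped, "mapped", "unmapped")

    for c in mapped_chroms:
        on_c = chrom == c
        if on_c.all():
            raise InvalidConfigError(f"all SNPs are on chromosome {c}; G(-c) is empty")
        zc = z[:, on_c]
        g_loco = (zz_full - zc @ zc.T) / (2 * (denom_full - het[on_c].sum()))
        if per_chromosome_vc:
            vc_c = fit_greml_univariate(
                design, GRMatrix(gm.sample_ids, (g_loco + g_loco.T) / 2, int((~on_c).sum())),
                reml_options,
            )
        else:
            vc_c = vc
        v = vc_c.sigma2_g * g_loco + vc_c.sigma2_e * np.eye(n)
        p_mat, py = _projection(v, x, y)
        a, se, chi2, pv = _gls_scan(z[:, on_c], py, p_mat)
        for key, val in zip(("alpha", "se_alpha", "wald_chi2", "p_value"), (a, se, chi2, pv)):
            out[key][on_c] = val

    if (~mapped).any():
        v = vc.sigma2_g * grm_full.values + vc.sigma2_e * np.eye(n)
        p_mat, py = _projection(v, x, y)
        a, se, chi2, pv = _gls_scan(z[:, ~mapped], py, p_mat)
        for key, val in zip(("alpha", "se_alpha", "wald_chi2", "p_value"), (a, se, chi2, pv)):
            out[key][~mapped] = val

    table = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "chrom": chrom,
            "pos": gm.snp_map["pos"].to_numpy(),
            "freq": p_freq,
            "alpha": out["alpha"],
            "se_alpha": out["se_alpha"],
            "wald_chi2": out["wald_chi2"],
            "p_value": out["p_value"],
            "stratum": stratum,
        }
    )
    lam = inflation_factor(table["wald_chi2"].to_numpy())
    n_per_chr = (
        int(round(mapped.sum() / len(mapped_chroms))) if len(mapped_chroms) else None
    )
    thresholds = bonferroni_thresholds(gm.n_snps, n_per_chr, alpha_level)
    return GwasResult(table=table, lambda_=lam, thresholds=thresholds, vc=vc)


def candidate_gene_scan(
    result: GwasResult,
    annotation: AnnotationIndex,
    top_k: int = 10,
    window: int = 200_000,
) -> pd.DataFrame:
    """Genes within +/- ``window`` bp of the ``top_k`` most significant SNPs.

    SNPs are ranked by ascending p (ties by chromosome, then position, then
    id); the search interval is closed on both ends and clipped at 1. The
    gene list may be empty for a SNP.
    """
    tab = result.table.dropna(subset=["p_value"])
    if tab.empty:
        raise InvalidConfigError("empty GWAS result")
    top = tab.sort_values(
        ["p_value", "chrom", "pos", "snp_id"], kind="mergesort"
    ).head(top_k)
    rows = []
    for _, snp in top.iterrows():
        lo = max(1, int(snp["pos"]) - window)
        hi = int(snp["pos"]) + window
        hits = annotation.query(snp["chrom"], lo, hi)
        if hits.empty:
            rows.append(
                {"snp_id": snp["snp_id"], "chrom": snp["chrom"], "pos": snp["pos"],
                 "p_value": snp["p_value"], "gene_id": None, "gene_name": None,
                 "gene_start": None, "gene_end": None}
            )
        for _, g in hits.iterrows():
            rows.append(
                {"snp_id": snp["snp_id"], "chrom": snp["chrom"], "pos": snp["pos"],
                 "p_value": snp["p_value"], "gene_id": g["gene_id"],
                 "gene_name": g["name"], "gene_start": g["start"], "gene_end": g["end"]}
            )
    return pd.DataFrame(rows)


def export_plots_data(result: GwasResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan table (cumulative position, -log10 p) and QQ table
    (expected vs observed -log10 p, expected quantile -log10((i-0.5)/m))."""
    tab = result.table.dropna(subset=["p_value"]).copy()
    if tab.empty:
        raise InvalidConfigError("empty GWAS result")
    tab["neglog10_p"] = -np.log10(tab["p_value"])
    tab["cumulative_pos"] = manhattan_offsets(tab["chrom"], tab["pos"])
    manhattan = tab[
        ["snp_id", "chrom", "pos", "cumulative_pos", "neglog10_p", "stratum"]
    ].reset_index(drop=True)
    obs = np.sort(tab["neglog10_p"].to_numpy())[::-1]
    m = obs.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected_neglog10_p": expected, "observed_neglog10_p": obs})
    return manhattan, qq
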