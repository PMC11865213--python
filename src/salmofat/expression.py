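"""Expression normalisation and the per-gene trait~expression mixed model.

Counts are normalised with median-of-geometric-means size factors, scaled to
FPKM (fragments per kilobase per million mapped fragments) and log2
transformed with a pseudocount of 1. Each retained gene is then tested with

    trait_i = b0 + b1 * expr_i + sex_i + family_p(i) + eps_i

where the full-sib family enters as a random intercept whose variance is
estimated by restricted likelihood, profiling the family-to-residual
variance ratio. When that ratio is estimated at zero the fit reduces
exactly to ordinary least squares, which is the common outcome with 48
fish spread over nearly as many families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, DegenerateGeneError, InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x sample fragment counts with gene lengths and derived layers."""

    counts: pd.DataFrame  # genes x samples, integer fragment counts
    lengths: pd.Series  # bp per gene
    size_factors: pd.Series | None = None
    fpkm: pd.DataFrame | None = None
    log2_fpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise AlignmentError("every gene needs a length")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("fragment counts must be >= 0")
        if (self.lengths < 1).any():
            raise InvalidConfigError("gene lengths must be >= 1 bp")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.counts.columns.to_numpy(object)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy(object)


def normalize_expression(
    counts: pd.DataFrame, lengths: pd.Series, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Size factors, FPKM and log2(FPKM + pseudocount).

    Size factor of sample j = median over reference genes (genes with
    positive counts in every sample) of count / geometric mean across
    samples. The normalised library size of sample j is
    ``sf_j * median_k(library_k / sf_k)``, so FPKM is invariant to
    depth-only differences between samples.
    """
    c = counts.to_numpy(float)
    lib = c.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise InvalidConfigError(f"samples with zero total counts: {bad}")
    ref = (c > 0).all(axis=1)
    if not ref.any():
        raise InvalidConfigError(
            "no reference genes: every gene has a zero count in some sample"
        )
    log_geo = np.log(c[ref]).mean(axis=1)
    sf = np.exp(np.median(np.log(c[ref]) - log_geo[:, None], axis=0))
    norm_lib = sf * np.median(lib / sf)
    fpkm = c * 1e9 / (lengths.to_numpy(float)[:, None] * norm_lib[None, :])
    em = ExpressionMatrix(
        counts=counts,
        lengths=lengths,
        size_factors=pd.Series(sf, index=counts.columns, name="size_factor"),
        fpkm=pd.DataFrame(fpkm, index=counts.index, columns=counts.columns),
    )
    em.log2_fpkm = np.log2(em.fpkm + pseudocount)
    return em


def filter_genes(em: ExpressionMatrix, min_expressed_fraction: float = 0.5) -> np.ndarray:
    """Boolean retention mask: expressed (FPKM > 0) in at least the given
    fraction of samples. The published pipeline dropped genes at an
    unspecified QC step; this filter is the configurable analogue."""
    if em.fpkm is None:
        raise InvalidConfigError("normalize_expression first")
    return (em.fpkm.to_numpy() > 0).mean(axis=1) >= min_expressed_fraction


@dataclass
class GeneAssociationRecord:
    gene_id: str
    beta1: float
    se_beta1: float
    p_value: float
    significant: bool
    gamma: float  # estimated family-to-residual variance ratio
    sigma2_e: float
    sigma2_family: float
    n: int


def _profile_reml_gamma(yt, Xt, lam, gamma):
    """Restricted log-likelihood of the family-ratio parameter (profiled
    over fixed effects and the residual variance), in the rotated basis."""
    n, p = Xt.shape
    v = 1.0 + gamma * lam
    Xv = Xt / v[:, None]
    W = Xt.T @ Xv
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        return -np.inf, None, None, None
    b = Xv.T @ yt
    beta = np.linalg.solve(W, b)
    ypy = yt @ (yt / v) - b @ beta
    if ypy <= 0:
        return -np.inf, None, None, None
    sigma2_e = ypy / (n - p)
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + np.log(v).sum() + logdet_w)
    return ll, beta, sigma2_e, W


def fit_gene_trait_lmm(
    trait: np.ndarray,
    expr: np.ndarray,
    sex: np.ndarray,
    family: np.ndarray,
    gene_id: str = "gene",
    alpha: float = 0.05,
    family_variance_ratio: float | None = None,
    use_t: bool = False,
    _rotation=None,
) -> GeneAssociationRecord:
    """Fit the trait ~ expression model for a single gene.

    ``family_variance_ratio`` fixes sigma2_family / sigma2_e instead of
    estimating it (0 forces the exact OLS limit). ``use_t`` swaps the Wald
    normal reference for a t with residual degrees of freedom, which some
    users prefer at n = 48.
    """
    trait = np.asarray(trait, float)
    expr = np.asarray(expr, float)
    if np.unique(expr).size < 3:
        raise DegenerateGeneError(
            f"{gene_id}: needs >= 3 distinct expression values"
        )
    if np.ptp(trait) == 0:
        raise DegenerateGeneError(f"{gene_id}: trait is constant")
    n = trait.size
    male = np.asarray(
        [1.0 if str(s).upper().startswith("M") else 0.0 for s in sex]
    )
    X = np.column_stack([np.ones(n), expr, male])

    if _rotation is None:
        fam_codes, _ = pd.factorize(np.asarray(family))
        Z = np.zeros((n, fam_codes.max() + 1))
        Z[np.arange(n), fam_codes] = 1.0
        lam, U = np.linalg.eigh(Z @ Z.T)
    else:
        lam, U = _rotation
    yt = U.T @ trait
    Xt = U.T @ X

    if family_variance_ratio is not None:
        gamma = float(family_variance_ratio)
        ll, beta, sigma2_e, W = _profile_reml_gamma(yt, Xt, lam, gamma)
    else:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 100.0, 25)])
        lls = np.array([_profile_reml_gamma(yt, Xt, lam, g)[0] for g in grid])
        best = int(np.argmax(lls))
        if best == 0:
            gamma = 0.0
        else:
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda g: -_profile_reml_gamma(yt, Xt, lam, g)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            gamma = float(res.x)
            if _profile_reml_gamma(yt, Xt, lam, 0.0)[0] >= -res.fun:
                gamma = 0.0  # boundary optimum: exact OLS reduction
        ll, beta, sigma2_e, W = _profile_reml_gamma(yt, Xt, lam, gamma)
    if beta is None:
        raise DegenerateGeneError(f"{gene_id}: singular design")
    cov = sigma2_e * np.linalg.inv(W)
    beta1, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    z = beta1 / se
    if use_t:
        p = 2.0 * stats.t.sf(abs(z), df=n - X.shape[1])
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return GeneAssociationRecord(
        gene_id=gene_id,
        beta1=beta1,
        se_beta1=se,
        p_value=p,
        significant=p < alpha,
        gamma=gamma,
        sigma2_e=float(sigma2_e),
        sigma2_family=float(gamma * sigma2_e),
        n=n,
    )


def run_association_scan(
    em: ExpressionMatrix,
    phenotypes: pd.DataFrame,
    trait: str = "liver_fat",
    alpha: float = 0.05,
    min_expressed_fraction: float = 0.5,
    use_t: bool = False,
) -> pd.DataFrame:
    """One trait~expression fit per retained gene.

    The significant set is defined by raw p < alpha with no multiple-testing
    correction, matching the published definition of trait-associated genes.
    """
    if em.log2_fpkm is None:
        em = normalize_expression(em.counts, em.lengths)
    phen = phenotypes.set_index("individual_id")
    common = [s for s in em.sample_ids if s in phen.index]
    if not common:
        raise AlignmentError("no overlapping samples between expression and phenotypes")
    phen = phen.loc[common]
    keep = filter_genes(em, min_expressed_fraction)
    expr = em.log2_fpkm.loc[keep, common]
    if expr.empty:
        warnings.warn("no genes retained by the expression filter", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_id", "beta1", "se_beta1", "p_value", "significant", "gamma"]
        )
    y = phen[trait].to_numpy(float)
    sex = phen["sex"].to_numpy()
    family = phen["family_id"].to_numpy()
    fam_codes, _ = pd.factorize(family)
    Z = np.zeros((len(common), fam_codes.max() + 1))
    Z[np.arange(len(common)), fam_codes] = 1.0
    rotation = np.linalg.eigh(Z @ Z.T)

    records = []
    for gene_id, row in expr.iterrows():
        try:
            rec = fit_gene_trait_lmm(
                y, row.to_numpy(), sex, family,
                gene_id=gene_id, alpha=alpha, use_t=use_t, _rotation=rotation,
            )
        except DegenerateGeneError as err:
            logger.info("skipping gene: %s", err)
            continue
        records.append(rec)
    return pd.DataFrame([vars(r) for r in records])
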