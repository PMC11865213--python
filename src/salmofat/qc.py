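"""Per-SNP quality control: call rate, minor allele frequency, and a
Hardy-Weinberg equilibrium test.

A SNP passes when call rate > 0.9, MAF > 0.02 and HWE p > 0.001 (strict
inequalities, matching the array-QC convention). The HWE test is the
standard 1-df Pearson chi-square of observed vs expected genotype counts
(equivalently n*r^2 on the allelic correlation); an exact test is available
for small panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import EmptyPanelError, InvalidConfigError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    call_rate: float = 0.9
    maf: float = 0.02
    hwe_p: float = 0.001

    def __post_init__(self):
        if not (0 <= self.call_rate <= 1 and 0 <= self.maf <= 0.5 and 0 <= self.hwe_p <= 1):
            raise InvalidConfigError(f"thresholds out of range: {self}")


@dataclass
class SNPQCReport:
    """Per-SNP metrics plus removal counts by reason.

    A SNP failing several filters is counted once per filter and once in
    ``removed_total``.
    """

    metrics: pd.DataFrame
    thresholds: QCThresholds
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_undefined: int = 0
    removed_total: int = 0
    _: dict = field(default_factory=dict, repr=False)


def hwe_chi2_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """1-df Pearson chi-square p for HWE given genotype counts (AA, AB, BB).

    Degenerate columns (monomorphic, where expected heterozygote and
    minor-homozygote counts vanish together with the observed ones) get
    chi2 = 0, p = 1.
    """
    n0, n1, n2 = (np.asarray(a, float) for a in (n0, n1, n2))
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.stack([n0, n1, n2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    return stats.chi2.sf(chi2, df=1)


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test (sum of probabilities of heterozygote counts no more
    likely than observed, conditional on allele counts)."""
    n = n0 + n1 + n2
    n_rare = min(n1 + 2 * n0, n1 + 2 * n2)
    het_obs = n1
    hets = np.arange(het_obs % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == het_obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_metrics(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    hwe_method: str = "chisq",
) -> SNPQCReport:
    """Call rate, MAF and HWE p per SNP, with pass flags.

    Missing dosages are excluded from the MAF and HWE denominators. SNPs
    with fewer than two called samples get undefined (NaN) metrics and fail.
    """
    d = genotypes.dosages
    n_called = (~np.isnan(d)).sum(axis=0)
    call_rate = n_called / d.shape[0]
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 + 2 * n2) / (2 * n_called)
        maf = np.minimum(pbar, 1 - pbar)
    if hwe_method == "chisq":
        hwe_p = hwe_chi2_p(n0, n1, n2)
    elif hwe_method == "exact":
        hwe_p = np.array(
            [hwe_exact_p(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]
        )
    else:
        raise InvalidConfigError(f"unknown hwe_method {hwe_method!r}")
    undefined = n_called < 2
    if undefined.any():
        logger.warning("%d SNP(s) with <2 calls: metrics undefined, SNP fails",
                       int(undefined.sum()))
    maf = np.where(undefined, np.nan, maf)
    hwe_p = np.where(undefined, np.nan, hwe_p)
    pass_cr = call_rate > thresholds.call_rate
    pass_maf = maf > thresholds.maf
    pass_hwe = hwe_p > thresholds.hwe_p
    ok = pass_cr & pass_maf & pass_hwe & ~undefined
    metrics = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "n_called": n_called,
            "pass_call_rate": pass_cr,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "undefined": undefined,
            "pass": ok,
        }
    )
    return SNPQCReport(
        metrics=metrics,
        thresholds=thresholds,
        removed_call_rate=int((~pass_cr).sum()),
        removed_maf=int((~pass_maf & ~undefined).sum()),
        removed_hwe=int((~pass_hwe & ~undefined).sum()),
        removed_undefined=int(undefined.sum()),
        removed_total=int((~ok).sum()),
    )


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, SNPQCReport]:
    """Restrict the panel to passing SNPs; report removals by reason."""
    report = snp_metrics(genotypes, thresholds, hwe_method)
    keep = report.metrics["pass"].to_numpy()
    if not keep.any():
        raise EmptyPanelError("quality control removed every SNP")
    return genotypes.subset_snps(keep), report
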