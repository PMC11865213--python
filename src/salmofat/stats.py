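"""Term enrichment by Yates-corrected chi-square, plus the descriptive
statistics, Spearman correlations, hepatosomatic index and liver-score
handling used alongside the genetic analyses."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square for the 2x2 table [[a, b], [c, d]].

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), clamped to zero
    when the continuity correction exceeds |ad - bc|; p from the 1-df
    chi-square survival function.
    """
    if min(a, b, c, d) < 0:
        raise UndefinedStatisticError("counts must be >= 0")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise UndefinedStatisticError(f"zero margin in table {[a, b, c, d]}")
    diff = abs(a * d - b * c)
    corrected = max(diff - n / 2.0, 0.0)
    chi2 = n * corrected**2 / np.prod([float(m) for m in margins])
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def enrich_terms(
    significant_genes,
    background_genes,
    term_map: pd.DataFrame,
    min_term_genes: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term 2x2 enrichment of the significant set within the background.

    Terms with fewer than ``min_term_genes`` background genes are skipped
    (no p reported). A degenerate margin — e.g. the significant set equals
    the background — also skips the term, with a warning.
    """
    sig = set(significant_genes)
    bg = set(background_genes)
    if not bg:
        raise UndefinedStatisticError("empty background gene set")
    if not sig <= bg:
        raise UndefinedStatisticError("significant genes must be a subset of background")
    tm = term_map[term_map["gene_id"].isin(bg)]
    rows = []
    for term, genes in tm.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        n_term_bg = len(term_genes)
        a = len(term_genes & sig)
        if n_term_bg < min_term_genes:
            rows.append(
                {"term_id": term, "n_term_significant": a,
                 "n_term_background": n_term_bg, "chi2_yates": np.nan,
                 "p_value": np.nan, "direction": 0, "enriched": False, "skipped": True}
            )
            continue
        b = len(sig) - a
        c = n_term_bg - a
        d = len(bg) - len(sig) - c
        try:
            chi2, p = yates_chi_square(a, b, c, d)
        except UndefinedStatisticError:
            warnings.warn(
                f"term {term}: degenerate 2x2 margin, skipped", stacklevel=2
            )
            rows.append(
                {"term_id": term, "n_term_significant": a,
                 "n_term_background": n_term_bg, "chi2_yates": np.nan,
                 "p_value": np.nan, "direction": 0, "enriched": False, "skipped": True}
            )
            continue
        expected_a = len(sig) * n_term_bg / len(bg)
        direction = int(np.sign(a - expected_a))
        rows.append(
            {"term_id": term, "n_term_significant": a,
             "n_term_background": n_term_bg, "chi2_yates": chi2, "p_value": p,
             "direction": direction, "enriched": p < alpha, "skipped": False}
        )
    return pd.DataFrame(rows)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho on midranks with the t-approximation p (n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise UndefinedStatisticError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def hepatosomatic_index(liver_weight, body_weight):
    """HSI = liver weight / body weight * 100 (same units for both)."""
    liver_weight = np.asarray(liver_weight, float)
    body_weight = np.asarray(body_weight, float)
    if (body_weight <= 0).any():
        raise UndefinedStatisticError("body weight must be > 0")
    out = liver_weight / body_weight * 100.0
    return float(out) if out.ndim == 0 else out


def reverse_liver_score(score):
    """Reverse the 1-5 liver-colour scale (score' = 6 - score) so that a
    higher score means a fattier liver."""
    arr = np.asarray(score)
    if not np.isin(arr, [1, 2, 3, 4, 5]).all():
        raise UndefinedStatisticError("liver scores must be integers in 1..5")
    out = 6 - arr
    return int(out) if out.ndim == 0 else out


def descriptive_stats(phenotypes: pd.DataFrame, columns) -> pd.DataFrame:
    """n, mean, SD, min, max per column; missing values excluded and n
    reported accordingly. A single observation gets SD 0 with a warning."""
    rows = []
    for col in columns:
        x = pd.to_numeric(phenotypes[col], errors="coerce").dropna()
        n = len(x)
        if n == 1:
            warnings.warn(f"column {col!r}: single observation, SD set to 0",
                          stacklevel=2)
        rows.append(
            {
                "trait": col,
                "n": n,
                "mean": x.mean() if n else np.nan,
                "sd": (x.std(ddof=1) if n > 1 else (0.0 if n == 1 else np.nan)),
                "min": x.min() if n else np.nan,
                "max": x.max() if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
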