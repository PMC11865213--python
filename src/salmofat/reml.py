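"""GREML variance-component estimation by average-information REML.

Univariate model:  y = X beta + u + e,  u ~ N(0, G sigma2_g),  e ~ N(0, I sigma2_e)
Bivariate model:   vec(Y) likewise with 2x2 genetic (Cg) and residual (Ce)
covariance matrices; the genetic correlation is rg = Cg12 / sqrt(Cg11 Cg22).

Both fits eigendecompose G once so every REML iteration works with a
diagonal (univariate) or 2x2-block (bivariate) covariance, which is exactly
equivalent to direct dense solves. The univariate optimiser takes one EM
step as burn-in and then average-information updates with step-halving, so
the accepted restricted log-likelihood never decreases; components are
clamped at 1e-8 of the phenotypic variance and flagged when they sit on
that boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateTraitError, InvalidConfigError, UndefinedStatisticError
from .grm import GRMatrix

# ---------------------------------------------------------------------------
# design


@dataclass
class ModelDesign:
    """Aligned response(s), fixed-effect design and sample ids."""

    y: np.ndarray  # (n,) or (n, 2)
    X: np.ndarray  # (n, p) including intercept
    sample_ids: np.ndarray
    trait_names: tuple[str, ...] = ("trait",)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        n = self.y.shape[0]
        if self.X.shape[0] != n or len(self.sample_ids) != n:
            raise AlignmentError("rows of y, X and sample_ids must align")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise InvalidConfigError("fixed-effect design X is rank deficient")


def build_design(
    phenotypes: pd.DataFrame,
    trait: str | tuple[str, str],
    covariates: tuple[str, ...] = ("sex",),
    pcs: pd.DataFrame | None = None,
) -> ModelDesign:
    """Assemble a ModelDesign from a phenotype table.

    Fixed effects are an intercept, a male indicator for ``sex``, any other
    listed numeric covariates, and optionally principal-component
    coordinates indexed by individual id. Rows with a missing response are
    dropped (for a trait pair: rows missing either trait).
    """
    traits = (trait,) if isinstance(trait, str) else tuple(trait)
    df = phenotypes.set_index("individual_id")
    keep = df[list(traits)].notna().all(axis=1)
    if pcs is not None:
        keep &= df.index.isin(pcs.index)
    df = df.loc[keep]
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov == "sex":
            cols.append((df["sex"].astype(str).str.upper().str.startswith("M")).to_numpy(float))
        else:
            cols.append(df[cov].to_numpy(float))
    if pcs is not None:
        cols.extend(pcs.loc[df.index].to_numpy(float).T)
    y = df[traits[0]].to_numpy(float) if len(traits) == 1 else df[list(traits)].to_numpy(float)
    return ModelDesign(y, np.column_stack(cols), df.index.to_numpy(object), traits)


# ---------------------------------------------------------------------------
# results


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    h2: float
    se_h2: float
    reml_loglik: float
    n_iterations: int
    converged: bool
    boundary: bool
    n: int
    loglik_path: list = field(default_factory=list, repr=False)


@dataclass
class BivariateComponents:
    cov_genetic: np.ndarray  # 2x2
    cov_residual: np.ndarray  # 2x2
    rg: float
    se_rg: float
    rg_at_boundary: bool
    psd_projected: bool
    reml_loglik: float
    n_iterations: int
    converged: bool
    n: int
    trait_names: tuple[str, str] = ("trait1", "trait2")
    loglik_path: list = field(default_factory=list, repr=False)

    @property
    def sigma2_g(self) -> np.ndarray:
        return np.diag(self.cov_genetic)

    @property
    def sigma2_e(self) -> np.ndarray:
        return np.diag(self.cov_residual)

    @property
    def h2(self) -> np.ndarray:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass(frozen=True)
class REMLOptions:
    max_iter: int = 100
    tol: float = 1e-8
    log_transform: bool = False
    max_halvings: int = 30


# ---------------------------------------------------------------------------
# simple ratios


def heritability_from_components(sigma2_g: float, sigma2_e: float) -> float:
    """Narrow-sense heritability: additive over total phenotypic variance."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise UndefinedStatisticError("variance components must be >= 0")
    total = sigma2_g + sigma2_e
    if total == 0:
        raise UndefinedStatisticError("h2 undefined when both components are zero")
    return sigma2_g / total


def coefficient_of_variation(sd: float, mean: float) -> float:
    """CV = SD / mean (e.g. genetic CV = genetic SD over the trait mean)."""
    if mean <= 0:
        raise UndefinedStatisticError(f"CV undefined for mean {mean}")
    return sd / mean


# ---------------------------------------------------------------------------
# univariate GREML


def _align_grm(design: ModelDesign, grm: GRMatrix) -> np.ndarray:
    missing = set(design.sample_ids) - set(grm.sample_ids)
    if missing:
        raise AlignmentError(f"design samples absent from GRM: {sorted(missing)[:5]}")
    return grm.subset(design.sample_ids).values


def reml_loglik(
    design: ModelDesign, grm: GRMatrix, sigma2_g: float, sigma2_e: float
) -> float:
    """Restricted log-likelihood (additive constant dropped) at the given
    components — exposed so grid searches can audit the optimiser."""
    g = _align_grm(design, grm)
    d, u = np.linalg.eigh(g)
    yt, xt = u.T @ design.y, u.T @ design.X
    ll, *_ = _uni_parts(np.array([sigma2_g, sigma2_e]), d, yt, xt)
    return ll


def _uni_parts(theta, d, yt, xt):
    vg, ve = theta
    v = vg * d + ve
    if (v <= 0).any():
        return -np.inf, None, None, None, None
    xv = xt / v[:, None]
    w = xt.T @ xv
    sign, logdet_w = np.linalg.slogdet(w)
    if sign <= 0:
        return -np.inf, None, None, None, None
    b = xv.T @ yt
    beta = np.linalg.solve(w, b)
    py = (yt - xt @ beta) / v
    ll = -0.5 * (np.log(v).sum() + logdet_w + yt @ py)
    return ll, v, w, py, beta


def fit_greml_univariate(
    design: ModelDesign, grm: GRMatrix, options: REMLOptions = REMLOptions()
) -> VarianceComponents:
    """AI-REML fit of (sigma2_g, sigma2_e); SEs from the inverse AI matrix,
    SE(h2) by the delta method. Non-convergence is flagged, not raised."""
    y = np.asarray(design.y, float)
    if y.ndim != 1:
        raise InvalidConfigError("univariate fit needs a single response")
    if options.log_transform:
        if (y <= 0).any():
            raise DegenerateTraitError("log transform needs strictly positive responses")
        y = np.log(y)
    if np.ptp(y) == 0:
        raise DegenerateTraitError("response is constant")
    n = y.size
    if n < 50:
        warnings.warn(
            f"n={n} is small for GREML; estimates will be unstable", stacklevel=2
        )
    g = _align_grm(design, grm)
    try:
        d, u = np.linalg.eigh(g)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise InvalidConfigError(f"GRM eigendecomposition failed: {err}")
    if d.min() < -1e-6:
        raise InvalidConfigError("GRM is not positive semidefinite")
    d = np.clip(d, 0, None)
    yt, xt = u.T @ y, u.T @ design.X

    vp = y.var(ddof=1)
    floor = 1e-8 * vp
    theta = np.array([vp / 2, vp / 2])
    ll, v, w, py, _ = _uni_parts(theta, d, yt, xt)
    path = [ll]
    ai = np.eye(2)
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        winv = np.linalg.inv(w)

        def tr_p_times(weights):
            a = xt * (weights / v**2)[:, None]
            return (weights / v).sum() - np.trace(winv @ (xt.T @ a))

        tg = d * py
        te = py
        ypgpy = tg @ py
        ypipy = te @ py
        score = -0.5 * np.array(
            [tr_p_times(d) - ypgpy, tr_p_times(np.ones_like(d)) - ypipy]
        )

        def apply_p(z):
            zv = z / v
            return zv - (xt @ (winv @ (xt.T @ zv))) / v

        ptg, pte = apply_p(tg), apply_p(te)
        ai = 0.5 * np.array([[tg @ ptg, tg @ pte], [te @ ptg, te @ pte]])

        if it == 1:  # EM burn-in: slow but globally stable first move
            delta = theta**2 * np.array([ypgpy - tr_p_times(d),
                                         ypipy - tr_p_times(np.ones_like(d))]) / n
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = score / max(np.diag(ai).max(), 1e-12)

        # step-halving: never accept a decrease in the restricted loglik
        accepted = False
        for _ in range(options.max_halvings):
            cand = np.maximum(theta + delta, floor)
            ll_new, v_new, w_new, py_new, _ = _uni_parts(cand, d, yt, xt)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            delta = delta / 2.0
        if not accepted:
            break
        moved = np.abs(cand - theta).max()
        theta, v, w, py = cand, v_new, w_new, py_new
        dll = ll_new - ll
        ll = ll_new
        path.append(ll)
        if it >= 2 and (abs(dll) < options.tol * (1 + abs(ll)) or moved < floor):
            converged = True
            break

    cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    sg, sev = theta
    h2 = heritability_from_components(sg, sev)
    grad = np.array([sev, -sg]) / (sg + sev) ** 2
    se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    boundary = bool(sg <= floor * 1.5 or sev <= floor * 1.5)
    return VarianceComponents(
        sigma2_g=float(sg),
        sigma2_e=float(sev),
        se_sigma2_g=float(se[0]),
        se_sigma2_e=float(se[1]),
        h2=float(np.clip(h2, 0.0, 1.0)),
        se_h2=se_h2,
        reml_loglik=float(ll),
        n_iterations=it,
        converged=converged,
        boundary=boundary,
        n=n,
        loglik_path=path,
    )


# ---------------------------------------------------------------------------
# bivariate GREML

_E = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
]


def _unpack(theta):
    cg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    ce = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return cg, ce


def _bi_parts(theta, d, yt, xt):
    """Blockwise quantities for the rotated bivariate model.

    Returns (ll, a, w_inv pieces, py, ...) where ``a`` holds the 2x2
    inverses of V_i = d_i Cg + Ce.
    """
    cg, ce = _unpack(theta)
    vi = d[:, None, None] * cg[None] + ce[None]  # (n, 2, 2)
    det = vi[:, 0, 0] * vi[:, 1, 1] - vi[:, 0, 1] ** 2
    if (det <= 0).any() or (vi[:, 0, 0] <= 0).any() or (vi[:, 1, 1] <= 0).any():
        return None
    a = np.empty_like(vi)
    a[:, 0, 0] = vi[:, 1, 1] / det
    a[:, 1, 1] = vi[:, 0, 0] / det
    a[:, 0, 1] = a[:, 1, 0] = -vi[:, 0, 1] / det
    p = xt.shape[1]
    w = np.empty((2 * p, 2 * p))
    for t1 in range(2):
        for t2 in range(2):
            w[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = np.einsum(
                "i,ij,ik->jk", a[:, t1, t2], xt, xt
            )
    sign, logdet_w = np.linalg.slogdet(w)
    if sign <= 0:
        return None
    az = np.einsum("ikl,il->ik", a, yt)
    b = np.concatenate([xt.T @ az[:, 0], xt.T @ az[:, 1]])
    beta = np.linalg.solve(w, b).reshape(2, p)
    r = yt - xt @ beta.T
    py = np.einsum("ikl,il->ik", a, r)
    ypy = float((yt * py).sum())
    ll = -0.5 * (np.log(det).sum() + logdet_w + ypy)
    return ll, a, w, py, beta


def _bi_apply_p(z, a, w, xt):
    p = xt.shape[1]
    az = np.einsum("ikl,il->ik", a, z)
    bz = np.concatenate([xt.T @ az[:, 0], xt.T @ az[:, 1]])
    betaz = np.linalg.solve(w, bz).reshape(2, p)
    rz = z - xt @ betaz.T
    return np.einsum("ikl,il->ik", a, rz)


def _project_psd(c, eps):
    w, v = np.linalg.eigh(c)
    if w.min() >= eps:
        return c, False
    w = np.clip(w, eps, None)
    return v @ np.diag(w) @ v.T, True


def fit_greml_bivariate(
    design: ModelDesign, grm: GRMatrix, options: REMLOptions = REMLOptions()
) -> BivariateComponents:
    """AI-REML fit of the 2x2 genetic and residual covariance matrices.

    Initialised from the two univariate fits; covariances start at a damped
    phenotypic-correlation guess. Records missing either trait are dropped
    (complete-case), and the component matrices are kept positive
    semidefinite by eigenvalue clipping (flagged when it bites).
    """
    y = np.asarray(design.y, float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise InvalidConfigError("bivariate fit needs two response columns")
    if np.ptp(y[:, 0]) == 0 or np.ptp(y[:, 1]) == 0:
        raise DegenerateTraitError("a response trait is constant")
    n = y.shape[0]
    g = _align_grm(design, grm)
    d, u = np.linalg.eigh(g)
    d = np.clip(d, 0, None)
    yt = u.T @ y
    xt = u.T @ design.X

    # univariate starting values (never log-transformed here)
    uni_opts = REMLOptions(max_iter=options.max_iter, tol=options.tol)
    uni = []
    for j in range(2):
        dj = ModelDesign(y[:, j], design.X, design.sample_ids)
        uni.append(fit_greml_univariate(dj, grm.subset(design.sample_ids), uni_opts))
    rp = float(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
    theta = np.array(
        [
            uni[0].sigma2_g,
            0.5 * rp * np.sqrt(uni[0].sigma2_g * uni[1].sigma2_g),
            uni[1].sigma2_g,
            uni[0].sigma2_e,
            0.5 * rp * np.sqrt(uni[0].sigma2_e * uni[1].sigma2_e),
            uni[1].sigma2_e,
        ]
    )
    vp = y.var(axis=0, ddof=1)
    floor = 1e-8 * float(vp.mean())

    parts = _bi_parts(theta, d, yt, xt)
    if parts is None:  # pathological start; shrink covariances
        theta[[1, 4]] = 0.0
        parts = _bi_parts(theta, d, yt, xt)
    ll, a, w, py, _ = parts
    path = [ll]
    weights = [d, d, d, np.ones_like(d), np.ones_like(d), np.ones_like(d)]
    ai = np.eye(6)
    psd_projected = False
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        winv = np.linalg.inv(w)
        p = xt.shape[1]
        score = np.empty(6)
        zs = []
        for k in range(6):
            e = _E[k % 3]
            wk = weights[k]
            zk = wk[:, None] * (py @ e)
            zs.append(zk)
            ypvpy = float((py * zk).sum())
            ae_a = np.einsum("ikl,lm,imn->ikn", a, e, a)
            tr_vinv = float((wk * np.einsum("ikl,lk->i", a, e)).sum())
            mk = np.empty((2 * p, 2 * p))
            for t1 in range(2):
                for t2 in range(2):
                    mk[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = np.einsum(
                        "i,ij,ik->jk", wk * ae_a[:, t1, t2], xt, xt
                    )
            tr_pv = tr_vinv - float(np.trace(winv @ mk))
            score[k] = -0.5 * (tr_pv - ypvpy)
        pzs = [_bi_apply_p(z, a, w, xt) for z in zs]
        ai = 0.5 * np.array(
            [[float((zs[j] * pzs[k]).sum()) for k in range(6)] for j in range(6)]
        )
        ai = (ai + ai.T) / 2.0
        try:
            delta = np.linalg.solve(ai + 1e-10 * np.eye(6), score)
        except np.linalg.LinAlgError:
            delta = score / max(np.diag(ai).max(), 1e-12)

        accepted = False
        for _ in range(options.max_halvings):
            cand = theta + delta
            cg, proj_g = _project_psd(_unpack(cand)[0], floor)
            ce, proj_e = _project_psd(_unpack(cand)[1], floor)
            cand = np.array([cg[0, 0], cg[0, 1], cg[1, 1], ce[0, 0], ce[0, 1], ce[1, 1]])
            parts = _bi_parts(cand, d, yt, xt)
            if parts is not None and parts[0] >= ll - 1e-12:
                accepted = True
                psd_projected = psd_projected or proj_g or proj_e
                break
            delta = delta / 2.0
        if not accepted:
            break
        moved = np.abs(cand - theta).max()
        theta = cand
        dll = parts[0] - ll
        ll, a, w, py, _ = parts
        path.append(ll)
        if it >= 2 and (abs(dll) < options.tol * (1 + abs(ll)) or moved < floor):
            converged = True
            break

    cg, ce = _unpack(theta)
    denom = np.sqrt(cg[0, 0] * cg[1, 1])
    rg_raw = cg[0, 1] / denom if denom > 0 else 0.0
    rg = float(np.clip(rg_raw, -1.0, 1.0))
    at_boundary = bool(abs(rg_raw) >= 1.0 - 1e-10)
    cov = np.linalg.pinv(ai)[:3, :3]
    grad = np.array(
        [
            -rg / (2 * cg[0, 0]) if cg[0, 0] > 0 else 0.0,
            1.0 / denom if denom > 0 else 0.0,
            -rg / (2 * cg[1, 1]) if cg[1, 1] > 0 else 0.0,
        ]
    )
    se_rg = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return BivariateComponents(
        cov_genetic=cg,
        cov_residual=ce,
        rg=rg,
        se_rg=se_rg,
        rg_at_boundary=at_boundary,
        psd_projected=psd_projected,
        reml_loglik=float(ll),
        n_iterations=it,
        converged=converged,
        n=n,
        trait_names=tuple(design.trait_names)
        if len(design.trait_names) == 2
        else ("trait1", "trait2"),
        loglik_path=path,
    )
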