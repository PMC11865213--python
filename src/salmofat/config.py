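"""Simulation configuration for the synthetic salmon cohort.

The defaults emulate the study population the downstream analyses assume:
634 phenotyped fish from 39 sires x 48 dams, 610 of them genotyped, a
48-fish RNA-seq subset, 29 chromosomes, and trait variance components /
genetic correlations calibrated to the published liver-fat tables
(liver fat: sigma2_g = 2.59, sigma2_e = 4.19, mean 7.6 %). The SNP panel
defaults to 5,000 markers as a scaled stand-in for the ~52,925-SNP array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

#: Liver fatty-acid panel: relative content (% of total fatty acids),
#: mean and SD for the 48-fish subset.
DEFAULT_FATTY_ACIDS: dict[str, tuple[float, float]] = {
    "16:0": (11.1, 1.9),
    "16:1n-7": (2.3, 0.7),
    "18:0": (5.2, 0.6),
    "18:1n-9": (22.4, 5.6),
    "18:2n-6": (5.6, 0.9),
    "18:3n-3": (2.2, 0.4),
    "20:5n-3": (6.5, 0.7),
    "22:5n-3": (3.5, 0.5),
    "22:6n-3": (13.8, 4.0),
}

#: Sign of the correlation between each fatty acid and liver fat:
#: fattier livers carry more 16:1n-7, 18:2n-6 and 18:1n-9 and less
#: 16:0, EPA (20:5n-3) and DHA (22:6n-3).
DEFAULT_FA_SIGNS: dict[str, int] = {
    "16:0": -1,
    "16:1n-7": +1,
    "18:0": 0,
    "18:1n-9": +1,
    "18:2n-6": +1,
    "18:3n-3": 0,
    "20:5n-3": -1,
    "22:5n-3": 0,
    "22:6n-3": -1,
}


@dataclass
class TraitSpec:
    """Generative parameters of one polygenic trait.

    ``var_g``/``var_e`` are the additive-genetic and residual variances in
    squared trait units; ``sex_effect`` is the male-minus-female shift added
    as a fixed effect (centred so the population mean is unchanged).
    ``kind`` controls post-processing of the Gaussian linear predictor:
    ``"gaussian"`` leaves it untouched, ``"floored"`` applies the soft
    lower bound used for liver fat, ``"score"`` discretises to 1..5.
    """

    mean: float
    var_g: float
    var_e: float
    sex_effect: float = 0.0
    kind: str = "gaussian"

    @property
    def h2(self) -> float:
        return self.var_g / (self.var_g + self.var_e)

    def validate(self, name: str) -> None:
        if self.var_g < 0 or self.var_e < 0:
            raise InvalidConfigError(f"trait {name!r}: variances must be >= 0")
        if self.var_g + self.var_e <= 0:
            raise InvalidConfigError(f"trait {name!r}: total variance must be > 0")
        if self.kind not in {"gaussian", "floored", "score"}:
            raise InvalidConfigError(f"trait {name!r}: unknown kind {self.kind!r}")


def default_traits() -> dict[str, TraitSpec]:
    """Trait panel calibrated to the published descriptive statistics and
    heritabilities (liver fat h2=0.38, muscle fat 0.43, body weight 0.58,
    liver score 0.28, HSI 0.19, viscera score 0.28)."""

    def from_h2(mean, sd_p, h2, sex_effect=0.0, kind="gaussian"):
        var_p = sd_p**2
        return TraitSpec(mean, h2 * var_p, (1 - h2) * var_p, sex_effect, kind)

    return {
        "liver_fat": TraitSpec(7.6, 2.59, 4.19, sex_effect=0.3, kind="floored"),
        "muscle_fat": from_h2(19.2, 3.0, 0.43, sex_effect=0.4),
        "body_weight": from_h2(3.56, 0.83, 0.58, sex_effect=0.15),
        "liver_score": from_h2(3.0, 1.0, 0.28, kind="score"),
        "hsi": from_h2(0.8, 0.1, 0.19),
        "viscera_score": from_h2(3.0, 1.0, 0.28, kind="score"),
    }


def default_genetic_correlations(trait_names: list[str]) -> np.ndarray:
    """Genetic correlation matrix built from the published first row
    (correlations of each trait with liver fat): R = v v' + diag(1 - v^2),
    which is positive semidefinite by construction and reproduces the
    liver-fat row exactly."""
    rg_with_liver_fat = {
        "liver_fat": 1.0,
        "muscle_fat": 0.37,
        "body_weight": 0.31,
        "liver_score": 0.70,
        "hsi": 0.25,
        "viscera_score": 0.28,
    }
    v = np.array([rg_with_liver_fat.get(t, 0.0) for t in trait_names])
    r = np.outer(v, v) + np.diag(1.0 - v**2)
    return r


def paired_trait_config(
    var_g_first: float = 2.59,
    var_e_first: float = 4.19,
    h2_second: float = 0.28,
    rg: float = 0.70,
    n_individuals: int = 600,
    n_snps: int = 5000,
    seed: int = 0,
    **overrides,
) -> "SimulationConfig":
    """Two Gaussian traits with chosen variance components and genetic
    correlation — the configuration used for estimator-recovery studies
    (liver fat at its published components next to a unit-variance
    liver-score-like trait)."""
    traits = {
        "liver_fat": TraitSpec(7.6, var_g_first, var_e_first, sex_effect=0.3),
        "liver_score": TraitSpec(3.0, h2_second, 1.0 - h2_second),
    }
    rmat = overrides.pop("genetic_correlations", np.array([[1.0, rg], [rg, 1.0]]))
    return SimulationConfig(
        n_individuals=n_individuals,
        n_genotyped=n_individuals,
        n_expression=min(48, n_individuals),
        n_snps=n_snps,
        gaussian_traits=True,
        traits=traits,
        genetic_correlations=rmat,
        qc_spike=(0, 0, 0),
        seed=seed,
        **overrides,
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    A single master ``seed`` drives every stage; per-stage generators are
    derived deterministically so each operation is reproducible in isolation.
    """

    n_individuals: int = 634
    n_genotyped: int = 610
    n_expression: int = 48
    n_sires: int = 39
    n_dams: int = 48
    n_chromosomes: int = 29
    n_snps: int = 5000
    chromosome_length: int = 80_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    traits: dict[str, TraitSpec] = field(default_factory=default_traits)
    genetic_correlations: np.ndarray | None = None
    residual_correlation_scale: float = 0.3
    sex_fraction_male: float = 0.55
    # soft lower bound of the liver-fat distribution (right-skew)
    liver_fat_floor: float = 4.0
    floor_softness: float = 0.5
    gaussian_traits: bool = False
    # expression generator
    n_genes: int = 2000
    assoc_gene_fraction: float = 0.10
    assoc_effect_sd: float = 0.10
    expr_noise_sd: float = 0.5
    expr_sex_effect_sd: float = 0.1
    family_variance_expr: float = 0.025
    n_zero_genes: int = 10
    # fatty-acid generator
    fatty_acid_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FATTY_ACIDS)
    )
    fa_sign_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FA_SIGNS))
    fa_coupling: float = 0.6
    # counts of SNPs constructed to violate (call-rate, MAF, HWE) filters
    qc_spike: tuple[int, int, int] = (50, 50, 50)
    # annotation / term generator
    n_terms: int = 40
    n_enriched_terms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.traits, dict):
            for name, spec in self.traits.items():
                spec.validate(name)
        counts = {
            "n_individuals": self.n_individuals,
            "n_sires": self.n_sires,
            "n_dams": self.n_dams,
            "n_chromosomes": self.n_chromosomes,
            "n_snps": self.n_snps,
        }
        for name, value in counts.items():
            if value < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {value}")
        if self.n_sires > self.n_individuals:
            raise InvalidConfigError("n_sires must not exceed n_individuals")
        if self.n_genotyped > self.n_individuals:
            raise InvalidConfigError("n_genotyped must not exceed n_individuals")
        if self.n_expression > self.n_individuals:
            raise InvalidConfigError("n_expression must not exceed n_individuals")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        for name, prop in [
            ("sex_fraction_male", self.sex_fraction_male),
            ("assoc_gene_fraction", self.assoc_gene_fraction),
        ]:
            if not (0.0 <= prop <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {prop}")
        if self.family_variance_expr < 0:
            raise InvalidConfigError("family_variance_expr must be >= 0")
        if sum(m for m, _ in self.fatty_acid_means_sds.values()) > 100.0:
            raise InvalidConfigError("fatty-acid means exceed 100% in total")
        if any(n < 0 for n in self.qc_spike) or sum(self.qc_spike) > self.n_snps:
            raise InvalidConfigError("qc_spike counts invalid for this panel size")
        if self.genetic_correlations is not None:
            self.genetic_correlations = np.asarray(self.genetic_correlations, float)
            self._check_correlation_matrix(self.genetic_correlations)

    def _check_correlation_matrix(self, r: np.ndarray) -> None:
        t = len(self.traits)
        if r.shape != (t, t):
            raise InvalidConfigError(
                f"genetic_correlations must be {t}x{t}, got {r.shape}"
            )
        if not np.allclose(r, r.T, atol=1e-10):
            raise InvalidConfigError("genetic_correlations must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise InvalidConfigError("genetic_correlations must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise InvalidConfigError("genetic_correlations must be positive semidefinite")

    # -- derived pieces ----------------------------------------------------

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def genetic_correlation_matrix(self) -> np.ndarray:
        if self.genetic_correlations is not None:
            return self.genetic_correlations
        return default_genetic_correlations(self.trait_names)

    def residual_correlation_matrix(self) -> np.ndarray:
        """Residual correlations: same one-factor structure as the genetic
        matrix, damped by ``residual_correlation_scale``."""
        rg = self.genetic_correlation_matrix()
        v = rg[0].copy()
        v[1:] *= self.residual_correlation_scale
        return np.outer(v, v) + np.diag(1.0 - v**2)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        stage_ids = {
            "pedigree": 1,
            "genotypes": 2,
            "phenotypes": 3,
            "expression": 4,
            "fatty_acids": 5,
            "annotation": 6,
        }
        if stage not in stage_ids:
            raise KeyError(f"unknown simulation stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stage_ids[stage]])
        )
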