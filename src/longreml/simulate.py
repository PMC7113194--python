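"""Synthetic genotypes and longitudinal phenotypes with known heritability.

The generator mirrors the model the downstream pipeline assumes: each subject
carries a true trait level ``b0`` (expected value at their mean observed age)
and a true annual change ``b1``, each the sum of a polygenic value and an
environmental residual.  Visit-level observations add period-specific
(heteroscedastic) measurement noise plus fixed sex and age effects, and
individual visits can be missing at random.  Polygenic effects follow an
infinitesimal model (i.i.d. Gaussian per SNP) and are rescaled so the realized
genetic variance matches the target exactly in-sample, which keeps
parameter-recovery tests sharp at moderate cohort sizes.

Genotypes are drawn at Hardy-Weinberg proportions with allele frequencies
uniform over a configurable range; no linkage disequilibrium or population
structure is simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .genotype import GenotypeMatrix

#: Default visit-level residual variances per period (trait-variance units).
#: Modest measurement noise that grows over follow-up.
DEFAULT_PERIOD_NOISE = (0.30, 0.36, 0.42, 0.48, 0.54, 0.60)


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture knobs for one simulated trait.

    A biennial six-visit cohort of middle-aged adults is the default design:
    baseline ages uniform on 40-69 years and follow-ups at exact two-year
    increments.
    """

    n_subjects: int = 300
    n_snps: int = 1000
    n_periods: int = 6
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_B0: float = 0.3
    h2_B1: float = 0.1
    var_B0: float = 1.0
    var_B1: float = 1.0
    period_noise_variances: tuple[float, ...] | None = None
    baseline_age_range: tuple[float, float] = (40.0, 69.0)
    visit_spacing: float = 2.0
    missing_visit_prob: float = 0.0
    drop_periods: tuple[int, ...] = ()   # whole trait-period dropout (1-based)
    sex_effect: float = 0.5
    age_effect: float = 0.0
    b0_b1_env_correlation: float = 0.0
    mean_level: float = 0.0
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ParameterError("n_subjects and n_snps must be positive")
        if self.n_periods < 2:
            raise ParameterError("a longitudinal design needs n_periods >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        for h2 in (self.h2_B0, self.h2_B1):
            if not 0.0 <= h2 < 1.0:
                raise ParameterError(f"heritability {h2} outside [0, 1)")
        if self.period_noise_variances is None:
            base = np.array(DEFAULT_PERIOD_NOISE)
            if self.n_periods == len(base):
                w = base
            else:
                w = np.linspace(base[0], base[-1], self.n_periods)
            self.period_noise_variances = tuple(float(v) for v in w)
        w = np.asarray(self.period_noise_variances, dtype=float)
        if len(w) != self.n_periods or (w <= 0).any():
            raise ParameterError(
                "period_noise_variances must be strictly positive, one per period"
            )
        if not 0.0 <= self.missing_visit_prob < 1.0:
            raise ParameterError("missing_visit_prob must be in [0, 1)")
        if not -1.0 < self.b0_b1_env_correlation < 1.0:
            raise ParameterError("b0_b1_env_correlation must be in (-1, 1)")


@dataclass
class TrueEffects:
    """Ground truth retained for parameter-recovery tests."""

    snp_effects_b0: np.ndarray   # per-SNP effects on the subject intercept
    snp_effects_b1: np.ndarray   # per-SNP effects on the subject slope
    b0: np.ndarray               # per-subject true intercept (genetic + env)
    b1: np.ndarray               # per-subject true slope
    genetic_b0: np.ndarray       # polygenic component of b0
    genetic_b1: np.ndarray

    def realized_h2_b0(self) -> float:
        v = float(np.var(self.b0))
        return float(np.var(self.genetic_b0)) / v if v > 0 else 0.0

    def realized_h2_b1(self) -> float:
        v = float(np.var(self.b1))
        return float(np.var(self.genetic_b1)) / v if v > 0 else 0.0

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "b0": self.b0,
                "b1": self.b1,
                "genetic_b0": self.genetic_b0,
                "genetic_b1": self.genetic_b1,
            }
        ).to_csv(f"{prefix}.subjects.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"effect_b0": self.snp_effects_b0, "effect_b1": self.snp_effects_b1}
        ).to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes at frequencies uniform over ``maf_range``.

    Chromosome labels are assigned in ``n_chromosomes`` near-equal blocks;
    positions are evenly spaced within each chromosome.  Fully deterministic
    under ``config.seed``.
    """
    rng = _rng(config, 0)
    n, m = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)

    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    for c, block in enumerate(np.array_split(np.arange(m), config.n_chromosomes), start=1):
        chrom[block] = c
        pos[block] = 10_000 * (np.arange(len(block)) + 1)
    snp_meta = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
            "cm": 0.0,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    sex = rng.integers(1, 3, size=n)  # PLINK coding: 1 male, 2 female
    sample_meta = pd.DataFrame(
        {
            "fid": [f"fam{i + 1:05d}" for i in range(n)],
            "iid": [f"id{i + 1:05d}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": sex,
            "phenotype": -9,
        }
    )
    return GenotypeMatrix(dosages, snp_meta, sample_meta)


def _polygenic(
    Z: np.ndarray, target_var: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Infinitesimal-model genetic values rescaled to target_var in-sample."""
    m = Z.shape[1]
    u = rng.standard_normal(m)
    g = Z @ u
    if target_var <= 0.0:
        return np.zeros(Z.shape[0]), np.zeros(m)
    sd = g.std()
    if sd == 0.0:
        raise ParameterError("polygenic values are constant; need polymorphic SNPs")
    scale = np.sqrt(target_var) / sd
    return g * scale - (g * scale).mean(), u * scale


def simulate_longitudinal_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig, trait_name: str = "trait1"
) -> tuple[pd.DataFrame, TrueEffects]:
    """Simulate one trait's long-format visit table plus its ground truth.

    Each subject's observation at period j is

        y_ij = mu + b0_i + b1_i (age_ij - mean(age_i)) + beta_sex sex_i
               + beta_age age_ij + e_ij,   Var(e_ij) = w_j

    with ``mean(age_i)`` taken over the subject's *observed* visits, so the
    intercept is the expected trait value at the subject's own mean age,
    matching the downstream trajectory model.  Missing visits appear as rows
    with a missing value.
    """
    rng = _rng(config, 1, zlib.crc32(trait_name.encode()) & 0x7FFFFFFF)
    n, P = config.n_subjects, config.n_periods
    if genotypes.n_subjects != n:
        raise ParameterError("genotype matrix does not match config.n_subjects")

    X = genotypes.dosages
    p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    Z = np.zeros_like(X)
    with np.errstate(invalid="ignore"):
        Z[:, poly] = (X[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    Z[~np.isfinite(Z)] = 0.0  # missing calls contribute the mean genotype

    g0, u0 = _polygenic(Z, config.h2_B0 * config.var_B0, rng)
    g1, u1 = _polygenic(Z, config.h2_B1 * config.var_B1, rng)

    rho = config.b0_b1_env_correlation
    z0 = rng.standard_normal(n)
    z1 = rho * z0 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    e0 = z0 * np.sqrt((1 - config.h2_B0) * config.var_B0)
    e1 = z1 * np.sqrt((1 - config.h2_B1) * config.var_B1)
    b0 = g0 + e0
    b1 = g1 + e1

    base_age = rng.uniform(*config.baseline_age_range, size=n)
    ages = base_age[:, None] + config.visit_spacing * np.arange(P)[None, :]

    observed = rng.random((n, P)) >= config.missing_visit_prob
    for period in config.drop_periods:
        observed[:, period - 1] = False

    # mean observed age per subject (scheduled mean where nothing is observed;
    # such subjects are dropped by downstream inclusion filters anyway)
    n_obs = observed.sum(axis=1)
    mean_age = np.where(
        n_obs > 0,
        (ages * observed).sum(axis=1) / np.maximum(n_obs, 1),
        ages.mean(axis=1),
    )

    sex = genotypes.sample_meta["sex"].to_numpy()
    w = np.asarray(config.period_noise_variances)
    noise = rng.standard_normal((n, P)) * np.sqrt(w)[None, :]
    y = (
        config.mean_level
        + b0[:, None]
        + b1[:, None] * (ages - mean_age[:, None])
        + config.sex_effect * (sex[:, None] - 1)
        + config.age_effect * ages
        + noise
    )
    y = np.where(observed, y, np.nan)

    table = pd.DataFrame(
        {
            "subject_id": np.repeat(genotypes.sample_meta["iid"].to_numpy(), P),
            "period": np.tile(np.arange(1, P + 1), n),
            "age": ages.ravel(),
            "sex": np.repeat(sex, P),
            "trait": trait_name,
            "value": y.ravel(),
        }
    )
    truth = TrueEffects(
        snp_effects_b0=u0, snp_effects_b1=u1, b0=b0, b1=b1, genetic_b0=g0, genetic_b1=g1
    )
    return table, truth


def simulate_snp_response(
    dosage: np.ndarray, frac_variance: float, rng: np.random.Generator
) -> np.ndarray:
    """A quantitative response in which one SNP explains exactly
    ``frac_variance`` of the sample variance.

    The Gaussian noise is orthogonalized against the centred dosage and the
    effect size rescaled in-sample, in the same sharp-by-construction spirit
    as the polygenic generator, so power analyses see the nominal effect
    size rather than its sampling fluctuation.
    """
    if not 0.0 <= frac_variance < 1.0:
        raise ParameterError("frac_variance must be in [0, 1)")
    x = np.asarray(dosage, dtype=float)
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        raise ParameterError("monomorphic SNP cannot explain variance")
    e = rng.standard_normal(x.size)
    e -= xc * (xc @ e) / (xc @ xc)
    if frac_variance == 0.0:
        return e
    beta = np.sqrt(frac_variance / (1.0 - frac_variance) * e.var() / xc.var())
    return beta * xc + e


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Long-format tab-separated phenotype table with header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str, "trait": str})
    required = {"subject_id", "period", "age", "sex", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"phenotype table lacks columns: {sorted(missing)}")
    return df
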