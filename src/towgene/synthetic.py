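"""Synthetic genotype/phenotype generator with known causal structure.

Emulates the statistical structure the association pipeline assumes: a few
hundred unrelated samples typed at a mix of rare (MAF < 0.01) and common
variants, a quantitative trait driven linearly by covariates and by a causal
subset of variants whose effects may point in both directions, plus
independent Gaussian noise.  Blood-pressure-style scenarios can emit two
correlated traits (SBP, DBP) sharing the genetic signal through per-trait
loadings, from which the composite MAP trait is derived downstream.

Genotypes are Hardy-Weinberg draws, Binomial(2, MAF), independent across
variants by default; an optional block-correlation mode (Gaussian copula
with a common factor per block) exists for stress tests.  Every random
element is driven by named sub-streams of one scenario seed — per-variant
streams in particular — so adding variants to a scenario never perturbs the
columns already generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import PhenotypeTable
from .genotype import GenotypeMatrix

__all__ = [
    "Covariate",
    "Scenario",
    "generate_genotypes",
    "generate_phenotype",
    "generate_dataset",
    "generate_null_dataset",
    "apply_missing",
]

# Stream labels for deterministic per-operation RNG sub-streams.
_GENO, _COVAR, _NOISE, _MISS, _BLOCK = 0, 1, 2, 3, 4


def _stream(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(p) for p in path)))


@dataclass(frozen=True)
class Covariate:
    """A covariate recipe: distribution plus its linear effect on the trait.

    ``dist`` is ``"normal"`` (params = (mean, sd)) or ``"bernoulli"``
    (params = (p,)); ``coef`` is the trait change per unit of the covariate.
    """

    name: str
    dist: str
    params: tuple
    coef: float

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size=n)
        if self.dist == "bernoulli":
            (p,) = self.params
            return rng.binomial(1, p, size=n).astype(float)
        raise ValueError(f"unknown covariate distribution {self.dist!r}")


@dataclass(frozen=True)
class Scenario:
    """A complete synthetic-data recipe.

    Attributes
    ----------
    n_samples, mafs : sample count and per-variant minor-allele frequencies
        (each in (0, 0.5]).
    causal_indices, effect_sizes : causal variant columns and their signed
        per-allele trait effects (mixed directions allowed — that mixture is
        precisely what the optimally weighted test is built for).
    covariates : tuple of :class:`Covariate`.
    intercept, noise_sd : trait baseline and residual noise SD.
    trait_loadings : None for a single trait ``y``; otherwise a mapping
        trait name -> (baseline mean, loading) producing one trait per entry
        whose genetic term is ``loading *`` the shared causal score (e.g.
        ``{"SBP": (120, 1.0), "DBP": (80, 0.6)}``), each with independent
        noise.
    missing_rate : fraction of dosages masked at random in the emitted
        genotypes (the trait is always built from the complete dosages).
    ld_blocks : optional (block_size, r) for block-correlated genotypes via
        a Gaussian copula.
    seed : master seed; identical scenarios are bit-reproducible.
    """

    n_samples: int
    mafs: tuple
    causal_indices: tuple = ()
    effect_sizes: tuple = ()
    covariates: tuple = ()
    intercept: float = 0.0
    noise_sd: float = 1.0
    trait_loadings: dict | None = None
    missing_rate: float = 0.0
    ld_blocks: tuple | None = None
    seed: int = 0
    chrom: str = "3"
    position_start: int = 10_001
    position_step: int = 500

    def __post_init__(self):
        object.__setattr__(self, "mafs", tuple(float(m) for m in self.mafs))
        object.__setattr__(self, "causal_indices", tuple(int(c) for c in self.causal_indices))
        object.__setattr__(self, "effect_sizes", tuple(float(b) for b in self.effect_sizes))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        for j, m in enumerate(self.mafs):
            if not np.isfinite(m) or not (0.0 < m <= 0.5):
                raise ValueError(
                    f"MAF for variant {j} is {m!r}; must be finite and in (0, 0.5]"
                )
        M = len(self.mafs)
        for c in self.causal_indices:
            if not (0 <= c < M):
                raise ValueError(f"causal index {c} out of range for {M} variants")
        if len(self.causal_indices) != len(self.effect_sizes):
            raise ValueError("causal_indices and effect_sizes differ in length")
        if not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_variants(self) -> int:
        return len(self.mafs)

    @property
    def trait_names(self) -> tuple:
        return ("y",) if self.trait_loadings is None else tuple(self.trait_loadings)


# ---------------------------------------------------------------------- #
def generate_genotypes(scenario: Scenario) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages, Binomial(2, MAF) per variant.

    No missingness is introduced here (see :func:`apply_missing`) and
    monomorphic columns arising by chance are kept — filtering is the region
    mapper's job.
    """
    n, M = scenario.n_samples, scenario.n_variants
    D = np.empty((n, M))
    if scenario.ld_blocks is None:
        for j in range(M):
            rng = _stream(scenario.seed, _GENO, j)
            D[:, j] = rng.binomial(2, scenario.mafs[j], size=n)
    else:
        block_size, r = scenario.ld_blocks
        if not (0.0 <= r < 1.0):
            raise ValueError("block correlation r must lie in [0, 1)")
        from scipy.stats import norm

        for j in range(M):
            block = j // block_size
            common = _stream(scenario.seed, _BLOCK, block).standard_normal(n)
            idio = _stream(scenario.seed, _GENO, j).standard_normal(n)
            z = np.sqrt(r) * common + np.sqrt(1.0 - r) * idio
            p = scenario.mafs[j]
            # genotype from copula thresholds of the HWE probabilities
            q0 = norm.ppf((1 - p) ** 2)
            q1 = norm.ppf((1 - p) ** 2 + 2 * p * (1 - p))
            D[:, j] = np.where(z <= q0, 0.0, np.where(z <= q1, 1.0, 2.0))
    pos = scenario.position_start + scenario.position_step * np.arange(M)
    return GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variant_ids=[f"var{j:04d}" for j in range(M)],
        chrom=np.full(M, scenario.chrom, dtype=object),
        pos=pos,
        dosages=D,
    )


def generate_phenotype(genotypes: GenotypeMatrix, scenario: Scenario) -> PhenotypeTable:
    """Simulate trait(s) and covariates from complete dosages.

    The linear model is ``y_i = intercept + sum_p coef_p z_ip +
    sum_{m causal} beta_m x_im + eps_i`` with independent Gaussian noise.
    The true causal labels are attached as ``table.data.attrs["causal"]``
    (a DataFrame of variant id / index / effect) for test oracles.
    """
    n = scenario.n_samples
    if genotypes.n_samples != n:
        raise ValueError("genotype sample count does not match the scenario")
    X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("phenotype generation requires complete dosages")

    cov_cols = {}
    cov_effect = np.zeros(n)
    for j, cov in enumerate(scenario.covariates):
        z = cov.draw(n, _stream(scenario.seed, _COVAR, j))
        cov_cols[cov.name] = z
        cov_effect += cov.coef * z

    genetic = np.zeros(n)
    for c, beta in zip(scenario.causal_indices, scenario.effect_sizes):
        genetic += beta * X[:, c]

    data = pd.DataFrame(index=pd.Index(genotypes.sample_ids, name="sample_id"))
    if scenario.trait_loadings is None:
        eps = _stream(scenario.seed, _NOISE, 0).normal(0.0, scenario.noise_sd, size=n)
        data["y"] = scenario.intercept + cov_effect + genetic + eps
    else:
        for t, (tname, (baseline, loading)) in enumerate(scenario.trait_loadings.items()):
            eps = _stream(scenario.seed, _NOISE, t).normal(0.0, scenario.noise_sd, size=n)
            data[tname] = baseline + cov_effect + loading * genetic + eps
    for name, z in cov_cols.items():
        data[name] = z

    table = PhenotypeTable(
        data,
        trait_cols=scenario.trait_names,
        covariate_cols=tuple(c.name for c in scenario.covariates),
    )
    table.data.attrs["causal"] = pd.DataFrame(
        {
            "variant_id": [genotypes.variant_ids[c] for c in scenario.causal_indices],
            "index": list(scenario.causal_indices),
            "effect": list(scenario.effect_sizes),
        }
    )
    return table


def apply_missing(genotypes: GenotypeMatrix, scenario: Scenario) -> GenotypeMatrix:
    """Mask ``scenario.missing_rate`` of dosages at random (own sub-stream)."""
    if scenario.missing_rate == 0.0:
        return genotypes
    rng = _stream(scenario.seed, _MISS, 0)
    mask = rng.random(genotypes.dosages.shape) < scenario.missing_rate
    D = genotypes.dosages.copy()
    D[mask] = np.nan
    out = genotypes.subset_variants(np.arange(genotypes.n_variants))
    out.dosages = D
    return out


def generate_dataset(scenario: Scenario):
    """Full recipe: genotypes (with missingness applied) plus phenotypes.

    The trait is always computed from the complete dosages; masking only
    affects the genotype matrix handed to the analysis.
    """
    gm = generate_genotypes(scenario)
    pheno = generate_phenotype(gm, scenario)
    return apply_missing(gm, scenario), pheno


def generate_null_dataset(n_samples: int, n_variants: int, seed: int):
    """A dataset with zero true association: trait = covariate + noise only.

    MAFs are drawn once from Uniform(0.005, 0.4) (a mixed rare/common
    spectrum) using a dedicated stream of ``seed``; the phenotype depends on
    one standard-normal covariate and noise but on no genotype.
    """
    maf_rng = _stream(seed, _GENO, 2**20)
    mafs = maf_rng.uniform(0.005, 0.4, size=n_variants)
    scenario = Scenario(
        n_samples=n_samples,
        mafs=tuple(mafs),
        covariates=(Covariate("z1", "normal", (0.0, 1.0), 0.5),),
        noise_sd=1.0,
        seed=seed,
    )
    gm, pheno = generate_dataset(scenario)
    return gm, pheno, scenario


# Convenience scenario builders -------------------------------------------------
def mixed_maf_spectrum(n_rare: int, n_common: int, seed: int,
                       rare_range=(0.002, 0.01), common_range=(0.05, 0.4)) -> tuple:
    """A MAF tuple with ``n_rare`` rare and ``n_common`` common variants."""
    rng = _stream(seed, _GENO, 2**20 + 1)
    rare = rng.uniform(*rare_range, size=n_rare)
    common = rng.uniform(*common_range, size=n_common)
    out = np.concatenate([rare, common])
    rng.shuffle(out)
    return tuple(out)
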