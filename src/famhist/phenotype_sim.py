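"""Liability phenotype simulation and case-control dichotomization.

Three liability models are supported, all on a latent continuous scale Y:

* ``null_model``      Y = 0.015*age + 0.45*sex + gamma + eps
* ``causal_model``    Y = sum_k beta_k g_k + 0.015*age + 0.45*sex + gamma + eps
* ``interaction_model``
                      Y = 0.02*age*sum_k beta_k g_k + sum_k beta_k g_k
                          + 0.015*age + 0.45*sex + gamma + eps

with eight causal variants at MAFs 1-50%, per-variant effects chosen so each
explains a fixed fraction of total phenotypic variance (1% in the causal
model, 0.5% in the interaction model), a polygenic component gamma with
family covariance proportional to twice the kinship matrix (individual
variance sigma_g2 = 0.2), and Gaussian residual eps. Total heritability is
0.28. Y is dichotomized at the empirical 70th percentile so the case
fraction equals the disease prevalence of 0.3 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree_sim import CohortStructure, GenotypeTable

__all__ = [
    "DEFAULT_MAFS",
    "MODEL3_SIGMA_E2",
    "PhenotypeModelConfig",
    "PhenotypeSet",
    "effect_size",
    "simulate_polygenic",
    "simulate_phenotype",
    "dichotomize",
    "realized_variance_shares",
]

DEFAULT_MAFS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

#: Residual variance of the interaction model. The nominal variance budget
#: (genotype 4% + age-by-genotype interaction 4% + age 10% + sex 5% +
#: polygenic 20%) leaves 57% for the residual, the same value as the causal
#: model. The budget treats the terms as orthogonal; because age and the
#: genotype sum are uncentered the realized Var(Y) exceeds 1 somewhat (see
#: :func:`realized_variance_shares`), which the empirical dichotomization
#: threshold absorbs.
MODEL3_SIGMA_E2 = 0.57

_MODELS = ("null_model", "causal_model", "interaction_model")


@dataclass
class PhenotypeModelConfig:
    model: str = "causal_model"
    mafs: tuple = DEFAULT_MAFS
    pve_per_snp: float | None = None  # defaults by model below
    sigma_g2: float = 0.2
    sigma_e2: float | None = None
    age_coef: float = 0.015
    sex_coef: float = 0.45
    interaction_age_coef: float = 0.02
    prevalence: float = 0.3
    h2: float = 0.28

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.pve_per_snp is None:
            self.pve_per_snp = {
                "null_model": 0.0,
                "causal_model": 0.01,
                "interaction_model": 0.005,
            }[self.model]
        if self.sigma_e2 is None:
            self.sigma_e2 = {
                "null_model": 0.65,
                "causal_model": 0.57,
                "interaction_model": MODEL3_SIGMA_E2,
            }[self.model]


@dataclass
class PhenotypeSet:
    """Continuous liability ``y``, binary status ``z`` and its components.

    ``components`` stores each additive term of the liability; their sum
    reconstructs ``y`` to machine precision.
    """

    y: np.ndarray
    z: np.ndarray | None = None
    components: dict = field(default_factory=dict)
    threshold: float | None = None


def effect_size(maf: float, pve: float) -> float:
    """Per-allele liability effect giving variance share ``pve`` under HWE.

    beta = sqrt(pve / (2 * maf * (1 - maf))), so Var(beta * g) = pve when
    Var(g) = 2*maf*(1-maf).
    """
    maf = float(maf)
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    if pve <= 0.0:
        raise ValueError("variance share must be positive")
    return float(np.sqrt(pve / (2.0 * maf * (1.0 - maf))))


def simulate_polygenic(cohort: CohortStructure, sigma_g2: float, seed) -> np.ndarray:
    """Draw the polygenic component gamma for every individual.

    Within a family gamma is multivariate normal with mean 0 and covariance
    2*phi*sigma_g2 (phi the kinship matrix), i.e. the additive numerator
    relationship matrix, so each individual has polygenic variance sigma_g2
    and parent-offspring covariance 0.5*sigma_g2. Sampling uses the exact
    recursive construction for non-inbred pedigrees: founders are
    N(0, sigma_g2) and each non-founder is the parental midvalue plus an
    independent Mendelian-segregation deviate N(0, sigma_g2 / 2).
    """
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    rng = np.random.default_rng(seed)
    gamma = np.zeros(cohort.total_n)
    if sigma_g2 == 0.0 or cohort.total_n == 0:
        return gamma
    founders = cohort.is_founder
    gamma[founders] = rng.normal(0.0, np.sqrt(sigma_g2), size=int(founders.sum()))
    for gen in range(1, int(cohort.generation.max()) + 1):
        rows = np.flatnonzero((cohort.generation == gen) & ~founders)
        if rows.size:
            mid = 0.5 * (gamma[cohort.father[rows]] + gamma[cohort.mother[rows]])
            gamma[rows] = mid + rng.normal(0.0, np.sqrt(sigma_g2 / 2.0), size=rows.size)
    return gamma


def simulate_phenotype(
    cohort: CohortStructure,
    genotypes: GenotypeTable | None,
    config: PhenotypeModelConfig,
    seed,
) -> PhenotypeSet:
    """Simulate the continuous liability Y for every cohort member.

    ``genotypes`` is required (with one column per configured MAF) unless the
    model is the null model. Age enters in years, uncentered.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_gamma, s_eps = ss.spawn(2)
    n = cohort.total_n

    comp = {}
    if config.model == "null_model":
        comp["snp"] = np.zeros(n)
        comp["interaction"] = np.zeros(n)
    else:
        if genotypes is None:
            raise ValueError("genotypes required for models with causal variants")
        g = genotypes.codes[:, : len(config.mafs)].astype(np.float64)
        if g.shape[1] != len(config.mafs) or np.any(g < 0):
            raise ValueError("every individual needs genotypes at all causal variants")
        betas = np.array([effect_size(m, config.pve_per_snp) for m in config.mafs])
        snp = g @ betas
        comp["snp"] = snp
        if config.model == "interaction_model":
            comp["interaction"] = config.interaction_age_coef * cohort.age * snp
        else:
            comp["interaction"] = np.zeros(n)

    comp["age"] = config.age_coef * cohort.age
    comp["sex"] = config.sex_coef * cohort.sex.astype(np.float64)
    comp["polygenic"] = simulate_polygenic(cohort, config.sigma_g2, s_gamma)
    comp["error"] = np.random.default_rng(s_eps).normal(
        0.0, np.sqrt(config.sigma_e2), size=n
    )
    y = comp["snp"] + comp["interaction"] + comp["age"] + comp["sex"] + comp["polygenic"] + comp["error"]
    return PhenotypeSet(y=y, components=comp)


def dichotomize(phenos: PhenotypeSet, prevalence: float) -> PhenotypeSet:
    """Assign case-control status by the empirical liability threshold.

    The round(prevalence * n) individuals with the largest Y become cases,
    so the realized case fraction equals the prevalence up to integer
    rounding in every replicate. Ties at the threshold are broken
    deterministically by individual id (higher id becomes the case).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    y = phenos.y
    n = y.shape[0]
    n_cases = int(round(prevalence * n))
    order = np.lexsort((np.arange(n), y))  # ascending Y, ties by id
    z = np.zeros(n, dtype=np.int8)
    if n_cases:
        z[order[n - n_cases :]] = 1
    phenos.z = z
    phenos.threshold = float(y[order[n - n_cases]]) if n_cases else float("inf")
    return phenos


def simulate_case_control(cohort, genotypes, config, seed) -> PhenotypeSet:
    """Convenience: simulate Y and dichotomize at the configured prevalence."""
    phenos = simulate_phenotype(cohort, genotypes, config, seed)
    return dichotomize(phenos, config.prevalence)


def realized_variance_shares(
    config: PhenotypeModelConfig | None = None,
    n_individuals: int = 200_000,
    seed: int = 20240501,
) -> dict:
    """Empirical variance share of each liability component on a large cohort.

    Simulates ``n_individuals`` (as 2/3-child nuclear families), returns
    ``{component: Var(component) / Var(Y)}`` plus ``total_variance``.
    Diagnostic for how close the realized shares come to the nominal budget
    (e.g. 1% per causal variant, 20% polygenic, 10% age, 5% sex).
    """
    from .pedigree_sim import generate_cohort, simulate_genotypes

    if config is None:
        config = PhenotypeModelConfig()
    n_fam = max(1, int(round(n_individuals / 4.5)))
    ss = np.random.SeedSequence(seed)
    s_cohort, s_geno, s_pheno = ss.spawn(3)
    cohort = generate_cohort(n_fam - n_fam // 2, n_fam // 2, s_cohort)
    genotypes = (
        None
        if config.model == "null_model"
        else simulate_genotypes(cohort, config.mafs, s_geno)
    )
    phenos = simulate_phenotype(cohort, genotypes, config, s_pheno)
    total = float(np.var(phenos.y))
    shares = {k: float(np.var(v)) / total for k, v in phenos.components.items()}
    shares["total_variance"] = total
    return shares
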