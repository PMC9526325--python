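"""Fam-meta: kinship-weighted inverse-variance meta-analysis of a proband
regression and a relatives regression.

The proband stream is exactly CC-GWAS (logistic regression of the genotyped
offspring's status on their own genotype). The relatives stream regresses an
ungenotyped relative's case-control status on the average genotype of the
family's probands, adjusting for the probands' average phenotype and the
relative's age and sex. The two coefficients are combined as

    T_meta = (beta_P / var_P + 2*phi * beta_R / var_R)
             / sqrt(1 / var_P + 4*phi^2 / var_R)

where phi is the kinship coefficient between relative and proband (0.25 for
parents, 0.125 for grandparents); 2*phi is the expected attenuation of the
genotype signal in the relatives regression, making the weights the optimal
inverse-variance weights for the common liability effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import AssociationResult, ccgwas_test, logistic_fit
from .pedigree_sim import Role

__all__ = [
    "RelativeRecords",
    "MetaResult",
    "PHI_BY_ROLE",
    "build_relative_records",
    "relative_test",
    "combine_meta",
    "fammeta_test",
]

PHI_BY_ROLE = {"parents": 0.25, "two_grandparents": 0.125, "four_grandparents": 0.125}

_GRANDPARENT_CODES = (
    Role.GRANDFATHER_PATERNAL,
    Role.GRANDMOTHER_PATERNAL,
    Role.GRANDFATHER_MATERNAL,
    Role.GRANDMOTHER_MATERNAL,
)


@dataclass
class RelativeRecords:
    """Per-relative rows for the relatives regression (column-oriented)."""

    relative_index: np.ndarray  # cohort row of the relative
    family: np.ndarray  # family id of the relative (cluster for robust SEs)
    status: np.ndarray  # relative's case-control status
    age: np.ndarray
    sex: np.ndarray
    proband_genotype_mean: np.ndarray  # (n_relatives, n_variants)
    proband_phenotype_mean: np.ndarray
    phi: float
    relative_role: str

    def __len__(self) -> int:
        return self.relative_index.shape[0]

    def to_frame(self, variant: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_id": self.relative_index,
                "relative_status": self.status,
                "relative_age": self.age,
                "relative_sex": self.sex,
                "proband_genotype_mean": self.proband_genotype_mean[:, variant],
                "proband_phenotype_mean": self.proband_phenotype_mean,
                "phi": self.phi,
            }
        )


@dataclass
class MetaResult:
    t_meta: float
    pvalue: float
    proband_result: AssociationResult
    relative_result: AssociationResult
    phi: float

    @property
    def converged(self) -> bool:
        return self.proband_result.converged and self.relative_result.converged


def build_relative_records(
    cohort, genotypes, z, relative_role: str = "parents", seed=None
) -> RelativeRecords:
    """Assemble the relatives-regression rows for one cohort.

    ``relative_role`` selects which ungenotyped relatives contribute their
    disease status: both ``parents`` (nuclear cohorts), all four grandparents,
    or one grandparent pair (paternal or maternal, chosen uniformly per
    family with ``seed``). Probands' genotypes and phenotypes are averaged
    within each family, as each relative is related to all of the family's
    probands.
    """
    if relative_role not in PHI_BY_ROLE:
        raise ValueError(f"unknown relative role {relative_role!r}")
    if relative_role == "parents":
        rel_rows = np.flatnonzero(np.isin(cohort.role, (Role.FATHER, Role.MOTHER)))
    else:
        if cohort.mode != "three_generation":
            raise ValueError("grandparent roles require a three-generation cohort")
        rel_rows = np.flatnonzero(np.isin(cohort.role, _GRANDPARENT_CODES))
        if relative_role == "two_grandparents":
            rng = np.random.default_rng(seed)
            paternal = rng.integers(0, 2, size=cohort.n_families).astype(bool)
            is_paternal = np.isin(
                cohort.role[rel_rows],
                (Role.GRANDFATHER_PATERNAL, Role.GRANDMOTHER_PATERNAL),
            )
            keep = np.where(paternal[cohort.family[rel_rows]], is_paternal, ~is_paternal)
            rel_rows = rel_rows[keep]

    z = np.asarray(z, dtype=np.float64)
    off = np.flatnonzero(cohort.is_offspring)
    fam_off = cohort.family[off]
    n_fam = cohort.n_families
    counts = np.bincount(fam_off, minlength=n_fam).astype(np.float64)
    g_off = genotypes.codes[off].astype(np.float64)
    g_sum = np.zeros((n_fam, g_off.shape[1]))
    np.add.at(g_sum, fam_off, g_off)
    g_mean = g_sum / counts[:, None]
    z_mean = np.bincount(fam_off, weights=z[off], minlength=n_fam) / counts

    fam_rel = cohort.family[rel_rows]
    return RelativeRecords(
        relative_index=rel_rows,
        family=fam_rel,
        status=z[rel_rows].astype(np.int8),
        age=cohort.age[rel_rows],
        sex=cohort.sex[rel_rows].astype(np.float64),
        proband_genotype_mean=g_mean[fam_rel],
        proband_phenotype_mean=z_mean[fam_rel],
        phi=PHI_BY_ROLE[relative_role],
        relative_role=relative_role,
    )


def relative_test(records: RelativeRecords, variant: int = 0) -> AssociationResult:
    """Logistic regression of relative status on the probands' mean genotype,
    adjusting for the probands' mean phenotype and the relative's age and
    sex; reports the mean-genotype coefficient. Standard errors are
    family-cluster robust (relatives of one family share the proband means
    and a polygenic component)."""
    X = np.column_stack(
        [
            records.proband_genotype_mean[:, variant],
            records.proband_phenotype_mean,
            records.age,
            records.sex,
        ]
    )
    return logistic_fit(records.status, X, clusters=records.family)


def combine_meta(
    beta_p: float,
    var_p: float,
    beta_r: float,
    var_r: float,
    phi: float,
    proband_result: AssociationResult | None = None,
    relative_result: AssociationResult | None = None,
) -> MetaResult:
    """Kinship-weighted inverse-variance combination of the two streams."""
    if var_p <= 0 or var_r <= 0:
        raise ValueError("variances must be positive")
    w = 2.0 * phi
    t = (beta_p / var_p + w * beta_r / var_r) / np.sqrt(1.0 / var_p + w**2 / var_r)
    p = max(2.0 * norm.sf(abs(t)), 5e-324)
    return MetaResult(
        t_meta=float(t),
        pvalue=float(p),
        proband_result=proband_result,
        relative_result=relative_result,
        phi=phi,
    )


def genetic_attenuation(
    relative_role: str = "parents",
    n_replicates: int = 130,
    seed: int = 0,
    maf_index: int = 5,
    scale: str = "liability",
) -> float:
    """Recovered attenuation of a proband's genotype signal in a relative.

    Pools many simulated cohorts (causal model) and regresses one relative
    outcome per family on a single reference proband's genotype (the
    family's first offspring), adjusting for the relative's age and sex.

    With ``scale="liability"`` the outcome is the relative's continuous
    liability and the returned value is slope / beta_true, which equals
    2*phi (0.5 for parents, 0.25 for grandparents) in expectation — the
    transmission coefficient the T_meta weight assumes. With
    ``scale="status"`` the outcome is the binary status and the ratio is
    taken to the probands' own logistic coefficient; generation-specific
    case rates compress this ratio below 2*phi (see docs), which is why the
    kinship weight is an approximation on the observed scale.
    """
    from .pedigree_sim import generate_cohort, generate_three_generation_cohort, simulate_genotypes
    from .phenotype_sim import PhenotypeModelConfig, effect_size, simulate_case_control
    from .association import linear_fit

    if relative_role not in PHI_BY_ROLE:
        raise ValueError(f"unknown relative role {relative_role!r}")
    three = relative_role != "parents"
    gen = generate_three_generation_cohort if three else generate_cohort
    cfg = PhenotypeModelConfig(model="causal_model")
    Xr, yr, cr = [], [], []
    Xp, yp, cp = [], [], []
    master = np.random.SeedSequence(seed)
    for k, rep_ss in enumerate(master.spawn(n_replicates)):
        a, b, c = rep_ss.spawn(3)
        cohort = gen(200, 200, a)
        g = simulate_genotypes(cohort, cfg.mafs, b)
        ph = simulate_case_control(cohort, g, cfg, c)
        off = np.flatnonzero(cohort.is_offspring)
        first = off[np.unique(cohort.family[off], return_index=True)[1]]
        gprob = g.codes[first, maf_index].astype(np.float64)
        if relative_role == "parents":
            rel = np.flatnonzero(np.isin(cohort.role, (Role.FATHER, Role.MOTHER)))
        else:
            rel = np.flatnonzero(np.isin(cohort.role, _GRANDPARENT_CODES))
        Xr.append(
            np.column_stack(
                [gprob[cohort.family[rel]], cohort.age[rel], cohort.sex[rel].astype(float)]
            )
        )
        cr.append(cohort.family[rel] + k * cohort.n_families)
        if scale == "status":
            yr.append(ph.z[rel])
            Xp.append(np.column_stack([gprob, cohort.age[first], cohort.sex[first].astype(float)]))
            yp.append(ph.z[first])
            cp.append(cohort.family[first] + k * cohort.n_families)
        else:
            yr.append(ph.y[rel])
    if scale == "status":
        rres = logistic_fit(np.concatenate(yr), np.vstack(Xr), clusters=np.concatenate(cr))
        pres = logistic_fit(np.concatenate(yp), np.vstack(Xp), clusters=np.concatenate(cp))
        return rres.beta / pres.beta
    res = linear_fit(np.concatenate(yr), np.vstack(Xr), clusters=np.concatenate(cr))
    return res.beta / effect_size(cfg.mafs[maf_index], cfg.pve_per_snp)


def fammeta_test(
    cohort,
    genotypes,
    z,
    variant: int,
    relative_role: str = "parents",
    adjust_covariates: bool = True,
    records: RelativeRecords | None = None,
) -> MetaResult:
    """Full Fam-meta test for one variant: CC-GWAS on the probands plus the
    relatives regression, combined with the role's kinship weight.

    Precomputed ``records`` (shared across variants of one replicate) avoid
    rebuilding the relative rows per variant. A non-converged stream yields a
    flagged MetaResult with p-value 1 (counted as a non-rejection).
    """
    pres = ccgwas_test(cohort, genotypes, z, variant, adjust_covariates)
    if records is None:
        records = build_relative_records(cohort, genotypes, z, relative_role)
    rres = relative_test(records, variant)
    if not (pres.converged and rres.converged):
        return MetaResult(np.nan, 1.0, pres, rres, records.phi)
    return combine_meta(pres.beta, pres.variance, rres.beta, rres.variance, records.phi, pres, rres)
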