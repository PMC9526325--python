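"""Pedigree structure simulation: nuclear and three-generation families.

Cohorts are held in a column-oriented :class:`CohortStructure` (numpy arrays,
one row per individual) for speed; :meth:`CohortStructure.families` yields
per-family dataclass views for inspection and export.

Age rules
---------
Each child's age is uniform on [18, 45] years; the mother is 20-45 years
older than her oldest child; the father is within five years of the mother
and at least 20 years older than the oldest child. In three-generation mode
the same rules are applied one generation up, treating each parent as the
"oldest child" of their own two parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Sex",
    "IndividualRecord",
    "FamilyStructure",
    "CohortStructure",
    "GenotypeTable",
    "generate_cohort",
    "generate_three_generation_cohort",
    "draw_founder_genotypes",
    "gene_drop",
    "kinship",
]


class Role(IntEnum):
    FATHER = 0
    MOTHER = 1
    OFFSPRING = 2
    GRANDFATHER_PATERNAL = 3
    GRANDMOTHER_PATERNAL = 4
    GRANDFATHER_MATERNAL = 5
    GRANDMOTHER_MATERNAL = 6


class Sex(IntEnum):
    """Sex coding used throughout, including regression covariates."""

    MALE = 0
    FEMALE = 1


_GRANDPARENT_ROLES = (
    Role.GRANDFATHER_PATERNAL,
    Role.GRANDMOTHER_PATERNAL,
    Role.GRANDFATHER_MATERNAL,
    Role.GRANDMOTHER_MATERNAL,
)


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: int
    family_id: int
    role: Role
    sex: Sex
    age: float
    generation: int
    father_id: int | None = None
    mother_id: int | None = None


@dataclass(frozen=True)
class FamilyStructure:
    family_id: int
    members: tuple[IndividualRecord, ...]

    @property
    def n_offspring(self) -> int:
        return sum(1 for m in self.members if m.role == Role.OFFSPRING)


@dataclass
class CohortStructure:
    """Column-oriented pedigree of all families in a simulated cohort.

    ``father`` / ``mother`` hold row indices into the cohort arrays
    (-1 for founders). Individual ids equal row indices.
    """

    family: np.ndarray  # family index per individual
    role: np.ndarray  # Role codes
    sex: np.ndarray  # Sex codes (0 male, 1 female)
    age: np.ndarray  # years
    generation: np.ndarray  # 0 = oldest generation present
    father: np.ndarray  # row index of father, -1 if founder
    mother: np.ndarray  # row index of mother, -1 if founder
    mode: str  # "nuclear" | "three_generation"
    n_families: int

    @property
    def total_n(self) -> int:
        return self.family.shape[0]

    @property
    def is_founder(self) -> np.ndarray:
        return self.father < 0

    @property
    def is_offspring(self) -> np.ndarray:
        """Probands: the youngest generation (genotyped study participants)."""
        return self.role == Role.OFFSPRING

    def family_members(self, family_id: int) -> np.ndarray:
        return np.flatnonzero(self.family == family_id)

    def families(self):
        """Yield :class:`FamilyStructure` views (slow; for inspection/export)."""
        for fid in range(self.n_families):
            idx = self.family_members(fid)
            members = tuple(
                IndividualRecord(
                    individual_id=int(i),
                    family_id=fid,
                    role=Role(int(self.role[i])),
                    sex=Sex(int(self.sex[i])),
                    age=float(self.age[i]),
                    generation=int(self.generation[i]),
                    father_id=int(self.father[i]) if self.father[i] >= 0 else None,
                    mother_id=int(self.mother[i]) if self.mother[i] >= 0 else None,
                )
                for i in idx
            )
            yield FamilyStructure(family_id=fid, members=members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": np.arange(self.total_n),
                "family_id": self.family,
                "role": [Role(r).name.lower() for r in self.role],
                "sex": self.sex,
                "age": self.age,
                "generation": self.generation,
                "father_id": self.father,
                "mother_id": self.mother,
            }
        )


@dataclass
class GenotypeTable:
    """Additive genotype codes (minor-allele counts 0/1/2).

    ``codes`` has one row per individual (aligned with the cohort) and one
    column per variant; rows for individuals without genotypes are -1.
    """

    codes: np.ndarray  # (n_individuals, n_variants) int8
    mafs: np.ndarray  # nominal founder MAF per variant
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.variant_ids:
            self.variant_ids = [f"v{i}" for i in range(self.codes.shape[1])]

    @property
    def n_variants(self) -> int:
        return self.codes.shape[1]


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_parent_ages(rng, oldest_child_age):
    """Mother 20-45 yr above the oldest child; father within 5 yr of the
    mother and >= 20 yr above the oldest child."""
    mother = oldest_child_age + rng.uniform(20.0, 45.0, size=oldest_child_age.shape)
    father = mother + rng.uniform(-5.0, 5.0, size=oldest_child_age.shape)
    # clamping preserves |father - mother| <= 5 because the clamp can only
    # trigger when mother - oldest < 25
    return mother, np.maximum(father, oldest_child_age + 20.0)


def _build_cohort(n_two_child, n_three_child, seed, three_generation):
    if n_two_child < 0 or n_three_child < 0:
        raise ValueError("family counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_fam = n_two_child + n_three_child
    n_children = np.repeat(
        np.array([2, 3], dtype=np.int64), [n_two_child, n_three_child]
    )
    fam_size = n_children + 2 + (4 if three_generation else 0)
    n_total = int(fam_size.sum())

    family = np.empty(n_total, dtype=np.int64)
    role = np.empty(n_total, dtype=np.int8)
    sex = np.empty(n_total, dtype=np.int8)
    age = np.empty(n_total, dtype=np.float64)
    generation = np.empty(n_total, dtype=np.int8)
    father = np.full(n_total, -1, dtype=np.int64)
    mother = np.full(n_total, -1, dtype=np.int64)

    child_gen = 1 if not three_generation else 2
    offset = np.concatenate(([0], np.cumsum(fam_size)))
    fa_idx = offset[:-1]  # father row per family
    mo_idx = fa_idx + 1

    for fid in range(n_fam):
        lo = offset[fid]
        family[lo : offset[fid + 1]] = fid
        role[lo] = Role.FATHER
        role[lo + 1] = Role.MOTHER
        sex[lo] = Sex.MALE
        sex[lo + 1] = Sex.FEMALE
        generation[lo : lo + 2] = child_gen - 1
        c0 = lo + 2
        ck = c0 + n_children[fid]
        role[c0:ck] = Role.OFFSPRING
        generation[c0:ck] = child_gen
        father[c0:ck] = lo
        mother[c0:ck] = lo + 1
        if three_generation:
            for j, gp_role in enumerate(_GRANDPARENT_ROLES):
                i = ck + j
                role[i] = gp_role
                sex[i] = (
                    Sex.MALE
                    if gp_role in (Role.GRANDFATHER_PATERNAL, Role.GRANDFATHER_MATERNAL)
                    else Sex.FEMALE
                )
                generation[i] = 0
            father[lo] = ck  # paternal grandfather -> father
            mother[lo] = ck + 1
            father[lo + 1] = ck + 2  # maternal grandparents -> mother
            mother[lo + 1] = ck + 3

    is_child = role == Role.OFFSPRING
    n_child_total = int(is_child.sum())
    # ages and child sexes
    child_age = rng.uniform(18.0, 45.0, size=n_child_total)
    age[is_child] = child_age
    sex[is_child] = rng.integers(0, 2, size=n_child_total, dtype=np.int8)
    if n_fam:
        oldest = np.maximum.reduceat(np.where(is_child, age, -np.inf), offset[:-1])
        mother_age, father_age = _draw_parent_ages(rng, oldest)
        age[mo_idx] = mother_age
        age[fa_idx] = father_age
        if three_generation:
            gp0 = offset[:-1] + 2 + n_children  # paternal grandfather rows
            gm_pat, gf_pat = _draw_parent_ages(rng, age[fa_idx])
            gm_mat, gf_mat = _draw_parent_ages(rng, age[mo_idx])
            age[gp0] = gf_pat
            age[gp0 + 1] = gm_pat
            age[gp0 + 2] = gf_mat
            age[gp0 + 3] = gm_mat

    return CohortStructure(
        family=family,
        role=role,
        sex=sex,
        age=age,
        generation=generation,
        father=father,
        mother=mother,
        mode="three_generation" if three_generation else "nuclear",
        n_families=n_fam,
    )


def generate_cohort(n_two_child: int, n_three_child: int, seed) -> CohortStructure:
    """Generate a nuclear-family cohort (2 parents + 2 or 3 children each).

    With the default study design of 200 two-child and 200 three-child
    families the cohort has N = 1800 individuals, of whom 1000 are offspring.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence` /
    :class:`numpy.random.Generator`.
    """
    return _build_cohort(n_two_child, n_three_child, seed, three_generation=False)


def generate_three_generation_cohort(
    n_two_child: int, n_three_child: int, seed
) -> CohortStructure:
    """Generate a three-generation cohort: each family additionally carries
    the four grandparents (two per parent); 200+200 families give N = 3400."""
    return _build_cohort(n_two_child, n_three_child, seed, three_generation=True)


# ---------------------------------------------------------------------------
# Genotypes


def draw_founder_genotypes(
    maf, founders: np.ndarray, n_individuals: int, seed, variant_ids=None
) -> GenotypeTable:
    """Draw founder genotypes under Hardy-Weinberg equilibrium.

    Minor-allele counts are i.i.d. with P(2) = maf^2, P(1) = 2*maf*(1-maf),
    P(0) = (1-maf)^2, so the expected sample minor-allele frequency equals
    ``maf``. ``maf`` may be a scalar or a vector (one entry per variant).

    Parameters
    ----------
    founders : row indices of the founder individuals.
    n_individuals : total cohort size (non-founder rows are filled with -1).
    """
    mafs = np.atleast_1d(np.asarray(maf, dtype=np.float64))
    if np.any(mafs <= 0.0) or np.any(mafs > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n_var = mafs.shape[0]
    codes = np.full((n_individuals, n_var), -1, dtype=np.int8)
    # each genotype is the sum of two independent allele draws
    draws = rng.random((founders.shape[0], n_var, 2)) < mafs[None, :, None]
    codes[founders] = draws.sum(axis=2).astype(np.int8)
    return GenotypeTable(codes=codes, mafs=mafs, variant_ids=list(variant_ids or []))


def gene_drop(cohort: CohortStructure, founder_genotypes: GenotypeTable, seed) -> GenotypeTable:
    """Fill in non-founder genotypes by Mendelian gene dropping.

    Each parent transmits one of their two alleles with equal probability;
    a heterozygote (code 1) transmits the minor allele with probability 1/2,
    homozygotes transmit deterministically. Generations are processed oldest
    first so that in three-generation cohorts parents receive genotypes from
    the grandparents before transmitting to the children.
    """
    rng = np.random.default_rng(seed)
    codes = founder_genotypes.codes.copy()
    if np.any(codes[cohort.is_founder] < 0):
        raise ValueError("every founder must have a genotype before gene dropping")
    max_gen = int(cohort.generation.max()) if cohort.total_n else 0
    for gen in range(1, max_gen + 1):
        rows = np.flatnonzero((cohort.generation == gen) & ~cohort.is_founder)
        if rows.size == 0:
            continue
        pf = codes[cohort.father[rows]].astype(np.float64)
        pm = codes[cohort.mother[rows]].astype(np.float64)
        if np.any(pf < 0) or np.any(pm < 0):
            raise ValueError("missing parental genotype during gene dropping")
        a_f = rng.random(pf.shape) < pf / 2.0
        a_m = rng.random(pm.shape) < pm / 2.0
        codes[rows] = (a_f.astype(np.int8) + a_m.astype(np.int8))
    return GenotypeTable(
        codes=codes,
        mafs=founder_genotypes.mafs,
        variant_ids=list(founder_genotypes.variant_ids),
    )


def simulate_genotypes(cohort: CohortStructure, mafs, seed) -> GenotypeTable:
    """Founder HWE draw + gene dropping in one call."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_founder, s_drop = ss.spawn(2)
    founders = np.flatnonzero(cohort.is_founder)
    founder_gt = draw_founder_genotypes(mafs, founders, cohort.total_n, s_founder)
    return gene_drop(cohort, founder_gt, s_drop)


# ---------------------------------------------------------------------------
# Kinship


def kinship_from_pedigree(father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Kinship matrix for one pedigree ordered oldest-first.

    Standard recursive kinship: phi(i,i) = 0.5 * (1 + phi(f_i, m_i)),
    phi(i,j) = 0.5 * (phi(f_i, j) + phi(m_i, j)) for i younger than j.
    Founders are non-inbred and mutually unrelated.
    """
    n = father.shape[0]
    phi = np.zeros((n, n))
    # process individuals in an order where parents precede children
    order = sorted(range(n), key=lambda i: _depth(i, father, mother))
    for i in order:
        fi, mi = father[i], mother[i]
        phi[i, i] = 0.5 if fi < 0 else 0.5 * (1.0 + phi[fi, mi])
        for j in order:
            if j == i:
                break
            if fi < 0:
                phi[i, j] = phi[j, i] = 0.0
            else:
                phi[i, j] = phi[j, i] = 0.5 * (phi[fi, j] + phi[mi, j])
    return phi


def _depth(i, father, mother):
    d = 0
    while father[i] >= 0:
        i = father[i]
        d += 1
    return d


def kinship(cohort: CohortStructure, family_id: int) -> np.ndarray:
    """Kinship matrix of one family, indexed by `cohort.family_members(family_id)`.

    Canonical coefficients: diagonal 0.5, parent-offspring and full siblings
    0.25, grandparent-grandchild 0.125, spouses 0.
    """
    idx = cohort.family_members(family_id)
    pos = {int(g): k for k, g in enumerate(idx)}
    father = np.array([pos.get(int(cohort.father[i]), -1) for i in idx])
    mother = np.array([pos.get(int(cohort.mother[i]), -1) for i in idx])
    return kinship_from_pedigree(father, mother)
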