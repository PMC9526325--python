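"""Plain-text import/export: PLINK-style PED/MAP/FAM and phenotype TSVs.

Exports use 1-based individual ids (0 = unknown parent) and PLINK sex codes
(1 = male, 2 = female). Genotype alleles are written as 'A' (major) and 'B'
(minor), so a code-2 individual is ``B B``. Missing genotypes are ``0 0``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree_sim import CohortStructure, GenotypeTable

__all__ = [
    "write_ped",
    "write_map",
    "write_fam",
    "write_phenotypes",
    "read_phenotypes",
    "read_ped",
    "export_cohort",
    "association_results_frame",
    "write_association_results",
]


def _plink_columns(cohort: CohortStructure, z=None):
    n = cohort.total_n
    pheno = np.full(n, -9, dtype=np.int64)
    if z is not None:
        pheno = np.asarray(z).astype(np.int64) + 1  # PLINK: 1 control, 2 case
    return pd.DataFrame(
        {
            "family_id": cohort.family + 1,
            "individual_id": np.arange(1, n + 1),
            "paternal_id": np.where(cohort.father >= 0, cohort.father + 1, 0),
            "maternal_id": np.where(cohort.mother >= 0, cohort.mother + 1, 0),
            "sex": np.where(cohort.sex == 0, 1, 2),
            "phenotype": pheno,
        }
    )


def write_fam(cohort: CohortStructure, path, z=None) -> None:
    _plink_columns(cohort, z).to_csv(path, sep=" ", header=False, index=False)


def write_ped(cohort: CohortStructure, genotypes: GenotypeTable, path, z=None) -> None:
    """Six PLINK columns followed by two allele columns per variant."""
    base = _plink_columns(cohort, z)
    codes = genotypes.codes
    allele1 = np.where(codes < 0, "0", np.where(codes >= 1, "B", "A"))
    allele2 = np.where(codes < 0, "0", np.where(codes == 2, "B", "A"))
    cols = {}
    for j in range(codes.shape[1]):
        cols[f"a{j}_1"] = allele1[:, j]
        cols[f"a{j}_2"] = allele2[:, j]
    pd.concat([base, pd.DataFrame(cols)], axis=1).to_csv(
        path, sep=" ", header=False, index=False
    )


def write_map(genotypes: GenotypeTable, path, chromosome: int = 1) -> None:
    """One row per variant: chrom, id, genetic distance (0), position."""
    with open(path, "w") as fh:
        for j, vid in enumerate(genotypes.variant_ids):
            fh.write(f"{chromosome} {vid} 0 {j + 1}\n")


def write_phenotypes(cohort: CohortStructure, path, phenos=None, components: bool = False) -> None:
    """Phenotype/covariate TSV: individual_id, family_id, role, age, sex, Y, Z."""
    df = cohort.to_frame()[["individual_id", "family_id", "role", "age", "sex"]].copy()
    if phenos is not None:
        df["Y"] = phenos.y
        df["Z"] = phenos.z if phenos.z is not None else np.nan
        if components:
            for name, values in phenos.components.items():
                df[f"component_{name}"] = values
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ped(path, n_variants: int | None = None):
    """Read a PED file back into a cohort skeleton + genotype codes.

    Ages are not part of the PED format and come back as NaN; roles and
    generations are reconstructed from the parent pointers (founders are
    generation 0 only when they have no recorded parents).
    Returns ``(cohort, genotype_codes)``.
    """
    raw = pd.read_csv(path, sep=r"\s+", header=None)
    n = raw.shape[0]
    fam = raw[0].to_numpy(dtype=np.int64) - 1
    iid = raw[1].to_numpy(dtype=np.int64) - 1
    pos = {int(v): k for k, v in enumerate(iid)}
    father = np.array([pos.get(int(v) - 1, -1) for v in raw[2]], dtype=np.int64)
    mother = np.array([pos.get(int(v) - 1, -1) for v in raw[3]], dtype=np.int64)
    sex = np.where(raw[4].to_numpy() == 2, 1, 0).astype(np.int8)
    pheno = raw[5].to_numpy(dtype=np.int64)
    z = np.where(pheno >= 1, pheno - 1, -9).astype(np.int8)

    generation = np.zeros(n, dtype=np.int8)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if father[i] >= 0:
                g = generation[father[i]] + 1
                if generation[i] != g:
                    generation[i] = g
                    changed = True
    max_gen = int(generation.max()) if n else 0
    role = np.where(generation == max_gen, 2, np.where(sex == 1, 1, 0)).astype(np.int8)

    cohort = CohortStructure(
        family=fam,
        role=role,
        sex=sex,
        age=np.full(n, np.nan),
        generation=generation,
        father=father,
        mother=mother,
        mode="three_generation" if max_gen >= 2 else "nuclear",
        n_families=int(fam.max()) + 1 if n else 0,
    )
    allele_cols = raw.shape[1] - 6
    k = allele_cols // 2
    if n_variants is not None and n_variants != k:
        raise ValueError(f"expected {n_variants} variants, found {k}")
    codes = np.full((n, k), -1, dtype=np.int8)
    for j in range(k):
        a1 = raw[6 + 2 * j].astype(str).to_numpy()
        a2 = raw[7 + 2 * j].astype(str).to_numpy()
        missing = (a1 == "0") | (a2 == "0")
        codes[:, j] = (a1 == "B").astype(np.int8) + (a2 == "B").astype(np.int8)
        codes[missing, j] = -1
    return cohort, codes, z


def association_results_frame(results: dict) -> pd.DataFrame:
    """Tabulate association/meta results keyed by (variant, method).

    Accepts plain Wald results and Fam-meta results (which carry the combined
    statistic plus both stream coefficients).
    """
    rows = []
    for (variant, method), res in results.items():
        if hasattr(res, "t_meta"):  # MetaResult
            p, r = res.proband_result, res.relative_result
            rows.append(
                {
                    "variant": variant,
                    "method": method,
                    "statistic": res.t_meta,
                    "pvalue": res.pvalue,
                    "beta": p.beta if p else np.nan,
                    "se": np.sqrt(p.variance) if p else np.nan,
                    "relative_beta": r.beta if r else np.nan,
                    "relative_se": np.sqrt(r.variance) if r else np.nan,
                    "phi": res.phi,
                    "converged": res.converged,
                }
            )
        else:
            rows.append(
                {
                    "variant": variant,
                    "method": method,
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "beta": res.beta,
                    "se": np.sqrt(res.variance),
                    "relative_beta": np.nan,
                    "relative_se": np.nan,
                    "phi": np.nan,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def write_association_results(results: dict, path) -> None:
    association_results_frame(results).to_csv(path, sep="\t", index=False)


def export_cohort(cohort, genotypes, phenos, out_dir, prefix: str = "cohort") -> dict:
    """Write PED + MAP + FAM + phenotype TSV into ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    z = phenos.z if phenos is not None else None
    paths = {
        "ped": out / f"{prefix}.ped",
        "map": out / f"{prefix}.map",
        "fam": out / f"{prefix}.fam",
        "phen": out / f"{prefix}.phen.tsv",
    }
    write_ped(cohort, genotypes, paths["ped"], z)
    write_map(genotypes, paths["map"])
    write_fam(cohort, paths["fam"], z)
    write_phenotypes(cohort, paths["phen"], phenos)
    return paths
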