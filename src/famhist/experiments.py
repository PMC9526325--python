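"""Power and type-I-error experiments comparing CC-GWAS, LT-FH and Fam-meta.

Each replicate re-simulates everything: family structure (ages, sexes),
founder genotypes, gene dropping, polygenic effects, the liability phenotype
and its dichotomization. Eight variants with MAFs 1-50% are tested per
replicate; under the null, eight additional variants independent of the
phenotype are generated and tested instead. Power / type-I error for a
(MAF, method) cell is the proportion of replicates whose two-sided p-value
falls below alpha, with exact (Clopper-Pearson) binomial confidence
intervals. Replicates where a method fails to converge count as
non-rejections and are reported via ``nonconvergence_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .association import ccgwas_test
from .fammeta import build_relative_records, combine_meta, relative_test
from .ltfh import LTFHConfig, build_posterior_table, ltfh_test
from .pedigree_sim import generate_cohort, generate_three_generation_cohort, simulate_genotypes
from .phenotype_sim import DEFAULT_MAFS, PhenotypeModelConfig, simulate_case_control

__all__ = [
    "ExperimentConfig",
    "run_type1",
    "run_power",
    "run_grandparent_power",
    "lambda_gc",
    "confidence_interval",
]

_CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class ExperimentConfig:
    """Settings for one simulation experiment.

    Defaults reproduce the benchmark design: 400 nuclear families (200 with
    two children, 200 with three; N = 1800, 1000 offspring), prevalence 0.3,
    heritability 0.28, eight variants at MAFs 1-50%.
    """

    model: str = "causal_model"
    methods: tuple = ("ccgwas", "ltfh", "fammeta")
    n_replicates: int = 5000
    alphas: tuple = (0.05,)
    mafs: tuple = DEFAULT_MAFS
    relative_role: str = "parents"
    master_seed: int = 1
    n_two_child: int = 200
    n_three_child: int = 200
    include_siblings: bool = False
    adjust_covariates: bool = True
    ltfh_n_mc: int = 1_000_000
    ltfh_table_cache: str | None = None
    pheno_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(not 0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError("alpha levels must lie in (0, 1]")
        unknown = set(self.methods) - {"ccgwas", "ltfh", "fammeta"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def phenotype_config(self) -> PhenotypeModelConfig:
        return PhenotypeModelConfig(model=self.model, mafs=self.mafs, **self.pheno_overrides)


def _ltfh_table(config: ExperimentConfig, pheno_cfg: PhenotypeModelConfig, seed: int):
    ltfh_cfg = LTFHConfig(
        h2=pheno_cfg.h2,
        prevalence=pheno_cfg.prevalence,
        n_mc=config.ltfh_n_mc,
        seed=seed,
    )
    max_sibs = 2 if config.include_siblings else 0
    return build_posterior_table(ltfh_cfg, max_siblings=max_sibs, cache_dir=config.ltfh_table_cache)


def _spawned_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _replicate_pvalues(config, pheno_cfg, table, rep_ss, null_variants: bool, grandparents: bool):
    """One replicate; returns {method: (pvalues, converged)} over the tested variants."""
    s_cohort, s_geno, s_pheno, s_pair = rep_ss.spawn(4)
    gen = generate_three_generation_cohort if grandparents else generate_cohort
    cohort = gen(config.n_two_child, config.n_three_child, s_cohort)

    mafs = list(config.mafs)
    n_test = len(mafs)
    if null_variants and config.model != "null_model":
        # causal block drives the phenotype; an independent null block is tested
        all_mafs = mafs + mafs
        test_slice = slice(n_test, 2 * n_test)
    else:
        all_mafs = mafs
        test_slice = slice(0, n_test)
    genotypes = simulate_genotypes(cohort, all_mafs, s_geno)
    phenos = simulate_case_control(
        cohort, None if config.model == "null_model" else genotypes, pheno_cfg, s_pheno
    )
    z = phenos.z
    test_variants = range(test_slice.start or 0, test_slice.stop or n_test)

    methods = (
        ("ccgwas", "fammeta_two_grandparents", "fammeta_four_grandparents")
        if grandparents
        else config.methods
    )
    if grandparents:
        rec_by_method = {
            "fammeta_two_grandparents": build_relative_records(
                cohort, genotypes, z, "two_grandparents", seed=_spawned_int(s_pair)
            ),
            "fammeta_four_grandparents": build_relative_records(
                cohort, genotypes, z, "four_grandparents"
            ),
        }
    elif "fammeta" in methods:
        rec_by_method = {
            "fammeta": build_relative_records(cohort, genotypes, z, config.relative_role)
        }
    else:
        rec_by_method = {}

    fammeta_methods = [m for m in methods if m.startswith("fammeta")]
    need_cc = "ccgwas" in methods or fammeta_methods
    out = {m: (np.ones(n_test), np.ones(n_test, dtype=bool)) for m in methods}
    for j, v in enumerate(test_variants):
        cc_res = (
            ccgwas_test(cohort, genotypes, z, v, config.adjust_covariates)
            if need_cc
            else None
        )
        if "ccgwas" in out:
            out["ccgwas"][0][j] = cc_res.pvalue
            out["ccgwas"][1][j] = cc_res.converged
        if "ltfh" in out:
            res = ltfh_test(
                cohort, genotypes, z, table, v,
                adjust_covariates=config.adjust_covariates,
                include_siblings=config.include_siblings,
            )
            out["ltfh"][0][j] = res.pvalue
            out["ltfh"][1][j] = res.converged
        for m in fammeta_methods:
            records = rec_by_method[m]
            rres = relative_test(records, v)
            if cc_res.converged and rres.converged:
                meta = combine_meta(
                    cc_res.beta, cc_res.variance, rres.beta, rres.variance, records.phi
                )
                out[m][0][j] = meta.pvalue
            else:
                out[m][1][j] = False
    return out


def _run(config: ExperimentConfig, null_variants: bool, grandparents: bool) -> pd.DataFrame:
    pheno_cfg = config.phenotype_config()
    master = np.random.SeedSequence(config.master_seed)
    s_table, s_reps = master.spawn(2)
    table = None
    needs_ltfh = (not grandparents) and "ltfh" in config.methods
    if needs_ltfh:
        table = _ltfh_table(config, pheno_cfg, _spawned_int(s_table))

    n_test = len(config.mafs)
    rejections = {}  # (method, alpha) -> counts per variant
    failures = {}  # method -> counts per variant
    method_names = (
        ("ccgwas", "fammeta_two_grandparents", "fammeta_four_grandparents")
        if grandparents
        else config.methods
    )
    for m in method_names:
        failures[m] = np.zeros(n_test, dtype=np.int64)
        for a in config.alphas:
            rejections[(m, a)] = np.zeros(n_test, dtype=np.int64)

    for rep_ss in s_reps.spawn(config.n_replicates):
        res = _replicate_pvalues(config, pheno_cfg, table, rep_ss, null_variants, grandparents)
        for m, (pvals, conv) in res.items():
            failures[m] += ~conv
            for a in config.alphas:
                rejections[(m, a)] += (pvals < a) & conv

    rows = []
    R = config.n_replicates
    for a in config.alphas:
        cc = rejections.get(("ccgwas", a))
        for m in method_names:
            rej = rejections[(m, a)]
            for j, maf in enumerate(config.mafs):
                lo, hi = confidence_interval(int(rej[j]), R, 0.95)
                rows.append(
                    {
                        "maf": maf,
                        "method": m,
                        "alpha": a,
                        "power": rej[j] / R,
                        "ci_low": lo,
                        "ci_high": hi,
                        "increase_over_ccgwas": (rej[j] - cc[j]) / R if cc is not None and m != "ccgwas" else (0.0 if m == "ccgwas" else np.nan),
                        "nonconvergence_rate": failures[m][j] / R,
                        "n_replicates": R,
                    }
                )
    return pd.DataFrame(rows)


def run_type1(config: ExperimentConfig | None = None, **kwargs) -> pd.DataFrame:
    """Type-I error: test variants simulated independently of the phenotype.

    Defaults to the null phenotype model at alphas 5%, 1% and 0.5%. For the
    causal models the eight causal variants still shape the phenotype while
    an independent batch of eight null variants is tested.
    """
    if config is None:
        kwargs.setdefault("model", "null_model")
        kwargs.setdefault("alphas", (0.05, 0.01, 0.005))
        config = ExperimentConfig(**kwargs)
    return _run(config, null_variants=True, grandparents=False)


def run_power(config: ExperimentConfig | None = None, **kwargs) -> pd.DataFrame:
    """Power: test the eight causal variants at alpha = 5% (by default)."""
    if config is None:
        config = ExperimentConfig(**kwargs)
    if config.model == "null_model":
        raise ValueError("power runs need a model with causal variants")
    return _run(config, null_variants=False, grandparents=False)


def run_grandparent_power(config: ExperimentConfig | None = None, **kwargs) -> pd.DataFrame:
    """Power with grandparents as the family history source.

    Uses the three-generation cohort (N = 3400): CC-GWAS on the grandchildren
    (n = 1000), Fam-meta with either all four grandparents (n = 1600) or one
    randomly selected grandparent pair per family (n = 800). LT-FH is not run
    (it models first-degree relatives only).
    """
    if config is None:
        kwargs.setdefault("model", "causal_model")
        config = ExperimentConfig(**kwargs)
    if config.model == "null_model":
        raise ValueError("power runs need a model with causal variants")
    return _run(config, null_variants=False, grandparents=True)


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation factor: median 1-df chi-square implied by
    the p-values divided by the null chi-square median (0.4549)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / _CHI2_1_MEDIAN)


def confidence_interval(successes: int, trials: int, level: float = 0.95):
    """Clopper-Pearson exact binomial confidence interval."""
    if not 0 <= successes <= trials or trials <= 0:
        raise ValueError("need 0 <= successes <= trials with trials > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(beta_dist.ppf(a, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(beta_dist.ppf(1.0 - a, successes + 1, trials - successes))
    return lo, hi
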