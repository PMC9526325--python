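"""LT-FH: association testing on posterior mean genetic liabilities.

Under the liability threshold model an individual's liability splits into an
environmental part e_env ~ N(0, 1 - h2) and a genetic part e_gen ~ N(0, h2);
disease status is liability > t with t the upper-prevalence standard-normal
quantile. The genetic liabilities of first-degree relatives have covariance
0.5*h2 with the index individual's e_gen and with each other, while the
relatives' total liabilities have unit variance.

LT-FH replaces the binary status with E[e_gen | own status, parents'
statuses, siblings' statuses], estimated once per (h2, prevalence) by Monte
Carlo integration over the joint multivariate normal and cached in a lookup
table; the association test is then an ordinary linear regression of this
score on genotype.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import AssociationResult, linear_fit

__all__ = [
    "LTFHConfig",
    "FHConfiguration",
    "PosteriorLiabilityTable",
    "liability_threshold",
    "build_posterior_table",
    "posterior_liability",
    "ltfh_scores",
    "ltfh_test",
]


@dataclass(frozen=True)
class LTFHConfig:
    h2: float = 0.28
    prevalence: float = 0.3
    n_mc: int = 1_000_000
    seed: int = 2024

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_mc < 100_000:
            raise ValueError("n_mc must be at least 1e5 for stable table cells")


@dataclass(frozen=True)
class FHConfiguration:
    """One family-history configuration.

    Parents and siblings are exchangeable under the model, so only the
    numbers observed and affected matter. ``n_parents_observed`` < 2 means
    the remaining parents' statuses are missing and marginalized over.
    """

    own_status: int
    n_parents_observed: int = 2
    n_affected_parents: int = 0
    n_siblings: int = 0
    n_affected_siblings: int = 0

    def __post_init__(self):
        if self.own_status not in (0, 1):
            raise ValueError("own_status must be 0 or 1")
        if not 0 <= self.n_parents_observed <= 2:
            raise ValueError("n_parents_observed must be 0, 1 or 2")
        if not 0 <= self.n_affected_parents <= self.n_parents_observed:
            raise ValueError("more affected parents than observed")
        if not 0 <= self.n_affected_siblings <= self.n_siblings:
            raise ValueError("more affected siblings than observed")


@dataclass
class PosteriorLiabilityTable:
    """Posterior mean genetic liability per family-history configuration.

    ``score``, ``se`` and ``prob`` are indexed
    ``[own, n_par_obs, n_aff_par, n_sib, n_aff_sib]``; invalid index
    combinations are NaN. ``prob`` is the Monte-Carlo estimate of the
    configuration probability under the model.
    """

    config: LTFHConfig
    max_siblings: int
    score: np.ndarray
    se: np.ndarray
    prob: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for own in (0, 1):
            for npo in range(3):
                for nap in range(npo + 1):
                    for ns in range(self.max_siblings + 1):
                        for nas in range(ns + 1):
                            rows.append(
                                {
                                    "own_status": own,
                                    "n_parents_observed": npo,
                                    "n_affected_parents": nap,
                                    "n_siblings": ns,
                                    "n_affected_siblings": nas,
                                    "posterior_mean_genetic_liability": self.score[own, npo, nap, ns, nas],
                                    "mc_se": self.se[own, npo, nap, ns, nas],
                                    "config_probability": self.prob[own, npo, nap, ns, nas],
                                }
                            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: LTFHConfig, max_siblings: int):
        shape = (2, 3, 3, max_siblings + 1, max_siblings + 1)
        score = np.full(shape, np.nan)
        se = np.full(shape, np.nan)
        prob = np.full(shape, np.nan)
        for row in df.itertuples(index=False):
            key = (
                int(row.own_status),
                int(row.n_parents_observed),
                int(row.n_affected_parents),
                int(row.n_siblings),
                int(row.n_affected_siblings),
            )
            score[key] = row.posterior_mean_genetic_liability
            se[key] = row.mc_se
            prob[key] = row.config_probability
        return cls(config=config, max_siblings=max_siblings, score=score, se=se, prob=prob)


def liability_threshold(prevalence: float) -> float:
    """Standard-normal threshold above which a fraction ``prevalence`` lies."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    return float(norm.isf(prevalence))


def _liability_covariance(h2: float, max_siblings: int) -> np.ndarray:
    """Joint covariance of (e_env, e_gen, parent1, parent2, sib_1..sib_k).

    Parents and siblings enter with their total (unit-variance) liabilities;
    each relative's covariance with e_gen and each sibling-sibling /
    parent-sibling covariance is 0.5*h2; the two parents are uncorrelated.
    """
    k = max_siblings
    dim = 4 + k
    cov = np.zeros((dim, dim))
    cov[0, 0] = 1.0 - h2
    cov[1, 1] = h2
    half = 0.5 * h2
    for r in range(2, dim):
        cov[r, r] = 1.0
        cov[1, r] = cov[r, 1] = half
    for i in range(4, dim):  # sibling rows
        cov[2, i] = cov[i, 2] = half
        cov[3, i] = cov[i, 3] = half
        for j in range(4, i):
            cov[i, j] = cov[j, i] = half
    return cov


def _cache_key(config: LTFHConfig, max_siblings: int) -> str:
    raw = f"{config.h2}:{config.prevalence}:{config.n_mc}:{config.seed}:{max_siblings}"
    return hashlib.sha1(raw.encode()).hexdigest()[:16]


def build_posterior_table(
    config: LTFHConfig,
    max_siblings: int = 2,
    cache_dir: str | Path | None = None,
) -> PosteriorLiabilityTable:
    """Monte-Carlo estimate of E[e_gen | configuration] for every
    configuration with up to 2 parents and ``max_siblings`` siblings.

    Draws ``config.n_mc`` joint samples from the liability MVN, converts
    each relative's liability to a status via the threshold, and averages
    e_gen over the samples matching each configuration (rejection sampling;
    unbiased). Configurations with no matching samples get NaN scores.

    With ``cache_dir`` set, the table is persisted as a TSV keyed by
    (h2, prevalence, n_mc, seed, max_siblings) and reloaded on repeat calls.
    """
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"ltfh_table_{_cache_key(config, max_siblings)}.tsv"
        if cache_path.exists():
            df = pd.read_csv(cache_path, sep="\t")
            return PosteriorLiabilityTable.from_frame(df, config, max_siblings)

    t = liability_threshold(config.prevalence)
    cov = _liability_covariance(config.h2, max_siblings)
    rng = np.random.default_rng(config.seed)
    draws = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=config.n_mc, method="cholesky")
    e_gen = draws[:, 1]
    own_case = (draws[:, 0] + draws[:, 1]) > t
    parent_case = draws[:, 2:4] > t
    sib_case = draws[:, 4:] > t
    n_aff_p1 = parent_case[:, 0].astype(np.int64)
    n_aff_both = parent_case.sum(axis=1)
    sib_counts = np.column_stack(
        [np.zeros(config.n_mc, dtype=np.int64)]
        + [sib_case[:, :k].sum(axis=1) for k in range(1, max_siblings + 1)]
    )

    shape = (2, 3, 3, max_siblings + 1, max_siblings + 1)
    score = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    prob = np.full(shape, np.nan)
    for own in (0, 1):
        m_own = own_case == own
        for npo in range(3):
            for nap in range(npo + 1):
                if npo == 0:
                    m_par = np.ones(config.n_mc, dtype=bool)
                elif npo == 1:
                    m_par = n_aff_p1 == nap  # parents exchangeable: condition on p1
                else:
                    m_par = n_aff_both == nap
                m_op = m_own & m_par
                for ns in range(max_siblings + 1):
                    counts = sib_counts[:, ns]
                    for nas in range(ns + 1):
                        m = m_op & (counts == nas) if ns else m_op
                        vals = e_gen[m]
                        if vals.size == 0:
                            continue
                        score[own, npo, nap, ns, nas] = vals.mean()
                        se[own, npo, nap, ns, nas] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                        prob[own, npo, nap, ns, nas] = vals.size / config.n_mc

    table = PosteriorLiabilityTable(config=config, max_siblings=max_siblings, score=score, se=se, prob=prob)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(cache_path, sep="\t", index=False)
    return table


def posterior_liability(table: PosteriorLiabilityTable, fh: FHConfiguration) -> float:
    """Exact table lookup of the posterior mean genetic liability."""
    if fh.n_siblings > table.max_siblings:
        raise KeyError(
            f"configuration with {fh.n_siblings} siblings exceeds the table's "
            f"max_siblings={table.max_siblings}"
        )
    val = table.score[
        fh.own_status,
        fh.n_parents_observed,
        fh.n_affected_parents,
        fh.n_siblings,
        fh.n_affected_siblings,
    ]
    if np.isnan(val):
        raise KeyError(f"no Monte-Carlo mass in table cell for {fh}")
    return float(val)


def ltfh_scores(
    cohort,
    z: np.ndarray,
    table: PosteriorLiabilityTable,
    include_siblings: bool = False,
) -> np.ndarray:
    """Posterior mean genetic liability for every offspring (proband).

    Each offspring's configuration uses their own status and both parents'
    statuses; with ``include_siblings=True`` the statuses of the family's
    other children additionally enter as sibling history. Parents-only is
    the default: sibling scores within a family are otherwise so strongly
    correlated (sharing the parents' and each other's statuses) that a
    family-clustered regression cannot recover the extra information.
    """
    z = np.asarray(z)
    rows = np.flatnonzero(cohort.is_offspring)
    own = z[rows].astype(np.int64)
    n_aff_par = z[cohort.father[rows]].astype(np.int64) + z[cohort.mother[rows]].astype(np.int64)
    if include_siblings:
        # per family: number of children and affected children
        fam = cohort.family[rows]
        n_fam = cohort.n_families
        kids = np.bincount(fam, minlength=n_fam)
        aff_kids = np.bincount(fam, weights=own.astype(np.float64), minlength=n_fam).astype(np.int64)
        n_sib = kids[fam] - 1
        n_aff_sib = aff_kids[fam] - own
    else:
        n_sib = np.zeros(rows.size, dtype=np.int64)
        n_aff_sib = n_sib
    scores = table.score[own, 2, n_aff_par, n_sib, n_aff_sib]
    if np.any(np.isnan(scores)):
        bad = np.flatnonzero(np.isnan(scores))[0]
        raise KeyError(
            "no table cell for configuration "
            f"(own={own[bad]}, affected_parents={n_aff_par[bad]}, "
            f"siblings={n_sib[bad]}, affected_siblings={n_aff_sib[bad]})"
        )
    return scores


def ltfh_test(
    cohort,
    genotypes,
    z,
    table: PosteriorLiabilityTable,
    variant: int,
    adjust_covariates: bool = True,
    include_siblings: bool = False,
) -> AssociationResult:
    """LT-FH association test: linear regression of the posterior mean
    genetic liability on offspring genotype, adjusting for age and sex.

    Sibling scores share the parents' statuses and are strongly correlated,
    so the Wald variance is family-cluster robust.
    """
    scores = ltfh_scores(cohort, z, table, include_siblings=include_siblings)
    rows = np.flatnonzero(cohort.is_offspring)
    g = genotypes.codes[rows, variant].astype(np.float64)
    if np.ptp(scores) == 0.0:
        return AssociationResult.failed(rows.size)
    if adjust_covariates:
        X = np.column_stack([g, cohort.age[rows], cohort.sex[rows].astype(np.float64)])
    else:
        X = g[:, None]
    # the working correlation is bounded by the additive-kinship structure
    # a family mixed model can represent for full siblings (<= 0.5)
    return linear_fit(scores, X, clusters=cohort.family[rows], max_rho=0.5)
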