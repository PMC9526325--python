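"""Pedigree structures, age rules, HWE founders, gene dropping, kinship."""

import numpy as np
import pytest

import famhist as fh
from famhist.pedigree_sim import (
    Role,
    draw_founder_genotypes,
    gene_drop,
    kinship,
    kinship_from_pedigree,
)


class TestCohortStructure:
    def test_default_nuclear_design_sizes(self, nuclear_cohort):
        assert nuclear_cohort.total_n == 1800
        assert nuclear_cohort.n_families == 400
        assert int(nuclear_cohort.is_offspring.sum()) == 1000
        # 200 two-child + 200 three-child families
        kids = np.bincount(nuclear_cohort.family[nuclear_cohort.is_offspring])
        assert sorted(np.bincount(kids).tolist()) == [0, 0, 200, 200]

    def test_three_generation_design_sizes(self, three_gen_cohort):
        assert three_gen_cohort.total_n == 3400
        gp = np.isin(
            three_gen_cohort.role,
            (
                Role.GRANDFATHER_PATERNAL,
                Role.GRANDMOTHER_PATERNAL,
                Role.GRANDFATHER_MATERNAL,
                Role.GRANDMOTHER_MATERNAL,
            ),
        )
        per_family = np.bincount(three_gen_cohort.family[gp])
        assert np.all(per_family == 4)

    def test_single_family_three_generation_size(self):
        cohort = fh.generate_three_generation_cohort(1, 0, seed=5)
        assert cohort.total_n == 8  # 4 grandparents + 2 parents + 2 children

    def test_empty_cohort(self):
        cohort = fh.generate_cohort(0, 0, seed=1)
        assert cohort.total_n == 0

    def test_age_rules_hold_in_every_family(self):
        """Exhaustive scan of the four generation/age rules on 1000 families."""
        cohort = fh.generate_cohort(1000, 0, seed=42)
        for lo in range(0, cohort.total_n, 4):
            father, mother = cohort.age[lo], cohort.age[lo + 1]
            children = cohort.age[lo + 2 : lo + 4]
            oldest = children.max()
            eps = 1e-9  # clamped draws can sit on a bound to rounding error
            assert np.all((children >= 18.0 - eps) & (children <= 45.0 + eps))
            assert 20.0 - eps <= mother - oldest <= 45.0 + eps
            assert abs(father - mother) <= 5.0 + eps
            assert father - oldest >= 20.0 - eps

    def test_grandparent_ages_follow_parent_rules(self, three_gen_cohort):
        c = three_gen_cohort
        for fam in range(0, 50):
            idx = c.family_members(fam)
            by_role = {Role(int(c.role[i])): c.age[i] for i in idx if c.role[i] != Role.OFFSPRING}
            for gm, gf, parent in (
                (Role.GRANDMOTHER_PATERNAL, Role.GRANDFATHER_PATERNAL, Role.FATHER),
                (Role.GRANDMOTHER_MATERNAL, Role.GRANDFATHER_MATERNAL, Role.MOTHER),
            ):
                eps = 1e-9
                assert 20.0 - eps <= by_role[gm] - by_role[parent] <= 45.0 + eps
                assert abs(by_role[gf] - by_role[gm]) <= 5.0 + eps
                assert by_role[gf] - by_role[parent] >= 20.0 - eps

    def test_seed_reproducibility(self):
        a = fh.generate_cohort(50, 50, seed=9)
        b = fh.generate_cohort(50, 50, seed=9)
        assert np.array_equal(a.age, b.age)
        assert np.array_equal(a.sex, b.sex)


class TestGenotypes:
    def test_founder_hwe_frequencies(self):
        cohort = fh.generate_cohort(0, 0, seed=1)
        founders = np.arange(100_000)
        gt = draw_founder_genotypes(0.1, founders, 100_000, seed=3)
        freq = gt.codes.mean() / 2.0
        se = np.sqrt(0.1 * 0.9 / (2 * 100_000))
        assert abs(freq - 0.1) < 3 * se
        counts = np.bincount(gt.codes[:, 0], minlength=3) / 100_000
        assert np.allclose(counts, [0.81, 0.18, 0.01], atol=0.01)

    def test_symmetric_maf_genotype_distribution(self):
        gt = draw_founder_genotypes(0.5, np.arange(60_000), 60_000, seed=4)
        counts = np.bincount(gt.codes[:, 0], minlength=3) / 60_000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    @pytest.mark.parametrize("bad_maf", [0.0, -0.1, 0.6])
    def test_invalid_maf_rejected(self, bad_maf):
        with pytest.raises(ValueError):
            draw_founder_genotypes(bad_maf, np.arange(10), 10, seed=1)

    def test_homozygous_parents_force_heterozygous_child(self):
        cohort = fh.generate_cohort(200, 0, seed=6)
        codes = np.full((cohort.total_n, 1), -1, dtype=np.int8)
        fathers = cohort.role == Role.FATHER
        mothers = cohort.role == Role.MOTHER
        codes[fathers] = 2
        codes[mothers] = 0
        gt = gene_drop(cohort, fh.GenotypeTable(codes, np.array([0.5])), seed=7)
        assert np.all(gt.codes[cohort.is_offspring] == 1)

    def test_het_by_het_cross_segregates_one_quarter_half_quarter(self):
        cohort = fh.generate_cohort(5000, 0, seed=8)
        codes = np.full((cohort.total_n, 1), -1, dtype=np.int8)
        codes[~cohort.is_offspring] = 1
        gt = gene_drop(cohort, fh.GenotypeTable(codes, np.array([0.5])), seed=9)
        counts = np.bincount(gt.codes[cohort.is_offspring][:, 0], minlength=3) / 10_000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_allele_frequency_conserved_across_generations(self, three_gen_cohort):
        gt = fh.simulate_genotypes(three_gen_cohort, [0.2], seed=10)
        founder_freq = gt.codes[three_gen_cohort.is_founder].mean() / 2
        child_freq = gt.codes[three_gen_cohort.is_offspring].mean() / 2
        # binomial SE for 1000 offspring
        assert abs(child_freq - founder_freq) < 3 * np.sqrt(0.2 * 0.8 / 2000)

    def test_mendelian_consistency(self, causal_sim, nuclear_cohort):
        genotypes, _, _ = causal_sim
        c = nuclear_cohort
        kids = np.flatnonzero(c.is_offspring)
        gk = genotypes.codes[kids]
        gf = genotypes.codes[c.father[kids]]
        gm = genotypes.codes[c.mother[kids]]
        # each parent transmits one allele: a homozygous-minor parent forces a
        # minor allele, a parent without minor alleles cannot transmit one
        assert np.all(gk >= (gf == 2).astype(int) + (gm == 2).astype(int))
        assert np.all(gk <= (gf > 0).astype(int) + (gm > 0).astype(int))

    def test_missing_founder_genotype_raises(self, nuclear_cohort):
        codes = np.full((nuclear_cohort.total_n, 1), -1, dtype=np.int8)
        with pytest.raises(ValueError):
            gene_drop(nuclear_cohort, fh.GenotypeTable(codes, np.array([0.1])), seed=1)


class TestKinship:
    def test_nuclear_family_coefficients(self, nuclear_cohort):
        phi = kinship(nuclear_cohort, 0)
        m = phi.shape[0]
        assert np.allclose(np.diag(phi), 0.5)
        assert phi[0, 1] == 0.0  # spouses
        for child in range(2, m):
            assert phi[0, child] == 0.25 and phi[1, child] == 0.25
        for c1 in range(2, m):
            for c2 in range(c1 + 1, m):
                assert phi[c1, c2] == 0.25  # full siblings
        assert np.allclose(phi, phi.T)
        assert np.all(np.linalg.eigvalsh(phi) > -1e-12)

    def test_grandparent_grandchild_coefficient(self, three_gen_cohort):
        c = three_gen_cohort
        phi = kinship(c, 0)
        idx = c.family_members(0)
        pos = {int(g): k for k, g in enumerate(idx)}
        child = next(int(i) for i in idx if c.role[i] == Role.OFFSPRING)
        gp = next(int(i) for i in idx if c.role[i] == Role.GRANDFATHER_PATERNAL)
        assert phi[pos[child], pos[gp]] == 0.125

    def test_kinship_matches_monte_carlo_ibd_sharing(self):
        """phi equals half the expected IBD sharing at one biallelic locus,
        estimated by brute-force gene dropping of distinct founder alleles."""
        rng = np.random.default_rng(11)
        # 3-generation pedigree: 4 grandparents, 2 parents, 2 children
        father = np.array([-1, -1, -1, -1, 0, 2, 4, 4])
        mother = np.array([-1, -1, -1, -1, 1, 3, 5, 5])
        n = father.shape[0]
        n_rep = 40_000
        alleles = np.zeros((n_rep, n, 2), dtype=np.int64)
        founder_label = np.arange(8).reshape(4, 2)
        for i in range(4):
            alleles[:, i] = founder_label[i]
        for i in range(4, n):
            pick_f = rng.integers(0, 2, n_rep)
            pick_m = rng.integers(0, 2, n_rep)
            alleles[:, i, 0] = alleles[np.arange(n_rep), father[i], pick_f]
            alleles[:, i, 1] = alleles[np.arange(n_rep), mother[i], pick_m]
        phi = kinship_from_pedigree(father, mother)
        for i, j in [(4, 6), (0, 6), (6, 7), (0, 4), (4, 5), (0, 1)]:
            # P(random allele from i IBD to random allele from j)
            same = (
                alleles[:, i, :, None] == alleles[:, j, None, :]
            ).mean()
            assert phi[i, j] == pytest.approx(same, abs=0.01)
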