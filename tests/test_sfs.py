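import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfs2d import (JointSFS, PopMap, allele_counts, build_jsfs,
                   choose_projection, diversity_stats, filter_genotypes,
                   fold, project_counts)
from sfs2d.containers import MISSING

from conftest import make_matrix, random_jsfs


class TestFilterGenotypes:
    def test_low_and_unknown_depth_set_missing(self):
        gm = make_matrix([[0, 1, 2]], depths=[[9, 10, -1]])
        out = filter_genotypes(gm, max_missing_frac=1.0, min_depth=10,
                               max_obs_het=1.0, one_snp_per_locus=False)
        assert out.genotypes[0, 0] == MISSING   # depth 9 < 10
        assert out.genotypes[0, 1] == 1         # depth exactly 10 passes
        assert out.genotypes[0, 2] == MISSING   # unknown depth fails

    def test_missingness_threshold(self):
        # 5 of 10 genotypes missing: 0.5 > 0.4 -> removed
        row = [0, 1, 2, 0, 1] + [MISSING] * 5
        gm = make_matrix([row, [0] * 9 + [1]])
        out = filter_genotypes(gm, max_missing_frac=0.4, min_depth=0,
                               max_obs_het=1.0, one_snp_per_locus=False)
        assert out.n_sites == 1

    def test_all_het_site_removed_as_paralog(self):
        gm = make_matrix([[1, 1, 1, 1], [0, 1, 2, 0]])
        out = filter_genotypes(gm, max_missing_frac=1.0, min_depth=0,
                               max_obs_het=0.65, one_snp_per_locus=False)
        assert out.n_sites == 1
        assert out.locus[0] == "loc1"

    def test_one_snp_per_locus_keeps_lowest_position(self):
        # 10 loci x 3 SNPs each -> 10 survivors, each the first by position
        geno, loci, pos = [], [], []
        for l in range(10):
            for snp, p in enumerate((37, 12, 90)):
                geno.append([0, 1, 0, 1])
                loci.append(f"locus{l}")
                pos.append(p)
        gm = make_matrix(geno, loci=loci, pos=pos)
        out = filter_genotypes(gm, max_missing_frac=1.0, min_depth=0,
                               max_obs_het=1.0, one_snp_per_locus=True)
        assert out.n_sites == 10
        assert all(p == 12 for p in out.pos)

    def test_empty_output_is_legal(self):
        gm = make_matrix([[1, 1, 1, 1]])
        out = filter_genotypes(gm, max_missing_frac=1.0, min_depth=0,
                               max_obs_het=0.5, one_snp_per_locus=True)
        assert out.n_sites == 0


class TestAlleleCounts:
    def test_simple_tally(self, two_pop_map):
        gm = make_matrix([[0, 1, 2, 2]])
        alt, called = allele_counts(gm, two_pop_map, "pop1")
        assert (alt[0], called[0]) == (1, 4)
        alt, called = allele_counts(gm, two_pop_map, "pop2")
        assert (alt[0], called[0]) == (4, 4)

    def test_all_missing_site(self, two_pop_map):
        gm = make_matrix([[MISSING, MISSING, 0, 0]])
        alt, called = allele_counts(gm, two_pop_map, "pop1")
        assert (alt[0], called[0]) == (0, 0)

    def test_brute_force_recount(self, two_pop_map):
        rng = np.random.default_rng(42)
        geno = rng.integers(-1, 3, size=(50, 4))
        gm = make_matrix(geno)
        alt, called = allele_counts(gm, two_pop_map, "pop2")
        for s in range(50):
            manual_alt = sum(g for g in geno[s, 2:4] if g >= 0)
            manual_called = 2 * sum(1 for g in geno[s, 2:4] if g >= 0)
            assert alt[s] == manual_alt and called[s] == manual_called

    def test_unknown_population_rejected(self, two_pop_map):
        gm = make_matrix([[0, 0, 0, 0]])
        with pytest.raises(KeyError):
            allele_counts(gm, two_pop_map, "atlantis")


class TestProjectCounts:
    def test_identity_projection(self):
        v = project_counts(3, 6, 6)
        assert np.allclose(v, np.eye(7)[3])

    def test_monomorphic_input(self):
        assert np.allclose(project_counts(0, 8, 4), np.eye(5)[0])

    def test_enumeration_example(self):
        # (i=2, n=4, n_proj=2): all C(4,2) subsamples give (1/6, 4/6, 1/6)
        assert np.allclose(project_counts(2, 4, 2), [1 / 6, 4 / 6, 1 / 6])

    @pytest.mark.parametrize("n", range(1, 9))
    def test_exhaustive_enumeration_oracle(self, n):
        """Hypergeometric projection equals brute-force subsample counting
        for every (i, n <= 8, n_proj <= 6)."""
        for n_proj in range(1, min(n, 6) + 1):
            for i in range(n + 1):
                alleles = [1] * i + [0] * (n - i)
                tally = np.zeros(n_proj + 1)
                for combo in itertools.combinations(range(n), n_proj):
                    tally[sum(alleles[c] for c in combo)] += 1
                expected = tally / math.comb(n, n_proj)
                assert np.allclose(project_counts(i, n, n_proj), expected)

    def test_projection_larger_than_sample_rejected(self):
        with pytest.raises(ValueError):
            project_counts(1, 4, 6)


class TestBuildJSFS:
    def test_unit_mass_single_site(self, two_pop_map):
        gm = make_matrix([[1, MISSING, 0, 0]])
        sfs = build_jsfs(gm, two_pop_map, "pop1", "pop2", 2, 2,
                         fold_spectrum=False)
        assert sfs.counts[1, 0] == pytest.approx(1.0)
        assert sfs.sum() == pytest.approx(1.0)

    def test_insufficient_alleles_excluded(self, two_pop_map):
        gm = make_matrix([[1, MISSING, 0, 0]])
        sfs = build_jsfs(gm, two_pop_map, "pop1", "pop2", 4, 2,
                         fold_spectrum=False)
        assert sfs.sum() == pytest.approx(0.0)

    def test_full_projection_equals_direct_histogram(self, two_pop_map):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(60, 4))
        gm = make_matrix(geno)
        sfs = build_jsfs(gm, two_pop_map, "pop1", "pop2", 4, 4,
                         fold_spectrum=False)
        direct = np.zeros((5, 5))
        for s in range(60):
            direct[geno[s, :2].sum(), geno[s, 2:].sum()] += 1
        direct[0, 0] = direct[4, 4] = 0
        assert np.allclose(sfs.counts, direct)

    def test_monte_carlo_subsampling_oracle(self, two_pop_map):
        """Projected spectrum equals the mean over random allele subsamples."""
        rng = np.random.default_rng(11)
        geno = rng.integers(0, 3, size=(20, 4))
        gm = make_matrix(geno)
        n1 = n2 = 2
        sfs = build_jsfs(gm, two_pop_map, "pop1", "pop2", n1, n2,
                         fold_spectrum=False)
        ndraw = 100_000
        acc = np.zeros((n1 + 1, n2 + 1))
        sq = np.zeros_like(acc)
        for s in range(20):
            a1, a2 = geno[s, :2].sum(), geno[s, 2:].sum()
            pool1 = np.array([1] * a1 + [0] * (4 - a1))
            pool2 = np.array([1] * a2 + [0] * (4 - a2))
            cell = np.zeros_like(acc)
            i = rng.permuted(np.broadcast_to(pool1, (ndraw, 4)), axis=1)[:, :n1].sum(axis=1)
            j = rng.permuted(np.broadcast_to(pool2, (ndraw, 4)), axis=1)[:, :n2].sum(axis=1)
            np.add.at(cell, (i, j), 1.0)
            acc += cell / ndraw
            sq += (cell / ndraw) * (1 - cell / ndraw) / ndraw
        se = np.sqrt(sq)
        masked = sfs.mask
        diff = np.abs(sfs.counts - acc)
        assert np.all(diff[~masked] <= 3 * se[~masked] + 1e-9)

    def test_same_population_twice_rejected(self, two_pop_map):
        gm = make_matrix([[0, 0, 0, 0]])
        with pytest.raises(ValueError):
            build_jsfs(gm, two_pop_map, "pop1", "pop1", 2, 2)


class TestFold:
    def test_complement_cell_example(self):
        # n1 = n2 = 2: cell (2,1) folds into (0,1)
        counts = np.zeros((3, 3))
        counts[2, 1] = 5.0
        folded = fold(JointSFS(counts))
        assert folded.counts[0, 1] == pytest.approx(5.0)
        assert folded.mask[2, 1]

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10 ** 6))
    def test_mass_conserved_and_idempotent(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        sfs = random_jsfs(rng, n1, n2)
        folded = fold(sfs)
        assert folded.sum() == pytest.approx(sfs.sum())
        again = fold(folded)
        assert again == folded

    def test_hinge_cells(self):
        # n1 = n2 = 2: hinge i+j == 2; (0,2) pairs with (2,0); (1,1) is
        # self-complementary and keeps its own value
        counts = np.arange(9, dtype=float).reshape(3, 3)
        folded = fold(JointSFS(counts.copy()))
        assert folded.counts[0, 2] == pytest.approx(counts[0, 2] + counts[2, 0])
        assert folded.mask[2, 0]
        assert folded.counts[1, 1] == pytest.approx(counts[1, 1])


class TestChooseProjection:
    def test_full_counts_without_missing_data(self, two_pop_map):
        rng = np.random.default_rng(5)
        gm = make_matrix(rng.integers(0, 3, size=(40, 4)))
        assert choose_projection(gm, two_pop_map, ("pop1", "pop2")) == (4, 4)

    def test_fully_missing_individual_caps_projection(self, two_pop_map):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, size=(40, 4))
        geno[:, 0] = MISSING
        gm = make_matrix(geno)
        n1, n2 = choose_projection(gm, two_pop_map, ("pop1", "pop2"))
        assert n1 <= 2

    def test_matches_exhaustive_scan(self, two_pop_map):
        from scipy.stats import hypergeom
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 3, size=(80, 4))
        geno[rng.random(geno.shape) < 0.6] = MISSING
        gm = make_matrix(geno)
        chosen = choose_projection(gm, two_pop_map, ("pop1", "pop2"))

        a1, c1 = allele_counts(gm, two_pop_map, "pop1")
        a2, c2 = allele_counts(gm, two_pop_map, "pop2")
        best, best_score = None, -1.0
        for n1 in (2, 4):
            for n2 in (2, 4):
                score = 0.0
                for s in range(80):
                    if c1[s] < n1 or c2[s] < n2:
                        continue
                    m1 = (hypergeom.pmf(0, c1[s], a1[s], n1)
                          + hypergeom.pmf(n1, c1[s], a1[s], n1))
                    m2 = (hypergeom.pmf(0, c2[s], a2[s], n2)
                          + hypergeom.pmf(n2, c2[s], a2[s], n2))
                    score += 1 - m1 * m2
                if score > best_score + 1e-12 or (
                        abs(score - best_score) <= 1e-12
                        and best and n1 + n2 > sum(best)):
                    best, best_score = (n1, n2), score
        assert chosen == best


class TestDiversityStats:
    def test_monomorphic_matrix(self, two_pop_map):
        gm = make_matrix([[0, 0, 0, 0], [2, 2, 2, 2]])
        stats = diversity_stats(gm, two_pop_map)
        for s in stats.values():
            assert s.pi == 0.0
            assert s.private_alleles == 0

    def test_unbiased_pi_hand_value(self):
        # one site, alt 2 of 4 alleles: pi = 2 * 0.5 * 0.5 * 4/3 = 2/3
        pm = PopMap({"ind0": "p", "ind1": "p"})
        gm = make_matrix([[1, 1]])
        s = diversity_stats(gm, pm)["p"]
        assert s.pi == pytest.approx(2 / 3)
        assert s.exp_het == pytest.approx(0.5)
        assert s.pct_polymorphic == pytest.approx(1.0)

    def test_identical_populations_share_no_private_alleles(self, two_pop_map):
        gm = make_matrix([[1, 0, 1, 0], [2, 1, 2, 1]])
        stats = diversity_stats(gm, two_pop_map)
        assert stats["pop1"].private_alleles == 0
        assert stats["pop2"].private_alleles == 0

    def test_private_allele_counting(self, two_pop_map):
        # site 0: alt only in pop1; site 1: ref only in pop2
        gm = make_matrix([[1, 0, 0, 0], [2, 2, 2, 1]])
        stats = diversity_stats(gm, two_pop_map)
        assert stats["pop1"].private_alleles == 1
        assert stats["pop2"].private_alleles == 1

    def test_population_without_data_is_undefined(self, two_pop_map):
        gm = make_matrix([[MISSING, MISSING, 0, 1]])
        stats = diversity_stats(gm, two_pop_map)
        assert math.isnan(stats["pop1"].pi)
        assert stats["pop2"].pi >= 0

    def test_total_sites_denominator(self, two_pop_map):
        gm = make_matrix([[1, 1, 0, 0]])
        stats_var = diversity_stats(gm, two_pop_map)
        stats_all = diversity_stats(gm, two_pop_map, n_total_sites=100)
        assert stats_all["pop1"].pi == pytest.approx(
            stats_var["pop1"].pi / 100)
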