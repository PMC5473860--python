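import itertools

import numpy as np
import pytest

from fdtraitkit import (CommunityMatrix, TraitMatrix, fad, fd_branch_length,
                        fd_profile, fdis, functional_dendrogram, pc_scores,
                        rao_q, species_distance_matrix, standardize_traits)
from fdtraitkit.synthetic_data import FIXTURE_EXPECTED

import oracles


@pytest.fixture
def two_species_dm():
    tm = TraitMatrix(["a", "b"], ["t"], [[-1.0], [1.0]])
    # column already has mean 0; sd(ddof=0)=1
    return species_distance_matrix(standardize_traits(tm, ddof=0))


class TestDistances:
    def test_two_species_one_trait(self, two_species_dm):
        assert two_species_dm.d[0, 1] == pytest.approx(2.0)

    def test_identical_rows_zero_distance(self, rng):
        X = rng.standard_normal((4, 3))
        X[1] = X[0]
        tm = standardize_traits(TraitMatrix(list("abcd"), ["x", "y", "z"], X))
        dm = species_distance_matrix(tm)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_loop(self, small_std):
        tm, _ = small_std
        dm = species_distance_matrix(tm, ["height", "sla"])
        idx = [tm.trait_names.index(t) for t in ("height", "sla")]
        expected = oracles.pairwise_euclidean(tm.values[:, idx])
        np.testing.assert_allclose(dm.d, expected, atol=1e-12)

    def test_requires_standardized_input(self, small_fixture):
        tm, _ = small_fixture
        with pytest.raises(ValueError, match="standardized"):
            species_distance_matrix(tm)


class TestFAD:
    def test_singleton_is_zero(self, small_std):
        dm = species_distance_matrix(small_std[0])
        assert fad(["s1"], dm) == 0.0

    def test_two_species_equals_distance(self, two_species_dm):
        assert fad(["a", "b"], two_species_dm) == pytest.approx(2.0)

    def test_matches_pair_enumeration(self, small_std):
        dm = species_distance_matrix(small_std[0])
        got = fad(["s1", "s3", "s4", "s6"], dm)
        expected = oracles.fad_naive(dm.d, [0, 2, 3, 5])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unknown_species_rejected(self, small_std):
        dm = species_distance_matrix(small_std[0])
        with pytest.raises(KeyError):
            fad(["nope"], dm)


class TestDendrogram:
    def test_two_species_tree(self, two_species_dm):
        dg = functional_dendrogram(two_species_dm)
        assert dg.node_heights[-1] == pytest.approx(1.0)  # merge at d/2
        assert dg.total_branch_length == pytest.approx(2.0)

    def test_three_equidistant_species(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        from fdtraitkit.functional_diversity import DistanceMatrix
        dm = DistanceMatrix(list("abc"), oracles.pairwise_euclidean(X))
        dg = functional_dendrogram(dm)
        np.testing.assert_allclose(dg.node_heights[3:], [0.5, 0.5], atol=1e-12)

    def test_merge_heights_match_textbook_upgma(self, small_std):
        dm = species_distance_matrix(small_std[0])
        dg = functional_dendrogram(dm)
        merges = oracles.upgma_naive(dm.d)
        np.testing.assert_allclose(sorted(dg.Z[:, 2]),
                                   sorted(m[2] for m in merges), atol=1e-10)
        total = oracles.upgma_total_branch_length(merges, 6)
        assert dg.total_branch_length == pytest.approx(total, abs=1e-10)

    def test_heights_nondecreasing(self, random_tm):
        dm = species_distance_matrix(random_tm)
        dg = functional_dendrogram(dm)
        assert np.all(np.diff(dg.Z[:, 2]) >= -1e-12)


class TestFDBranchLength:
    def test_full_pool_recovers_total(self, small_std):
        dm = species_distance_matrix(small_std[0])
        dg = functional_dendrogram(dm)
        got = fd_branch_length(small_std[0].species_ids, dg)
        assert got == pytest.approx(dg.total_branch_length, abs=1e-12)

    def test_singleton_zero(self, small_std):
        dg = functional_dendrogram(species_distance_matrix(small_std[0]))
        assert fd_branch_length(["s2"], dg) == 0.0

    def test_pairs_match_edge_walk_oracle(self, small_std):
        dm = species_distance_matrix(small_std[0])
        dg = functional_dendrogram(dm)
        merges = oracles.upgma_naive(dm.d)
        names = small_std[0].species_ids
        for pair in itertools.combinations(range(6), 2):
            got = fd_branch_length([names[i] for i in pair], dg)
            expected = oracles.subtree_length_naive(merges, 6, pair)
            assert got == pytest.approx(expected, abs=1e-10), pair

    def test_root_inclusion_variant_adds_stem(self, small_std):
        dg = functional_dendrogram(species_distance_matrix(small_std[0]))
        base = fd_branch_length(["s1", "s2"], dg)
        rooted = fd_branch_length(["s1", "s2"], dg, include_root=True)
        assert rooted > base


class TestRaoQ:
    def test_singleton_zero(self, small_std):
        dm = species_distance_matrix(small_std[0])
        w = np.array([1.0, 0, 0, 0, 0, 0])
        assert rao_q(w, dm) == 0.0

    def test_two_species_equal_abundance(self, two_species_dm):
        assert rao_q(np.array([0.5, 0.5]), two_species_dm) == pytest.approx(0.5)

    def test_matches_pair_enumeration(self, small_std):
        dm = species_distance_matrix(small_std[0])
        w = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
        expected = oracles.rao_q_naive(dm.d[np.ix_([0, 1, 2], [0, 1, 2])],
                                       np.array([0.5, 0.3, 0.2]))
        assert rao_q(w, dm) == pytest.approx(expected, abs=1e-12)

    def test_conventions(self, two_species_dm):
        w = np.array([0.5, 0.5])
        assert rao_q(w, two_species_dm, ordered=True) == pytest.approx(1.0)
        assert rao_q(w, two_species_dm, squared=True) == pytest.approx(0.5)

    def test_unnormalized_input_normalized_with_notice(self, two_species_dm):
        with pytest.warns(RuntimeWarning, match="normaliz"):
            v = rao_q(np.array([2.0, 2.0]), two_species_dm)
        assert v == pytest.approx(0.5)


class TestFDis:
    def test_singleton_zero(self, small_std):
        tm, _ = small_std
        w = np.zeros(6)
        w[2] = 1.0
        assert fdis(w, tm) == 0.0

    def test_two_species_equal_abundance(self):
        tm = standardize_traits(TraitMatrix(["a", "b"], ["t"],
                                            [[-1.0], [1.0]]), ddof=0)
        assert fdis(np.array([0.5, 0.5]), tm) == pytest.approx(1.0)  # d/2 with d=2

    def test_matches_centroid_oracle(self, small_std):
        tm, _ = small_std
        w = np.array([0.1, 0.0, 0.4, 0.0, 0.5, 0.0])
        idx = [0, 2, 4]
        expected = oracles.fdis_naive(tm.values[idx], w[idx])
        assert fdis(w, tm) == pytest.approx(expected, abs=1e-12)


class TestFixtureReference:
    """The shipped 6-species fixture against its recorded oracle values."""

    def test_fad_full_pool(self, small_std):
        dm = species_distance_matrix(small_std[0])
        got = fad(small_std[0].species_ids, dm)
        assert got == pytest.approx(FIXTURE_EXPECTED["fad_full_pool"], abs=1e-9)

    def test_upgma_merge_heights(self, small_std):
        dg = functional_dendrogram(species_distance_matrix(small_std[0]))
        np.testing.assert_allclose(np.sort(dg.node_heights[6:]),
                                   FIXTURE_EXPECTED["upgma_merge_heights"],
                                   atol=1e-9)
        assert dg.total_branch_length == pytest.approx(
            FIXTURE_EXPECTED["fd_total_branch_length"], abs=1e-9)

    @pytest.mark.parametrize("key,members", [
        ("fd_c3", ["s1", "s2"]),
        ("fd_c4", ["s3", "s4"]),
        ("fd_c8", ["s1", "s3", "s6"]),
    ])
    def test_fd_subtree_lengths(self, small_std, key, members):
        dg = functional_dendrogram(species_distance_matrix(small_std[0]))
        assert fd_branch_length(members, dg) == pytest.approx(
            FIXTURE_EXPECTED[key], abs=1e-9)

    def test_q_and_fdis_community_five(self, small_std):
        tm, cm = small_std
        w = cm.abundances[4]
        dm = species_distance_matrix(tm)
        assert rao_q(w / w.sum(), dm) == pytest.approx(
            FIXTURE_EXPECTED["q_com5"], abs=1e-9)
        assert fdis(w, tm) == pytest.approx(
            FIXTURE_EXPECTED["fdis_com5"], abs=1e-9)


class TestProfileAndInvariants:
    def test_profile_cells_match_single_calls(self, small_fixture):
        tm, cm = small_fixture
        table = fd_profile(cm, tm)
        tms = standardize_traits(tm)
        dm = species_distance_matrix(tms)
        dg = functional_dendrogram(dm)
        rel = cm.relative_abundances()
        for i, com in enumerate(cm.community_ids):
            present = [s for s, a in zip(cm.species_ids, cm.abundances[i]) if a > 0]
            row = table.loc[com]
            assert row["richness"] == len(present)
            assert row["fad"] == pytest.approx(fad(present, dm), abs=1e-10)
            assert row["fd"] == pytest.approx(fd_branch_length(present, dg),
                                              abs=1e-10)
            assert row["q"] == pytest.approx(rao_q(rel[i], dm), abs=1e-10)
            assert row["fdis"] == pytest.approx(fdis(rel[i], tms), abs=1e-10)

    def test_all_singletons_give_zero(self, small_fixture):
        tm, _ = small_fixture
        cm = CommunityMatrix(["c1", "c2"], tm.species_ids,
                             [[1, 0, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0]])
        table = fd_profile(cm, tm)
        assert (table[["fad", "fd", "q", "fdis"]].to_numpy() == 0).all()

    def test_fad_fd_monotone_under_species_addition(self, small_std):
        tm, _ = small_std
        dm = species_distance_matrix(tm)
        dg = functional_dendrogram(dm)
        names = tm.species_ids
        for r in range(1, 6):
            for sub in itertools.combinations(range(6), r):
                f0 = fad([names[i] for i in sub], dm)
                b0 = fd_branch_length([names[i] for i in sub], dg)
                for extra in set(range(6)) - set(sub):
                    bigger = [names[i] for i in sub + (extra,)]
                    assert fad(bigger, dm) >= f0 - 1e-12
                    assert fd_branch_length(bigger, dg) >= b0 - 1e-12

    def test_rotation_isometry_traits_vs_pc_scores(self, small_fixture):
        tm, cm = small_fixture
        tms = standardize_traits(tm)
        scores = pc_scores(tms, tms.n_traits)
        t1 = fd_profile(cm, tms)
        t2 = fd_profile(cm, scores)
        for col in ("fad", "fd", "q", "fdis"):
            np.testing.assert_allclose(t1[col], t2[col], atol=1e-9)

    def test_species_order_invariance(self, small_fixture):
        tm, cm = small_fixture
        perm = [3, 0, 5, 1, 4, 2]
        tm2 = TraitMatrix([tm.species_ids[i] for i in perm], tm.trait_names,
                          tm.values[perm])
        t1 = fd_profile(cm, tm).sort_index()
        t2 = fd_profile(cm, tm2).sort_index()
        for col in ("fad", "fd", "q", "fdis"):
            np.testing.assert_allclose(t1[col], t2[col], atol=1e-9)

    def test_bounds_on_random_fixture(self, rng):
        X = rng.standard_normal((8, 3))
        tm = standardize_traits(TraitMatrix(
            [f"s{i}" for i in range(8)], ["a", "b", "c"], X))
        dm = species_distance_matrix(tm)
        w = rng.dirichlet(np.ones(8))
        assert rao_q(w, dm) <= dm.d.max()
        c = w @ tm.values
        assert fdis(w, tm) <= np.linalg.norm(tm.values - c, axis=1).max() + 1e-12
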