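"""Ward clustering against a hand-coded Lance–Williams oracle, cuts, rubric."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import ptrubric as pt
from ptrubric.clustering import DistanceMatrix, all_nearest_neighbours

from conftest import make_similarity


def make_distance(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"PT{i + 1}" for i in range(arr.shape[0])]
    return DistanceMatrix(pd.DataFrame(arr, index=names, columns=names))


def random_distance(rng, n, low=0.05, high=1.9):
    A = rng.uniform(low, high, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def lance_williams_oracle(d):
    """Step-by-step Ward merging over explicit cluster sets.

    Independent bookkeeping (dict of frozensets) rather than index arrays;
    returns the merge sequence as (leafset_left, leafset_right, height).
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}  # id -> leaves
    d2 = {frozenset((i, j)): d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = min(
            ((ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))),
            key=lambda pair: (d2[frozenset(pair)], pair),
        )
        i, j = best
        dij = d2[frozenset((i, j))]
        merges.append((clusters[i], clusters[j], np.sqrt(dij)))
        si, sj = len(clusters[i]), len(clusters[j])
        for k in ids:
            if k in (i, j):
                continue
            sk = len(clusters[k])
            d2[frozenset((next_id, k))] = (
                (si + sk) * d2[frozenset((i, k))]
                + (sj + sk) * d2[frozenset((j, k))]
                - sk * dij
            ) / (si + sj + sk)
        clusters[next_id] = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        next_id += 1
    return merges


class TestToDistance:
    def test_endpoints_and_paper_scale_arithmetic(self):
        S = make_similarity([[1, 1, -1], [1, 1, 0.176], [-1, 0.176, 1]])
        D = pt.to_distance(S)
        assert D.d[0, 1] == 0.0
        assert D.d[0, 2] == 2.0
        assert D.d[1, 2] == pytest.approx(0.824)
        assert np.all(np.diag(D.d) == 0.0)

    def test_strictly_decreasing_and_unit_correlations_give_zero_distance(self):
        rhos = np.linspace(-1, 1, 9)
        assert np.all(np.diff(1 - rhos) < 0)
        # all-ones correlation matrix maps to the zero distance matrix
        S = make_similarity(np.ones((3, 3)))
        np.testing.assert_array_equal(pt.to_distance(S).d, np.zeros((3, 3)))


class TestWardDendrogram:
    def test_two_leaves_single_merge_height(self):
        D = make_distance([[0, 0.6], [0.6, 0]])
        dendro = pt.ward_dendrogram(D)
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(0.6)

    def test_planted_pairs_merge_before_cross_merges(self):
        # two tight pairs far apart: within-pair merges must come first
        D = make_distance(
            [
                [0.0, 0.1, 1.5, 1.6],
                [0.1, 0.0, 1.7, 1.5],
                [1.5, 1.7, 0.0, 0.2],
                [1.6, 1.5, 0.2, 0.0],
            ]
        )
        merges = pt.ward_dendrogram(D).merges
        first_two = {frozenset(map(int, merges[0, :2])), frozenset(map(int, merges[1, :2]))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_coded_lance_williams_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = random_distance(rng, 5)
        dendro = pt.ward_dendrogram(make_distance(d))
        oracle = lance_williams_oracle(d)
        n = 5
        leafsets = {i: frozenset([i]) for i in range(n)}
        for t, (left, right, height) in enumerate(oracle):
            i, j = int(dendro.merges[t, 0]), int(dendro.merges[t, 1])
            assert {leafsets[i], leafsets[j]} == {left, right}
            assert dendro.merges[t, 2] == pytest.approx(height, abs=1e-12)
            leafsets[n + t] = leafsets[i] | leafsets[j]

    @pytest.mark.parametrize("seed", range(3))
    def test_merge_heights_match_scipy_linkage(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = random_distance(rng, 9)
        mine = pt.ward_dendrogram(make_distance(d)).merges
        Z = linkage(squareform(d), method="ward")
        np.testing.assert_allclose(np.sort(mine[:, 2]), np.sort(Z[:, 2]), atol=1e-10)

    def test_nan_distances_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(Exception, match="NaN"):
            pt.ward_dendrogram(make_distance(d))


class TestCut:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(2)
        dendro = pt.ward_dendrogram(make_distance(random_distance(rng, 6)))
        assert len(set(pt.cut(dendro, 6))) == 6
        assert len(set(pt.cut(dendro, 1))) == 1
        with pytest.raises(ValueError):
            pt.cut(dendro, 0)
        with pytest.raises(ValueError):
            pt.cut(dendro, 7)

    def test_recovers_13_planted_blocks_exactly(self):
        blocks = tuple(
            (f"blk{b}", tuple(f"B{b}M{m}" for m in range(2 + b % 3)), 0.7) for b in range(13)
        )
        S = pt.block_correlation_matrix(blocks, cross=0.0)
        labels = pt.cluster_labels(S, 13)
        truth = [name for name, members, _ in blocks for _ in members]
        assert adjusted_rand_score(truth, labels) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_cut_nesting(self, seed):
        rng = np.random.default_rng(300 + seed)
        dendro = pt.ward_dendrogram(make_distance(random_distance(rng, 10)))
        for k1, k2 in [(2, 5), (3, 7), (1, 10)]:
            coarse, fine = pt.cut(dendro, k1), pt.cut(dendro, k2)
            # every fine cluster sits inside exactly one coarse cluster
            for lab in set(fine):
                assert len(set(coarse[fine == lab])) == 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(31)
        d = random_distance(rng, 8)
        names = [f"PT{i + 1}" for i in range(8)]
        base = pt.cut(pt.ward_dendrogram(make_distance(d, names)), 3)
        perm = rng.permutation(8)
        shuffled = pt.cut(
            pt.ward_dendrogram(make_distance(d[np.ix_(perm, perm)], [names[i] for i in perm])), 3
        )
        unshuffled = np.empty(8, dtype=int)
        unshuffled[perm] = shuffled
        assert adjusted_rand_score(base, unshuffled) == 1.0


class TestBuildRubric:
    @staticmethod
    def nested_two_level_matrix():
        # 4 blocks of 2, paired into 2 super-blocks via moderate cross-correlation
        names = [f"G{g}P{i}" for g in range(4) for i in range(2)]
        A = np.zeros((8, 8))
        for g in range(4):
            A[2 * g, 2 * g + 1] = A[2 * g + 1, 2 * g] = 0.8
        for a, b in [(0, 1), (2, 3)]:  # super-blocks {0,1} and {2,3}
            for i in range(2):
                for j in range(2):
                    A[2 * a + i, 2 * b + j] = A[2 * b + j, 2 * a + i] = 0.45
        np.fill_diagonal(A, 1.0)
        return make_similarity(A, names)

    def test_nested_cuts_recover_both_levels(self):
        S = self.nested_two_level_matrix()
        rubric = pt.build_rubric(pt.to_distance(S), k_low=4, k_broad=2)
        low_truth = [i // 2 for i in range(8)]
        broad_truth = [i // 4 for i in range(8)]
        terms = S.vocab.terms
        assert adjusted_rand_score(low_truth, [rubric.low[t] for t in terms]) == 1.0
        assert adjusted_rand_score(broad_truth, [rubric.broad[t] for t in terms]) == 1.0

    def test_broad_clusters_are_unions_of_low_clusters(self):
        S = self.nested_two_level_matrix()
        rubric = pt.build_rubric(pt.to_distance(S), k_low=4, k_broad=2)
        for members in rubric.low_categories().values():
            assert len({rubric.broad[m] for m in members}) == 1

    def test_equal_cuts_coincide(self):
        S = self.nested_two_level_matrix()
        rubric = pt.build_rubric(pt.to_distance(S), k_low=2, k_broad=2)
        low_part = {frozenset(m) for m in rubric.low_categories().values()}
        broad_part = {frozenset(m) for m in rubric.broad_categories().values()}
        assert low_part == broad_part

    def test_manual_placement_merged_and_flagged(self):
        S = self.nested_two_level_matrix()
        D = pt.to_distance(S)
        rubric = pt.build_rubric(
            D, k_low=4, k_broad=2, manual={"G3P1": "with:G3P0"}, exclude=("G3P1",)
        )
        assert "G3P1" in rubric.manual
        assert rubric.low["G3P1"] == rubric.low["G3P0"]
        assert rubric.broad["G3P1"] == rubric.broad["G3P0"]
        assert set(rubric.low) == set(S.vocab.terms)

    def test_unknown_manual_category_is_an_error(self):
        S = self.nested_two_level_matrix()
        with pytest.raises(ValueError, match="unknown category"):
            pt.build_rubric(
                pt.to_distance(S),
                k_low=4,
                k_broad=2,
                manual={"G3P1": "No Such Category"},
                exclude=("G3P1",),
            )

    def test_excluded_pt_without_manual_placement_is_an_error(self):
        S = self.nested_two_level_matrix()
        with pytest.raises(ValueError, match="manual placement"):
            pt.build_rubric(pt.to_distance(S), k_low=4, k_broad=2, exclude=("G3P1",))


class TestNearestNeighbour:
    def test_two_pts_are_mutual_neighbours(self):
        S = make_similarity([[1, 0.2], [0.2, 1]], ["A", "B"])
        assert pt.nearest_neighbour(S, "A") == "B"
        assert pt.nearest_neighbour(S, "B") == "A"

    def test_matches_direct_argmax_scan(self):
        rng = np.random.default_rng(13)
        A = rng.uniform(-1, 1, size=(10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        S = make_similarity(A)
        nn = all_nearest_neighbours(S)
        for i, pti in enumerate(S.vocab.terms):
            best = max(
                (A[i, j], S.vocab.terms[j]) for j in range(10) if j != i
            )[0]
            candidates = {S.vocab.terms[j] for j in range(10) if j != i and A[i, j] == best}
            expected = min(candidates)
            assert pt.nearest_neighbour(S, pti) == expected == nn[pti]

    def test_ties_break_lexicographically(self):
        S = make_similarity(
            [[1, 0.5, 0.5], [0.5, 1, 0.1], [0.5, 0.1, 1]], ["M", "Z", "A"]
        )
        assert pt.nearest_neighbour(S, "M") == "A"

    def test_unknown_pt_is_an_error(self):
        S = make_similarity([[1, 0.2], [0.2, 1]])
        with pytest.raises(KeyError):
            pt.nearest_neighbour(S, "nope")


class TestNewick:
    def test_newick_well_formed_and_contains_all_leaves(self):
        rng = np.random.default_rng(4)
        names = ["Case Reports", "Case Series", "Review", "News, Weekly"]
        dendro = pt.ward_dendrogram(make_distance(random_distance(rng, 4), names))
        nwk = pt.to_newick(dendro)
        assert nwk.endswith(";") and nwk.count("(") == 3 == nwk.count(")")
        assert "'Case Reports'" in nwk and "'News, Weekly'" in nwk
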