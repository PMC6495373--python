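import itertools

import numpy as np
import pandas as pd
import pytest

from paleoferm.io import parse_newick
from paleoferm.phylo import (
    closest_relative,
    dbscan_cluster,
    intraspecific_distances,
    patristic_matrix,
    robinson_foulds,
    species_membership_test,
)

from conftest import (
    brute_force_dbscan,
    brute_force_patristic,
    enumerate_five_tip_topologies,
    random_tree,
)


@pytest.fixture
def three_tip_matrix():
    return patristic_matrix(parse_newick("((A:1,B:2):3,C:4);"))


class TestPatristicMatrix:
    def test_hand_worked_three_tip_tree(self, three_tip_matrix):
        m = three_tip_matrix
        assert m.at["A", "B"] == 3
        assert m.at["A", "C"] == 8
        assert m.at["B", "C"] == 9

    def test_zero_length_edges(self):
        m = patristic_matrix(parse_newick("(A:0,B:0);"))
        assert m.at["A", "B"] == 0

    def test_symmetric_zero_diagonal_nonnegative(self, rng):
        m = patristic_matrix(random_tree(rng, 20))
        arr = m.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all()

    def test_matches_per_pair_path_oracle(self, rng):
        tree = random_tree(rng, 20)
        m = patristic_matrix(tree)
        for a, b in itertools.combinations(m.index, 2):
            assert m.at[a, b] == pytest.approx(
                brute_force_patristic(tree, a, b), abs=1e-9
            )

    def test_invariant_to_rerooting(self, rng):
        tree = random_tree(rng, 15)
        m1 = patristic_matrix(tree)
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()][-1]
        tree.reroot_at_node(internal)
        m2 = patristic_matrix(tree)
        assert np.allclose(m1.to_numpy(), m2.loc[m1.index, m1.columns].to_numpy())

    def test_four_point_condition(self, rng):
        m = patristic_matrix(random_tree(rng, 12))
        for a, b, c, d in itertools.combinations(m.index, 4):
            sums = sorted(
                [
                    m.at[a, b] + m.at[c, d],
                    m.at[a, c] + m.at[b, d],
                    m.at[a, d] + m.at[b, c],
                ]
            )
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_single_tip_rejected(self):
        with pytest.raises(ValueError):
            patristic_matrix(parse_newick("(A:1,B:1);").extract_tree_with_taxa_labels(["A"]))


class TestIntraspecificDistances:
    def test_single_conspecific_pair(self, three_tip_matrix):
        assert intraspecific_distances(
            three_tip_matrix, {"A": "sp1", "B": "sp1", "C": "sp2"}
        ) == [3]

    def test_all_singletons_rejected(self, three_tip_matrix):
        with pytest.raises(ValueError, match="no intraspecific pairs"):
            intraspecific_distances(
                three_tip_matrix, {"A": "sp1", "B": "sp2", "C": "sp3"}
            )

    def test_two_species_of_two_tips_give_two_values(self):
        m = patristic_matrix(parse_newick("((A:1,B:1):5,(C:2,D:2):5);"))
        vals = intraspecific_distances(m, {"A": "x", "B": "x", "C": "y", "D": "y"})
        assert vals == [2, 4]

    def test_unmapped_tips_excluded(self, three_tip_matrix):
        vals = intraspecific_distances(three_tip_matrix, {"A": "sp1", "B": "sp1"})
        assert vals == [3]


class TestSpeciesMembershipTest:
    REF = [0.001, 0.002, 0.003, 0.004, 0.005]

    def test_zero_distance_is_conspecific_with_p_one(self):
        res = species_membership_test(0.0, self.REF, method="empirical")
        assert res.p_value == 1.0
        assert res.verdict == "conspecific"

    def test_empirical_counting_rule(self):
        res = species_membership_test(0.003, self.REF, method="empirical")
        assert res.p_value == pytest.approx(4 / 6)
        assert res.verdict == "conspecific"

    def test_query_beyond_reference_maximum_is_novel(self):
        # the divergent-isolate situation: observed distance roughly double
        # the largest intraspecific distance in the reference tree
        ref = list(np.linspace(0.001, 0.012, 40))
        res = species_membership_test(0.023, ref, method="parametric")
        assert res.verdict == "novel-species-candidate"
        assert res.method == "parametric-lognormal"

    def test_p_monotone_nonincreasing_in_distance(self):
        ref = list(np.linspace(0.001, 0.012, 30))
        for method in ("empirical", "parametric"):
            ps = [
                species_membership_test(d, ref, method=method).p_value
                for d in np.linspace(0, 0.05, 25)
            ]
            assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_parametric_matches_resampling_from_fitted_distribution(self, rng):
        from scipy import stats

        ref = list(rng.lognormal(mean=np.log(0.004), sigma=0.5, size=200))
        d_obs = 0.01
        res = species_membership_test(d_obs, ref, method="parametric")
        shape, loc, scale = stats.lognorm.fit(np.asarray(ref), floc=0)
        sims = stats.lognorm.rvs(
            shape, loc=loc, scale=scale, size=200_000, random_state=42
        )
        mc = np.mean(sims >= d_obs)
        assert res.p_value == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / 2e5) + 1e-4)

    def test_small_reference_falls_back_to_empirical(self):
        with pytest.warns(UserWarning, match="falling back"):
            res = species_membership_test(0.01, [0.001, 0.002], method="parametric")
        assert res.method == "empirical"


class TestClosestRelative:
    def test_hand_worked_matrix(self, three_tip_matrix):
        assert closest_relative(three_tip_matrix, "A") == ("B", 3.0)

    def test_tie_broken_lexicographically(self):
        m = pd.DataFrame(
            [[0, 1, 1], [1, 0, 2], [1, 2, 0]],
            index=list("QBA"),
            columns=list("QBA"),
        ).astype(float)
        assert closest_relative(m, "Q") == ("A", 1.0)

    def test_two_tip_tree(self):
        m = patristic_matrix(parse_newick("(A:1,B:2);"))
        assert closest_relative(m, "A") == ("B", 3.0)

    def test_absent_query_raises(self, three_tip_matrix):
        with pytest.raises(KeyError):
            closest_relative(three_tip_matrix, "Z")


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self, rng):
        tree = random_tree(rng, 10)
        text = tree.as_string(schema="newick")
        assert robinson_foulds(parse_newick(text), parse_newick(text)) == 0
        assert robinson_foulds(parse_newick(text), parse_newick(text), weighted=True) == 0

    def test_four_taxon_swap_is_two(self):
        a = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(a, b) == 2

    def test_weighted_same_topology_length_difference(self):
        a = parse_newick("((A:1,B:1):1.0,(C:1,D:1):1);")
        b = parse_newick("((A:1,B:1):1.5,(C:1,D:1):1);")
        assert robinson_foulds(a, b, weighted=True) == pytest.approx(0.5)

    def test_metric_on_all_five_tip_topologies(self):
        trees = [parse_newick(t) for t in enumerate_five_tip_topologies()]
        n = len(trees)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = robinson_foulds(trees[i], trees[j])
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d[~np.eye(n, dtype=bool)] > 0).all()  # distinct topologies
        assert d.max() == 4  # 2(n-3) for n=5
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_agrees_with_dendropy_oracle(self, rng):
        import dendropy

        for _ in range(10):
            t1 = random_tree(rng, 12)
            t2 = random_tree(rng, 12)
            ours = robinson_foulds(
                parse_newick(t1.as_string(schema="newick")),
                parse_newick(t2.as_string(schema="newick")),
            )
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == theirs

    def test_mismatched_tip_sets_rejected(self):
        with pytest.raises(ValueError, match="tip sets differ"):
            robinson_foulds(parse_newick("(A:1,B:1);"), parse_newick("(A:1,C:1);"))


class TestDbscanCluster:
    @staticmethod
    def _blob_matrix():
        ids = [f"t{i}" for i in range(10)]
        d = np.full((10, 10), 1.0)
        for blob in (range(5), range(5, 10)):
            for i in blob:
                for j in blob:
                    d[i, j] = 0.01
        np.fill_diagonal(d, 0)
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_two_blobs_two_clusters_no_noise(self):
        out = dbscan_cluster(self._blob_matrix(), eps=0.03, min_neighbors=3)
        assert None not in out.values()
        assert len(set(out.values())) == 2

    def test_matches_density_reachability_oracle(self):
        df = self._blob_matrix()
        out = dbscan_cluster(df, eps=0.03, min_neighbors=3)
        oracle = brute_force_dbscan(df.to_numpy(), eps=0.03, min_neighbors=3)
        ours = {}
        for tid, lab in out.items():
            ours.setdefault(lab, set()).add(list(df.index).index(tid))
        assert sorted(map(sorted, ours.values())) == sorted(map(sorted, oracle))

    def test_everything_noise_when_sparse(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(1 - np.eye(3), index=ids, columns=ids)
        out = dbscan_cluster(d, eps=0.03, min_neighbors=2)
        assert all(v is None for v in out.values())

    def test_stable_under_row_permutation(self, rng):
        df = self._blob_matrix()
        perm = list(rng.permutation(df.index))
        shuffled = df.loc[perm, perm]
        a = dbscan_cluster(df, eps=0.03, min_neighbors=3)
        b = dbscan_cluster(shuffled, eps=0.03, min_neighbors=3)
        group = lambda d: sorted(  # noqa: E731 - cluster contents up to relabeling
            sorted(k for k, v in d.items() if v == lab)
            for lab in set(d.values())
        )
        assert group(a) == group(b)

    @pytest.mark.parametrize("eps,minn", [(0, 2), (-1, 2), (0.1, 0)])
    def test_bad_parameters_rejected(self, eps, minn):
        df = self._blob_matrix()
        with pytest.raises(ValueError):
            dbscan_cluster(df, eps=eps, min_neighbors=minn)
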