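import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings, strategies as st

from phyllocom.clustering import (
    ConsensusDendrogram,
    DissimilarityMatrix,
    bootstrap_support,
    bray_curtis,
    bray_curtis_matrix,
    clades,
    cluster_table,
    is_supported,
    linkage_complete,
    majority_consensus,
    rarefaction_support,
    support_table,
    to_newick,
)
from phyllocom.preprocess import RarefactionPlan
from phyllocom.tables import CountTable


def make_matrix(ids, pairs):
    n = len(ids)
    mat = np.zeros((n, n))
    for (i, j), v in pairs.items():
        mat[i, j] = mat[j, i] = v
    return DissimilarityMatrix(tuple(ids), mat, "bray_curtis")


def brute_force_clades(d: DissimilarityMatrix) -> set[frozenset]:
    """Independent agglomerator: recompute max pairwise distance from the
    original matrix at every step, same lexicographic tie rule."""
    ids = list(d.sample_ids)
    idx = {s: k for k, s in enumerate(ids)}
    clusters = [frozenset([s]) for s in ids]
    found = set()
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                cx, cy = clusters[x], clusters[y]
                dd = max(d.values[idx[p], idx[q]] for p in cx for q in cy)
                la, lb = sorted((min(cx), min(cy)))
                key = (dd, la, lb)
                if best is None or key < best[0]:
                    best = (key, x, y)
        _, x, y = best
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
        if len(merged) < len(ids):
            found.add(merged)
    return found


class TestBrayCurtis:
    def test_identical_profiles_are_at_zero(self):
        assert bray_curtis([2, 0, 1], [2, 0, 1]) == 0.0

    def test_disjoint_supports_are_at_one(self):
        assert bray_curtis([3, 0], [0, 5]) == 1.0

    def test_worked_example_count_and_binary(self):
        assert bray_curtis([2, 0, 1], [1, 1, 0]) == pytest.approx(0.6)
        assert bray_curtis([2, 0, 1], [1, 1, 0], binary=True) == pytest.approx(0.5)

    def test_two_empty_profiles_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert bray_curtis([0, 0], [0, 0]) == 0.0

    def test_matrix_matches_scalar_formula(self):
        rng = np.random.default_rng(3)
        table = CountTable.from_arrays(
            [f"s{i}" for i in range(5)],
            [f"a{j}" for j in range(20)],
            rng.integers(0, 30, size=(5, 20)),
        )
        for binary in (False, True):
            mat = bray_curtis_matrix(table, binary=binary).values
            for i in range(5):
                for j in range(5):
                    expected = bray_curtis(
                        table.counts[i], table.counts[j], binary=binary
                    )
                    assert mat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_equal_depth_counts_equal_proportions(self):
        # at a common depth, Bray-Curtis on counts equals it on proportions
        rng = np.random.default_rng(5)
        x = rng.multinomial(500, np.ones(30) / 30)
        y = rng.multinomial(500, np.ones(30) / 30)
        assert bray_curtis(x, y) == pytest.approx(
            bray_curtis(x / 500, y / 500), abs=1e-12
        )


class TestLinkageComplete:
    def test_hand_executed_three_samples(self):
        d = make_matrix(["A", "B", "C"], {(0, 1): 0.1, (0, 2): 0.9, (1, 2): 0.8})
        tree = linkage_complete(d)
        merges = tree.merges()
        assert merges[0] == (frozenset("A"), frozenset("B"), 0.1)
        assert merges[1][2] == 0.9
        assert clades(tree) == {frozenset(["A", "B"])}

    def test_all_equal_distances_merge_lexicographically(self):
        d = make_matrix(
            ["c", "a", "b"],
            {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5},
        )
        tree = linkage_complete(d)
        assert clades(tree) == {frozenset(["a", "b"])}

    def test_two_samples_single_merge(self):
        d = make_matrix(["x", "y"], {(0, 1): 0.3})
        tree = linkage_complete(d)
        assert tree.root.height == 0.3
        assert clades(tree) == set()

    def test_nonfinite_matrix_rejected(self):
        mat = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            DissimilarityMatrix(("a", "b"), mat, "bray_curtis")

    def test_agrees_with_bruteforce_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(3, 7))
            ids = [f"s{chr(97 + i)}" for i in range(n)]
            vals = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
            vals = vals + vals.T
            d = DissimilarityMatrix(tuple(ids), vals, "bray_curtis")
            ours = clades(linkage_complete(d))
            assert ours == brute_force_clades(d)
            # scipy oracle (tie-free random matrices)
            z = sch.linkage(vals[iu], method="complete")
            tree = sch.to_tree(z)
            scipy_clades = set()

            def collect(node):
                if node.is_leaf():
                    return frozenset([ids[node.id]])
                members = collect(node.left) | collect(node.right)
                if 1 < len(members) < n:
                    scipy_clades.add(members)
                return members

            collect(tree)
            assert ours == scipy_clades

    def test_monotone_heights_and_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        table = CountTable.from_arrays(
            [f"s{i}" for i in range(8)],
            [f"a{j}" for j in range(40)],
            rng.integers(0, 40, size=(8, 40)),
        )
        tree = cluster_table(table)
        heights = [h for _, _, h in tree.merges()]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        perm = rng.permutation(8)
        shuffled = CountTable.from_arrays(
            [table.sample_ids[i] for i in perm],
            table.asv_ids,
            table.counts[perm],
        )
        assert clades(cluster_table(shuffled)) == clades(tree)


class TestSupport:
    def test_disjoint_blocks_get_full_bootstrap_support(self):
        # two sample blocks supported by disjoint high-count ASV sets: every
        # column resample preserves the split
        counts = np.zeros((6, 10), dtype=int)
        counts[:3, :5] = 50
        counts[3:, 5:] = 50
        table = CountTable.from_arrays(
            [f"s{i}" for i in range(6)], [f"a{j}" for j in range(10)], counts
        )
        support = bootstrap_support(table, n_boot=50, seed=0)
        assert support.get(frozenset(["s0", "s1", "s2"])) == 1.0
        assert support.get(frozenset(["s3", "s4", "s5"])) == 1.0

    def test_single_asv_table_fractions_are_zero_or_one(self):
        counts = np.array([[10], [10], [1], [1]])
        table = CountTable.from_arrays(
            ["s0", "s1", "s2", "s3"], ["a"], counts
        )
        support = bootstrap_support(table, n_boot=20, seed=1)
        assert set(support.values()) <= {0.0, 1.0}

    def test_rarefaction_identity_depth_gives_degenerate_fractions(self):
        counts = np.array([[5, 5], [5, 5], [1, 9]])
        table = CountTable.from_arrays(["x", "y", "z"], ["a", "b"], counts)
        support = rarefaction_support(
            table, RarefactionPlan(depth=10, n_iterations=5, base_seed=0)
        )
        assert set(support.values()) <= {0.0, 1.0}

    def test_planted_blocks_recovered_across_rarefactions(self, small_study):
        table, sheet, _, truth = small_study
        ids = sheet.select(
            location="outside", habitat="soil_substitute", treatment=["AG", "FO"]
        )
        sub = table.select_samples(ids)
        support = rarefaction_support(
            sub, RarefactionPlan(depth=1084, n_iterations=20, base_seed=3)
        )
        ag = frozenset(truth.expected_clusters["soil_outside_AG"])
        fo = frozenset(truth.expected_clusters["soil_outside_FO"])
        assert support.get(ag, 0.0) >= 0.95
        assert support.get(fo, 0.0) >= 0.95

    def test_is_supported_requires_both_axes(self):
        clade = frozenset(["a", "b"])
        boot = {clade: 0.86}
        rare = {clade: 1.0}
        assert is_supported(clade, boot, rare)
        assert not is_supported(clade, {clade: 0.40}, rare)
        assert is_supported(clade, {clade: 0.51}, {clade: 0.51})

    def test_support_table_schema(self):
        clade = frozenset(["a", "b"])
        frame = support_table({clade: 0.9}, {clade: 0.4})
        assert list(frame.columns) == [
            "clade", "size", "bootstrap_fraction", "rarefaction_fraction", "supported",
        ]
        assert not frame["supported"].iloc[0]


class TestConsensus:
    def test_identical_trees_give_full_support(self):
        d = make_matrix(["a", "b", "c"], {(0, 1): 0.2, (0, 2): 0.8, (1, 2): 0.8})
        trees = [linkage_complete(d) for _ in range(3)]
        counts: dict = {}
        for t in trees:
            for c in clades(t):
                counts[c] = counts.get(c, 0) + 1
        supports = {c: v / 3 for c, v in counts.items()}
        cons = majority_consensus(supports, trees[0])
        assert cons.clades == {frozenset(["a", "b"]): 1.0}

    def test_two_of_three_retained_one_of_three_collapsed(self):
        c1, c2 = frozenset(["a", "b"]), frozenset(["c", "d"])
        cons = majority_consensus({c1: 2 / 3, c2: 1 / 3})
        assert cons.clades == {c1: 2 / 3}

    def test_incompatible_clades_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            ConsensusDendrogram(
                {frozenset(["a", "b"]): 0.9, frozenset(["b", "c"]): 0.8}
            )


class TestNewick:
    def test_export_contains_supports_and_parses(self):
        d = make_matrix(["a", "b", "c"], {(0, 1): 0.2, (0, 2): 0.9, (1, 2): 0.9})
        tree = linkage_complete(d)
        ab = frozenset(["a", "b"])
        text = to_newick(tree, {ab: 0.86}, {ab: 1.0})
        assert text.endswith(";")
        assert "86/100" in text
        assert {"a", "b", "c"} <= set(text.replace("(", " ").replace(")", " ").replace(",", " ").replace(":", " ").split())
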