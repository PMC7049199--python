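import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exohub import (
    CarrierSets,
    GeneCountMatrix,
    carrier_sets,
    cut_clusters,
    distance_matrix,
    jaccard,
    rank_clusters,
    ward_linkage,
)
from exohub.hubclust import to_newick


def naive_ward_oracle(D):
    """O(n^3) agglomerative oracle: merge costs recomputed from the original
    leaf distances via the centroid/ESS closed form at every step, never via
    the recurrence the implementation uses."""
    D2 = np.asarray(D, dtype=float) ** 2
    n = D2.shape[0]
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n

    def pair_sum(A, B):
        return D2[np.ix_(A, B)].sum()

    def cost(a, b):
        A, B = members[a], members[b]
        sq_centroid_dist = (
            pair_sum(A, B) / (len(A) * len(B))
            - pair_sum(A, A) / (2 * len(A) ** 2)
            - pair_sum(B, B) / (2 * len(B) ** 2)
        )
        return 2 * len(A) * len(B) / (len(A) + len(B)) * sq_centroid_dist

    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = sorted((active[ai], active[bi]))
                c = cost(a, b)
                if best is None or c < best[0] - 1e-15 or (
                    abs(c - best[0]) <= 1e-15 and (a, b) < best[1]
                ):
                    best = (c, (a, b))
        c, (a, b) = best
        merges.append((a, b, np.sqrt(max(c, 0.0)), len(members[a]) + len(members[b])))
        members[next_id] = members.pop(a) + members.pop(b)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return np.array(merges)


def random_distance_matrix(rng, n):
    # continuous entries: merge-order ties have probability zero
    M = rng.uniform(0.05, 1.0, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


def toy_gene_counts():
    values = np.array(
        [
            # GA GB GC
            [1, 0, 2],
            [0, 0, 1],
            [-1, 3, 0],
            [2, 1, 0],
        ]
    )
    return GeneCountMatrix(
        sample_ids=["c1", "c2", "c3", "c4"],
        gene_ids=["GA", "GB", "GC"],
        values=values,
        adjusted_phenotype=np.array([-1, -1, -1, -1]),
        labels=np.array(["SCZ", "SCZ", "SCZ", "ASD"]),
    )


class TestCarrierSets:
    def test_strictly_positive_rule(self):
        C = toy_gene_counts()
        sets = carrier_sets(C, "SCZ")
        # GA counts over SCZ cases: {1, 0, -1} -> only c1
        assert sets.sets["GA"] == frozenset({"c1"})
        assert sets.sets["GB"] == frozenset({"c3"})
        assert sets.sets["GC"] == frozenset({"c1", "c2"})
        assert sets.n_cases_total == 3

    def test_empty_gene_excluded_by_default(self):
        C = toy_gene_counts()
        C.values[:, 1] = 0
        sets = carrier_sets(C, "SCZ")
        assert "GB" not in sets.sets
        assert "GB" in carrier_sets(C, "SCZ", drop_empty=False).sets

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            carrier_sets(toy_gene_counts(), "XYZ")

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            carrier_sets(toy_gene_counts(), "SCZ", gene_subset=["NOPE"])


class TestJaccard:
    def test_identical_nonempty(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0

    def test_disjoint(self):
        assert jaccard({1}, {2}) == 0.0

    def test_half_overlap(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_convention(self):
        assert jaccard(set(), set()) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        u=st.sets(st.integers(0, 30)),
        v=st.sets(st.integers(0, 30)),
        w=st.sets(st.integers(0, 30)),
    )
    def test_metric_properties(self, u, v, w):
        juv = jaccard(u, v)
        assert jaccard(v, u) == juv
        assert 0.0 <= juv <= 1.0
        # 1 - J is a metric: triangle inequality
        duv, dvw, duw = 1 - juv, 1 - jaccard(v, w), 1 - jaccard(u, w)
        assert duw <= duv + dvw + 1e-12


class TestDistanceMatrix:
    def test_complement_of_jaccard(self):
        sets = CarrierSets(
            sets={"a": frozenset({1, 2, 3}), "b": frozenset({2, 3, 4}), "c": frozenset({9})},
            class_label="SCZ",
            n_cases_total=10,
        )
        genes, D = distance_matrix(sets)
        i, j = genes.index("a"), genes.index("b")
        assert D[i, j] == pytest.approx(0.5)
        assert D[i, genes.index("c")] == 1.0
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_single_gene_rejected(self):
        sets = CarrierSets(sets={"a": frozenset({1})}, class_label="SCZ", n_cases_total=5)
        with pytest.raises(ValueError):
            distance_matrix(sets)


class TestWardLinkage:
    def test_three_leaf_first_merge(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = ward_linkage(D)
        assert tuple(tree.merges[0, :2]) == (0.0, 1.0)
        assert tree.merges[0, 2] == pytest.approx(0.1)

    def test_merge_count(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 7)
        assert ward_linkage(D).merges.shape == (6, 4)

    def test_heights_monotone(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            D = random_distance_matrix(np.random.default_rng(seed), 10)
            h = ward_linkage(D).heights
            assert (np.diff(h) >= -1e-12).all()

    def test_matches_naive_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 9))
            D = random_distance_matrix(rng, n)
            ours = ward_linkage(D).merges
            oracle = naive_ward_oracle(D)
            assert np.allclose(ours, oracle, atol=1e-9), f"seed {seed}"

    def test_matches_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            D = random_distance_matrix(rng, int(rng.integers(4, 12)))
            ours = ward_linkage(D).merges
            Z = linkage(squareform(D, checks=False), method="ward")
            assert np.allclose(ours, Z, atol=1e-9), f"seed {seed}"

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCutClusters:
    def test_k_equals_n_gives_singletons(self):
        D = random_distance_matrix(np.random.default_rng(2), 5)
        tree = ward_linkage(D, leaf_labels=list("abcde"))
        assignments = cut_clusters(tree, k=5)
        assert len(set(assignments.values())) == 5

    def test_k_one_single_cluster(self):
        D = random_distance_matrix(np.random.default_rng(3), 5)
        tree = ward_linkage(D, leaf_labels=list("abcde"))
        assert set(cut_clusters(tree, k=1).values()) == {1}

    def test_unattainable_k_rejected(self):
        tree = ward_linkage(random_distance_matrix(np.random.default_rng(4), 4))
        with pytest.raises(ValueError):
            cut_clusters(tree, k=9)

    def test_auto_recovers_planted_modules(self):
        # two well-separated modules: tight within, far between
        rng = np.random.default_rng(5)
        n1, n2 = 4, 5
        D = np.full((n1 + n2, n1 + n2), 0.9)
        D[:n1, :n1] = rng.uniform(0.05, 0.15, (n1, n1))
        D[n1:, n1:] = rng.uniform(0.05, 0.15, (n2, n2))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"g{i}" for i in range(n1 + n2)]
        assignments = cut_clusters(ward_linkage(D, labels), k="auto")
        groups = {}
        for g, cid in assignments.items():
            groups.setdefault(cid, set()).add(g)
        assert sorted(map(sorted, groups.values())) == [
            sorted(labels[:n1]),
            sorted(labels[n1:]),
        ]


class TestRankClusters:
    @staticmethod
    def synthetic_sets(n_genes, n_union, n_total, prefix="case"):
        cases = [f"{prefix}{i}" for i in range(n_union)]
        sets = {}
        for gi in range(n_genes):
            carried = frozenset(cases[gi::n_genes]) | frozenset(cases[:1])
            sets[f"g{gi:03d}"] = carried
        return CarrierSets(sets=sets, class_label="SCZ", n_cases_total=n_total)

    def test_printed_ratio_67_genes(self):
        sets = self.synthetic_sets(67, 506, 598)
        result = rank_clusters({g: 1 for g in sets.sets}, sets)
        sel = result.selected()
        assert sel.a == 67 and sel.b == 506
        assert round(sel.ratio, 2) == 7.55
        assert round(100 * sel.coverage, 2) == 84.62

    def test_printed_ratio_38_genes(self):
        sets = self.synthetic_sets(38, 589, 598)
        result = rank_clusters({g: 1 for g in sets.sets}, sets)
        sel = result.selected()
        assert round(sel.ratio, 2) == 15.5
        assert round(100 * sel.coverage, 2) == 98.49

    def test_singleton_cluster_ratio_one(self):
        sets = CarrierSets(sets={"g": frozenset({"c1"})}, class_label="SCZ", n_cases_total=10)
        result = rank_clusters({"g": 1}, sets)
        assert result.selected().ratio == 1.0

    def test_union_bounds(self):
        rng = np.random.default_rng(6)
        cases = [f"c{i}" for i in range(40)]
        sets = CarrierSets(
            sets={
                f"g{j}": frozenset(rng.choice(cases, size=rng.integers(1, 15), replace=False))
                for j in range(8)
            },
            class_label="SCZ",
            n_cases_total=40,
        )
        assignments = {g: 1 + (i % 2) for i, g in enumerate(sets.sets)}
        result = rank_clusters(assignments, sets)
        assert sum(c.a for c in result.clusters) == 8
        for c in result.clusters:
            per_gene = [len(sets.sets[g]) for g in c.genes]
            assert max(per_gene) <= c.b <= sum(per_gene)
            assert c.b <= sets.n_cases_total

    def test_highest_ratio_selected(self):
        sets = CarrierSets(
            sets={
                "a": frozenset({"c1", "c2", "c3"}),
                "b": frozenset({"c4"}),
                "c": frozenset({"c5"}),
            },
            class_label="SCZ",
            n_cases_total=6,
        )
        result = rank_clusters({"a": 1, "b": 2, "c": 2}, sets)
        assert result.selected_cluster == 1  # ratio 3 vs 1

    def test_missing_carrier_sets_rejected(self):
        sets = CarrierSets(sets={"a": frozenset({"c"})}, class_label="SCZ", n_cases_total=2)
        with pytest.raises(ValueError):
            rank_clusters({"a": 1, "zz": 1}, sets)


def test_newick_roundtrip_leaf_names():
    import dendropy

    D = random_distance_matrix(np.random.default_rng(7), 6)
    labels = [f"gene{i}" for i in range(6)]
    tree = ward_linkage(D, leaf_labels=labels)
    newick = to_newick(tree)
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    taxa = sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter())
    assert taxa == sorted(labels)


def test_end_to_end_determinism(small_matrix):
    from exohub import adjust_dataset, compute_axes, gene_counts

    G, truth = small_matrix
    A = adjust_dataset(G, compute_axes(G, 4))
    C = gene_counts(A)
    results = []
    subset = [g for g in truth.discriminative_genes["SCZ"] if g in C.gene_ids]
    for _ in range(2):
        sets = carrier_sets(C, "SCZ", gene_subset=subset)
        genes, D = distance_matrix(sets)
        tree = ward_linkage(D, genes)
        results.append(rank_clusters(cut_clusters(tree, "auto"), sets).to_dict())
    assert results[0] == results[1]
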