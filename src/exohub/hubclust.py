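"""Co-mutation hub-gene clustering.

Within one class's cases, each gene is represented by its carrier set (cases
with gene-level count strictly greater than 0).  Genes are clustered by
Ward's linkage on 1 - Jaccard distances between carrier sets; flat clusters
are ranked by the cases-per-gene ratio b/a, where a is the cluster's gene
count and b the size of the union of its carrier sets.  The highest-ratio
cluster is the "hub" cluster.

Ward linkage is computed by the Lance-Williams recurrence applied directly to
the precomputed (non-Euclidean) Jaccard distances; heights follow the usual
square-root convention so the merge table is drop-in compatible with scipy's
``linkage`` output format.  Ties are broken by the smallest cluster index
pair, which reduces to the smallest leaf index for singleton merges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import GeneCountMatrix

logger = logging.getLogger(__name__)


@dataclass
class CarrierSets:
    """Per-gene sets of case ids with gene-level count > 0, one class only."""

    sets: dict[str, frozenset[str]]
    class_label: str
    n_cases_total: int

    def genes(self) -> list[str]:
        return list(self.sets)


@dataclass
class LinkageTree:
    """Scipy-format merge table: rows (node_i, node_j, height, size)."""

    merges: np.ndarray
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError(f"expected {n - 1} merges for {n} leaves")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterStats:
    cluster_id: int
    genes: list[str]
    a: int
    b: int
    ratio: float
    coverage: float


@dataclass
class HubClusterResult:
    assignments: dict[str, int]
    clusters: list[ClusterStats]
    selected_cluster: int
    n_cases_total: int

    def selected(self) -> ClusterStats:
        return next(c for c in self.clusters if c.cluster_id == self.selected_cluster)

    def to_dict(self) -> dict:
        return {
            "n_cases_total": self.n_cases_total,
            "selected_cluster": self.selected_cluster,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "a_genes": c.a,
                    "b_unique_carriers": c.b,
                    "ratio": c.ratio,
                    "coverage": c.coverage,
                    "genes": c.genes,
                }
                for c in self.clusters
            ],
        }


def carrier_sets(
    C: GeneCountMatrix,
    class_filter: str,
    gene_subset: list[str] | None = None,
    drop_empty: bool = True,
) -> CarrierSets:
    """Carrier sets of the given class; counts must be strictly positive.

    Genes with no carriers in the class are excluded (and logged) by default,
    since they carry no co-mutation information and degrade the distance.
    """
    mask = np.asarray(C.labels) == class_filter
    if not mask.any():
        raise ValueError(f"no cases with class {class_filter!r}")
    genes = gene_subset if gene_subset is not None else C.gene_ids
    missing = set(genes) - set(C.gene_ids)
    if missing:
        raise ValueError(f"genes not in the matrix: {sorted(missing)[:5]}")
    case_ids = np.asarray(C.sample_ids)[mask]
    col = {g: j for j, g in enumerate(C.gene_ids)}
    sets: dict[str, frozenset[str]] = {}
    n_empty = 0
    for g in genes:
        carriers = frozenset(case_ids[C.values[mask, col[g]] > 0])
        if not carriers and drop_empty:
            n_empty += 1
            continue
        sets[g] = carriers
    if n_empty:
        logger.info("excluded %d genes with empty carrier sets in class %s", n_empty, class_filter)
    return CarrierSets(sets=sets, class_label=class_filter, n_cases_total=int(mask.sum()))


def jaccard(set_u: frozenset | set, set_v: frozenset | set) -> float:
    """|U & V| / |U | V|; both empty -> 0 by convention."""
    union = len(set_u | set_v)
    if union == 0:
        return 0.0
    return len(set_u & set_v) / union


def distance_matrix(sets: CarrierSets) -> tuple[list[str], np.ndarray]:
    """Symmetric 1 - Jaccard distance matrix over the carrier sets."""
    genes = sets.genes()
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a distance matrix")
    n = len(genes)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard(sets.sets[genes[i]], sets.sets[genes[j]])
            D[i, j] = D[j, i] = d
    return genes, D


def ward_linkage(D: np.ndarray, leaf_labels: list[str] | None = None) -> LinkageTree:
    """Agglomerative Ward linkage over a precomputed distance matrix.

    Lance-Williams update on squared dissimilarities,
    ``d2(A+B, C) = ((nA+nC) d2(A,C) + (nB+nC) d2(B,C) - nC d2(A,B)) / (nA+nB+nC)``,
    heights reported as square roots (scipy convention).  Deterministic:
    minimal distance, ties broken by the smallest (i, j) cluster-index pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("NaN distances")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = leaf_labels if leaf_labels is not None else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("one label per leaf required")

    # active clusters keyed by scipy-style node id (leaves 0..n-1, merges n..)
    d2 = {}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = D[i, j] ** 2

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                pair = key(active[ai], active[bi])
                val = d2[pair]
                if best is None or val < best[0] - 1e-15 or (
                    abs(val - best[0]) <= 1e-15 and pair < best[1]
                ):
                    best = (val, pair)
        _, (a, b) = best
        h2 = d2[key(a, b)]
        merges[step] = (a, b, np.sqrt(max(h2, 0.0)), sizes[a] + sizes[b])
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            d2[key(next_id, c)] = (
                (na + nc) * d2[key(a, c)] + (nb + nc) * d2[key(b, c)] - nc * h2
            ) / (na + nb + nc)
        sizes[next_id] = na + nb
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return LinkageTree(merges=merges, leaf_labels=list(labels))


def cut_clusters(tree: LinkageTree, k: int | str = "auto", k_max: int = 6) -> dict[str, int]:
    """Flat clusters from the linkage tree.

    Integer ``k`` applies the first ``n - k`` merges (equivalent to cutting at
    the height that yields exactly k clusters).  ``k='auto'`` picks the k in
    [2, k_max] whose cut sits below the largest gap in successive merge
    heights (ties -> smaller k).  Cluster ids are 1-based, numbered by each
    cluster's smallest leaf index.
    """
    n = len(tree.leaf_labels)
    if k == "auto":
        if n == 1:
            k = 1
        else:
            # cutting into k clusters undoes the last k-1 merges; gap(k) is the
            # height jump the cut straddles (merge n-k vs. the one before it)
            h = tree.heights
            best_gap, k = -np.inf, 2
            for cand in range(2, min(k_max, n) + 1):
                gap = h[n - cand] - (h[n - cand - 1] if n - cand - 1 >= 0 else 0.0)
                if gap > best_gap + 1e-15:
                    best_gap, k = gap, cand
    k = int(k)
    if not 1 <= k <= n:
        raise ValueError(f"cannot cut {n} leaves into {k} clusters")

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b = int(tree.merges[step, 0]), int(tree.merges[step, 1])
        node_members[n + step] = node_members.pop(a) + node_members.pop(b)

    # number clusters by smallest member leaf index
    groups = sorted(node_members.values(), key=min)
    assignments: dict[str, int] = {}
    for cid, members in enumerate(groups, start=1):
        for leaf in members:
            assignments[tree.leaf_labels[leaf]] = cid
    return assignments


def rank_clusters(assignments: dict[str, int], sets: CarrierSets) -> HubClusterResult:
    """Per-cluster gene count a, unique-carrier union b, ratio b/a, coverage.

    The selected cluster maximizes the ratio; ties go to the larger b, then
    the smaller cluster id (logged).
    """
    missing = set(assignments) - set(sets.sets)
    if missing:
        raise ValueError(f"assignments reference genes without carrier sets: {sorted(missing)[:5]}")
    clusters: list[ClusterStats] = []
    for cid in sorted(set(assignments.values())):
        genes = sorted(g for g, c in assignments.items() if c == cid)
        union: set[str] = set()
        for g in genes:
            union |= sets.sets[g]
        a, b = len(genes), len(union)
        clusters.append(
            ClusterStats(
                cluster_id=cid,
                genes=genes,
                a=a,
                b=b,
                ratio=b / a,
                coverage=b / sets.n_cases_total,
            )
        )
    ranked = sorted(clusters, key=lambda c: (-c.ratio, -c.b, c.cluster_id))
    if len(ranked) > 1 and ranked[0].ratio == ranked[1].ratio:
        logger.info("ratio tie between clusters %d and %d", ranked[0].cluster_id, ranked[1].cluster_id)
    return HubClusterResult(
        assignments=dict(assignments),
        clusters=clusters,
        selected_cluster=ranked[0].cluster_id,
        n_cases_total=sets.n_cases_total,
    )


def to_newick(tree: LinkageTree) -> str:
    """Newick serialization with branch lengths = height differences."""
    n = len(tree.leaf_labels)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: tree.leaf_labels[i] for i in range(n)}
    for step in range(n - 1):
        a, b, h, _ = tree.merges[step]
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";" if n > 1 else node[0] + ";"


def plot_dendrogram(tree: LinkageTree, path: str) -> None:
    """Write a dendrogram figure (matplotlib, non-interactive backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(max(6, len(tree.leaf_labels) * 0.25), 5))
    dendrogram(tree.merges, labels=tree.leaf_labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("Ward height (1 - Jaccard)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
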