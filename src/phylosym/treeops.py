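"""Rooted dendrograms: newick I/O, UPGMA, random topologies, RF and MC metrics.

Trees are held as :class:`dendropy.Tree` objects. The congruence metrics are
the rooted (cluster-based) Robinson–Foulds distance — the size of the
symmetric difference between the two trees' sets of nontrivial clades — and
the Matching Cluster distance: the minimum total cost of a perfect matching
between the cluster sets, where matching cluster ``c1`` to ``c2`` costs
``|c1 XOR c2|`` over leaf sets. MC refines RF by giving credit for partial
clade overlap instead of scoring clades only as identical/different.

Both metrics are topology-only: branch lengths are ignored. Normalized
scores run from 0 (identical cluster sets) to 1 (maximally discordant).
nRF divides by ``|C1| + |C2|``; nMC divides by the maximum MC distance
attainable on the same number of leaves (see :func:`mc_max`).

Internally a topology is a nested pair structure (leaf label, or a 2-tuple
of subtrees); clusters are bitmasks over a fixed leaf ordering for speed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    InvalidArgumentError,
    LeafSetMismatchError,
    NewickParseError,
)

__all__ = [
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "tree_clusters",
    "rf_distance",
    "mc_distance",
    "mc_max",
    "random_topology",
    "enumerate_topologies",
    "upgma",
    "cophenetic_matrix",
    "TreeDistanceResult",
]

MC_EXHAUSTIVE_MAX_LEAVES = 8


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted tree.

    Raises :class:`NewickParseError` on malformed input or duplicate leaf
    labels; round-trips with :func:`write_newick`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"cannot parse newick: {exc}") from exc
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# cluster sets


def tree_clusters(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial clades of a rooted tree: leaf sets under each internal
    node, excluding the root clade and singletons.

    A bifurcating tree on n leaves has exactly n - 2 of them.
    """
    clusters: set[frozenset] = set()
    n_total = len(tree.leaf_nodes())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(leafset) <= n_total - 1:
            clusters.add(leafset)
    return clusters


def _check_leafsets(t1, t2) -> list[str]:
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise LeafSetMismatchError(l1 - l2, l2 - l1)
    return sorted(l1)


def _masks(clusters, label_index) -> list[int]:
    out = []
    for c in clusters:
        m = 0
        for lab in c:
            m |= 1 << label_index[lab]
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# results


@dataclass
class TreeDistanceResult:
    """Raw and normalized tree-distance score.

    ``normalizer_method`` records how the normalization constant was
    obtained ("cluster-count" for RF; "exhaustive" or
    "caterpillar+null" for MC), since the MC maximum is only searched
    exhaustively at small leaf counts.
    """

    metric: str
    raw: float
    normalized: float
    n_leaves: int
    normalizer: float
    normalizer_method: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "raw": self.raw,
            "normalized": self.normalized,
            "n": self.n_leaves,
            "normalizer": self.normalizer,
            "normalizer_method": self.normalizer_method,
        }


# ---------------------------------------------------------------------------
# RF / MC on cluster bitmask lists


def _rf_raw_masks(m1: list[int], m2: list[int]) -> int:
    s1, s2 = set(m1), set(m2)
    return len(s1 ^ s2)


def _mc_raw_masks(m1: list[int], m2: list[int]) -> int:
    """Minimum-weight perfect matching between cluster sets.

    The shorter list is padded with empty clusters (mask 0); cost of a pair
    is the popcount of the XOR of the two masks.
    """
    k = max(len(m1), len(m2))
    if k == 0:
        return 0
    a = list(m1) + [0] * (k - len(m1))
    b = list(m2) + [0] * (k - len(m2))
    cost = np.empty((k, k), dtype=np.int64)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            cost[i, j] = (x ^ y).bit_count()
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> TreeDistanceResult:
    """Rooted Robinson–Foulds distance between two leaf-labeled trees.

    raw = |C1 XOR C2| over nontrivial clades; nRF = raw / (|C1| + |C2|),
    which for two bifurcating trees equals raw / (2(n-2)). Branch lengths
    are ignored.
    """
    labels = _check_leafsets(t1, t2)
    idx = {lab: i for i, lab in enumerate(labels)}
    m1 = _masks(tree_clusters(t1), idx)
    m2 = _masks(tree_clusters(t2), idx)
    raw = _rf_raw_masks(m1, m2)
    denom = len(m1) + len(m2)
    norm = raw / denom if denom else 0.0
    return TreeDistanceResult("rf", float(raw), norm, len(labels), float(denom),
                              "cluster-count")


def mc_distance(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    normalizer: float | None = None,
    normalizer_method: str | None = None,
) -> TreeDistanceResult:
    """Matching Cluster distance between two leaf-labeled rooted trees.

    Pass a precomputed ``normalizer`` (e.g. from :func:`mc_max` augmented
    with a Monte-Carlo null sample) to avoid recomputing the maximum; by
    default :func:`mc_max` is consulted, and for leaf counts where the
    exhaustive maximum is impractical the caterpillar-pair heuristic is
    used, with the observed raw score folded in so nMC never exceeds 1.
    """
    labels = _check_leafsets(t1, t2)
    idx = {lab: i for i, lab in enumerate(labels)}
    m1 = _masks(tree_clusters(t1), idx)
    m2 = _masks(tree_clusters(t2), idx)
    raw = _mc_raw_masks(m1, m2)
    n = len(labels)
    if normalizer is None:
        normalizer, normalizer_method = mc_max(n)
        if raw > normalizer:  # heuristic bound exceeded; observed is a witness
            normalizer = float(raw)
            normalizer_method += "+observed"
    elif normalizer_method is None:
        normalizer_method = "caller-supplied"
    norm = raw / normalizer if normalizer else 0.0
    return TreeDistanceResult("mc", float(raw), norm, n, float(normalizer),
                              normalizer_method)


# ---------------------------------------------------------------------------
# topology enumeration and random sampling (nested-pair representation)


def _nested_insert_all(t, leaf):
    # every node of t is an attachment point (edge above it, or above root)
    yield (t, leaf)
    if isinstance(t, tuple):
        left, right = t
        for nl in _nested_insert_all(left, leaf):
            yield (nl, right)
        for nr in _nested_insert_all(right, leaf):
            yield (left, nr)


def _nested_node_count(t) -> int:
    if not isinstance(t, tuple):
        return 1
    return 1 + _nested_node_count(t[0]) + _nested_node_count(t[1])


def _nested_insert_at(t, leaf, k):
    # k-th node in preorder (0 = this subtree's root => attach above it)
    if k == 0:
        return (t, leaf)
    left, right = t
    nl = _nested_node_count(left)
    if k - 1 < nl:
        return (_nested_insert_at(left, leaf, k - 1), right)
    return (left, _nested_insert_at(right, leaf, k - 1 - nl))


def _iter_nested_topologies(labels):
    """All rooted bifurcating labeled topologies, one per sequential-insertion
    history; the scheme is a bijection onto the (2n-3)!! topologies."""
    if len(labels) == 1:
        yield labels[0]
        return
    trees = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [nt for t in trees for nt in _nested_insert_all(t, leaf)]
    yield from trees


def _random_nested(labels, rng) -> object:
    """Uniform random topology by sequential uniform attachment: leaf k+1
    attaches to one of the 2k-1 edges (or above the root) with equal
    probability, giving the uniform law over (2n-3)!! labeled topologies."""
    t = (labels[0], labels[1]) if len(labels) >= 2 else labels[0]
    for leaf in labels[2:]:
        k = int(rng.integers(_nested_node_count(t)))
        t = _nested_insert_at(t, leaf, k)
    return t


def _nested_clusters_masks(t, idx, masks_out) -> int:
    """Collect internal-node leaf bitmasks (post-order); returns this
    subtree's mask. Root and singleton clusters are filtered by caller."""
    if not isinstance(t, tuple):
        return 1 << idx[t]
    m = _nested_clusters_masks(t[0], idx, masks_out) | _nested_clusters_masks(
        t[1], idx, masks_out
    )
    masks_out.append(m)
    return m


def _nested_to_mask_clusters(t, idx, n) -> list[int]:
    masks: list[int] = []
    full = _nested_clusters_masks(t, idx, masks)
    assert full == (1 << n) - 1
    return [m for m in masks if m != full and m.bit_count() >= 2]


def _nested_to_newick(t) -> str:
    def render(x):
        if not isinstance(x, tuple):
            return x
        return f"({render(x[0])},{render(x[1])})"

    return render(t) + ";"


def _nested_to_tree(t) -> dendropy.Tree:
    return parse_newick(_nested_to_newick(t))


def random_topology(labels, rng) -> dendropy.Tree:
    """Uniform random rooted bifurcating labeled topology (unit branch
    lengths are not set; the tree is topology-only).

    ``rng`` is a :class:`numpy.random.Generator` (or a seed acceptable to
    ``numpy.random.default_rng``).
    """
    labels = list(labels)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 labels")
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate labels")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _nested_to_tree(_random_nested(labels, rng))


def enumerate_topologies(labels):
    """Yield every rooted bifurcating labeled topology on ``labels`` as a
    tree; there are (2n-3)!! of them. Intended for exhaustive checks at
    small n."""
    labels = list(labels)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 labels")
    for nested in _iter_nested_topologies(labels):
        yield _nested_to_tree(nested)


# ---------------------------------------------------------------------------
# MC normalization constant


def _caterpillar_nested(labels):
    t = (labels[0], labels[1])
    for lab in labels[2:]:
        t = (t, lab)
    return t


def _shape_signature(t):
    if not isinstance(t, tuple):
        return 1
    a = _shape_signature(t[0])
    b = _shape_signature(t[1])
    return (a, b) if repr(a) <= repr(b) else (b, a)


_MC_MAX_CACHE: dict[int, int] = {}


def _mc_max_exhaustive(n: int) -> int:
    """Exact maximum MC distance over pairs of rooted bifurcating topologies
    on n leaves.

    MC is invariant under relabeling applied to both trees, so the maximum
    over all ordered pairs equals the maximum over (one labeled
    representative per unlabeled shape) x (all labeled topologies); this
    reduces the search space by the orbit size and keeps n <= 8 tractable.
    """
    if n in _MC_MAX_CACHE:
        return _MC_MAX_CACHE[n]
    labels = [f"L{i}" for i in range(n)]
    idx = {lab: i for i, lab in enumerate(labels)}
    all_clusters = [
        _nested_to_mask_clusters(t, idx, n) for t in _iter_nested_topologies(labels)
    ]
    reps: dict[object, list[int]] = {}
    for nested, cl in zip(_iter_nested_topologies(labels), all_clusters):
        sig = _shape_signature(nested)
        reps.setdefault(repr(sig), cl)
    best = 0
    for rep_cl in reps.values():
        for cl in all_clusters:
            d = _mc_raw_masks(rep_cl, cl)
            if d > best:
                best = d
    _MC_MAX_CACHE[n] = best
    return best


def _mc_caterpillar_pair(n: int) -> int:
    """MC distance between a caterpillar and a caterpillar on interleaved
    label order — a strong lower-bound witness for the maximum."""
    labels = [f"L{i}" for i in range(n)]
    idx = {lab: i for i, lab in enumerate(labels)}
    order2 = labels[0::2] + labels[1::2]
    c1 = _nested_to_mask_clusters(_caterpillar_nested(labels), idx, n)
    c2 = _nested_to_mask_clusters(_caterpillar_nested(order2), idx, n)
    return _mc_raw_masks(c1, c2)


def mc_max(n: int, null_scores=None) -> tuple[float, str]:
    """Normalization constant for the Matching Cluster distance on n leaves.

    Returns ``(value, method)``. For n <= 8 the maximum over all topology
    pairs is found by exhaustive (shape-representative) search and is exact.
    For larger n the exhaustive search is impractical; the constant is the
    maximum of the caterpillar-vs-interleaved-caterpillar witness pair and
    any ``null_scores`` observed (e.g. the Monte-Carlo null sample of a
    congruence test), and the method string says so.
    """
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    if n <= MC_EXHAUSTIVE_MAX_LEAVES:
        return float(_mc_max_exhaustive(n)), "exhaustive"
    val = float(_mc_caterpillar_pair(n))
    method = "caterpillar"
    if null_scores is not None and len(null_scores) > 0:
        mx = float(max(null_scores))
        if mx > val:
            val = mx
        method = "caterpillar+null"
    return val, method


# ---------------------------------------------------------------------------
# UPGMA


def upgma(dm) -> dendropy.Tree:
    """UPGMA (size-weighted average linkage) on an skbio ``DistanceMatrix``.

    The closest pair of clusters is merged at height d/2; after a merge the
    distance from the new cluster to any other is the size-weighted mean of
    the two member distances (true UPGMA, not WPGMA). Exact ties are broken
    by the lexicographically smallest pair of cluster labels, where a
    cluster is labeled by its smallest leaf label, so the merge order is
    deterministic across platforms. The output is ultrametric.
    """
    data = np.asarray(dm.data, dtype=float)
    if np.isnan(data).any():
        raise InvalidArgumentError("distance matrix contains NaN")
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise InvalidArgumentError("need at least 2 items")

    taxa = dendropy.TaxonNamespace(ids)
    nodes = {}
    for i, lab in enumerate(ids):
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd._height = 0.0
        nodes[i] = nd

    active = {i: (ids[i], 1) for i in range(n)}  # id -> (min leaf label, size)
    dist = {frozenset((i, j)): data[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best_key, best_d, best_pair = None, None, None
        for key, d in dist.items():
            i, j = sorted(key)
            pair = tuple(sorted((active[i][0], active[j][0])))
            if (
                best_d is None
                or d < best_d
                or (d == best_d and pair < best_pair)
            ):
                best_key, best_d, best_pair = key, d, pair
        i, j = sorted(best_key)
        hi = best_d / 2.0
        parent = dendropy.Node()
        parent._height = hi
        for child_id in (i, j):
            child = nodes.pop(child_id)
            child.edge.length = hi - child._height
            parent.add_child(child)
        nodes[next_id] = parent
        li, si = active.pop(i)
        lj, sj = active.pop(j)
        del dist[best_key]
        for k in list(active):
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        active[next_id] = (min(li, lj), si + sj)
        next_id += 1

    root = nodes[next_id - 1]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree


def cophenetic_matrix(tree: dendropy.Tree):
    """Leaf-to-leaf path-length (patristic) distances as an skbio
    ``DistanceMatrix``; edges without a length count as 0."""
    from skbio.stats.distance import DistanceMatrix

    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
        mat[a, b] = mat[b, a] = d
    return DistanceMatrix(mat, ids=labels)
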