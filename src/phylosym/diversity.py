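"""Depth normalization, alpha and beta diversity, and shared-OTU summaries.

Conventions pinned here (all overridable):

* Shannon entropy is reported in bits (log base 2).
* Simpson is the Gini–Simpson index ``1 - sum(p_i^2)``; the inverse form is
  available via ``variant="inverse"``.
* Chao1 defaults to the bias-corrected estimator, which stays defined when
  there are no doubletons; the classic form is available.
* ACE uses the conventional rare/abundant cutoff of 10 and clamps the
  coefficient of variation ``gamma^2`` at 0.
* Faith's PD includes the path to the root (whole-tree convention).
* Weighted UniFrac defaults to the normalized variant, bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .errors import (
    DepthExceedsSampleError,
    InvalidArgumentError,
    MetadataMismatchError,
    MissingTaxaError,
    UndefinedStatisticError,
)
from .otu import OTUTable, SampleMetadata

ALPHA_INDICES = ("observed", "chao1", "ace", "shannon", "simpson", "faith_pd")
BETA_METRICS = ("bray_curtis", "binary_jaccard", "unweighted_unifrac", "weighted_unifrac")
ACE_RARE_CUTOFF = 10


# ---------------------------------------------------------------------------
# rarefaction


def rarefy_table(table: OTUTable, depth="min", seed=None, drop_empty_otus=False) -> OTUTable:
    """Subsample every sample, without replacement, to a common depth.

    ``depth="min"`` uses the shallowest sample's total — the normalization
    rule where the sample with the fewest sequences sets the standard.
    Samples shallower than an explicit ``depth`` are an error rather than
    being silently dropped. Zero-count OTU rows are retained by default so
    OTU indexing stays aligned across tables.
    """
    totals = table.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    for sid, tot in totals.items():
        if tot < depth:
            raise DepthExceedsSampleError(sid, int(tot), depth)
    rng = np.random.default_rng(seed)
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col.copy()
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    res = OTUTable(pd.DataFrame(out, index=table.counts.index), table.taxonomy)
    return res.drop_empty_otus() if drop_empty_otus else res


def rarefaction_curve(table: OTUTable, depths, reps=10, seed=None) -> pd.DataFrame:
    """Mean observed-species count per sample over a depth grid.

    For each sample, depths above its total are skipped (NaN); each point is
    the mean over ``reps`` independent subsamples.
    """
    if reps < 1:
        raise InvalidArgumentError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    depths = [int(d) for d in depths]
    rows = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        tot = int(col.sum())
        vals = []
        for d in depths:
            if d > tot:
                vals.append(np.nan)
            elif d == tot:
                vals.append(float((col > 0).sum()))
            else:
                obs = [
                    float((rng.multivariate_hypergeometric(col, d) > 0).sum())
                    for _ in range(reps)
                ]
                vals.append(float(np.mean(obs)))
        rows[sid] = vals
    return pd.DataFrame(rows, index=pd.Index(depths, name="depth")).T


# ---------------------------------------------------------------------------
# alpha diversity


def _freqs(counts):
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or (x < 0).any():
        raise InvalidArgumentError("counts must be a nonnegative 1-D vector")
    if x.sum() == 0:
        raise UndefinedStatisticError("all-zero count vector")
    return x


def observed_species(counts) -> float:
    return float((_freqs(counts) > 0).sum())


def chao1(counts, bias_corrected=True) -> float:
    x = _freqs(counts)
    s_obs = float((x > 0).sum())
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def ace(counts, rare_cutoff=ACE_RARE_CUTOFF) -> float:
    x = _freqs(counts)
    x = x[x > 0]
    rare = x[x <= rare_cutoff]
    s_abund = float((x > rare_cutoff).sum())
    s_rare = float(len(rare))
    n_rare = float(rare.sum())
    f1 = float((rare == 1).sum())
    if s_rare == 0:
        return s_abund
    if n_rare == f1:
        # every rare OTU is a singleton; sample coverage is 0 and the
        # estimator is undefined
        raise UndefinedStatisticError("ACE undefined: all rare OTUs are singletons")
    c_ace = 1.0 - f1 / n_rare
    ssum = sum(i * (i - 1) * float((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max((s_rare / c_ace) * ssum / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts, base=2) -> float:
    x = _freqs(counts)
    p = x[x > 0] / x.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(counts, variant="gini") -> float:
    x = _freqs(counts)
    p = x / x.sum()
    ss = float((p**2).sum())
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise InvalidArgumentError(f"unknown simpson variant {variant!r}")


def faith_pd(counts, otu_ids, tree: dendropy.Tree) -> float:
    """Total branch length of the minimal rooted subtree spanning the
    observed OTUs, including the path to the root."""
    x = _freqs(counts)
    present = {oid for oid, c in zip(otu_ids, x) if c > 0}
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = present - tree_leaves
    if missing:
        raise MissingTaxaError(missing)
    total = 0.0
    stack_presence: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has = node.taxon.label in present
        else:
            has = any(stack_presence.pop(id(ch)) for ch in node.child_nodes())
        stack_presence[id(node)] = has
        if has and node.parent_node is not None and node.edge.length:
            total += node.edge.length
    return total


_ALPHA_FUNCS = {
    "observed": lambda c, **k: observed_species(c),
    "chao1": lambda c, bias_corrected=True, **k: chao1(c, bias_corrected),
    "ace": lambda c, **k: ace(c),
    "shannon": lambda c, base=2, **k: shannon(c, base),
    "simpson": lambda c, variant="gini", **k: simpson(c, variant),
}


def alpha_diversity(counts, index, tree=None, otu_ids=None, **options) -> float:
    """Single alpha-diversity value for one sample's count vector.

    ``index`` is one of observed, chao1, ace, shannon, simpson, faith_pd;
    faith_pd additionally needs ``otu_ids`` and a reference ``tree``
    containing all observed OTUs.
    """
    if index == "faith_pd":
        if tree is None or otu_ids is None:
            raise InvalidArgumentError("faith_pd requires otu_ids and a tree")
        return faith_pd(counts, otu_ids, tree)
    try:
        fn = _ALPHA_FUNCS[index]
    except KeyError:
        raise InvalidArgumentError(f"unknown alpha index {index!r}") from None
    return fn(counts, **options)


def alpha_table(table: OTUTable, indices=ALPHA_INDICES, tree=None, **options) -> pd.DataFrame:
    """Alpha diversity for every sample (rows) and index (columns)."""
    rows = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        rows[sid] = {
            idx: alpha_diversity(col, idx, tree=tree, otu_ids=table.otu_ids, **options)
            for idx in indices
        }
    return pd.DataFrame(rows).T.loc[table.sample_ids, list(indices)]


# ---------------------------------------------------------------------------
# beta diversity


def _branch_table(tree: dendropy.Tree, otu_ids):
    """Per-branch (length, descendant-leaf index list) over the OTU order."""
    leafset = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(otu_ids) - leafset
    if missing:
        raise MissingTaxaError(missing)
    pos = {oid: i for i, oid in enumerate(otu_ids)}
    lengths, members = [], []
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idxs = [pos[node.taxon.label]] if node.taxon.label in pos else []
        else:
            idxs = []
            for ch in node.child_nodes():
                idxs.extend(below.pop(id(ch)))
        below[id(node)] = idxs
        if node.parent_node is not None:
            lengths.append(node.edge.length or 0.0)
            members.append(idxs)
    return np.asarray(lengths), members


def _branch_props(lengths, members, x):
    """Fraction of a sample's reads descending from each branch."""
    tot = x.sum()
    return np.array([x[m].sum() for m in members]) / tot


def _unifrac(x, y, lengths, members, weighted, normalized):
    px = _branch_props(lengths, members, np.asarray(x, dtype=float))
    py = _branch_props(lengths, members, np.asarray(y, dtype=float))
    if not weighted:
        ax, ay = px > 0, py > 0
        either = float(lengths[ax | ay].sum())
        unique = float(lengths[ax ^ ay].sum())
        return unique / either if either else 0.0
    raw = float((lengths * np.abs(px - py)).sum())
    if not normalized:
        return raw
    # sum_b L_b (p_b(x)+p_b(y)) telescopes to
    # sum_leaf depth_leaf * (p_leaf(x)+p_leaf(y)), the standard normalizer
    denom = float((lengths * (px + py)).sum())
    return raw / denom if denom else 0.0


def beta_distance(x, y, metric, tree=None, otu_ids=None, normalized=True) -> float:
    """Dissimilarity between two samples' count vectors on a shared OTU order.

    bray_curtis and weighted UniFrac use abundances; binary_jaccard and
    unweighted UniFrac use presence/absence. UniFrac variants require the
    bacterial reference ``tree`` and the ``otu_ids`` giving each vector
    entry's leaf label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("vectors must have equal length")
    if x.sum() == 0 and y.sum() == 0:
        raise UndefinedStatisticError("both vectors are all-zero")
    if metric == "bray_curtis":
        return float(np.abs(x - y).sum() / (x + y).sum())
    if metric == "binary_jaccard":
        bx, by = x > 0, y > 0
        union = (bx | by).sum()
        return float(1.0 - (bx & by).sum() / union)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None or otu_ids is None:
            raise InvalidArgumentError(f"{metric} requires otu_ids and a tree")
        lengths, members = _branch_table(tree, otu_ids)
        return _unifrac(x, y, lengths, members,
                        weighted=(metric == "weighted_unifrac"), normalized=normalized)
    raise InvalidArgumentError(f"unknown beta metric {metric!r}")


def distance_matrix(table: OTUTable, metric, tree=None, normalized=True) -> DistanceMatrix:
    """All pairwise sample dissimilarities for one metric."""
    sids = table.sample_ids
    if len(sids) < 2:
        raise InvalidArgumentError("need at least 2 samples")
    X = table.counts.to_numpy(dtype=float).T  # samples x OTUs
    n = len(sids)
    mat = np.zeros((n, n))
    prec = None
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise InvalidArgumentError(f"{metric} requires a tree")
        prec = _branch_table(tree, table.otu_ids)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if prec is not None:
                    if X[i].sum() == 0 and X[j].sum() == 0:
                        raise UndefinedStatisticError("both vectors are all-zero")
                    d = _unifrac(X[i], X[j], *prec,
                                 weighted=(metric == "weighted_unifrac"),
                                 normalized=normalized)
                else:
                    d = beta_distance(X[i], X[j], metric)
            except UndefinedStatisticError as exc:
                raise UndefinedStatisticError(
                    f"pair ({sids[i]}, {sids[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=sids)


def collapse_to_populations(dm: DistanceMatrix, metadata: SampleMetadata) -> DistanceMatrix:
    """Population-level distance matrix: each between-population entry is the
    mean of all between-sample distances across the two populations."""
    pops = metadata.population_of(dm.ids)
    labels = sorted(set(pops))
    if len(labels) < 2:
        raise MetadataMismatchError("need at least 2 populations")
    groups = {lab: np.flatnonzero((pops == lab).to_numpy()) for lab in labels}
    k = len(labels)
    mat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = dm.data[np.ix_(groups[labels[a]], groups[labels[b]])]
            mat[a, b] = mat[b, a] = float(block.mean())
    return DistanceMatrix(mat, ids=labels)


# ---------------------------------------------------------------------------
# shared / core OTUs and endosymbiont proportion


@dataclass
class SharedOtuResult:
    core_otus: list[str]
    per_population_richness: dict[str, int]
    shared_percent: dict[str, float]  # |core| / per-population richness * 100
    shared_percent_of_total: dict[str, float]  # |core| / total OTU count * 100


def shared_otus(table: OTUTable, metadata: SampleMetadata, mode="any") -> SharedOtuResult:
    """Core OTUs present in every population, plus per-population shared
    fractions.

    Presence in a population means detected in at least one of its samples
    (``mode="any"``, the pooled convention); ``mode="all"`` requires
    detection in every sample of the population.
    """
    pops = metadata.population_of(table.sample_ids)
    labels = sorted(set(pops))
    presence = {}
    for lab in labels:
        cols = [s for s, p in zip(table.sample_ids, pops) if p == lab]
        if not cols:
            raise MetadataMismatchError(f"population {lab!r} has no samples")
        sub = table.counts[cols].to_numpy()
        if mode == "any":
            pres = (sub > 0).any(axis=1)
        elif mode == "all":
            pres = (sub > 0).all(axis=1)
        else:
            raise InvalidArgumentError(f"unknown mode {mode!r}")
        presence[lab] = pres
    core_mask = np.logical_and.reduce([presence[lab] for lab in labels])
    core = [oid for oid, c in zip(table.otu_ids, core_mask) if c]
    n_total = len(table.otu_ids)
    richness = {lab: int(presence[lab].sum()) for lab in labels}
    shared_pct = {
        lab: (100.0 * len(core) / richness[lab]) if richness[lab] else 0.0
        for lab in labels
    }
    shared_total = {lab: 100.0 * len(core) / n_total for lab in labels}
    return SharedOtuResult(core, richness, shared_pct, shared_total)


def endosymbiont_proportion(table: OTUTable, target="Wolbachia") -> pd.Series:
    """Per-sample relative abundance of an endosymbiont genus.

    OTUs are matched by case-insensitive substring of their taxonomy string
    (several OTUs may map to the same genus; their counts are summed).
    """
    if table.taxonomy is None:
        raise InvalidArgumentError("table has no taxonomy annotations")
    tgt = target.lower()
    mask = table.taxonomy.fillna("").str.lower().str.contains(tgt, regex=False)
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise UndefinedStatisticError(f"samples with zero total counts: {bad}")
    hits = table.counts.loc[mask.to_numpy()].sum(axis=0)
    return (hits / totals).astype(float)
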