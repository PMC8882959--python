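"""Phylosymbiosis tests: Mantel matrix correlation and topological congruence.

A phylosymbiotic signal is host-associated community similarity that
recapitulates the hosts' phylogeny. Two complementary tests are provided:

* :func:`mantel_test` — permutation test of the correlation between a host
  genetic/cophenetic distance matrix and a microbiota beta-diversity matrix
  (one-sided "greater" by default: phylosymbiosis predicts a positive
  association).
* :func:`topological_congruence` — compares the host tree to the microbiota
  UPGMA dendrogram with the Robinson–Foulds or Matching Cluster distance and
  evaluates significance against a Monte-Carlo null of uniform random
  bifurcating topologies on the same leaves: P is the fraction of random
  topologies at least as congruent with the microbiota dendrogram as the
  host tree is (with the +1 correction, so P is never 0).

:func:`phylosymbiosis_report` chains the whole analysis from an OTU table.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from . import diversity, treeops
from .errors import InvalidArgumentError, UndefinedStatisticError
from .otu import OTUTable, SampleMetadata

DEFAULT_N_RANDOM = 100_000


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    alternative: str
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r, "P": self.p_value, "n_perm": self.n_permutations,
            "method": self.method, "alternative": self.alternative, "n": self.n,
        }


@dataclass
class CongruenceResult:
    metric: str
    raw: float
    normalized: float
    p_value: float
    n_random: int
    n_leaves: int
    null_mean: float
    null_quantiles: dict[str, float]
    normalizer: float
    normalizer_method: str
    seed: object = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "score": self.raw, "normalized": self.normalized,
            "P": self.p_value, "n_random": self.n_random, "n": self.n_leaves,
            "null_mean": self.null_mean, "null_quantiles": self.null_quantiles,
            "normalizer": self.normalizer,
            "normalizer_method": self.normalizer_method, "seed": self.seed,
        }


def _aligned_condensed(a: DistanceMatrix, b: DistanceMatrix):
    if set(a.ids) != set(b.ids):
        only_a = sorted(set(a.ids) - set(b.ids))
        only_b = sorted(set(b.ids) - set(a.ids))
        raise InvalidArgumentError(
            f"matrix labels differ: only in first {only_a}, only in second {only_b}"
        )
    b = b.filter(a.ids)
    return np.asarray(a.data, dtype=float), np.asarray(b.data, dtype=float)


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm=9999,
    method="pearson",
    alternative="greater",
    seed=None,
) -> MantelResult:
    """Mantel permutation test between two labeled distance matrices.

    Matrices are aligned by label (not position). r is the pearson (or
    spearman) correlation over the n(n-1)/2 off-diagonal entries; the null
    is built by jointly permuting rows/columns of the second matrix, and
    P = (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the default
    ``alternative="greater"`` ("less" and "two-sided" available).
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    if alternative not in ("greater", "less", "two-sided"):
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    am, bm = _aligned_condensed(a, b)
    n = am.shape[0]
    if n < 3:
        raise InvalidArgumentError("need at least 3 items")
    iu = np.triu_indices(n, k=1)
    if method == "spearman":
        # rank the off-diagonal entries once; a joint row/column permutation
        # only rearranges them, so spearman reduces to pearson on ranks
        am = _rank_offdiag(am, iu)
        bm = _rank_offdiag(bm, iu)
    va = am[iu]
    if np.ptp(va) == 0 or np.ptp(bm[iu]) == 0:
        raise UndefinedStatisticError("constant distance matrix; r undefined")
    za = (va - va.mean()) / va.std()

    def corr(mat):
        vb = mat[iu]
        sd = vb.std()
        if sd == 0:
            return 0.0
        return float((za * (vb - vb.mean()) / sd).mean())

    r_obs = corr(bm)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(bm[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs
        elif alternative == "less":
            hits += r_p <= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, method, alternative, n)


def _rank_offdiag(mat, iu):
    out = np.zeros_like(mat)
    ranks = stats.rankdata(mat[iu])
    out[iu] = ranks
    out.T[iu] = ranks
    return out


def topological_congruence(
    host: dendropy.Tree,
    micro: dendropy.Tree,
    metric="rf",
    n_random=DEFAULT_N_RANDOM,
    seed=None,
) -> CongruenceResult:
    """Monte-Carlo congruence test of a host tree against a microbiota
    dendrogram.

    The observed RF or MC distance is compared with the distances from
    ``n_random`` uniform random bifurcating topologies (same leaves) to the
    microbiota dendrogram; P = (1 + #{null <= observed}) / (n_random + 1).
    For the MC metric the normalization constant on more than 8 leaves is
    the maximum of the caterpillar witness pair, the null sample and the
    observed score (recorded in ``normalizer_method``).
    """
    if metric not in ("rf", "mc"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    if n_random < 1:
        raise InvalidArgumentError("n_random must be >= 1")
    labels = treeops._check_leafsets(host, micro)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    m_host = treeops._masks(treeops.tree_clusters(host), idx)
    m_micro = treeops._masks(treeops.tree_clusters(micro), idx)
    dist = treeops._rf_raw_masks if metric == "rf" else treeops._mc_raw_masks
    s_obs = dist(m_host, m_micro)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        nested = treeops._random_nested(labels, rng)
        null[i] = dist(treeops._nested_to_mask_clusters(nested, idx, n), m_micro)
    p = (1 + int((null <= s_obs).sum())) / (n_random + 1)
    if metric == "rf":
        normalizer = float(len(m_host) + len(m_micro))
        norm_method = "cluster-count"
    else:
        if n <= treeops.MC_EXHAUSTIVE_MAX_LEAVES:
            normalizer, norm_method = treeops.mc_max(n)
        else:
            normalizer, norm_method = treeops.mc_max(n, null_scores=null)
            if s_obs > normalizer:
                normalizer, norm_method = float(s_obs), norm_method + "+observed"
    quantiles = {
        q: float(np.quantile(null, float(q)))
        for q in ("0.05", "0.25", "0.5", "0.75", "0.95")
    }
    return CongruenceResult(
        metric, float(s_obs), float(s_obs) / normalizer if normalizer else 0.0,
        float(p), n_random, n, float(null.mean()), quantiles,
        float(normalizer), norm_method, seed,
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PhylosymbiosisConfig:
    beta_metrics: tuple = ("bray_curtis", "binary_jaccard",
                           "unweighted_unifrac", "weighted_unifrac")
    dendrogram_metric: str = "bray_curtis"  # metric behind the UPGMA dendrogram
    congruence_metrics: tuple = ("rf", "mc")
    rarefy_depth: object = "min"
    n_perm: int = 9999
    n_random: int = 1000
    mantel_method: str = "pearson"
    mantel_alternative: str = "greater"
    seed: int = 0


def phylosymbiosis_report(
    host,
    table: OTUTable,
    metadata: SampleMetadata,
    bacterial_tree: dendropy.Tree | None = None,
    config: PhylosymbiosisConfig | None = None,
) -> dict:
    """Run the full phylosymbiosis analysis and return a JSON-ready report.

    ``host`` is either a rooted tree over the population labels (cophenetic
    distances are computed from it) or a precomputed genetic
    ``DistanceMatrix``. The chain: rarefy to common depth -> per-sample beta
    matrices for the configured metrics -> collapse to populations ->
    Mantel test per metric against the host distances -> UPGMA on the
    configured dendrogram metric -> RF/MC Monte-Carlo congruence against the
    host tree (skipped, with a note, when the host is given only as a
    distance matrix).
    """
    cfg = config or PhylosymbiosisConfig()
    if isinstance(host, DistanceMatrix):
        host_dm, host_tree = host, None
    else:
        host_dm, host_tree = treeops.cophenetic_matrix(host), host

    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(rng.integers(2**31))
        for name in ("rarefy", "mantel", "congruence")
    }
    report: dict = {
        "config": {
            "beta_metrics": list(cfg.beta_metrics),
            "dendrogram_metric": cfg.dendrogram_metric,
            "congruence_metrics": list(cfg.congruence_metrics),
            "rarefy_depth": cfg.rarefy_depth,
            "n_perm": cfg.n_perm,
            "n_random": cfg.n_random,
            "mantel_method": cfg.mantel_method,
            "mantel_alternative": cfg.mantel_alternative,
            "seed": cfg.seed,
            "stage_seeds": stage_seeds,
        },
        "notes": [
            "Mantel P-values are reported per beta metric without "
            "multiple-testing correction."
        ],
    }

    rare = diversity.rarefy_table(table, depth=cfg.rarefy_depth,
                                  seed=stage_seeds["rarefy"])
    report["rarefied_depth"] = int(rare.sample_totals().iloc[0])

    pop_dms = {}
    mantel_out = {}
    for metric in cfg.beta_metrics:
        dm = diversity.distance_matrix(rare, metric, tree=bacterial_tree)
        pop_dm = diversity.collapse_to_populations(dm, metadata)
        pop_dms[metric] = pop_dm
        res = mantel_test(
            host_dm, pop_dm, n_perm=cfg.n_perm, method=cfg.mantel_method,
            alternative=cfg.mantel_alternative, seed=stage_seeds["mantel"],
        )
        mantel_out[metric] = res.to_dict()
    report["mantel"] = mantel_out

    micro_tree = treeops.upgma(pop_dms[cfg.dendrogram_metric])
    report["microbiota_dendrogram"] = treeops.write_newick(micro_tree)

    if host_tree is None:
        report["congruence"] = None
        report["notes"].append(
            "host given as a distance matrix; topological congruence skipped"
        )
    else:
        cong = {}
        for metric in cfg.congruence_metrics:
            res = topological_congruence(
                host_tree, micro_tree, metric=metric,
                n_random=cfg.n_random, seed=stage_seeds["congruence"],
            )
            cong[metric] = res.to_dict()
        report["congruence"] = cong
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a phylosymbiosis report."""
    lines = ["Phylosymbiosis report", "====================="]
    lines.append(f"rarefied depth: {report.get('rarefied_depth')}")
    lines.append("")
    lines.append("Mantel tests (host distances vs microbiota beta diversity):")
    for metric, r in report["mantel"].items():
        lines.append(
            f"  {metric:>20s}: r = {r['r']: .3f}  P = {r['P']:.4g} "
            f"({r['method']}, {r['alternative']}, {r['n_perm']} permutations)"
        )
    lines.append("")
    if report.get("congruence"):
        lines.append("Topological congruence (host tree vs microbiota dendrogram):")
        for metric, c in report["congruence"].items():
            lines.append(
                f"  {metric:>4s}: raw = {c['score']:.0f}  "
                f"normalized = {c['normalized']:.3f}  P = {c['P']:.4g} "
                f"({c['n_random']} random topologies; "
                f"normalizer {c['normalizer']:.0f} via {c['normalizer_method']})"
            )
    for note in report.get("notes", []):
        lines.append(f"note: {note}")
    return "\n".join(lines)
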