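"""Synthetic holobiont data: host trees and OTU tables with a tunable
phylosymbiosis signal and an endosymbiont spike-in.

The generator emulates a multi-population host survey: by default 9 host
populations with 6 individuals each, of which 6 populations carry a
dominant intracellular endosymbiont (a *Wolbachia*-like taxon) whose
relative abundance per infected population is drawn uniformly from
(0.203, 0.964) — the observed prevalence range such endosymbionts reach in
infected insect hosts.

Community model: each background OTU has a root log-abundance drawn
N(0, 1); log-abundances evolve along the host tree as Brownian motion with
variance ``sigma_phylo**2 * branch_length``, giving a population-level
profile at each leaf; each individual adds i.i.d. N(0, sigma_ind**2) noise
per OTU; relative abundances are the softmax of the log-profile; in
infected populations the endosymbiont OTU takes a fixed fraction ``w`` of
the community (background rescaled by ``1 - w``); reads are multinomial at
a fixed sequencing depth. ``sigma_phylo / sigma_ind`` therefore dials the
phylosymbiosis signal from none (0) to strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .otu import OTUTable, SampleMetadata, write_metadata, write_otu_table
from .treeops import _nested_to_newick, _random_nested, leaf_labels, parse_newick, write_newick

ENDO_OTU_ID = "OTU_ENDO"
ENDO_TAXONOMY = (
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; "
    "o__Rickettsiales; f__Anaplasmataceae; g__Wolbachia; s__"
)


@dataclass
class SimParams:
    """Parameters of the synthetic holobiont design.

    Defaults mirror the emulated survey: 9 populations x 6 individuals,
    6 infected populations (36 infected vs 18 uninfected samples), and an
    endosymbiont load of 20.3–96.4% of reads in infected hosts. ``n_otus``
    and ``depth`` are desk-scale; ``sigma_phylo`` and ``sigma_ind`` set the
    between- vs within-population variance of log-abundances.
    """

    n_populations: int = 9
    n_individuals_per_population: int = 6
    n_otus: int = 200
    depth: int = 20_000
    sigma_phylo: float = 1.0
    sigma_ind: float = 0.3
    infected_populations: tuple | None = None  # default: first 6 populations
    endo_prop_range: tuple = (0.203, 0.964)
    host_branch_lengths: str = "exponential"  # or "coalescent" (clock-like)
    seed: int = 0

    def __post_init__(self):
        if self.n_populations < 2:
            raise InvalidArgumentError("n_populations must be >= 2")
        if self.n_individuals_per_population < 1:
            raise InvalidArgumentError("n_individuals_per_population must be >= 1")
        if self.n_otus < 2:
            raise InvalidArgumentError("n_otus must be >= 2")
        if self.depth < 1:
            raise InvalidArgumentError("depth must be >= 1")
        if self.sigma_phylo < 0 or self.sigma_ind < 0:
            raise InvalidArgumentError("sigma parameters must be >= 0")
        lo, hi = self.endo_prop_range
        if not (0 <= lo <= hi < 1):
            raise InvalidArgumentError("need 0 <= endo_prop_min <= endo_prop_max < 1")
        if self.host_branch_lengths not in ("exponential", "coalescent"):
            raise InvalidArgumentError(
                f"unknown host_branch_lengths {self.host_branch_lengths!r}"
            )

    def to_dict(self) -> dict:
        return {
            "n_populations": self.n_populations,
            "n_individuals_per_population": self.n_individuals_per_population,
            "n_otus": self.n_otus,
            "depth": self.depth,
            "sigma_phylo": self.sigma_phylo,
            "sigma_ind": self.sigma_ind,
            "infected_populations": (
                list(self.infected_populations)
                if self.infected_populations is not None else None
            ),
            "endo_prop_range": list(self.endo_prop_range),
            "host_branch_lengths": self.host_branch_lengths,
            "seed": self.seed,
        }


@dataclass
class SyntheticDataset:
    table: OTUTable
    metadata: SampleMetadata
    host_tree: dendropy.Tree
    bacterial_tree: dendropy.Tree
    endo_proportions: dict[str, float]  # true w per infected population
    params: SimParams = field(repr=False, default=None)


def population_labels(n: int) -> list[str]:
    return [f"P{i + 1}" for i in range(n)]


def _random_tree(labels, rng, lengths="exponential") -> dendropy.Tree:
    nested = _random_nested(list(labels), rng)
    tree = parse_newick(_nested_to_newick(nested))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        edge.length = float(rng.exponential(1.0)) if lengths == "exponential" else 1.0
        if edge.length == 0.0:  # exponential(1) draw of exactly 0 is measure-zero
            edge.length = np.finfo(float).tiny
    return tree


def _coalescent_tree(labels, rng) -> dendropy.Tree:
    """Kingman-coalescent host tree: ultrametric (clock-like), as befits
    contemporaneous populations; pair to merge chosen uniformly, waiting
    times exponential with rate k(k-1)/2."""
    taxa = dendropy.TaxonNamespace(list(labels))
    lineages = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd._height = 0.0
        lineages.append(nd)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += float(rng.exponential(2.0 / (k * (k - 1))))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = dendropy.Node()
        parent._height = t
        for child in (a, b):
            child.edge.length = t - child._height
            parent.add_child(child)
        lineages = [nd for nd in lineages if nd not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = lineages[0]
    return tree


def simulate_host_tree(n_populations: int, seed=None,
                       branch_lengths="exponential") -> dendropy.Tree:
    """Random rooted bifurcating host topology over population labels
    P1..Pn.

    ``branch_lengths="exponential"`` (default) draws a uniform random
    labeled topology with i.i.d. exponential(1) branch lengths — generally
    non-clock. ``"coalescent"`` draws a Kingman coalescent tree, which is
    ultrametric; use it when the downstream analysis assumes clock-like
    host divergence (UPGMA recovery is only consistent in that regime).
    """
    if n_populations < 2:
        raise InvalidArgumentError("n_populations must be >= 2")
    rng = np.random.default_rng(seed)
    labels = population_labels(n_populations)
    if branch_lengths == "exponential":
        return _random_tree(labels, rng)
    if branch_lengths == "coalescent":
        return _coalescent_tree(labels, rng)
    raise InvalidArgumentError(f"unknown branch_lengths mode {branch_lengths!r}")


def simulate_bacterial_tree(otu_ids, seed=None) -> dendropy.Tree:
    """Random rooted bifurcating reference tree over OTU ids with
    exponential(1) branch lengths (stands in for a 16S gene tree)."""
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise InvalidArgumentError("need at least 2 OTU ids")
    if len(set(otu_ids)) != len(otu_ids):
        raise InvalidArgumentError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    return _random_tree(otu_ids, rng)


def _brownian_leaf_profiles(host, root_profile, sigma_phylo, rng):
    """Evolve the K-vector log-profile along the tree; returns {leaf: vector}."""
    profiles = {}
    values = {id(host.seed_node): root_profile}
    for node in host.preorder_node_iter():
        if node is host.seed_node:
            continue
        parent = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, 1.0, size=root_profile.shape) * sigma_phylo * np.sqrt(bl)
        values[id(node)] = parent + step
        if node.is_leaf():
            profiles[node.taxon.label] = values[id(node)]
    return profiles


def simulate_dataset(host: dendropy.Tree, params: SimParams) -> SyntheticDataset:
    """Generate an OTU table, metadata and bacterial tree for a host tree.

    Deterministic given ``params.seed``; every sample's counts sum exactly
    to ``params.depth``. The endosymbiont proportion is drawn once per
    infected population (infection status is a population-level trait), and
    the endosymbiont OTU row exists only when at least one population is
    infected.
    """
    pops = leaf_labels(host)
    if len(pops) != params.n_populations:
        raise InvalidArgumentError(
            f"host tree has {len(pops)} leaves, params expect {params.n_populations}"
        )
    if params.infected_populations is None:
        infected = sorted(pops)[: min(6, len(pops))]
    else:
        infected = list(params.infected_populations)
        unknown = set(infected) - set(pops)
        if unknown:
            raise InvalidArgumentError(
                f"infected populations not in host tree: {sorted(unknown)}"
            )
    rng = np.random.default_rng(params.seed)

    k = params.n_otus - (1 if infected else 0)  # background OTUs
    if k < 1:
        raise InvalidArgumentError("need at least 2 OTUs with an endosymbiont")
    bg_ids = [f"OTU_{i + 1:04d}" for i in range(k)]
    otu_ids = bg_ids + ([ENDO_OTU_ID] if infected else [])

    root_profile = rng.normal(0.0, 1.0, size=k)
    leaf_profiles = _brownian_leaf_profiles(host, root_profile, params.sigma_phylo, rng)
    endo_w = {
        pop: float(rng.uniform(*params.endo_prop_range)) for pop in sorted(infected)
    }

    columns = {}
    meta_rows = {}
    for pop in pops:
        for i in range(params.n_individuals_per_population):
            sid = f"{pop}_s{i + 1}"
            logp = leaf_profiles[pop] + rng.normal(0.0, params.sigma_ind, size=k)
            p = np.exp(logp - logp.max())
            p /= p.sum()
            if pop in endo_w:
                w = endo_w[pop]
                p = np.concatenate([p * (1.0 - w), [w]])
            elif infected:
                p = np.concatenate([p, [0.0]])
            columns[sid] = rng.multinomial(params.depth, p)
            meta_rows[sid] = {
                "population": pop,
                "endosymbiont_status": "infected" if pop in endo_w else "uninfected",
            }

    taxonomy = pd.Series(
        [f"k__Bacteria; g__Genus{i + 1}; s__" for i in range(k)]
        + ([ENDO_TAXONOMY] if infected else []),
        index=otu_ids,
    )
    table = OTUTable(pd.DataFrame(columns, index=otu_ids), taxonomy)
    metadata = SampleMetadata(pd.DataFrame(meta_rows).T)
    bact_seed = int(rng.integers(2**31))
    bacterial_tree = simulate_bacterial_tree(otu_ids, seed=bact_seed)
    return SyntheticDataset(table, metadata, host, bacterial_tree, endo_w, params)


def simulate_study(params: SimParams) -> SyntheticDataset:
    """Host tree + dataset in one call, fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    host_seed = int(rng.integers(2**31))
    host = simulate_host_tree(params.n_populations, seed=host_seed,
                              branch_lengths=params.host_branch_lengths)
    return simulate_dataset(host, params)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset bundle (OTU TSV, metadata TSV, newicks, params
    JSON); returns the mapping of artifact name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "metadata": outdir / "metadata.tsv",
        "host_tree": outdir / "host_tree.nwk",
        "bacterial_tree": outdir / "bacterial_tree.nwk",
        "params": outdir / "params.json",
    }
    write_otu_table(ds.table, paths["otu_table"])
    write_metadata(ds.metadata, paths["metadata"])
    paths["host_tree"].write_text(write_newick(ds.host_tree) + "\n")
    paths["bacterial_tree"].write_text(write_newick(ds.bacterial_tree) + "\n")
    payload = {
        "params": ds.params.to_dict() if ds.params else None,
        "endo_proportions": ds.endo_proportions,
    }
    paths["params"].write_text(json.dumps(payload, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
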