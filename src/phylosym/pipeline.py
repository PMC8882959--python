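"""End-to-end pipeline: config resolution, execution, manifest and logging.

A run is described by a single YAML/JSON config with either an ``inputs``
block (paths to an OTU table, metadata, host tree or host distance matrix,
and optionally a bacterial tree) or a ``simulate`` block (SimParams fields)
— exactly one of the two. The pipeline rarefies, writes the alpha table,
the four beta distance matrices, the population-collapsed matrices, the
microbiota UPGMA dendrogram, group statistics, the endosymbiont
correlation, and the phylosymbiosis report; every output is checksummed
into a MANIFEST and all seeds appear in the report so a rerun from the
resolved config reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import congruence, diversity, groupstats, simulate as sim, treeops
from .errors import InvalidArgumentError, PhylosymError
from .otu import (
    read_distance_matrix,
    read_metadata,
    read_otu_table,
    write_distance_matrix,
)

DEFAULTS = {
    "beta_metrics": ["bray_curtis", "binary_jaccard",
                     "unweighted_unifrac", "weighted_unifrac"],
    "dendrogram_metric": "bray_curtis",
    "congruence_metrics": ["rf", "mc"],
    "rarefy_depth": "min",
    "n_perm": 9999,
    "n_random": 1000,
    "mantel_method": "pearson",
    "mantel_alternative": "greater",
    "endosymbiont_target": "Wolbachia",
    "seed": 0,
}


@dataclass
class RunConfig:
    outdir: str
    inputs: dict | None = None
    simulate: dict | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise InvalidArgumentError(
                "config must contain exactly one of 'inputs' or 'simulate'"
            )
        unknown = set(self.options) - set(DEFAULTS)
        if unknown:
            raise InvalidArgumentError(f"unknown options: {sorted(unknown)}")
        self.options = {**DEFAULTS, **self.options}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            outdir=doc.get("outdir", "phylosym_out"),
            inputs=doc.get("inputs"),
            simulate=doc.get("simulate"),
            options=doc.get("options", {}) or {},
        )

    def resolved(self) -> dict:
        return {
            "outdir": self.outdir,
            "inputs": self.inputs,
            "simulate": self.simulate,
            "options": self.options,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict.

    Any stage failure is re-raised with the stage name prepended; outputs
    written before the failure stay on disk and the MANIFEST marks the run
    incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    log_lines = []
    manifest: dict = {"complete": False, "outputs": {}}

    def log(msg):
        log_lines.append(msg)

    def emit(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    stage = "configure"
    try:
        (outdir / "resolved_config.json").write_text(
            json.dumps(config.resolved(), indent=2, sort_keys=True) + "\n"
        )
        emit("resolved_config", outdir / "resolved_config.json")

        stage = "load-inputs"
        if config.simulate is not None:
            params = sim.SimParams(**config.simulate)
            ds = sim.simulate_study(params)
            for name, path in sim.write_dataset(ds, outdir / "simulated").items():
                emit(f"simulated/{name}", path)
            table, metadata = ds.table, ds.metadata
            host: object = ds.host_tree
            bact = ds.bacterial_tree
            log(f"simulated dataset: {params.to_dict()}")
        else:
            inp = config.inputs
            table = read_otu_table(inp["otu_table"])
            metadata = read_metadata(inp["metadata"])
            if "host_tree" in inp:
                host = treeops.parse_newick(Path(inp["host_tree"]).read_text())
            elif "host_distances" in inp:
                host = read_distance_matrix(inp["host_distances"])
            else:
                raise InvalidArgumentError(
                    "inputs need 'host_tree' or 'host_distances'"
                )
            bact = (
                treeops.parse_newick(Path(inp["bacterial_tree"]).read_text())
                if "bacterial_tree" in inp else None
            )
        log(f"samples: {len(table.sample_ids)}, OTUs: {len(table.otu_ids)}")

        stage = "rarefy"
        rng = np.random.default_rng(opts["seed"])
        seeds = {k: int(rng.integers(2**31))
                 for k in ("rarefy", "groupstats", "report")}
        rare = diversity.rarefy_table(table, depth=opts["rarefy_depth"],
                                      seed=seeds["rarefy"])
        depth = int(rare.sample_totals().iloc[0])
        log(f"rarefied to depth {depth}")

        stage = "alpha"
        indices = ["observed", "chao1", "ace", "shannon", "simpson"]
        if bact is not None:
            indices.append("faith_pd")
        alpha = diversity.alpha_table(rare, indices=indices, tree=bact)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id")
        emit("alpha_diversity", outdir / "alpha_diversity.tsv")

        stage = "beta"
        metrics = [m for m in opts["beta_metrics"]
                   if bact is not None or "unifrac" not in m]
        sample_dms, pop_dms = {}, {}
        for metric in metrics:
            dm = diversity.distance_matrix(rare, metric, tree=bact)
            sample_dms[metric] = dm
            write_distance_matrix(dm, outdir / f"beta_{metric}.tsv")
            emit(f"beta_{metric}", outdir / f"beta_{metric}.tsv")
            pop_dm = diversity.collapse_to_populations(dm, metadata)
            pop_dms[metric] = pop_dm
            write_distance_matrix(pop_dm, outdir / f"beta_{metric}_populations.tsv")
            emit(f"beta_{metric}_populations",
                 outdir / f"beta_{metric}_populations.tsv")

        stage = "upgma"
        micro = treeops.upgma(pop_dms[opts["dendrogram_metric"]])
        (outdir / "microbiota_dendrogram.nwk").write_text(
            treeops.write_newick(micro) + "\n"
        )
        emit("microbiota_dendrogram", outdir / "microbiota_dendrogram.nwk")

        stage = "groupstats"
        pops = metadata.population_of(sample_dms[metrics[0]].ids)
        bc = sample_dms.get("bray_curtis", sample_dms[metrics[0]])
        ares = groupstats.anosim(bc, pops, n_perm=opts["n_perm"],
                                 seed=seeds["groupstats"])
        mres = groupstats.mrpp(bc, pops, n_perm=opts["n_perm"],
                               seed=seeds["groupstats"])
        group_out = {
            "anosim": {"R": ares.r, "P": ares.p_value, "n_perm": ares.n_permutations},
            "mrpp": {"delta": mres.delta, "A": mres.a, "P": mres.p_value,
                     "n_perm": mres.n_permutations},
        }

        stage = "endosymbiont"
        endo = None
        if table.taxonomy is not None:
            prop = diversity.endosymbiont_proportion(
                rare, target=opts["endosymbiont_target"]
            )
            infected_samples = [
                s for s in rare.sample_ids
                if metadata.frame.loc[s, "endosymbiont_status"] == "infected"
            ]
            endo = {"per_sample_proportion": {s: float(prop[s])
                                              for s in rare.sample_ids}}
            if len(infected_samples) >= 3:
                for idx in ("shannon", "simpson"):
                    vals = alpha.loc[infected_samples, idx]
                    if prop[infected_samples].nunique() > 1 and vals.nunique() > 1:
                        rho, p = groupstats.spearman_corr(
                            prop[infected_samples], vals
                        )
                        endo[f"spearman_{idx}"] = {"rho": rho, "P": p}

        stage = "phylosymbiosis"
        cfg = congruence.PhylosymbiosisConfig(
            beta_metrics=tuple(metrics),
            dendrogram_metric=opts["dendrogram_metric"],
            congruence_metrics=tuple(opts["congruence_metrics"]),
            rarefy_depth=opts["rarefy_depth"],
            n_perm=opts["n_perm"],
            n_random=opts["n_random"],
            mantel_method=opts["mantel_method"],
            mantel_alternative=opts["mantel_alternative"],
            seed=seeds["report"],
        )
        report = congruence.phylosymbiosis_report(host, table, metadata, bact, cfg)
        report["groupstats"] = group_out
        report["endosymbiont"] = endo
        report["pipeline_seeds"] = {"root": opts["seed"], **seeds}
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        emit("report", outdir / "report.json")
        (outdir / "report.txt").write_text(congruence.render_report(report) + "\n")
        emit("report_text", outdir / "report.txt")

        manifest["complete"] = True
        return report
    except PhylosymError as exc:
        raise PhylosymError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        (outdir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
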