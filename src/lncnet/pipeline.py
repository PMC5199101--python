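"""End-to-end orchestration: simulate? -> de -> cluster -> enrich -> ggnet ->
cerna -> corrnet, with one structured config, per-stage outputs and a
machine-readable summary.

The summary is deterministic for a fixed config and seed (no timestamps),
and every count in it is recomputable from the per-stage TSVs written next
to it.  A stage failure aborts the run with the failing stage named; partial
outputs stay on disk next to a ``FAILED_<stage>`` marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cerna as cerna_mod
from . import cluster as cluster_mod
from . import coexpr as coexpr_mod
from . import de as de_mod
from . import enrich as enrich_mod
from . import ggnet as ggnet_mod
from . import io as lio
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

ALL_STAGES = ("de", "cluster", "enrich", "ggnet", "cerna", "corrnet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All paths, thresholds and toggles of one pipeline run.

    Default thresholds are the published ones: fold change >= 2 with p < 0.05
    for the DE filter, betweenness centrality >= 0.005 for core genes in the
    interaction network, |r| >= 0.92 for co-expression edges; the ceRNA
    correlation cutoffs (+0.8 / -0.8) are this package's defaults.
    """

    out_dir: str = "lncnet_out"
    # inputs (ignored when simulate=True: the generated fixture is used)
    expression: str | None = None
    groups: str | None = None
    mirna_expression: str | None = None
    annotation: str | None = None
    targets: str | None = None
    interactions: str | None = None
    gene_sets: str | None = None
    # stage parameters
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    bc_threshold: float = 0.005
    corr_cutoff: float = 0.92
    cerna_pos_threshold: float = 0.8
    cerna_neg_threshold: float = -0.8
    linkage: str = "average"
    top_k: int = 20
    seed: int = 0
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SyntheticSpec overrides
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if not (self.fc_threshold >= 1):
            raise ValueError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if not (0 < self.p_threshold <= 1):
            raise ValueError(f"p_threshold must lie in (0, 1], got {self.p_threshold}")
        if not (0 <= self.bc_threshold <= 1):
            raise ValueError(f"bc_threshold must lie in [0, 1], got {self.bc_threshold}")
        if not (0 < self.corr_cutoff <= 1):
            raise ValueError(f"corr_cutoff must lie in (0, 1], got {self.corr_cutoff}")
        if not (self.cerna_pos_threshold > 0 > self.cerna_neg_threshold):
            raise ValueError("need cerna_pos_threshold > 0 > cerna_neg_threshold")
        if self.linkage not in cluster_mod.LINKAGES:
            raise ValueError(f"linkage must be one of {cluster_mod.LINKAGES}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; allowed: {ALL_STAGES}")
        if "de" not in self.stages:
            raise ValueError("the 'de' stage is required: every later stage consumes its output")
        if not self.simulate:
            required = ("expression", "groups", "annotation")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"inputs {missing} required unless simulate=True generates them"
                )

    # -- round-trip through YAML -------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(Path(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(Path(path), encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _write_marker(out: Path, stage: str, exc: Exception) -> None:
    (out / f"FAILED_{stage}").write_text(f"stage {stage} failed: {exc}\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the machine-readable summary.

    The summary (also written to ``<out_dir>/summary.json``) holds the
    headline counts of the run: up/down DE mRNAs and lncRNAs, clustering
    separation, enriched terms, interaction-network core genes, competing
    triplets, and co-expression degree-difference leaders.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline: effective config written to %s", out / "config.yaml")

    # -- inputs --------------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            spec = sim_mod.SyntheticSpec(**{"seed": config.seed, **config.sim})
            dataset = sim_mod.generate_dataset(spec)
            sim_mod.write_dataset(dataset, out / "inputs")
            expression = dataset.expression
            mirna_expression = dataset.mirna_expression
            annotation = dataset.annotation
            targets = dataset.targets
            graph = dataset.graph
            gene_sets = dataset.gene_sets
            logger.info("simulate: fixture written to %s", out / "inputs")
        else:
            expression = lio.read_expression_matrix(config.expression, config.groups)
            annotation = lio.read_annotation(config.annotation)
            mirna_expression = None
            if config.mirna_expression:
                mirna_expression = lio.read_expression_matrix(
                    config.mirna_expression, config.groups
                )
            targets = lio.read_target_map(config.targets) if config.targets else None
            graph = lio.read_interaction_edges(config.interactions) if config.interactions else None
            gene_sets = lio.read_gene_sets(config.gene_sets) if config.gene_sets else None
    except Exception as exc:
        _write_marker(out, stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    biotype_of = annotation.biotype_of()
    gene_matrix = lio.collapse_to_genes(expression, annotation)
    summary: dict = {"seed": config.seed, "stages": {}}

    de_records = None
    up = down = None

    def _run(stage_name: str, fn) -> None:
        if stage_name not in config.stages:
            return
        try:
            logger.info("stage %s: start", stage_name)
            fn()
            logger.info("stage %s: done", stage_name)
        except Exception as exc:
            _write_marker(out, stage_name, exc)
            raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc

    # -- differential expression ----------------------------------------------
    def _de() -> None:
        nonlocal de_records, up, down
        de_records = de_mod.de_table(
            expression,
            annotation,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
        )
        up, down = de_mod.filter_differential(
            de_records, config.fc_threshold, config.p_threshold
        )
        lio.write_results({"de_table": de_records, "de_up": up, "de_down": down}, out)
        counts = {}
        for direction, table in (("up", up), ("down", down)):
            symbols = set(table["gene_symbol"])
            counts[f"{direction}_mrna"] = sum(1 for s in symbols if biotype_of.get(s) == "mRNA")
            counts[f"{direction}_lncrna"] = sum(
                1 for s in symbols if biotype_of.get(s) == "lncRNA"
            )
        counts["up_total"], counts["down_total"] = len(up), len(down)
        summary["stages"]["de"] = counts

    _run("de", _de)
    if de_records is None:
        raise PipelineError("the 'de' stage is required by every downstream stage")
    de_probes = list(up["probe_id"]) + list(down["probe_id"])
    de_directions = {
        **{s: "up" for s in up["gene_symbol"]},
        **{s: "down" for s in down["gene_symbol"]},
    }

    # -- hierarchical clustering of samples on DE probes ------------------------
    def _cluster() -> None:
        if len(de_probes) < 2:
            summary["stages"]["cluster"] = {"skipped": "fewer than 2 DE probes"}
            return
        profiles = expression.values.loc[de_probes].T  # rows = samples
        dist = cluster_mod.correlation_distance(profiles)
        dendro = cluster_mod.hierarchical_cluster(dist, linkage=config.linkage)
        purity = cluster_mod.separation_score(dendro, expression.group_of)
        merges = dendro.to_table()
        merges["linkage"] = config.linkage
        lio.write_results({"cluster_merges": merges}, out)
        (out / "cluster_leaf_order.txt").write_text(
            "\n".join(dendro.leaf_order()) + "\n", encoding="utf-8"
        )
        summary["stages"]["cluster"] = {
            "linkage": config.linkage,
            "n_de_probes": len(de_probes),
            "separation_purity": purity,
        }

    _run("cluster", _cluster)

    # -- over-representation ---------------------------------------------------
    def _enrich() -> None:
        if gene_sets is None:
            summary["stages"]["enrich"] = {"skipped": "no gene-set collection supplied"}
            return
        universe = {s for s, b in biotype_of.items() if b in ("mRNA", "lncRNA")}
        counts = {}
        for direction, table in (("up", up), ("down", down)):
            genes = set(table["gene_symbol"]) & universe
            if not genes:
                results = pd.DataFrame()
            else:
                results = enrich_mod.enrich(genes, universe, gene_sets, config.p_threshold)
            lio.write_results({f"enrichment_{direction}": results}, out)
            counts[f"{direction}_significant_terms"] = (
                int(results["significant"].sum()) if "significant" in results else 0
            )
            counts[f"{direction}_tested_terms"] = len(results)
        summary["stages"]["enrich"] = counts

    _run("enrich", _enrich)

    # -- gene-gene interaction subnetwork ---------------------------------------
    def _ggnet() -> None:
        if graph is None:
            summary["stages"]["ggnet"] = {"skipped": "no interaction edge list supplied"}
            return
        sub = ggnet_mod.build_subnetwork(graph, de_directions)
        records = ggnet_mod.centrality_table(sub)
        core = ggnet_mod.select_core_genes(records, config.bc_threshold)
        lio.write_results({"ggnet_centrality": records, "ggnet_core": core}, out)
        lio.write_graphml(sub, out / "ggnet.graphml")
        summary["stages"]["ggnet"] = {
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "n_core_genes": len(core),
            "top_gene": core["gene"].iloc[0] if len(core) else None,
        }

    _run("ggnet", _ggnet)

    # -- ceRNA triplets ----------------------------------------------------------
    def _cerna() -> None:
        if targets is None:
            summary["stages"]["cerna"] = {"skipped": "no target map supplied"}
            return
        lnc_genes = [g for g in gene_matrix.probe_ids if biotype_of.get(g) == "lncRNA"]
        mrna_genes = [g for g in gene_matrix.probe_ids if biotype_of.get(g) == "mRNA"]
        lnc_expr = gene_matrix.subset_probes(lnc_genes)
        mrna_expr = gene_matrix.subset_probes(mrna_genes)
        mode = "strict" if mirna_expression is not None else "lenient"
        triplets = cerna_mod.find_competing_triplets(
            targets,
            lnc_expr,
            mrna_expr,
            mirna_expression,
            pos_threshold=config.cerna_pos_threshold,
            neg_threshold=config.cerna_neg_threshold,
            mode=mode,
        )
        degrees, hubs = cerna_mod.triplet_network_summary(triplets)
        lio.write_results({"cerna_triplets": triplets, "cerna_degrees": degrees}, out)
        summary["stages"]["cerna"] = {
            "mode": mode,
            "n_triplets": len(triplets),
            "hubs": hubs,
        }

    _run("cerna", _cerna)

    # -- per-group co-expression networks -----------------------------------------
    def _corrnet() -> None:
        net_t = coexpr_mod.build_correlation_network(
            gene_matrix, biotype_of, "tumor", config.corr_cutoff
        )
        net_n = coexpr_mod.build_correlation_network(
            gene_matrix, biotype_of, "normal", config.corr_cutoff
        )
        core = coexpr_mod.degree_difference_core(net_t, net_n, top_k=config.top_k)
        pairs = coexpr_mod.pair_report(net_t, list(core["gene"]))
        lio.write_results({"corrnet_core": core, "corrnet_pairs_tumor": pairs}, out)
        lio.write_graphml(net_t, out / "corrnet_tumor.graphml")
        lio.write_graphml(net_n, out / "corrnet_normal.graphml")
        summary["stages"]["corrnet"] = {
            "n_edges_tumor": net_t.number_of_edges(),
            "n_edges_normal": net_n.number_of_edges(),
            "top_gene": core["gene"].iloc[0] if len(core) else None,
            "top_degree_diff": int(core["degree_diff"].iloc[0]) if len(core) else 0,
        }

    _run("corrnet", _corrnet)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
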