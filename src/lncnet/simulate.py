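"""Synthetic paired tumor/normal datasets with planted ground truth.

The generator emulates the study design the pipeline targets: a small paired
cohort (default 9 tumor/normal pairs) profiled on an integrated lncRNA+mRNA
platform, with gene-wise variances drawn from the same inverse-gamma family
the moderated t-test assumes (precision ~ Gamma(shape=a, scale=b)), so that
hyperparameter recovery closes the loop on the DE stage.  Into this null it
plants, with known identities:

* up/down differentially expressed genes (a fixed log2 shift in tumor),
* lncRNA-mRNA co-expression pairs at a target |r|, active in the tumor group
  only (the disease rewires co-expression),
* miRNA-anchored ceRNA triplets: a latent factor enters the miRNA profile
  positively and both target profiles negatively, across all samples,
* a target map holding every planted relation plus decoy relations,
* an interaction graph whose planted DE genes form a connected core around a
  hub, plus background edges,
* gene sets genuinely enriched for planted DE genes plus random decoys.

Latent factors use variance-preserving loadings (sqrt(rho)*z +
sqrt(1-rho)*eps) so planted correlation structure never distorts the
marginal variance distribution.  Identical seeds give identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as lio
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
    TargetMap,
)

__all__ = [
    "SyntheticSpec",
    "TruthBundle",
    "SyntheticDataset",
    "generate_dataset",
    "planted_pair_correlation_check",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the target design: 9 tumor/normal pairs, 1000
    lncRNA+mRNA features of which 100 are planted up and 50 down at a
    2-fold-and-above shift (log2_effect=2), variance prior (a=2, b=1.5),
    10 tumor-only co-expression pairs at |r|=0.97 and 3 ceRNA triplets at
    |r|=0.90, with 10:1 decoy target relations and 5:1 decoy gene sets.
    """

    n_pairs: int = 9
    n_mrna: int = 700
    n_lncrna: int = 300
    n_mirna: int = 40
    rvm_a: float = 2.0
    rvm_b: float = 1.5
    frac_up: float = 0.10
    frac_down: float = 0.05
    log2_effect: float = 2.0
    n_corr_pairs: int = 10
    pair_target_r: float = 0.97
    n_triplets: int = 3
    triplet_target_r: float = 0.90
    triplet_pair_target_r: float = 0.95
    decoy_relation_ratio: int = 10
    decoy_set_ratio: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.rvm_a > 0 and self.rvm_b > 0):
            raise ValueError("rvm_a and rvm_b must be positive")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if not (0 < self.pair_target_r < 1 and 0 < self.triplet_target_r < 1):
            raise ValueError("target correlations must lie in (0, 1)")
        if not (self.triplet_target_r <= self.triplet_pair_target_r < 1):
            raise ValueError(
                "triplet_pair_target_r must lie in [triplet_target_r, 1): the "
                "transcript pair shares the miRNA factor plus its own factor"
            )
        if self.n_corr_pairs < 0 or self.n_triplets < 0:
            raise ValueError("planted structure counts must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_mrna + self.n_lncrna

    @property
    def n_up(self) -> int:
        return round(self.frac_up * self.n_genes)

    @property
    def n_down(self) -> int:
        return round(self.frac_down * self.n_genes)


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth of one generated dataset."""

    de_up: frozenset[str]
    de_down: frozenset[str]
    variance_of: dict[str, float]
    corr_pairs: tuple[tuple[str, str, int], ...]  # (lncRNA, mRNA, sign)
    triplets: tuple[tuple[str, str, str], ...]  # (miRNA, lncRNA, mRNA)
    rvm_a: float
    rvm_b: float
    true_set_ids: tuple[str, ...] = ()
    hub_gene: str | None = None


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus its ground truth."""

    expression: ExpressionMatrix
    mirna_expression: ExpressionMatrix
    annotation: ProbeAnnotation
    targets: TargetMap
    graph: nx.Graph
    gene_sets: GeneSetCollection
    truth: TruthBundle


def _symbols(prefix: str, count: int) -> list[str]:
    width = max(4, len(str(count)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, count + 1)]


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one complete dataset + truth bundle from the study-design spec."""
    rng = np.random.default_rng(spec.seed)
    mrnas = _symbols("MRNA", spec.n_mrna)
    lncs = _symbols("LNC", spec.n_lncrna)
    mirnas = _symbols("MIR", spec.n_mirna)
    genes = mrnas + lncs

    n_up, n_down = spec.n_up, spec.n_down
    need_pairs = 2 * spec.n_corr_pairs
    need_triplets = 2 * spec.n_triplets
    free = spec.n_genes - n_up - n_down
    if free < need_pairs + need_triplets:
        raise ValueError(
            f"infeasible spec: {spec.n_genes} genes cannot host {n_up}+{n_down} DE genes, "
            f"{spec.n_corr_pairs} pairs and {spec.n_triplets} triplets"
        )
    if spec.n_triplets > spec.n_mirna:
        raise ValueError("more planted triplets than miRNAs")
    if spec.n_corr_pairs > min(spec.n_lncrna, spec.n_mrna) or spec.n_triplets > min(
        spec.n_lncrna, spec.n_mrna
    ):
        raise ValueError("not enough lncRNA/mRNA features for the planted structures")

    # -- planted identities ------------------------------------------------
    de_all = rng.choice(genes, size=n_up + n_down, replace=False)
    de_up = frozenset(de_all[:n_up])
    de_down = frozenset(de_all[n_up:])

    free_lncs = [g for g in lncs if g not in de_up and g not in de_down]
    free_mrnas = [g for g in mrnas if g not in de_up and g not in de_down]
    if len(free_lncs) < spec.n_corr_pairs + spec.n_triplets or len(free_mrnas) < (
        spec.n_corr_pairs + spec.n_triplets
    ):
        raise ValueError("infeasible spec: planted DE genes leave too few free lncRNAs/mRNAs")
    pick_lncs = rng.choice(free_lncs, size=spec.n_corr_pairs + spec.n_triplets, replace=False)
    pick_mrnas = rng.choice(free_mrnas, size=spec.n_corr_pairs + spec.n_triplets, replace=False)
    # roughly one planted pair in four is negatively correlated
    pair_signs = [(-1 if (i + 1) % 4 == 0 else 1) for i in range(spec.n_corr_pairs)]
    corr_pairs = tuple(
        (str(pick_lncs[i]), str(pick_mrnas[i]), pair_signs[i]) for i in range(spec.n_corr_pairs)
    )
    triplet_mirnas = rng.choice(mirnas, size=spec.n_triplets, replace=False)
    triplets = tuple(
        (
            str(triplet_mirnas[i]),
            str(pick_lncs[spec.n_corr_pairs + i]),
            str(pick_mrnas[spec.n_corr_pairs + i]),
        )
        for i in range(spec.n_triplets)
    )

    # -- samples -----------------------------------------------------------
    tumor_samples = [f"C{i}" for i in range(1, spec.n_pairs + 1)]
    normal_samples = [f"N{i}" for i in range(1, spec.n_pairs + 1)]
    samples = tumor_samples + normal_samples
    group_of = {s: ("tumor" if s.startswith("C") else "normal") for s in samples}
    pair_of = {s: f"P{s[1:]}" for s in samples}
    tumor_idx = np.arange(spec.n_pairs)

    # -- expression: baseline + group shift + sigma * (latent-structured) noise
    all_features = genes + mirnas
    feat_index = {g: i for i, g in enumerate(all_features)}
    n_feat = len(all_features)
    precisions = rng.gamma(shape=spec.rvm_a, scale=spec.rvm_b, size=n_feat)
    sigma = 1.0 / np.sqrt(precisions)
    variance_of = {g: float(sigma[i] ** 2) for g, i in feat_index.items()}
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_feat)
    noise = rng.standard_normal((n_feat, len(samples)))

    # All planted pairs share one tumor-only latent factor: a tumor-specific
    # co-expression module.  Each designated (lncRNA, mRNA) pair then reaches
    # r = sign * pair_target_r in the tumor group, and module members acquire
    # high tumor degree, the differential-co-expression signature the
    # degree-difference ranking is built to detect.
    rho_pair = spec.pair_target_r
    if corr_pairs:
        z = rng.standard_normal(spec.n_pairs)
        for lnc, mrna, sign in corr_pairs:
            for g, s in ((lnc, 1.0), (mrna, float(sign))):
                i = feat_index[g]
                noise[i, tumor_idx] = s * np.sqrt(rho_pair) * z + np.sqrt(
                    1 - rho_pair
                ) * noise[i, tumor_idx]
    # Triplets use two latent factors per trio: w enters the miRNA positively
    # and both transcripts negatively (miRNA-transcript r = -triplet_target_r);
    # u is shared by the two transcripts only, lifting their mutual r to
    # triplet_pair_target_r without touching the miRNA correlations.
    alpha = spec.triplet_target_r  # transcript loading^2 on w (miRNA loads alpha too)
    beta = spec.triplet_pair_target_r - alpha
    for mirna, lnc, mrna in triplets:
        w = rng.standard_normal(len(samples))
        u = rng.standard_normal(len(samples))
        i = feat_index[mirna]
        noise[i, :] = np.sqrt(alpha) * w + np.sqrt(1 - alpha) * noise[i, :]
        for g in (lnc, mrna):
            i = feat_index[g]
            noise[i, :] = (
                -np.sqrt(alpha) * w + np.sqrt(beta) * u + np.sqrt(1 - alpha - beta) * noise[i, :]
            )

    values = baseline[:, None] + sigma[:, None] * noise
    shift = np.zeros(n_feat)
    for g in de_up:
        shift[feat_index[g]] = spec.log2_effect
    for g in de_down:
        shift[feat_index[g]] = -spec.log2_effect
    values[:, tumor_idx] += shift[:, None]

    gene_values = pd.DataFrame(values[: len(genes)], index=genes, columns=samples)
    mir_values = pd.DataFrame(values[len(genes) :], index=mirnas, columns=samples)
    expression = ExpressionMatrix(gene_values, dict(group_of), dict(pair_of))
    mirna_expression = ExpressionMatrix(mir_values, dict(group_of), dict(pair_of))

    # -- annotation ----------------------------------------------------------
    biotype = ["mRNA"] * spec.n_mrna + ["lncRNA"] * spec.n_lncrna + ["miRNA"] * spec.n_mirna
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": all_features,
                "transcript_id": [f"tx_{g}" for g in all_features],
                "gene_symbol": all_features,
                "biotype": biotype,
            }
        )
    )

    # -- target map: planted relations + decoys ------------------------------
    relations: set[tuple[str, str, str]] = set()
    for mirna, lnc, mrna in triplets:
        relations.add((mirna, lnc, "lncRNA"))
        relations.add((mirna, mrna, "mRNA"))
    n_planted_rel = len(relations)
    structured = {g for pair in corr_pairs for g in pair[:2]} | {
        g for t in triplets for g in t[1:]
    }
    decoy_lncs = [g for g in lncs if g not in structured]
    decoy_mrnas = [g for g in mrnas if g not in structured]
    n_decoys = spec.decoy_relation_ratio * max(n_planted_rel, 1)
    guard = 0
    while len(relations) < n_planted_rel + n_decoys and guard < 100 * n_decoys:
        guard += 1
        mirna = str(rng.choice(mirnas))
        if rng.random() < 0.5 and decoy_lncs:
            relations.add((mirna, str(rng.choice(decoy_lncs)), "lncRNA"))
        elif decoy_mrnas:
            relations.add((mirna, str(rng.choice(decoy_mrnas)), "mRNA"))
    targets = TargetMap(frozenset(relations))

    # -- interaction graph: connected DE core around a hub + background -------
    graph = nx.Graph()
    direction_of = {g: "unmeasured" for g in genes}
    for g in de_up:
        direction_of[g] = "up"
    for g in de_down:
        direction_of[g] = "down"
    graph.add_nodes_from(genes)
    nx.set_node_attributes(graph, direction_of, name="direction")
    type_codes = sorted(lio.INTERACTION_TYPES)

    de_sorted = sorted(de_up) + sorted(de_down)
    hub = de_sorted[0] if de_sorted else None
    if hub is not None and len(de_sorted) > 1:
        others = de_sorted[1:]
        spokes = others[: min(30, len(others))]
        for s in spokes:
            graph.add_edge(hub, s, interaction=str(rng.choice(type_codes)))
        # remaining DE genes hang off the spokes (depth-2 core, stays connected)
        for j, g in enumerate(others[len(spokes) :]):
            graph.add_edge(spokes[j % len(spokes)], g, interaction=str(rng.choice(type_codes)))
    de_set = de_up | de_down
    n_background = 2 * spec.n_genes
    added = 0
    guard = 0
    while added < n_background and guard < 50 * n_background:
        guard += 1
        u, v = rng.choice(genes, size=2, replace=False)
        u, v = str(u), str(v)
        if (u in de_set and v in de_set) or graph.has_edge(u, v):
            continue
        graph.add_edge(u, v, interaction=str(rng.choice(type_codes)))
        added += 1

    # -- gene sets: truly enriched sets + decoys ------------------------------
    sets: dict[str, GeneSet] = {}
    non_de = [g for g in genes if g not in de_set]

    def _true_set(term_id: str, name: str, planted: list[str], n_planted: int, n_noise: int):
        members = list(rng.choice(planted, size=min(n_planted, len(planted)), replace=False))
        members += list(rng.choice(non_de, size=n_noise, replace=False))
        sets[term_id] = GeneSet(term_id, name, lio._category_of_term(term_id), tuple(sorted(members)))

    true_ids = []
    if de_up:
        _true_set("GO:TRUE_UP", "planted up-regulated process", sorted(de_up), 40, 10)
        true_ids.append("GO:TRUE_UP")
    if de_down:
        _true_set("PATH:TRUE_DOWN", "planted down-regulated pathway", sorted(de_down), 25, 10)
        true_ids.append("PATH:TRUE_DOWN")
    # Decoy sets are base-rate matched: their planted-DE membership equals the
    # background DE fraction exactly, so they are unenriched by construction
    # rather than merely in expectation (a uniform draw would leave decoy
    # Fisher p-values uniform, i.e. occasionally "significant" by design).
    n_decoy_sets = spec.decoy_set_ratio * max(len(true_ids), 1)
    up_list, down_list = sorted(de_up), sorted(de_down)
    for i in range(1, n_decoy_sets + 1):
        size = int(rng.integers(30, 61))
        k_up = round(size * len(up_list) / spec.n_genes)
        k_down = round(size * len(down_list) / spec.n_genes)
        members: list[str] = []
        if up_list and k_up:
            members += list(rng.choice(up_list, size=k_up, replace=False))
        if down_list and k_down:
            members += list(rng.choice(down_list, size=k_down, replace=False))
        members += list(rng.choice(non_de, size=size - len(members), replace=False))
        term_id = f"GO:D{i:04d}" if i % 2 else f"PATH:D{i:04d}"
        sets[term_id] = GeneSet(
            term_id, f"decoy set {i}", lio._category_of_term(term_id), tuple(sorted(members))
        )
    gene_sets = GeneSetCollection(sets)

    truth = TruthBundle(
        de_up=de_up,
        de_down=de_down,
        variance_of=variance_of,
        corr_pairs=corr_pairs,
        triplets=triplets,
        rvm_a=spec.rvm_a,
        rvm_b=spec.rvm_b,
        true_set_ids=tuple(true_ids),
        hub_gene=hub,
    )
    return SyntheticDataset(
        expression=expression,
        mirna_expression=mirna_expression,
        annotation=annotation,
        targets=targets,
        graph=graph,
        gene_sets=gene_sets,
        truth=truth,
    )


def planted_pair_correlation_check(truth: TruthBundle, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Empirical within-group Pearson r for every planted co-expression pair.

    Calibration helper: columns lncrna, mrna, sign, group, r.
    """
    rows = []
    for group in ("tumor", "normal"):
        sub = matrix.group_values(group)
        for lnc, mrna, sign in truth.corr_pairs:
            x = sub.loc[lnc].to_numpy(dtype=float)
            y = sub.loc[mrna].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"lncrna": lnc, "mrna": mrna, "sign": sign, "group": group, "r": r})
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture to a directory using the package writers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "mirna_expression": out / "mirna_expression.tsv",
        "annotation": out / "annotation.tsv",
        "targets": out / "targets.tsv",
        "interactions": out / "interactions.sif",
        "gene_sets": out / "gene_sets.gmt",
    }
    lio.write_expression_matrix(dataset.expression, paths["expression"], paths["groups"])
    lio.write_expression_matrix(dataset.mirna_expression, paths["mirna_expression"])
    lio.write_annotation(dataset.annotation, paths["annotation"])
    lio.write_target_map(dataset.targets, paths["targets"])
    lio.write_interaction_edges(dataset.graph, paths["interactions"])
    lio.write_gene_sets(dataset.gene_sets, paths["gene_sets"])
    return paths
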