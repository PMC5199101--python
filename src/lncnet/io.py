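"""Validated containers and readers/writers for every file the pipeline touches.

The pipeline consumes GEO-style tab-separated expression matrices of log2
intensities (rows = probes, columns = samples) together with a sample-group
file (tumor vs adjacent normal, optionally paired by patient), a probe
annotation table carrying biotypes (lncRNA / mRNA / miRNA), GMT gene-set
collections, SIF-style typed gene-gene interaction edge lists, miRNA target
maps, and qPCR Ct tables.  Everything downstream operates on the types
defined here.

Writers are deterministic — fixed column order, tab separator, UTF-8,
6 significant digits for reals — so that write -> read is the identity at
write precision and repeated writes are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ConsistencyError",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "TargetMap",
    "CtTable",
    "INTERACTION_TYPES",
    "GROUP_LABELS",
    "BIOTYPES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_interaction_edges",
    "write_interaction_edges",
    "read_target_map",
    "write_target_map",
    "read_ct_table",
    "write_ct_table",
    "write_results",
    "write_graphml",
    "validate_interaction_graph",
    "format_float",
]

#: Edge-type codes for functional interactions: activation, binding, compound,
#: phosphorylation, ubiquitination, missing interaction, inhibition,
#: expression, dephosphorylation, indirect effect.
INTERACTION_TYPES = frozenset({"a", "b", "c", "p", "u", "m", "inh", "ex", "dep", "ind"})

GROUP_LABELS = ("tumor", "normal")
BIOTYPES = ("lncRNA", "mRNA", "miRNA")

#: Significant digits used by all writers for real values.
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file violates its format contract (bad field count, bad code, duplicate id)."""


class ConsistencyError(ValueError):
    """Two inputs that must agree do not (e.g. sample missing from the group file)."""


def format_float(x: float) -> str:
    """Render a real value the way every writer in this package does."""
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities with sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns; entries are
        log2-scale, pre-normalized intensities (the package never
        renormalizes).
    group_of
        Mapping sample id -> ``"tumor"`` or ``"normal"``; must cover every
        column.
    pair_of
        Optional mapping sample id -> patient label for paired designs; when
        present each patient must map to exactly one tumor and one normal
        sample.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    pair_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ConsistencyError(f"samples missing from group file: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUP_LABELS}
        if bad:
            raise FormatError(f"group labels must be in {GROUP_LABELS}, got {bad}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.pair_of is not None:
            per_patient: dict[str, list[str]] = {}
            for s in cols:
                if s in self.pair_of:
                    per_patient.setdefault(self.pair_of[s], []).append(s)
            for patient, samples in per_patient.items():
                groups = sorted(self.group_of[s] for s in samples)
                if groups != ["normal", "tumor"]:
                    raise ConsistencyError(
                        f"patient {patient!r} must have exactly one tumor and one "
                        f"normal sample, got {samples}"
                    )

    # -- convenience views ---------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUP_LABELS:
            raise ValueError(f"unknown group {group!r}")
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group's samples (column order kept)."""
        return self.values[self.samples_in_group(group)]

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [p for p in probe_ids if p in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], dict(self.group_of), self.pair_of)

    def equals(self, other: "ExpressionMatrix", rtol: float = 0.0) -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        if {s: self.group_of[s] for s in self.sample_ids} != {
            s: other.group_of[s] for s in other.sample_ids
        }:
            return False
        mine = None if self.pair_of is None else {s: self.pair_of[s] for s in self.sample_ids if s in self.pair_of}
        theirs = None if other.pair_of is None else {s: other.pair_of[s] for s in other.sample_ids if s in other.pair_of}
        if mine != theirs:
            return False
        if rtol == 0.0:
            return bool(np.array_equal(self.values.to_numpy(), other.values.to_numpy()))
        return bool(np.allclose(self.values.to_numpy(), other.values.to_numpy(), rtol=rtol))


def read_expression_matrix(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sample-group file.

    The matrix has probe ids in the first column and sample ids in the header
    row.  The groups file has columns ``sample``, ``group`` and optionally
    ``patient``.
    """
    path, groups_path = Path(path), Path(groups_path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample ids in {path}: {dups}")
    try:
        values = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # malformed beyond repair
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad_rows = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric expression value in column {col!r}, "
                f"row(s) {list(bad_rows[:3])} of {path}"
            )
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if not required.issubset(groups.columns):
        raise FormatError(f"group file {groups_path} needs columns {sorted(required)}")
    if groups["sample"].duplicated().any():
        raise FormatError(f"duplicate sample in group file {groups_path}")
    group_of = dict(zip(groups["sample"], groups["group"]))
    pair_of = None
    if "patient" in groups.columns and groups["patient"].notna().any():
        pair_of = {
            s: p for s, p in zip(groups["sample"], groups["patient"]) if pd.notna(p)
        }
    return ExpressionMatrix(values=values, group_of=group_of, pair_of=pair_of)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path | None = None
) -> None:
    """Write the matrix (and, if a path is given, its group file) as TSV."""
    matrix.values.to_csv(
        Path(path), sep="\t", index_label="probe_id", float_format=FLOAT_FMT
    )
    if groups_path is not None:
        rows = {"sample": matrix.sample_ids, "group": [matrix.group_of[s] for s in matrix.sample_ids]}
        if matrix.pair_of is not None:
            rows["patient"] = [matrix.pair_of.get(s, "") for s in matrix.sample_ids]
        pd.DataFrame(rows).to_csv(Path(groups_path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Probe -> (transcript, gene symbol, biotype) mapping.

    ``table`` columns: probe_id, transcript_id, gene_symbol, biotype with
    biotype one of ``lncRNA``, ``mRNA``, ``miRNA``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "transcript_id", "gene_symbol", "biotype"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns {missing}")
        if self.table["probe_id"].duplicated().any():
            raise FormatError("duplicate probe_id in annotation")
        bad = set(self.table["biotype"]) - set(BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotypes {sorted(bad)}; allowed: {BIOTYPES}")
        self.table = self.table.reset_index(drop=True)

    def biotype_of(self) -> dict[str, str]:
        """gene_symbol -> biotype (first annotation wins for shared symbols)."""
        out: dict[str, str] = {}
        for sym, bio in zip(self.table["gene_symbol"], self.table["biotype"]):
            out.setdefault(sym, bio)
        return out

    def probes_of_biotype(self, biotype: str) -> list[str]:
        sub = self.table[self.table["biotype"] == biotype]
        return list(sub["probe_id"])

    def symbol_of(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["gene_symbol"]))


def read_annotation(path: str | Path) -> ProbeAnnotation:
    table = pd.read_csv(Path(path), sep="\t", dtype=str)
    return ProbeAnnotation(table)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    cols = ["probe_id", "transcript_id", "gene_symbol", "biotype"]
    annotation.table[cols].to_csv(Path(path), sep="\t", index=False)


def collapse_to_genes(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse probe-level values to gene symbols.

    For symbols measured by several probes the probe with the highest mean
    intensity represents the gene — the usual microarray convention for
    gene-level analyses (networks, enrichment); differential expression stays
    probe-level.
    """
    sym = annotation.symbol_of()
    keep: dict[str, str] = {}  # symbol -> winning probe
    means = matrix.values.mean(axis=1)
    for probe in matrix.probe_ids:
        if probe not in sym:
            continue
        s = sym[probe]
        if s not in keep or means[probe] > means[keep[s]]:
            keep[s] = probe
    probes = list(keep.values())
    collapsed = matrix.values.loc[probes].copy()
    collapsed.index = [sym[p] for p in probes]
    return ExpressionMatrix(collapsed, dict(matrix.group_of), matrix.pair_of)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    category: str  # "GO" or "pathway"
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Ordered mapping term_id -> GeneSet with non-empty member lists."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, gs in self.sets.items():
            if not gs.members:
                raise FormatError(f"gene set {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


def _category_of_term(term_id: str) -> str:
    return "GO" if term_id.upper().startswith("GO") else "pathway"


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: term, description, members (tab-separated).

    Category is inferred from the term id (``GO*`` -> GO, anything else ->
    pathway).
    """
    sets: dict[str, GeneSet] = {}
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            term_id, name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: term {term_id!r} has no members")
            if term_id in sets:
                raise FormatError(f"GMT line {lineno}: duplicate term id {term_id!r}")
            sets[term_id] = GeneSet(term_id, name, _category_of_term(term_id), tuple(members))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.term_name, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Interaction graph (SIF-like)
# ---------------------------------------------------------------------------


def validate_interaction_graph(graph: nx.Graph) -> None:
    """Check the invariants of a typed gene-gene interaction graph."""
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise FormatError(f"self-loop on {u!r}")
        itype = data.get("interaction")
        if itype not in INTERACTION_TYPES:
            raise FormatError(
                f"edge ({u},{v}) has interaction type {itype!r}; "
                f"allowed: {sorted(INTERACTION_TYPES)}"
            )


def read_interaction_edges(path: str | Path) -> nx.Graph:
    """Read a SIF-like TSV of (geneA, type, geneB) rows into an undirected graph.

    Repeated pairs collapse to a single edge keeping the first type; self-loops
    are dropped with a logged warning.  Edge types are metadata only — every
    graph statistic in this package treats edges as untyped and undirected.
    """
    graph = nx.Graph()
    dropped_loops = 0
    collapsed = 0
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"SIF line {lineno}: expected 3 fields, got {len(fields)}")
            a, itype, b = fields
            if itype not in INTERACTION_TYPES:
                raise FormatError(
                    f"SIF line {lineno}: unknown interaction type {itype!r}; "
                    f"allowed: {sorted(INTERACTION_TYPES)}"
                )
            if a == b:
                dropped_loops += 1
                logger.warning("SIF line %d: dropped self-loop on %r", lineno, a)
                continue
            if graph.has_edge(a, b):
                collapsed += 1
                continue
            graph.add_edge(a, b, interaction=itype)
    if dropped_loops or collapsed:
        logger.info(
            "read_interaction_edges: dropped %d self-loops, collapsed %d duplicate pairs",
            dropped_loops,
            collapsed,
        )
    return graph


def write_interaction_edges(graph: nx.Graph, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get('interaction', 'b')}\t{v}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Export a network as GraphML (text XML) for external viewers."""
    nx.write_graphml(graph, Path(path))


# ---------------------------------------------------------------------------
# miRNA target map
# ---------------------------------------------------------------------------

TARGET_BIOTYPES = ("mRNA", "lncRNA")


@dataclass
class TargetMap:
    """Deduplicated set of (miRNA, target, target biotype) relations."""

    relations: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        bad = {r[2] for r in self.relations} - set(TARGET_BIOTYPES)
        if bad:
            raise FormatError(f"target biotypes {sorted(bad)} not in {TARGET_BIOTYPES}")

    def __len__(self) -> int:
        return len(self.relations)

    def targets_of(self, mirna: str, biotype: str) -> list[str]:
        return sorted(t for m, t, b in self.relations if m == mirna and b == biotype)

    def mirnas(self) -> list[str]:
        return sorted({m for m, _, _ in self.relations})


def read_target_map(path: str | Path) -> TargetMap:
    """Read a TSV of (miRNA, target, biotype) rows; duplicates appear once."""
    relations: set[tuple[str, str, str]] = set()
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"target map line {lineno}: expected 3 fields")
            mirna, target, biotype = fields
            if biotype not in TARGET_BIOTYPES:
                raise FormatError(
                    f"target map line {lineno}: biotype {biotype!r} not in {TARGET_BIOTYPES}"
                )
            relations.add((mirna, target, biotype))
    return TargetMap(frozenset(relations))


def write_target_map(targets: TargetMap, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for mirna, target, biotype in sorted(targets.relations):
            fh.write(f"{mirna}\t{target}\t{biotype}\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold measurements plus the reference gene name.

    ``rows`` columns: sample, condition (case/control), gene, ct.  The
    reference gene must be measured in every sample and all Ct values must be
    finite and positive.
    """

    rows: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        required = ["sample", "condition", "gene", "ct"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"Ct table missing columns {missing}")
        bad = set(self.rows["condition"]) - {"case", "control"}
        if bad:
            raise FormatError(f"conditions must be case/control, got {sorted(bad)}")
        ct = pd.to_numeric(self.rows["ct"], errors="coerce")
        if ct.isna().any() or not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise FormatError("Ct values must be finite and positive")
        self.rows = self.rows.assign(ct=ct).reset_index(drop=True)
        samples = set(self.rows["sample"])
        ref_samples = set(self.rows.loc[self.rows["gene"] == self.reference, "sample"])
        if samples - ref_samples:
            raise ConsistencyError(
                f"reference gene {self.reference!r} missing in samples "
                f"{sorted(samples - ref_samples)}"
            )


def read_ct_table(path: str | Path, reference: str) -> CtTable:
    rows = pd.read_csv(Path(path), sep="\t", dtype={"sample": str, "condition": str, "gene": str})
    return CtTable(rows=rows, reference=reference)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.rows[["sample", "condition", "gene", "ct"]].to_csv(
        Path(path), sep="\t", index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named result DataFrames as TSV files under ``out_dir``.

    Returns the written paths (one ``<name>.tsv`` per table, fixed column
    order as given, 6 significant digits for reals).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)
    return written
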