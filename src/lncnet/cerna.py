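"""Competing-endogenous-RNA (ceRNA) triplet discovery.

A (miRNA, lncRNA, mRNA) trio is a competing triplet when both transcripts
are targets of the miRNA, the two transcripts are positively co-expressed,
and (when miRNA expression is available) each transcript correlates
negatively with the shared miRNA — the sponge signature.  Target relations
arrive as an input map (sequence-based site prediction is out of scope);
correlations are Pearson coefficients over the samples shared by the
expression matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TargetMap

__all__ = [
    "pearson",
    "find_competing_triplets",
    "triplet_network_summary",
]

TRIPLET_COLUMNS = [
    "mirna", "lncrna", "mrna", "r_lnc_mrna", "r_mir_mrna", "r_mir_lnc", "target_only",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length sample vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >=3 samples, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _shared_samples(*matrices: ExpressionMatrix) -> list[str]:
    shared = [s for s in matrices[0].sample_ids if all(s in m.sample_ids for m in matrices[1:])]
    if len(shared) < 3:
        raise ValueError(f"expression matrices share only {len(shared)} samples; need >=3")
    return shared


def find_competing_triplets(
    targets: TargetMap,
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix | None = None,
    pos_threshold: float = 0.8,
    neg_threshold: float = -0.8,
    mode: str = "strict",
) -> pd.DataFrame:
    """Enumerate competing triplets licensed by the target map and correlations.

    For every miRNA in the map and every (lncRNA, mRNA) pair of its targets
    present in the expression data, the lncRNA-mRNA Pearson r must reach
    ``pos_threshold``; with miRNA expression available both miRNA-transcript
    correlations must be at or below ``neg_threshold``.  Without a miRNA
    matrix, ``strict`` mode refuses to run while ``lenient`` mode applies only
    the co-expression constraint and flags rows as target-only.

    Output rows are ordered lexicographically by (miRNA, lncRNA, mRNA).
    """
    if not (pos_threshold > 0 > neg_threshold):
        raise ValueError(
            f"need pos_threshold > 0 > neg_threshold, got ({pos_threshold}, {neg_threshold})"
        )
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be strict or lenient, got {mode!r}")
    if mirna_expr is None and mode == "strict":
        raise ValueError("strict mode requires a miRNA expression matrix (or use mode='lenient')")
    if len(targets) == 0:
        return pd.DataFrame(columns=TRIPLET_COLUMNS)

    mats = [lnc_expr, mrna_expr] + ([mirna_expr] if mirna_expr is not None else [])
    shared = _shared_samples(*mats)
    lnc_vals = lnc_expr.values[shared]
    mrna_vals = mrna_expr.values[shared]
    mir_vals = mirna_expr.values[shared] if mirna_expr is not None else None

    rows = []
    for mirna in targets.mirnas():
        lnc_targets = [t for t in targets.targets_of(mirna, "lncRNA") if t in lnc_vals.index]
        mrna_targets = [t for t in targets.targets_of(mirna, "mRNA") if t in mrna_vals.index]
        if not lnc_targets or not mrna_targets:
            continue
        mir_profile = None
        if mir_vals is not None and mirna in mir_vals.index:
            profile = mir_vals.loc[mirna].to_numpy()
            if profile.std() > 0:
                mir_profile = profile
        for lnc in lnc_targets:
            x = lnc_vals.loc[lnc].to_numpy()
            if x.std() == 0:
                continue
            r_mir_lnc = pearson(mir_profile, x) if mir_profile is not None else np.nan
            if mir_profile is not None and not (r_mir_lnc <= neg_threshold):
                continue
            for mrna in mrna_targets:
                y = mrna_vals.loc[mrna].to_numpy()
                if y.std() == 0:
                    continue
                r_lnc_mrna = pearson(x, y)
                if r_lnc_mrna < pos_threshold:
                    continue
                r_mir_mrna = pearson(mir_profile, y) if mir_profile is not None else np.nan
                if mir_profile is not None and not (r_mir_mrna <= neg_threshold):
                    continue
                rows.append(
                    {
                        "mirna": mirna,
                        "lncrna": lnc,
                        "mrna": mrna,
                        "r_lnc_mrna": r_lnc_mrna,
                        "r_mir_mrna": r_mir_mrna,
                        "r_mir_lnc": r_mir_lnc,
                        "target_only": mir_profile is None,
                    }
                )
    out = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    return out.sort_values(["mirna", "lncrna", "mrna"], kind="mergesort").reset_index(drop=True)


def triplet_network_summary(triplets: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-molecule degree in the triplet network plus the hub report.

    Degree counts the triplets a molecule participates in; the hub list holds
    every molecule attaining the maximal degree (ties reported together,
    lexicographic order).
    """
    if triplets.empty:
        return pd.DataFrame(columns=["node", "role", "degree"]), []
    counts: dict[tuple[str, str], int] = {}
    for role in ("mirna", "lncrna", "mrna"):
        for node in triplets[role]:
            counts[(node, role)] = counts.get((node, role), 0) + 1
    table = pd.DataFrame(
        [{"node": n, "role": r, "degree": d} for (n, r), d in counts.items()]
    ).sort_values(["degree", "node"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    top = table["degree"].max()
    hubs = sorted(table.loc[table["degree"] == top, "node"])
    return table, hubs
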