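"""GO/pathway over-representation analysis for DE gene lists.

Each term is tested with a two-sided Fisher exact test (point-probability
rule: the p-value sums hypergeometric probabilities of all tables no more
likely than the observed one) and a chi-square test, with Benjamini-Hochberg
FDR across terms and -log10(p) reported for plotting.  The gene universe is
everything annotated on the array, the standard choice for microarray ORA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "fisher_exact_two_sided",
    "chi2_pvalue",
    "benjamini_hochberg",
    "enrich",
    "top_terms",
]

# R-style relative tolerance when comparing point probabilities: tables whose
# probability exceeds the observed one by less than this are counted as ties.
_REL_TOL = 1e-7


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible margins: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"impossible cell count k={k} for margins K={K}, n={n}, N={N}")


def two_sided_pvalues_for_margin(K: int, n: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every feasible k at fixed margins.

    Returns (support, pvalues) where support runs from max(0, n+K-N) to
    min(n, K).  Vectorized helper shared by :func:`fisher_exact_two_sided`.
    """
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    # p(k0) = sum of pmf over tables no more probable than k0 (with tie slack)
    p = np.array([pmf[pmf <= pmf_k * (1.0 + _REL_TOL)].sum() for pmf_k in pmf])
    return support, np.minimum(p, 1.0)


def fisher_exact_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table given as (k, K, n, N).

    ``k`` DE genes in the term, ``K`` universe genes in the term, ``n`` DE
    genes total, ``N`` universe genes total.  Uses the point-probability
    definition: the sum of hypergeometric probabilities of all tables whose
    probability does not exceed that of the observed table.
    """
    _check_margins(k, K, n, N)
    support, p = two_sided_pvalues_for_margin(K, n, N)
    return float(p[k - support[0]])


def chi2_pvalue(k: int, K: int, n: int, N: int, yates: bool = False) -> float:
    """Chi-square test p-value on the same 2x2 table (no Yates correction by
    default; pass ``yates=True`` to enable it).  Degenerate margins give 1.0."""
    _check_margins(k, K, n, N)
    table = np.array([[k, K - k], [n - k, (N - K) - (n - k)]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=yates)[1])


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    de_genes,
    universe,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
    yates: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``de_genes`` against each gene set.

    Membership is computed after intersecting every set with the universe;
    terms with no DE member (k = 0) or no universe member are omitted.
    Output is ranked by Fisher p ascending (ties by term id) with columns
    term_id, term_name, category, k, K, n, N, p, chi2_p, fdr, neg_log10_p,
    significant.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE gene list")
    stray = de - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(de)
    rows = []
    for gs in sets:
        members = set(gs.members) & universe
        K = len(members)
        k = len(members & de)
        if K == 0 or k == 0:
            continue
        p = fisher_exact_two_sided(k, K, n, N)
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "category": gs.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "chi2_p": chi2_pvalue(k, K, n, N, yates=yates),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "category", "k", "K", "n", "N",
                "p", "chi2_p", "fdr", "neg_log10_p", "significant",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["significant"] = out["p"] < p_threshold
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def top_terms(results: pd.DataFrame, top: int = 20, category: str | None = None) -> pd.DataFrame:
    """Top-ranked terms (optionally within one category), as in bar-chart
    summaries of the most enriched GO terms/pathways."""
    out = results
    if category is not None:
        out = out[out["category"] == category]
    return out.head(top).reset_index(drop=True)
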