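"""Random-variance-model (RVM) moderated t-test, fold changes, DE filtering,
and the 2^-ddCt arithmetic of the qPCR validation assay.

The RVM assumes gene-wise precisions 1/sigma_g^2 share a gamma prior with
shape ``a`` and scale ``b``; equivalently the variances are inverse-gamma.
Under this prior, for a residual sample variance s^2 on ``m`` degrees of
freedom, the quantity ``a*b*s^2`` follows an F(m, 2a) distribution — the
marginal used to fit (a, b) by maximum likelihood across all genes.  The
moderated test then replaces each gene's s^2 with the posterior-shrunken

    s_tilde^2 = (m*s^2 + 2/b) / (m + 2a)

and refers t = (mean_tumor - mean_normal) / sqrt(s_tilde^2*(1/n1 + 1/n2))
to a t distribution with m + 2a degrees of freedom.  As a -> 0 and
1/b -> 0 the prior becomes uninformative and the statistic reduces to the
classical pooled-variance two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import CtTable, ExpressionMatrix, ProbeAnnotation

__all__ = [
    "RVMHyperparams",
    "fit_rvm_hyperparameters",
    "rvm_t_test",
    "compute_fold_change",
    "de_table",
    "filter_differential",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class RVMHyperparams:
    """Inverse-gamma variance prior: precision ~ Gamma(shape=a, scale=b).

    ``m`` records the residual degrees of freedom the fit was performed at
    (n1 + n2 - 2 for the unpaired two-group design).
    """

    a: float
    b: float
    m: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"hyperparameters must be positive, got a={self.a}, b={self.b}")
        if self.m < 1:
            raise ValueError(f"degrees of freedom must be >= 1, got m={self.m}")


class RVMFitError(RuntimeError):
    """Raised when the variance-prior fit cannot proceed or does not converge."""


def _negative_log_likelihood(log_ab: np.ndarray, variances: np.ndarray, m: int) -> float:
    # x = s^2 observed; a*b*x ~ F(m, 2a)  =>  density a*b*f_F(a*b*x; m, 2a)
    a, b = np.exp(log_ab)
    scaled = a * b * variances
    ll = np.log(a * b) + stats.f.logpdf(scaled, m, 2.0 * a)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll))


def fit_rvm_hyperparameters(variances: np.ndarray, m: int) -> RVMHyperparams:
    """Fit the variance-prior hyperparameters (a, b) by maximum likelihood.

    Parameters
    ----------
    variances
        Per-gene residual sample variances (>=100 positive finite values).
    m
        Residual degrees of freedom each variance was computed on.

    The optimizer is deterministic: L-BFGS-B on (log a, log b) from a fixed
    multi-start grid, keeping the best converged optimum.
    """
    variances = np.asarray(variances, dtype=float)
    if variances.size < 100:
        raise RVMFitError(f"need >=100 variances, got {variances.size}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if not np.all(np.isfinite(variances)) or np.any(variances <= 0):
        raise RVMFitError("variances must be positive and finite")
    if np.var(variances) == 0:
        raise RVMFitError("degenerate input: all variances identical")

    starts = [(la, lb) for la in (-1.0, 0.0, 1.0, 2.0) for lb in (-2.0, 0.0, 2.0)]
    best: tuple[float, np.ndarray] | None = None
    for start in starts:
        res = optimize.minimize(
            _negative_log_likelihood,
            x0=np.asarray(start),
            args=(variances, m),
            method="L-BFGS-B",
            bounds=[(-10.0, 10.0), (-12.0, 12.0)],
            options={"maxiter": 500},
        )
        if res.success and np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x)
    if best is None:
        raise RVMFitError("hyperparameter fit did not converge from any grid start")
    a, b = np.exp(best[1])
    return RVMHyperparams(a=float(a), b=float(b), m=int(m))


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    tumor = matrix.group_values("tumor").to_numpy(dtype=float)
    normal = matrix.group_values("normal").to_numpy(dtype=float)
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError(
            f"each group needs >=2 samples (tumor={tumor.shape[1]}, normal={normal.shape[1]})"
        )
    return tumor, normal


def pooled_variances(matrix: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Per-probe pooled two-sample variance and its degrees of freedom."""
    tumor, normal = _group_arrays(matrix)
    n1, n2 = tumor.shape[1], normal.shape[1]
    m = n1 + n2 - 2
    s2 = ((n1 - 1) * tumor.var(axis=1, ddof=1) + (n2 - 1) * normal.var(axis=1, ddof=1)) / m
    return s2, m


def rvm_t_test(
    matrix: ExpressionMatrix, hyper: RVMHyperparams | None = None
) -> pd.DataFrame:
    """Moderated two-sample t-test per probe (tumor vs normal, unpaired).

    When ``hyper`` is None the hyperparameters are fitted from the matrix's
    own pooled variances.  Returns a DataFrame indexed by probe with columns
    ``t``, ``df``, ``p`` and the shrunken variance ``s2_tilde``.
    """
    tumor, normal = _group_arrays(matrix)
    n1, n2 = tumor.shape[1], normal.shape[1]
    s2, m = pooled_variances(matrix)
    if hyper is None:
        positive = s2[s2 > 0]
        hyper = fit_rvm_hyperparameters(positive, m)
    a, b = hyper.a, hyper.b
    s2_tilde = (m * s2 + 2.0 / b) / (m + 2.0 * a)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    diff = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    df = m + 2.0 * a
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "s2_tilde": s2_tilde}, index=matrix.values.index
    )


def compute_fold_change(matrix: ExpressionMatrix) -> pd.Series:
    """Linear fold change tumor/normal: 2^(mean log2 tumor - mean log2 normal)."""
    tumor, normal = _group_arrays(matrix)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    return pd.Series(np.exp2(log2fc), index=matrix.values.index, name="fc")


def de_table(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation | None = None,
    hyper: RVMHyperparams | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full differential-expression table, one row per probe.

    Columns: probe_id, gene_symbol, fc, log2fc, t, df, p, fdr, direction.
    ``direction`` is ``up`` for fc >= fc_threshold & p < p_threshold, ``down``
    for fc <= 1/fc_threshold & p < p_threshold, else ``not_significant``.
    FDR is Benjamini-Hochberg over all tested probes; the filter itself uses
    the raw p-value.
    """
    tests = rvm_t_test(matrix, hyper)
    fc = compute_fold_change(matrix)
    symbol = annotation.symbol_of() if annotation is not None else {}
    fdr = multipletests(tests["p"].to_numpy(), method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "gene_symbol": [symbol.get(p, p) for p in matrix.probe_ids],
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "t": tests["t"].to_numpy(),
            "df": tests["df"].to_numpy(),
            "p": tests["p"].to_numpy(),
            "fdr": fdr,
        }
    )
    sig = table["p"] < p_threshold
    direction = np.where(
        sig & (table["fc"] >= fc_threshold),
        "up",
        np.where(sig & (table["fc"] <= 1.0 / fc_threshold), "down", "not_significant"),
    )
    table["direction"] = direction
    return table


def filter_differential(
    records: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (up, down) lists at the fold-change/p filter.

    Up: fc >= fc_threshold and p < p_threshold (strict on p, inclusive on fc).
    Down: fc <= 1/fc_threshold and p < p_threshold.  Both lists are sorted by
    p ascending, ties by |log2fc| descending then probe id.
    """
    rec = records.copy()
    if "log2fc" not in rec.columns:
        rec["log2fc"] = np.log2(rec["fc"])
    rec["_abs_l2fc"] = rec["log2fc"].abs()
    sig = rec["p"] < p_threshold
    up = rec[sig & (rec["fc"] >= fc_threshold)]
    down = rec[sig & (rec["fc"] <= 1.0 / fc_threshold)]

    def _sorted(df: pd.DataFrame) -> pd.DataFrame:
        out = df.sort_values(
            ["p", "_abs_l2fc", "probe_id"], ascending=[True, False, True], kind="mergesort"
        )
        return out.drop(columns="_abs_l2fc").reset_index(drop=True)

    return _sorted(up), _sorted(down)


def delta_delta_ct(ct: CtTable) -> pd.DataFrame:
    """Relative expression 2^-ddCt per target gene from a qPCR Ct table.

    Per sample, dCt = Ct_target - Ct_reference; ddCt = mean dCt(case) - mean
    dCt(control); relative expression is 2^-ddCt.  A two-sided two-sample
    t-test on the per-sample dCt values provides the p-value.
    """
    rows = ct.rows
    ref = rows[rows["gene"] == ct.reference].set_index("sample")["ct"]
    results = []
    for gene in sorted(set(rows["gene"]) - {ct.reference}):
        sub = rows[rows["gene"] == gene]
        missing_ref = set(sub["sample"]) - set(ref.index)
        if missing_ref:
            raise ValueError(f"no reference measurement for samples {sorted(missing_ref)}")
        dct = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
        cond = sub["condition"].to_numpy()
        case, control = dct[cond == "case"], dct[cond == "control"]
        if case.size == 0 or control.size == 0:
            raise ValueError(f"gene {gene!r} needs both case and control measurements")
        ddct = case.mean() - control.mean()
        if case.size >= 2 and control.size >= 2:
            p = float(stats.ttest_ind(case, control).pvalue)
        else:
            p = float("nan")
        results.append(
            {"gene": gene, "ddct": float(ddct), "relative_expression": float(2.0 ** (-ddct)), "p": p}
        )
    return pd.DataFrame(results)
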