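"""Moderated t-test, fold change, DE filter, and ddCt arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncnet import de as de_mod
from lncnet.de import (
    RVMHyperparams,
    compute_fold_change,
    de_table,
    delta_delta_ct,
    filter_differential,
    fit_rvm_hyperparameters,
    rvm_t_test,
)
from lncnet.io import CtTable, ExpressionMatrix
from lncnet.simulate import SyntheticSpec, generate_dataset


def _matrix(values: np.ndarray, n_tumor: int, n_normal: int) -> ExpressionMatrix:
    cols = [f"C{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    groups = {c: ("tumor" if c.startswith("C") else "normal") for c in cols}
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols)
    return ExpressionMatrix(df, groups)


class TestHyperparameterFit:
    def test_recovery_from_own_draw(self):
        rng = np.random.default_rng(42)
        a, b, m = 2.0, 1.5, 16
        sigma2 = 1.0 / rng.gamma(a, b, 5000)
        s2 = sigma2 * rng.chisquare(m, 5000) / m
        h = fit_rvm_hyperparameters(s2, m)
        assert 1.7 < h.a < 2.3
        assert 1.3 < h.b < 1.7

    def test_constant_variances_rejected(self):
        with pytest.raises(de_mod.RVMFitError, match="degenerate"):
            fit_rvm_hyperparameters(np.full(500, 0.7), 16)

    def test_too_few_variances_rejected(self):
        with pytest.raises(de_mod.RVMFitError):
            fit_rvm_hyperparameters(np.random.default_rng(0).gamma(2, 1, 50), 16)

    def test_fitted_point_is_local_optimum(self):
        rng = np.random.default_rng(7)
        s2 = (1.0 / rng.gamma(2.0, 1.5, 2000)) * rng.chisquare(16, 2000) / 16
        h = fit_rvm_hyperparameters(s2, 16)

        def loglik(a, b):
            return np.sum(np.log(a * b) + stats.f.logpdf(a * b * s2, 16, 2 * a))

        base = loglik(h.a, h.b)
        assert base >= loglik(h.a * 1.1, h.b)
        assert base >= loglik(h.a, h.b * 1.1)
        assert base >= loglik(h.a / 1.1, h.b)
        assert base >= loglik(h.a, h.b / 1.1)


class TestModeratedT:
    def test_classical_limit(self):
        """With a vanishing prior (a -> 0, 1/b -> 0) the moderated statistic is
        the classical pooled-variance t with df = m."""
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, size=(200, 18)), 9, 9)
        mod = rvm_t_test(m, RVMHyperparams(a=1e-8, b=1e8, m=16))
        t_cl, _ = stats.ttest_ind(
            m.group_values("tumor"), m.group_values("normal"), axis=1
        )
        rel = np.abs(mod["t"].to_numpy() - t_cl) / np.abs(t_cl)
        assert rel.max() < 1e-4
        assert abs(mod["df"].iloc[0] - 16) < 1e-4

    def test_identical_group_means_give_t0_p1(self):
        block = np.random.default_rng(0).normal(size=(5, 3))
        values = np.hstack([block, block])  # tumor samples == normal samples
        mod = rvm_t_test(_matrix(values, 3, 3), RVMHyperparams(a=2.0, b=1.5, m=4))
        assert np.allclose(mod["t"], 0.0)
        assert np.allclose(mod["p"], 1.0)

    def test_group_with_one_sample_rejected(self):
        m = _matrix(np.random.default_rng(0).normal(size=(10, 3)), 1, 2)
        with pytest.raises(ValueError, match=">=2"):
            rvm_t_test(m, RVMHyperparams(a=2.0, b=1.5, m=1))

    def test_shrinkage_stays_between_data_and_prior(self):
        """The moderated variance is a weighted mean of s^2 and the prior's
        fixed point 1/(a*b): shrinkage moves toward the prior, never past it."""
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(8, 1.5, size=(300, 18)), 9, 9)
        hyper = RVMHyperparams(a=2.0, b=1.5, m=16)
        mod = rvm_t_test(m, hyper)
        s2, _ = de_mod.pooled_variances(m)
        anchor = 1.0 / (hyper.a * hyper.b)
        lo = np.minimum(s2, anchor) - 1e-12
        hi = np.maximum(s2, anchor) + 1e-12
        assert ((mod["s2_tilde"] >= lo) & (mod["s2_tilde"] <= hi)).all()


class TestFoldChange:
    def test_one_doubling(self):
        values = np.array([[5.0, 5.0, 4.0, 4.0]])
        fc = compute_fold_change(_matrix(values, 2, 2))
        assert fc.iloc[0] == pytest.approx(2.0)

    def test_equal_means_unity(self):
        values = np.array([[4.0, 6.0, 5.0, 5.0]])
        fc = compute_fold_change(_matrix(values, 2, 2))
        assert fc.iloc[0] == pytest.approx(1.0)

    def test_direction_labels_at_published_fold_changes(self):
        """A 2.99-fold gene at p<0.05 is labeled up-regulated; a 0.43-fold gene
        down-regulated — the labeling convention for tumor/normal ratios."""
        records = pd.DataFrame(
            {
                "probe_id": ["up_gene", "down_gene"],
                "fc": [2.99, 0.43],
                "log2fc": np.log2([2.99, 0.43]),
                "p": [0.000124, 0.001708],
            }
        )
        up, down = filter_differential(records)
        assert list(up["probe_id"]) == ["up_gene"]
        assert list(down["probe_id"]) == ["down_gene"]


class TestFilter:
    def test_thresholds_strict_on_p_inclusive_on_fc(self):
        records = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "d"],
                "fc": [2.0, 2.0, 0.5, 0.6],
                "log2fc": np.log2([2.0, 2.0, 0.5, 0.6]),
                "p": [0.049, 0.05, 0.01, 0.01],
            }
        )
        up, down = filter_differential(records)
        assert list(up["probe_id"]) == ["a"]  # p=0.05 excluded, fc=2.0 included
        assert list(down["probe_id"]) == ["c"]  # fc=0.6 above 1/2 boundary

    def test_reorder_invariance(self):
        rng = np.random.default_rng(9)
        records = pd.DataFrame(
            {
                "probe_id": [f"g{i}" for i in range(200)],
                "fc": np.exp2(rng.normal(0, 1.5, 200)),
                "p": rng.uniform(0, 1, 200),
            }
        )
        up1, down1 = filter_differential(records)
        shuffled = records.sample(frac=1, random_state=1).reset_index(drop=True)
        up2, down2 = filter_differential(shuffled)
        pd.testing.assert_frame_equal(up1, up2)
        pd.testing.assert_frame_equal(down1, down2)

    def test_planted_recovery_on_default_fixture(self, default_dataset, default_de):
        table, up, down = default_de
        truth = default_dataset.truth
        up_called, down_called = set(up["gene_symbol"]), set(down["gene_symbol"])
        recall = (
            len(up_called & truth.de_up) + len(down_called & truth.de_down)
        ) / (len(truth.de_up) + len(truth.de_down))
        nulls = set(table["gene_symbol"]) - truth.de_up - truth.de_down
        fpr = len((up_called | down_called) & nulls) / len(nulls)
        assert recall >= 0.95
        assert fpr <= 0.05

    def test_fdr_dominates_p(self, default_de):
        table, _, _ = default_de
        assert (table["fdr"] >= table["p"] - 1e-12).all()
        assert table["fc"].gt(0).all()


class TestDeltaDeltaCt:
    def _table(self, rows):
        return CtTable(
            pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"]), reference="18s"
        )

    def test_zero_ddct_is_unity(self):
        rows = [
            ("s1", "case", "18s", 15.0), ("s1", "case", "G", 20.0),
            ("s2", "control", "18s", 16.0), ("s2", "control", "G", 21.0),
        ]
        out = delta_delta_ct(self._table(rows))
        assert out["relative_expression"].iloc[0] == pytest.approx(1.0)

    def test_one_doubling(self):
        rows = [
            ("s1", "case", "18s", 15.0), ("s1", "case", "G", 20.0),
            ("s2", "control", "18s", 15.0), ("s2", "control", "G", 21.0),
        ]
        out = delta_delta_ct(self._table(rows))
        assert out["ddct"].iloc[0] == pytest.approx(-1.0)
        assert out["relative_expression"].iloc[0] == pytest.approx(2.0)

    def test_matches_direct_formula_on_random_table(self):
        rng = np.random.default_rng(17)
        rows = []
        ref_ct = {}
        for i in range(12):
            s = f"s{i}"
            cond = "case" if i < 6 else "control"
            ref_ct[s] = rng.uniform(14, 16)
            rows.append((s, cond, "18s", ref_ct[s]))
            rows.append((s, cond, "G1", rng.uniform(18, 26)))
        out = delta_delta_ct(self._table(rows))
        # independent arithmetic: per-sample dCt, then group means
        dct = {
            s: ct - ref_ct[s]
            for (s, cond, gene, ct) in rows
            if gene == "G1"
        }
        case = np.mean([dct[f"s{i}"] for i in range(6)])
        control = np.mean([dct[f"s{i}"] for i in range(6, 12)])
        assert out["relative_expression"].iloc[0] == pytest.approx(
            2.0 ** -(case - control), abs=1e-12
        )

    def test_missing_case_measurements_rejected(self):
        rows = [
            ("s1", "control", "18s", 15.0), ("s1", "control", "G", 20.0),
            ("s2", "control", "18s", 15.0), ("s2", "control", "G", 21.0),
        ]
        with pytest.raises(ValueError, match="case"):
            delta_delta_ct(self._table(rows))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_de_table_directions_consistent(seed):
    """Direction labels always agree with the thresholds that define them."""
    rng = np.random.default_rng(seed)
    m = _matrix(rng.normal(8, 1, size=(150, 10)), 5, 5)
    table = de_table(m, hyper=RVMHyperparams(a=2.0, b=1.5, m=8))
    up = table[table["direction"] == "up"]
    down = table[table["direction"] == "down"]
    ns = table[table["direction"] == "not_significant"]
    assert ((up["fc"] >= 2.0) & (up["p"] < 0.05)).all()
    assert ((down["fc"] <= 0.5) & (down["p"] < 0.05)).all()
    assert (~((ns["fc"] >= 2.0) & (ns["p"] < 0.05))).all()
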