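"""ceRNA triplet discovery: correlations, sign constraints, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from lncnet.cerna import find_competing_triplets, pearson, triplet_network_summary
from lncnet.io import ExpressionMatrix, TargetMap


def _expr(rows: dict, groups=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    groups = groups or {c: ("tumor" if i < df.shape[1] // 2 else "normal")
                        for i, c in enumerate(df.columns)}
    return ExpressionMatrix(df, groups)


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            x, y = rng.normal(size=(2, 8))
            direct = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert pearson(x, y) == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            pearson([1, 2], [3, 4])


class TestFindTriplets:
    def _planted_fixture(self):
        """One planted triplet plus decoy relations over 6 samples."""
        rng = np.random.default_rng(4)
        w = rng.normal(size=6)
        lnc = {"L1": 8 - 2 * w + 0.1 * rng.normal(size=6),
               "L2": rng.normal(8, 1, 6)}
        mrna = {"M1": 8 - 2 * w + 0.1 * rng.normal(size=6),
                "M2": rng.normal(8, 1, 6), "M3": rng.normal(8, 1, 6)}
        mir = {"mir1": 5 + 2 * w + 0.1 * rng.normal(size=6),
               "mir2": rng.normal(5, 1, 6)}
        rels = {("mir1", "L1", "lncRNA"), ("mir1", "M1", "mRNA")}
        # decoys: 10 relations that never form a correlated trio
        for i, (m, t, b) in enumerate(
            [("mir1", "M2", "mRNA"), ("mir1", "M3", "mRNA"), ("mir1", "L2", "lncRNA"),
             ("mir2", "L1", "lncRNA"), ("mir2", "L2", "lncRNA"), ("mir2", "M1", "mRNA"),
             ("mir2", "M2", "mRNA"), ("mir2", "M3", "mRNA")]
        ):
            rels.add((m, t, b))
        return TargetMap(frozenset(rels)), _expr(lnc), _expr(mrna), _expr(mir)

    def test_planted_triplet_recovered_exactly(self):
        targets, lnc, mrna, mir = self._planted_fixture()
        out = find_competing_triplets(targets, lnc, mrna, mir, 0.8, -0.8)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["mirna"], row["lncrna"], row["mrna"]) == ("mir1", "L1", "M1")
        assert row["r_lnc_mrna"] >= 0.8
        assert row["r_mir_lnc"] <= -0.8 and row["r_mir_mrna"] <= -0.8

    def test_positive_mirna_correlation_blocks_triplet(self):
        # mRNA co-varies WITH the miRNA: no sponge signature
        w = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        lnc = _expr({"L1": 8 - w})
        mrna = _expr({"M1": 8 - w})
        mir = _expr({"mir1": 5 - w})  # negative pair corrs required; here +... mir tracks targets
        targets = TargetMap(frozenset({("mir1", "L1", "lncRNA"), ("mir1", "M1", "mRNA")}))
        out = find_competing_triplets(targets, lnc, mrna, mir, 0.8, -0.8)
        assert out.empty  # r_mir_* = +1, fails the negative constraint

    def test_empty_target_map(self):
        lnc = _expr({"L1": np.arange(6.0)})
        mrna = _expr({"M1": np.arange(6.0)})
        out = find_competing_triplets(TargetMap(frozenset()), lnc, mrna, None, mode="lenient")
        assert out.empty

    def test_strict_mode_requires_mirna_matrix(self):
        targets, lnc, mrna, _ = self._planted_fixture()
        with pytest.raises(ValueError, match="strict"):
            find_competing_triplets(targets, lnc, mrna, None, mode="strict")

    def test_lenient_mode_flags_target_only(self):
        targets, lnc, mrna, _ = self._planted_fixture()
        out = find_competing_triplets(targets, lnc, mrna, None, mode="lenient")
        assert not out.empty
        assert out["target_only"].all()
        assert out["r_mir_mrna"].isna().all()

    def test_bad_thresholds_rejected(self):
        targets, lnc, mrna, mir = self._planted_fixture()
        with pytest.raises(ValueError, match="threshold"):
            find_competing_triplets(targets, lnc, mrna, mir, -0.5, -0.8)

    def test_threshold_monotonicity(self):
        """Raising the positive cutoff or lowering the negative one never adds
        triplets."""
        targets, lnc, mrna, mir = self._planted_fixture()
        base = find_competing_triplets(targets, lnc, mrna, mir, 0.5, -0.5)
        base_set = set(map(tuple, base[["mirna", "lncrna", "mrna"]].to_numpy()))
        rng = np.random.default_rng(8)
        for _ in range(25):
            pos = float(rng.uniform(0.5, 0.99))
            neg = float(-rng.uniform(0.5, 0.99))
            out = find_competing_triplets(targets, lnc, mrna, mir, pos, neg)
            got = set(map(tuple, out[["mirna", "lncrna", "mrna"]].to_numpy()))
            assert got <= base_set

    def test_decoy_relations_never_remove_valid_triplets(self):
        targets, lnc, mrna, mir = self._planted_fixture()
        out1 = find_competing_triplets(targets, lnc, mrna, mir, 0.8, -0.8)
        more = set(targets.relations) | {("mir2", "L2", "lncRNA"), ("mir1", "L2", "lncRNA")}
        out2 = find_competing_triplets(TargetMap(frozenset(more)), lnc, mrna, mir, 0.8, -0.8)
        s1 = set(map(tuple, out1[["mirna", "lncrna", "mrna"]].to_numpy()))
        s2 = set(map(tuple, out2[["mirna", "lncrna", "mrna"]].to_numpy()))
        assert s1 <= s2

    def test_fixture_planted_triplets_recovered(self, default_dataset):
        ds = default_dataset
        bio = ds.annotation.biotype_of()
        lnc = ds.expression.subset_probes([g for g in ds.expression.probe_ids if bio[g] == "lncRNA"])
        mrna = ds.expression.subset_probes([g for g in ds.expression.probe_ids if bio[g] == "mRNA"])
        out = find_competing_triplets(ds.targets, lnc, mrna, ds.mirna_expression, 0.8, -0.8)
        got = set(map(tuple, out[["mirna", "lncrna", "mrna"]].to_numpy()))
        assert got == set(ds.truth.triplets)


class TestSummary:
    def test_shared_mirna_is_hub(self):
        trip = pd.DataFrame(
            {
                "mirna": ["mir1"] * 3,
                "lncrna": ["L1", "L2", "L3"],
                "mrna": ["M1", "M2", "M3"],
            }
        )
        table, hubs = triplet_network_summary(trip)
        assert hubs == ["mir1"]
        assert int(table.loc[table["node"] == "mir1", "degree"].iloc[0]) == 3

    def test_single_triplet_all_degree_one(self):
        trip = pd.DataFrame({"mirna": ["m"], "lncrna": ["l"], "mrna": ["r"]})
        table, hubs = triplet_network_summary(trip)
        assert (table["degree"] == 1).all()
        assert hubs == ["l", "m", "r"]

    def test_degree_sums_count_every_role(self):
        rng = np.random.default_rng(1)
        trip = pd.DataFrame(
            {
                "mirna": [f"m{i}" for i in rng.integers(0, 4, 30)],
                "lncrna": [f"l{i}" for i in rng.integers(0, 6, 30)],
                "mrna": [f"r{i}" for i in rng.integers(0, 6, 30)],
            }
        )
        table, _ = triplet_network_summary(trip)
        assert table["degree"].sum() == 3 * len(trip)

    def test_empty(self):
        table, hubs = triplet_network_summary(pd.DataFrame(columns=["mirna", "lncrna", "mrna"]))
        assert table.empty and hubs == []
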