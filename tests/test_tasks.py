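import numpy as np
import pandas as pd
import pytest

from mapeval import (
    EmptyResultError,
    ProfileTable,
    SignificanceConfig,
    consensus,
    multilabel_ap,
    phenotypic_activity,
    phenotypic_consistency,
    phenotypic_distinctiveness,
    results_to_frame,
)

CFG = SignificanceConfig(null_size=2000, seed=0)


def blob_table(centers, reps, controls, noise=0.02, seed=0, d=6):
    """Tight replicate blobs per perturbation plus a control blob at origin."""
    rng = np.random.default_rng(seed)
    rows, perts, ids = [], [], []
    for p, c in enumerate(centers):
        for r in range(reps):
            base = np.zeros(d)
            base[: len(c)] = c
            rows.append(base + noise * rng.normal(size=d))
            perts.append(f"P{p}")
            ids.append(f"P{p}_r{r}")
    for j in range(controls):
        rows.append(np.r_[np.zeros(3), 5.0, 0, 0] + noise * rng.normal(size=d))
        perts.append("control")
        ids.append(f"c{j}")
    meta = pd.DataFrame({"pert": perts}, index=pd.Index(ids, name="profile"))
    return ProfileTable(meta, np.array(rows))


class TestActivity:
    def test_perfect_separation_gives_map_one(self):
        table = blob_table([(4.0, 0), (0, 4.0)], reps=3, controls=8)
        results = phenotypic_activity(table, "pert", "control", config=CFG)
        assert {r.group for r in results} == {"P0", "P1"}
        for r in results:
            assert r.map == 1.0
            assert all(m.ap == 1.0 for m in r.members)
            assert r.retrieved

    def test_row_count_bookkeeping(self):
        """One result per perturbation with >= 2 replicates; singletons skipped."""
        table = blob_table([(4.0, 0), (0, 4.0)], reps=2, controls=6)
        single = ProfileTable(
            pd.DataFrame({"pert": ["P9"]}, index=["P9_r0"]),
            np.ones((1, table.n_features)),
        )
        merged = ProfileTable(
            pd.concat([table.meta, single.meta]),
            np.vstack([table.X, single.X]),
        )
        results = phenotypic_activity(merged, "pert", "control", config=CFG)
        assert len(results) == 2
        for r in results:
            assert r.members[0].n_pos == 1
            assert r.members[0].n_total == 1 + 6

    def test_no_controls_errors(self):
        table = blob_table([(4.0, 0)], reps=2, controls=0)
        with pytest.raises(ValueError, match="no control"):
            phenotypic_activity(table, "pert", "control", config=CFG)

    def test_raw_mode_flags_on_unadjusted_p(self):
        table = blob_table([(4.0, 0)], reps=4, controls=12)
        res = phenotypic_activity(
            table, "pert", "control",
            config=SignificanceConfig(null_size=2000, seed=0, raw=True),
            adjust=False,
        )
        assert res[0].q_value == res[0].p_value

    def test_tidy_frame(self):
        table = blob_table([(4.0, 0), (0, 4.0)], reps=3, controls=8)
        df = results_to_frame(phenotypic_activity(table, "pert", "control", config=CFG))
        assert set(df.columns) >= {"group", "map", "p_value", "q_value", "retrieved"}
        assert df.attrs["percent_retrieved"] == 100.0


class TestConsensus:
    def test_feature_medians(self):
        meta = pd.DataFrame({"pert": ["A", "A", "A", "B"]}, index=list("wxyz"))
        X = np.array([[1.0], [2.0], [100.0], [7.0]])
        cons = consensus(ProfileTable(meta, X), "pert")
        assert cons.X[cons.meta.index.get_loc("A"), 0] == 2.0  # robust to outlier
        assert cons.X[cons.meta.index.get_loc("B"), 0] == 7.0
        assert cons.meta.loc["A", "n_replicates"] == 3

    def test_two_values_average(self):
        meta = pd.DataFrame({"pert": ["A", "A"]}, index=["r0", "r1"])
        cons = consensus(ProfileTable(meta, np.array([[1.0], [3.0]])), "pert")
        assert cons.X[0, 0] == 2.0

    def test_idempotent(self):
        meta = pd.DataFrame({"pert": list("AABB")}, index=list("wxyz"))
        X = np.arange(8.0).reshape(4, 2)
        once = consensus(ProfileTable(meta, X), "pert")
        twice = consensus(once, "pert")
        np.testing.assert_allclose(once.X, twice.X)

    def test_varying_metadata_dropped_constant_kept(self):
        meta = pd.DataFrame(
            {"pert": ["A", "A"], "plate": ["p1", "p2"], "cell": ["U2OS", "U2OS"]},
            index=["r0", "r1"],
        )
        cons = consensus(ProfileTable(meta, np.zeros((2, 1))), "pert")
        assert "cell" in cons.meta.columns
        assert "plate" not in cons.meta.columns

    def test_bounded_by_member_range(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({"pert": ["A"] * 5 + ["B"] * 3}, index=range(8))
        X = rng.normal(size=(8, 4))
        cons = consensus(ProfileTable(meta, X), "pert")
        for key, idx in [("A", slice(0, 5)), ("B", slice(5, 8))]:
            row = cons.X[cons.meta.index.get_loc(key)]
            assert np.all(row >= X[idx].min(axis=0) - 1e-12)
            assert np.all(row <= X[idx].max(axis=0) + 1e-12)


class TestConsistency:
    def test_separated_labels_map_one(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {"gene": ["g1"] * 2 + ["g2"] * 2},
            index=[f"guide{i}" for i in range(4)],
        )
        X = np.vstack([np.tile([5.0, 0, 0], (2, 1)), np.tile([0, 5.0, 0], (2, 1))])
        X += 0.01 * rng.normal(size=X.shape)
        res = phenotypic_consistency(ProfileTable(meta, X), "gene", config=CFG)
        assert all(r.map == 1.0 for r in res)

    def test_single_label_errors(self):
        meta = pd.DataFrame({"gene": ["g1", "g1"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="at least 2 labels"):
            phenotypic_consistency(ProfileTable(meta, np.eye(2)), "gene", config=CFG)

    def test_gate_restricts_profiles(self):
        meta = pd.DataFrame(
            {"gene": ["g1", "g1", "g2", "g2", "g3", "g3"]},
            index=[f"x{i}" for i in range(6)],
        )
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 5)) + 4 * np.eye(6, 5)
        res = phenotypic_consistency(
            ProfileTable(meta, X), "gene", gate={"x0", "x1", "x2", "x3"}, config=CFG
        )
        assert {r.group for r in res} == {"g1", "g2"}
        for r in res:
            assert r.members[0].n_total == 3  # 1 positive + 2 other-label

    def test_gating_monotone_in_alpha(self):
        """A stricter activity threshold never admits more perturbations."""
        table = blob_table([(4, 0), (0, 4), (1, 1), (0.2, 0.1)], reps=3, controls=10)
        act = phenotypic_activity(table, "pert", "control", config=CFG)
        gate_05 = {r.group for r in act if r.q_value < 0.05}
        gate_01 = {r.group for r in act if r.q_value < 0.01}
        assert gate_01 <= gate_05


class TestDistinctiveness:
    def test_separated_perturbations(self):
        table = blob_table([(4.0, 0), (0, 4.0)], reps=3, controls=4)
        res = phenotypic_distinctiveness(table, "pert", "control", config=CFG)
        assert {r.group for r in res} == {"P0", "P1"}
        assert all(r.map == 1.0 for r in res)

    def test_negative_counts(self):
        table = blob_table([(4, 0), (0, 4), (3, 3)], reps=3, controls=5)
        res = phenotypic_distinctiveness(table, "pert", "control", config=CFG)
        for r in res:
            # negatives = total non-control replicates - own replicates
            assert r.members[0].n_total - r.members[0].n_pos == 9 - 3

    def test_single_perturbation_errors(self):
        table = blob_table([(4.0, 0)], reps=3, controls=4)
        with pytest.raises(ValueError, match="at least 2 perturbations"):
            phenotypic_distinctiveness(table, "pert", "control", config=CFG)


class TestMultilabel:
    @staticmethod
    def consensus_fixture(seed=0):
        rng = np.random.default_rng(seed)
        n = 8
        meta = pd.DataFrame(
            {"pert": [f"p{i}" for i in range(n)]},
            index=pd.Index([f"p{i}" for i in range(n)], name="profile"),
        )
        X = rng.normal(size=(n, 6)) + 6 * np.eye(n, 6)[:, :6]
        return ProfileTable(meta, X)

    def test_singleton_label_sets_reduce_to_consistency(self):
        table = self.consensus_fixture()
        labels = {f"p{i}": {f"L{i // 2}"} for i in range(8)}
        matrix, per_label = multilabel_ap(table, labels, config=CFG)
        table2 = ProfileTable(
            table.meta.assign(label=[f"L{i // 2}" for i in range(8)]), table.X
        )
        cons_res = phenotypic_consistency(table2, "label", config=CFG)
        cons_maps = {r.group: r.map for r in cons_res}
        for t, mp in matrix.per_label_map().items():
            assert mp == pytest.approx(cons_maps[t])

    def test_two_labels_two_entries(self):
        table = self.consensus_fixture()
        labels = {"p0": {"A", "B"}, "p1": {"A"}, "p2": {"B"}, "p3": {"C"}, "p4": {"C"}}
        matrix, _ = multilabel_ap(table, labels, config=CFG)
        assert ("p0", "A") in matrix.entries and ("p0", "B") in matrix.entries
        assert len([k for k in matrix.entries if k[0] == "p0"]) == 2

    def test_separated_label_column_all_ones(self):
        rng = np.random.default_rng(3)
        meta = pd.DataFrame(index=pd.Index([f"p{i}" for i in range(6)], name="profile"))
        X = rng.normal(size=(6, 4))
        X[:3] += np.array([20.0, 0, 0, 0])
        table = ProfileTable(meta, X)
        labels = {"p0": {"far"}, "p1": {"far"}, "p2": {"far"},
                  "p3": {"near"}, "p4": {"near"}, "p5": {"near"}}
        matrix, _ = multilabel_ap(table, labels, config=CFG)
        assert all(
            ap == 1.0 for (p, t), ap in matrix.entries.items() if t == "far"
        )

    def test_singleton_label_excluded(self):
        table = self.consensus_fixture()
        labels = {"p0": {"solo"}, "p1": {"A"}, "p2": {"A"}}
        matrix, _ = multilabel_ap(table, labels, config=CFG)
        assert not any(t == "solo" for _, t in matrix.entries)

    def test_unknown_profile_errors(self):
        table = self.consensus_fixture()
        with pytest.raises(ValueError, match="unknown profiles"):
            multilabel_ap(table, {"ghost": {"A"}, "p0": {"A"}}, config=CFG)
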