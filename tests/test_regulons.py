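import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from hspcflow import regulons, simdata


def _auc(values, regs=None, cells=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    regs = regs or [f"R{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=regs, columns=cells)


class TestBatchCenter:
    def test_single_batch_leaves_matrix_unchanged(self):
        auc = _auc(np.random.default_rng(0).random((3, 10)))
        batches = pd.Series("b1", index=auc.columns)
        out = regulons.batch_center(auc, batches)
        assert np.allclose(out.to_numpy(), auc.to_numpy())

    def test_pure_offset_removed_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.random(40)
        vals = np.concatenate([base[:20], base[20:] + 0.3])[None, :]
        auc = _auc(vals)
        batches = pd.Series(["a"] * 20 + ["b"] * 20, index=auc.columns)
        out = regulons.batch_center(auc, batches)
        ma = out.loc[:, batches == "a"].mean(axis=1)
        mb = out.loc[:, batches == "b"].mean(axis=1)
        assert np.abs(ma - mb).max() < 1e-9

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(2)
        auc = _auc(rng.random((4, 30)))
        batches = pd.Series(rng.choice(["a", "b", "c"], 30), index=auc.columns)
        out = regulons.batch_center(auc, batches)
        assert np.abs(
            out.mean(axis=1).to_numpy() - auc.mean(axis=1).to_numpy()
        ).max() < 1e-9

    def test_tiny_batch_warns(self):
        auc = _auc(np.random.default_rng(3).random((2, 5)))
        batches = pd.Series(["a", "a", "a", "a", "b"], index=auc.columns)
        with pytest.warns(UserWarning, match="fewer than 2"):
            regulons.batch_center(auc, batches)


class TestBinarize:
    def test_well_separated_modes_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate(
            [rng.normal(0.1, 0.05, 500), rng.normal(0.8, 0.05, 500)]
        )
        truth = np.r_[np.zeros(500), np.ones(500)]
        binary, thr = regulons.binarize(_auc(x))
        mis = (binary.iloc[0].to_numpy() != truth).mean()
        assert mis < 0.01
        assert 0.1 < thr.iloc[0] < 0.8  # strictly between the modes
        assert set(np.unique(binary.to_numpy())) <= {0, 1}

    def test_constant_regulon_all_zero_with_warning(self):
        auc = _auc(np.full((1, 30), 0.4))
        with pytest.warns(UserWarning, match="constant"):
            binary, thr = regulons.binarize(auc)
        assert (binary.to_numpy() == 0).all()
        assert np.isnan(thr.iloc[0])

    def test_unimodal_regulon_all_zero_with_warning(self):
        rng = np.random.default_rng(1)
        auc = _auc(rng.normal(0.4, 0.02, 400))
        with pytest.warns(UserWarning, match="unimodal"):
            binary, _ = regulons.binarize(auc)
        assert (binary.to_numpy() == 0).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(regulons.RegulonError):
            regulons.binarize(_auc(np.random.default_rng(2).random((1, 10))))


class TestPercentActive:
    def test_simple_fractions(self):
        binary = _auc([[1, 1, 1, 1, 0, 0, 0, 0]]).astype(int)
        clusters = pd.Series(["C1"] * 8, index=binary.columns)
        out = regulons.percent_active(binary, clusters)
        assert out.loc["R0", "C1"] == 50.0
        zeros = regulons.percent_active(binary * 0, clusters)
        assert zeros.loc["R0", "C1"] == 0.0
        ones = regulons.percent_active((binary * 0 + 1), clusters)
        assert ones.loc["R0", "C1"] == 100.0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(3)
        binary = _auc(rng.integers(0, 2, size=(5, 60))).astype(int)
        clusters = pd.Series(rng.choice(["a", "b", "c"], 60),
                             index=binary.columns)
        out = regulons.percent_active(binary, clusters)
        for r in binary.index:
            for c in ["a", "b", "c"]:
                cells = clusters.index[(clusters == c).to_numpy()]
                manual = 100.0 * sum(binary.loc[r, x] for x in cells) / len(cells)
                assert out.loc[r, c] == manual

    def test_unlabeled_cell_rejected(self):
        binary = _auc([[1, 0]]).astype(int)
        clusters = pd.Series(["a"], index=[binary.columns[0]])
        with pytest.raises(regulons.RegulonError):
            regulons.percent_active(binary, clusters)


class TestRSS:
    def test_indicator_proportional_regulon_scores_one(self):
        auc = _auc([[0.5, 0.5, 0.0, 0.0]])
        clusters = pd.Series(["C1", "C1", "C2", "C2"], index=auc.columns)
        out = regulons.rss(auc, clusters)
        assert out.loc["R0", "C1"] == pytest.approx(1.0)

    def test_uniform_activity_matches_literal_jsd_oracle(self):
        auc = _auc([[0.25, 0.25, 0.25, 0.25]])
        clusters = pd.Series(["C1", "C1", "C2", "C2"], index=auc.columns)
        out = regulons.rss(auc, clusters)
        oracle = 1.0 - jensenshannon(
            np.full(4, 0.25), np.array([0.5, 0.5, 0, 0]), base=2
        )
        assert out.loc["R0", "C1"] == pytest.approx(oracle)

    def test_scores_bounded_for_random_matrices(self):
        rng = np.random.default_rng(4)
        auc = _auc(rng.random((6, 40)))
        clusters = pd.Series(rng.choice(["a", "b"], 40), index=auc.columns)
        out = regulons.rss(auc, clusters)
        assert ((out >= 0) & (out <= 1)).all().all()

    def test_specific_regulon_outranks_ubiquitous(self, small_config,
                                                  reference_small):
        _, truth = reference_small
        auc = simdata.generate_auc_matrix(small_config, truth)
        scores = regulons.rss(auc, truth.cell_labels)
        ubiq = f"R{1:02d}"  # active everywhere by construction
        for ctype, active in truth.active_regulon_map.items():
            specific = sorted(
                r for r in active
                if sum(r in s for s in truth.active_regulon_map.values()) == 1
            )
            if specific:
                assert scores.loc[specific[0], ctype] > scores.loc[ubiq, ctype]

    def test_all_zero_regulon_reported_missing(self):
        auc = _auc([[0.0, 0.0, 0.0], [0.1, 0.2, 0.3]])
        clusters = pd.Series(["a", "a", "b"], index=auc.columns)
        with pytest.warns(UserWarning, match="all-zero"):
            out = regulons.rss(auc, clusters)
        assert out.loc["R0"].isna().all()
        assert out.loc["R1"].notna().all()


class TestTopRegulons:
    def _scores(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            rng.random((20, 3)),
            index=[f"R{i:02d}" for i in range(20)],
            columns=["C1", "C2", "C3"],
        )

    def test_top_five_of_twenty(self):
        top = regulons.top_regulons(self._scores(), 5)
        scores = self._scores()
        for c, regs in top.items():
            assert len(regs) == 5
            assert scores[c].max() == scores.loc[regs[0], c]

    def test_k_one_returns_argmax(self):
        scores = self._scores()
        top = regulons.top_regulons(scores, 1)
        for c in scores.columns:
            assert top[c] == [scores[c].idxmax()]

    def test_ties_break_lexicographically(self):
        scores = pd.DataFrame(
            {"C1": [0.9, 0.9, 0.1]}, index=["Rb", "Ra", "Rc"]
        )
        assert regulons.top_regulons(scores, 1)["C1"] == ["Ra"]

    def test_fewer_regulons_than_k_warns(self):
        scores = pd.DataFrame({"C1": [0.5, 0.4]}, index=["Ra", "Rb"])
        with pytest.warns(UserWarning, match="top-5"):
            top = regulons.top_regulons(scores, 5)
        assert top["C1"] == ["Ra", "Rb"]


class TestTrimNetwork:
    def test_q3_on_one_to_eight(self):
        edges = pd.DataFrame({
            "TF": "R1",
            "target": [f"g{i}" for i in range(1, 9)],
            "importance": np.arange(1.0, 9.0),
        })
        trimmed, graph = regulons.trim_network(edges)
        # Q3 of 1..8 under linear interpolation is 6.25
        assert sorted(trimmed["importance"]) == [7.0, 8.0]
        assert set(graph.successors("R1")) == {"g7", "g8"}

    def test_all_equal_importances_keep_single_target(self):
        edges = pd.DataFrame({
            "TF": "R1", "target": ["a", "b", "c"], "importance": 2.0
        })
        with pytest.warns(UserWarning, match="empties"):
            trimmed, _ = regulons.trim_network(edges)
        assert len(trimmed) == 1

    def test_single_target_regulon_kept(self):
        edges = pd.DataFrame({"TF": ["R1"], "target": ["a"],
                              "importance": [1.5]})
        with pytest.warns(UserWarning, match="empties"):
            trimmed, _ = regulons.trim_network(edges)
        assert trimmed["target"].tolist() == ["a"]

    def test_invalid_edge_lists_rejected(self):
        dup = pd.DataFrame({"TF": ["R", "R"], "target": ["a", "a"],
                            "importance": [1.0, 2.0]})
        with pytest.raises(regulons.RegulonError):
            regulons.trim_network(dup)
        neg = pd.DataFrame({"TF": ["R"], "target": ["a"],
                            "importance": [-1.0]})
        with pytest.raises(regulons.RegulonError):
            regulons.trim_network(neg)
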