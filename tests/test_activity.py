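"""Marker selection, activity scores, threshold scans, PC distances."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_activity_scores
from editaudit.activity import (
    CellMatrix,
    critical_threshold,
    pc_pairwise_distances,
    score_cells,
    select_markers,
    threshold_scan,
)
from editaudit.exceptions import ParameterError
from editaudit.simulate import simulate_expression_matrix


def make_matrix(expr: np.ndarray, conditions, clusters=None, genes=None):
    n_genes, n_cells = expr.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    df = pd.DataFrame(expr, index=genes, columns=cells)
    cond = pd.Series(conditions, index=cells)
    clus = pd.Series(clusters or ["VCM"] * n_cells, index=cells)
    return CellMatrix(df, cond, clus)


class TestScoreCells:
    def test_extremes_map_to_zero_and_one(self, rng):
        expr = rng.uniform(1, 5, size=(10, 20))
        expr[:, 0] = expr.max(axis=1) + 1.0  # cell 0 is everywhere maximal
        expr[:, 1] = 0.0  # cell 1 is everywhere minimal
        m = make_matrix(expr, ["WT"] * 10 + ["MUT"] * 10)
        scores = score_cells(m, [f"g{i}" for i in range(10)])
        assert scores.iloc[0] == pytest.approx(1.0)
        assert scores.iloc[1] == pytest.approx(0.0)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_matches_mean_of_minmax_oracle(self, rng):
        expr = rng.uniform(0, 8, size=(50, 30))
        m = make_matrix(expr, ["WT"] * 15 + ["MUT"] * 15)
        genes = [f"g{i}" for i in range(50)]
        scores = score_cells(m, genes)
        oracle = oracle_activity_scores(m.expression.loc[genes])
        for cell, val in oracle.items():
            assert abs(scores[cell] - val) < 1e-12

    def test_invariant_under_per_gene_affine_transform(self, rng):
        expr = rng.uniform(0, 4, size=(8, 25))
        m1 = make_matrix(expr, ["A"] * 13 + ["B"] * 12)
        expr2 = expr.copy()
        expr2[3] = 2.5 * expr2[3] + 7.0  # positive affine on one gene
        m2 = make_matrix(expr2, ["A"] * 13 + ["B"] * 12)
        genes = [f"g{i}" for i in range(8)]
        assert np.allclose(score_cells(m1, genes), score_cells(m2, genes))

    def test_constant_genes_dropped_all_constant_errors(self, rng):
        expr = np.ones((3, 10))
        m = make_matrix(expr, ["A"] * 5 + ["B"] * 5)
        with pytest.raises(ParameterError):
            score_cells(m, ["g0", "g1", "g2"])


class TestThresholdScan:
    def test_all_maximal_scores(self):
        scores = pd.Series([1.0] * 10, index=[f"c{i}" for i in range(10)])
        cond = pd.Series(["A"] * 5 + ["B"] * 5, index=scores.index)
        res = threshold_scan(scores, cond)
        assert (res.percent_above.loc["A"].iloc[:-1] == 100.0).all()

    def test_curve_equals_empirical_survival(self, rng):
        vals = rng.uniform(0, 1, size=40)
        scores = pd.Series(vals, index=[f"c{i}" for i in range(40)])
        cond = pd.Series(["A"] * 20 + ["B"] * 20, index=scores.index)
        res = threshold_scan(scores, cond, grid_step=0.01)
        for t in (0.0, 0.25, 0.5, 0.99):
            i = int(round(t / 0.01))
            expected = (vals[:20] > res.threshold_grid[i]).mean() * 100
            assert res.percent_above.loc["A"].iloc[i] == pytest.approx(expected)

    def test_curves_non_increasing(self, rng):
        scores = pd.Series(rng.uniform(0, 1, 60),
                           index=[f"c{i}" for i in range(60)])
        cond = pd.Series(["A", "B", "C"] * 20, index=scores.index)
        res = threshold_scan(scores, cond)
        for c in "ABC":
            curve = res.percent_above.loc[c].to_numpy()
            assert (np.diff(curve) <= 1e-12).all()

    def test_single_condition_rejected(self):
        scores = pd.Series([0.5, 0.6], index=["a", "b"])
        with pytest.raises(ParameterError):
            threshold_scan(scores, pd.Series(["A", "A"], index=["a", "b"]))


class TestCriticalThreshold:
    def test_constant_scores_cross_at_their_value(self):
        idx = [f"c{i}" for i in range(20)]
        scores = pd.Series([0.4] * 10 + [0.8] * 10, index=idx)
        cond = pd.Series(["MUT"] * 10 + ["WT"] * 10, index=idx)
        res = critical_threshold(threshold_scan(scores, cond))
        # scores > 0.4 is false exactly from t = 0.40 on
        assert res.critical_threshold == pytest.approx(0.40)
        assert res.percent_at_critical["WT"] == 100.0
        assert res.percent_at_critical["MUT"] == 0.0

    def test_identical_conditions_equal_percentages(self, rng):
        vals = rng.uniform(0, 1, 30)
        idx = [f"c{i}" for i in range(60)]
        scores = pd.Series(np.concatenate([vals, vals]), index=idx)
        cond = pd.Series(["A"] * 30 + ["B"] * 30, index=idx)
        res = critical_threshold(threshold_scan(scores, cond),
                                 downregulated_condition="A")
        assert res.percent_at_critical["A"] == res.percent_at_critical["B"]

    def test_simulated_shift_separates_conditions(self, rng):
        mut = np.clip(rng.normal(0.4, 0.05, 500), 0, 1)
        wt = np.clip(rng.normal(0.6, 0.05, 500), 0, 1)
        idx = [f"c{i}" for i in range(1000)]
        scores = pd.Series(np.concatenate([mut, wt]), index=idx)
        cond = pd.Series(["MUT"] * 500 + ["WT"] * 500, index=idx)
        res = critical_threshold(threshold_scan(scores, cond))
        assert res.percent_at_critical["WT"] > 50.0 > res.percent_at_critical["MUT"]

    def test_never_dropping_curve_flagged(self):
        idx = ["a", "b"]
        scores = pd.Series([0.99, 0.99], index=idx)
        cond = pd.Series(["A", "B"], index=idx)
        res = threshold_scan(scores, cond, grid_step=0.5)
        res = critical_threshold(res, downregulated_condition="A")
        assert res.critical_threshold == pytest.approx(1.0)


class TestSelectMarkers:
    def test_top_k_cap(self):
        matrix, meta, truth = simulate_expression_matrix(
            n_cells_per_condition=150, n_genes=300, n_up=20, n_down=0,
            effect=4.0, seed=5)
        m = CellMatrix.from_frames(matrix, meta)
        up, down = select_markers(m, "VCM", "MUT", "WT", top_k=15)
        assert len(up) == 15
        assert set(up) <= set(truth.expression.up_genes)

    def test_recovery_at_two_sd_effect(self):
        matrix, meta, truth = simulate_expression_matrix(
            n_cells_per_condition=200, n_genes=500, n_up=10, n_down=10,
            effect=2.0, seed=6)
        m = CellMatrix.from_frames(matrix, meta)
        up, down = select_markers(m, "VCM", "MUT", "WT")
        t = truth.expression
        recovered = len(set(up) & set(t.up_genes)) + len(set(down) & set(t.down_genes))
        assert recovered >= 0.9 * (len(t.up_genes) + len(t.down_genes))

    def test_null_controls_false_positives(self):
        fp_rates = []
        for rep in range(5):
            matrix, meta, _ = simulate_expression_matrix(
                n_cells_per_condition=100, n_genes=400, n_up=0, n_down=0,
                effect=0.0, seed=100 + rep)
            m = CellMatrix.from_frames(matrix, meta)
            up, down = select_markers(m, "VCM", "MUT", "WT", top_k=400)
            fp_rates.append((len(up) + len(down)) / 400)
        mean_fp = np.mean(fp_rates)
        sigma = np.sqrt(0.05 * 0.95 / (5 * 400))
        assert mean_fp <= 0.05 + 3 * sigma

    def test_missing_condition_returns_empty(self):
        matrix, meta, _ = simulate_expression_matrix(
            n_cells_per_condition=20, n_genes=30, n_up=0, n_down=0,
            effect=0.0, seed=1)
        m = CellMatrix.from_frames(matrix, meta)
        assert select_markers(m, "VCM", "MUT", "EDITED") == ([], [])


class TestPcDistances:
    def test_identical_cells_distance_zero(self):
        expr = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        m = make_matrix(expr, ["WT", "WT", "MUT", "MUT"])
        out = pc_pairwise_distances(m, "WT")
        assert np.allclose(out["MUT"], 0.0)

    def test_axis_aligned_data_recovers_raw_distances(self, rng):
        # two "genes" with very different variances: PCs = coordinate axes
        n = 40
        x = np.vstack([rng.normal(20, 5.0, n), rng.normal(20, 0.5, n)])
        m = make_matrix(x, ["WT"] * 20 + ["MUT"] * 20)
        out = pc_pairwise_distances(m, "WT")
        raw = np.sqrt(
            ((x[:, 20:, None] - x[:, None, :20]) ** 2).sum(axis=0)
        ).ravel()
        assert np.allclose(out["MUT"], np.sort(raw))

    def test_duplicating_cells_keeps_distance_values(self, rng):
        # duplicating every cell leaves mean and covariance (hence the PC
        # plane) unchanged: the distance multiset scales, values do not
        x = rng.normal(5, 1, size=(6, 30))
        m1 = make_matrix(x, ["WT"] * 15 + ["MUT"] * 15)
        d1 = pc_pairwise_distances(m1, "WT")["MUT"]
        x2 = np.concatenate([x, x], axis=1)
        m2 = make_matrix(x2, (["WT"] * 15 + ["MUT"] * 15) * 2)
        d2 = pc_pairwise_distances(m2, "WT")["MUT"]
        assert np.allclose(np.unique(np.round(d1, 8)),
                           np.unique(np.round(d2, 8)))

    def test_too_few_cells_rejected(self):
        m = make_matrix(np.ones((3, 1)), ["WT"])
        with pytest.raises(ParameterError):
            pc_pairwise_distances(m, "WT")
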