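"""Connectome-based predictive modeling: selection, LOOCV, permutation,
threshold sweep, and lesion analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memconn import (
    CbpmConfig,
    lesion_analysis,
    loocv,
    make_atlas,
    permutation_test,
    run_cbpm,
    select_edges,
    summed_strengths,
    threshold_sweep,
)
from memconn.networks import edge_index_pairs


def residualize_oracle(x, y, covariates, alpha):
    """Residualize-then-Pearson reference for partial-correlation selection."""
    n, e = x.shape
    design = np.column_stack([np.ones(n), covariates])
    pos = np.zeros(e, bool)
    neg = np.zeros(e, bool)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    yres = y - design @ beta_y
    c = covariates.shape[1]
    for k in range(e):
        beta_x, *_ = np.linalg.lstsq(design, x[:, k], rcond=None)
        xres = x[:, k] - design @ beta_x
        r = stats.pearsonr(xres, yres).statistic
        t = r * np.sqrt((n - 2 - c) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2 - c)
        if p < alpha:
            (pos if r > 0 else neg)[k] = True
    return pos, neg


class TestSelectEdges:
    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 60))
        cov = rng.standard_normal((40, 3))
        y = x[:, 0] * 0.5 + cov[:, 0] * 0.3 + rng.standard_normal(40)
        for alpha in (0.01, 0.05, 0.2):
            pos, neg = select_edges(x, y, cov, alpha)
            want_pos, want_neg = residualize_oracle(x, y, cov, alpha)
            assert np.array_equal(pos, want_pos)
            assert np.array_equal(neg, want_neg)

    def test_matches_pingouin_partial_corr(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        x = rng.standard_normal((35, 10))
        cov = rng.standard_normal((35, 2))
        y = rng.standard_normal(35)
        _, _, r, p = select_edges(x, y, cov, 0.05, return_stats=True)
        for k in range(10):
            frame = pd.DataFrame(
                {"x": x[:, k], "y": y, "c1": cov[:, 0], "c2": cov[:, 1]}
            )
            ref = pingouin.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
            assert r[k] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p[k] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 25))
        y = rng.standard_normal(30)
        pos, neg, r, p = select_edges(x, y, None, 0.1, return_stats=True)
        for k in range(25):
            ref = stats.pearsonr(x[:, k], y)
            assert r[k] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[k] == pytest.approx(ref.pvalue, abs=1e-12)
        assert not (pos & neg).any()

    def test_perfect_edge_always_selected(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((20, 5))
        y = x[:, 2].copy()
        pos, _ = select_edges(x, y, None, 1e-10)
        assert pos[2]

    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        n, e, alpha = 60, 1000, 0.05
        x = rng.standard_normal((n, e))
        y = rng.standard_normal(n)
        pos, neg = select_edges(x, y, None, alpha)
        frac = (pos.sum() + neg.sum()) / e
        tol = 3 * np.sqrt(alpha * (1 - alpha) / e)
        assert frac == pytest.approx(alpha, abs=tol)

    def test_constant_edge_unselectable(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((25, 4))
        x[:, 1] = 3.0
        pos, neg = select_edges(x, x[:, 0], None, 0.9999)
        assert not pos[1] and not neg[1]


class TestSummedStrengths:
    def test_simple_sums(self):
        row = np.array([0.1, 0.2, -0.3, 0.4])
        pos = np.array([True, True, False, False])
        neg = np.array([False, False, True, False])
        assert summed_strengths(row, pos, neg) == (pytest.approx(0.3), pytest.approx(-0.3))

    def test_empty_masks_give_zero(self):
        row = np.array([0.5, 0.5])
        empty = np.zeros(2, bool)
        assert summed_strengths(row, empty, empty) == (0.0, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        row = rng.standard_normal(50)
        pos = rng.random(50) < 0.3
        neg = ~pos & (rng.random(50) < 0.3)
        ps, ns = summed_strengths(row, pos, neg)
        assert ps == pytest.approx(sum(row[k] for k in range(50) if pos[k]))
        assert ns == pytest.approx(sum(row[k] for k in range(50) if neg[k]))


def planted_data(seed=1, n=100, e=300, n_signal=5, strength=1.0, noise=0.1):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    x = rng.standard_normal((n, e)) * 0.2
    x[:, :n_signal] += strength * y[:, None] + noise * rng.standard_normal((n, n_signal))
    return x, y


class TestLoocv:
    def test_strong_signal_predicts_well(self):
        x, y = planted_data()
        res = loocv(x, y, None, CbpmConfig(selection_alpha=0.01))
        assert res.status == "ok"
        assert res.r_obs_pred > 0.95

    def test_null_r_centered_at_or_below_zero(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((40, 100))
            y = rng.standard_normal(40)
            rs.append(loocv(x, y).r_obs_pred)
        assert np.nanmean(rs) <= 0.05  # LOOCV is pessimistic under the null

    def test_all_empty_selections_fall_back_to_fold_means(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        res = loocv(x, y, None, CbpmConfig(selection_alpha=1e-12))
        assert len(res.fallback_folds) == 10
        assert res.status in ("ok", "degenerate")
        for f in range(10):
            train_mean = np.delete(y, f).mean()
            assert res.predicted[f] == pytest.approx(train_mean)

    def test_fold_masks_match_standalone_selection(self):
        x, y = planted_data(seed=4, n=30, e=50)
        res = loocv(x, y, None, CbpmConfig(selection_alpha=0.05))
        for f in (0, 13, 29):
            rows = np.arange(30) != f
            pos, neg = select_edges(x[rows], y[rows], None, 0.05)
            assert np.array_equal(res.fold_pos_masks[f], pos)
            assert np.array_equal(res.fold_neg_masks[f], neg)

    def test_fold_masks_match_selection_with_covariates(self):
        rng = np.random.default_rng(14)
        x, y = planted_data(seed=14, n=30, e=50)
        cov = rng.standard_normal((30, 2))
        res = loocv(x, y, cov, CbpmConfig(selection_alpha=0.05))
        for f in (0, 15):
            rows = np.arange(30) != f
            pos, neg = select_edges(x[rows], y[rows], cov[rows], 0.05)
            assert np.array_equal(res.fold_pos_masks[f], pos)
            assert np.array_equal(res.fold_neg_masks[f], neg)

    def test_no_leakage_when_heldout_row_corrupted(self):
        """Corrupting the held-out subject's edges and behavior leaves that
        fold's masks and fitted coefficients exactly unchanged."""
        x, y = planted_data(seed=2, n=40, e=80)
        config = CbpmConfig(selection_alpha=0.05)
        base = loocv(x, y, None, config)
        f = 17
        x_bad = x.copy()
        y_bad = y.copy()
        x_bad[f] = 1e6
        y_bad[f] = -1e6
        corrupted = loocv(x_bad, y_bad, None, config)
        assert np.array_equal(base.fold_pos_masks[f], corrupted.fold_pos_masks[f])
        assert np.array_equal(base.fold_neg_masks[f], corrupted.fold_neg_masks[f])
        assert base.fold_coefs[f] == corrupted.fold_coefs[f]

    def test_too_few_subjects_refused(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="at least 10"):
            loocv(rng.standard_normal((5, 10)), rng.standard_normal(5))

    def test_determinism(self):
        x, y = planted_data(seed=6, n=30, e=40)
        a = run_cbpm(x, y, None, CbpmConfig(n_permutations=10, seed=3))
        b = run_cbpm(x, y, None, CbpmConfig(n_permutations=10, seed=3))
        assert a.r_obs_pred == b.r_obs_pred
        assert np.array_equal(a.null_r, b.null_r)
        assert a.p_perm == b.p_perm


class TestPermutation:
    def test_strong_signal_beats_every_null(self):
        x, y = planted_data(seed=7, n=60, e=150)
        res = run_cbpm(x, y, None, CbpmConfig(n_permutations=50, seed=5))
        assert res.p_perm == 0.0
        assert res.p_perm_add_one == pytest.approx(1 / 51)

    def test_worst_possible_observed_gives_p_one(self):
        x, y = planted_data(seed=8, n=30, e=40)
        res = loocv(x, y)
        res.r_obs_pred = -1.0  # forced: every null run performs better
        p, null_r, _ = permutation_test(x, y, None, CbpmConfig(n_permutations=20, seed=1), res)
        assert p == 1.0

    def test_null_p_roughly_uniform(self):
        """Small calibration check: permutation p under the null is not
        concentrated (full calibration runs in the acceptance suite)."""
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal((20, 50))
            y = rng.standard_normal(20)
            res = run_cbpm(x, y, None, CbpmConfig(n_permutations=40, seed=seed))
            ps.append(res.p_perm)
        assert 0.2 < np.mean(ps) < 0.8


class TestThresholdSweep:
    def test_planted_signal_positive_at_every_alpha(self):
        x, y = planted_data(seed=9, n=60, e=100)
        config = CbpmConfig(n_permutations=5, seed=2,
                            threshold_sweep=(0.001, 0.01, 0.1))
        table = threshold_sweep(x, y, None, config)
        assert (table.r_obs_pred > 0).all()

    def test_monotone_selection_counts(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((40, 200))
        y = rng.standard_normal(40)
        counts = []
        for alpha in (0.001, 0.01, 0.05, 0.2):
            pos, neg = select_edges(x, y, None, alpha)
            counts.append(pos.sum() + neg.sum())
        assert counts == sorted(counts)

    def test_alpha_one_selects_by_sign_alone(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        pos, neg = select_edges(x, y, None, 1.0)
        assert (pos | neg).sum() == 50


class TestLesion:
    def test_edge_count_after_network_removal(self):
        atlas = make_atlas({"A": 4, "B": 6}, hippocampus_size=0)
        rng = np.random.default_rng(15)
        x = rng.standard_normal((12, edge_index_pairs(10)[0].size))
        y = rng.standard_normal(12)
        table = lesion_analysis(x, y, None, atlas, CbpmConfig(n_permutations=2, seed=0))
        removed = dict(zip(table.network, table.n_edges_removed))
        total = 10 * 9 // 2
        assert total - removed["A"] == 6 * 5 // 2
        assert total - removed["B"] == 4 * 3 // 2

    def test_lesioning_signal_network_destroys_prediction(self):
        atlas = make_atlas({"A": 6, "B": 6, "C": 6}, hippocampus_size=0)
        rows, cols = edge_index_pairs(18)
        # plant signal only on edges internal to network A (ROIs 0..5)
        internal_a = np.flatnonzero((rows < 6) & (cols < 6))
        rng = np.random.default_rng(16)
        n = 80
        y = rng.standard_normal(n)
        x = 0.2 * rng.standard_normal((n, rows.size))
        x[:, internal_a] += 0.8 * y[:, None]
        config = CbpmConfig(n_permutations=10, seed=4)
        table = lesion_analysis(x, y, None, atlas, config).set_index("network")
        full = run_cbpm(x, y, None, config)
        assert full.r_obs_pred > 0.9
        assert table.loc["A", "r"] < 0.3 or np.isnan(table.loc["A", "r"])
        assert table.loc["B", "r"] > 0.8
        assert table.loc["C", "r"] > 0.8

    def test_role_rows_added_when_distinct(self):
        atlas = make_atlas({"DefaultC": 3, "DefaultA": 3, "VisCent": 4},
                           hippocampus_size=2)
        rng = np.random.default_rng(17)
        x = rng.standard_normal((12, edge_index_pairs(12)[0].size))
        y = rng.standard_normal(12)
        table = lesion_analysis(x, y, None, atlas, CbpmConfig(n_permutations=2, seed=0))
        # DMN-C/Hipp coincide with the DefaultC/Hipp networks -> no duplicates
        assert list(table.network) == ["DefaultC", "DefaultA", "VisCent", "Hipp"]
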