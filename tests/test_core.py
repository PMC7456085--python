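"""Main-effects selection test: null probability, p-values, FDR, CV, refit."""

import numpy as np
import pytest
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from binomialrf import (
    CorrBinomSpec,
    Dataset,
    ForestConfig,
    ValidationError,
    adjust_by,
    count_root_frequencies,
    cv_feature_fraction,
    main_effects_test,
    p_root,
    quantile,
    refit_and_score,
    train_forest,
)
from binomialrf.simulate import SimulationConfig, simulate_logistic

from conftest import forest_of, single_leaf, stump


class TestRootFrequencies:
    def test_counts_and_zeros(self):
        forest = forest_of([stump(f) for f in [0, 0, 1, 0, 2]], P=5)
        freq = count_root_frequencies(forest)
        assert freq.tolist() == [3, 1, 1, 0, 0]

    def test_all_trees_on_one_feature(self):
        forest = forest_of([stump(3)] * 7, P=5)
        assert count_root_frequencies(forest)[3] == 7

    def test_conservation_with_degenerate_trees(self):
        forest = forest_of([stump(0), single_leaf(), stump(1), single_leaf()], P=3)
        freq = count_root_frequencies(forest)
        assert freq.sum() == forest.V - forest.n_degenerate == 2

    def test_conservation_on_trained_forest(self, trained_forest):
        forest, _, _ = trained_forest
        assert count_root_frequencies(forest).sum() == forest.V - forest.n_degenerate


class TestPRoot:
    @pytest.mark.parametrize("P,m,expected", [(10, 3, 0.1), (1, 1, 1.0), (100, 33, 0.01)])
    def test_telescoping_values(self, P, m, expected):
        assert p_root(P, m) == pytest.approx(expected, rel=1e-12)

    def test_uniform_over_wide_grid(self):
        for P in [2, 3, 10, 33, 100, 517, 1000, 5000]:
            for m in {1, 2, P // 3 or 1, P - 1, P}:
                if 1 <= m <= P:
                    assert p_root(P, m) == pytest.approx(1.0 / P, rel=1e-9)

    def test_monte_carlo_two_stage_oracle(self):
        """Draw m of P without replacement, pick one uniformly: the chance a
        given feature is the pick must match the analytic p_root within 3 SE."""
        rng = np.random.default_rng(12345)
        P, m, draws = 10, 3, 10**5
        hits = 0
        for _ in range(draws):
            candidates = rng.choice(P, size=m, replace=False)
            hits += candidates[rng.integers(m)] == 0
        phat = hits / draws
        se = np.sqrt(0.1 * 0.9 / draws)
        assert abs(phat - p_root(P, m)) < 3 * se

    def test_bad_m(self):
        with pytest.raises(ValidationError):
            p_root(10, 0)
        with pytest.raises(ValidationError):
            p_root(10, 11)


class TestAdjustBY:
    def test_worked_example(self):
        adj = adjust_by([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.055, 0.055, 0.055], abs=1e-12)

    def test_single_pvalue(self):
        assert adjust_by([0.7]) == pytest.approx([0.7])
        assert adjust_by([0.9])[0] <= 1.0

    def test_adjusted_dominates_raw_and_caps_at_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = adjust_by(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up monotone over the sorted order
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_input_order_is_restored(self):
        p = [0.5, 0.001, 0.2]
        adj = adjust_by(p)
        assert adj[1] == min(adj)

    def test_extended_family_matches_statsmodels_when_same_size(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        for method in ("BY", "BH"):
            manual = adjust_by(p, method=method, family_size=20)
            reference = multipletests(p, method="fdr_by" if method == "BY" else "fdr_bh")[1]
            assert np.allclose(manual, reference, atol=1e-12)

    def test_extended_family_inflates(self):
        p = [0.001, 0.01]
        assert np.all(adjust_by(p, family_size=100) >= adjust_by(p))

    def test_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            adjust_by([0.5, 1.5])
        with pytest.raises(ValidationError):
            adjust_by([-0.1])


class TestMainEffectsTest:
    def test_pvalue_is_exact_binomial_tail_at_rho_zero(self):
        # 100 stumps over 10 features, one feature rooted 30 times
        roots = [0] * 30 + [1] * 40 + [2] * 30
        forest = forest_of([stump(f) for f in roots], P=10, m=3)
        res = main_effects_test(forest, rho=0.0).set_index("feature")
        expected = binom.sf(29, 100, 0.1)  # P(F >= 30)
        assert res.loc[0, "pvalue"] == pytest.approx(expected, rel=1e-10)
        assert res.loc[0, "null_prob"] == pytest.approx(0.1)

    def test_zero_frequency_feature_has_pvalue_one(self):
        forest = forest_of([stump(0)] * 5, P=4, m=1)
        res = main_effects_test(forest, rho=0.0).set_index("feature")
        assert res.loc[3, "pvalue"] == 1.0
        assert not res.loc[3, "significant"]

    def test_all_features_reported_and_sorted(self, trained_forest):
        forest, _, _ = trained_forest
        res = main_effects_test(forest)
        assert len(res) == forest.n_features
        assert res["pvalue"].is_monotonic_increasing
        # within ties on pvalue, frequency is non-increasing
        for _, grp in res.groupby("pvalue"):
            assert grp["frequency"].is_monotonic_decreasing or len(grp) == 1

    def test_critical_value_phrasing_agrees_with_pvalue_phrasing(self):
        """significant <=> F_j exceeds the null quantile at the same level
        (fdr 'none' so the per-feature level is alpha itself)."""
        roots = [0] * 12 + [1] * 5 + list(range(2, 10)) * 2 + [2] * 7
        forest = forest_of([stump(f) for f in roots], P=10, m=3)
        alpha = 0.05
        res = main_effects_test(forest, alpha=alpha, rho=0.0, fdr_method="none")
        spec = CorrBinomSpec(forest.V, 0.1, 0.0)
        crit = quantile(spec, 1 - alpha)
        for _, row in res.iterrows():
            assert row["significant"] == (row["frequency"] > crit)

    def test_adjusted_dominates_raw(self, trained_forest):
        forest, _, _ = trained_forest
        res = main_effects_test(forest)
        assert np.all(res["adj_pvalue"] >= res["pvalue"] - 1e-15)

    def test_forest_without_root_splits_rejected(self):
        forest = forest_of([single_leaf()] * 3, P=2)
        with pytest.raises(ValidationError):
            main_effects_test(forest)

    def test_seeded_features_rank_first_under_strong_signal(self):
        cfg = SimulationConfig(P=40, N=150, n_seeded=3, effect_size=3.0, seed=21,
                               forest=ForestConfig(ntree=300, seed=21))
        dataset, truth = simulate_logistic(cfg)
        res = main_effects_test(train_forest(dataset, cfg.forest))
        top3 = set(res.head(3)["feature"])
        assert len(top3 & truth.mains) >= 2


class TestCVAndRefit:
    def test_grid_is_equally_spaced(self, monkeypatch):
        seen = []
        import binomialrf.core as core_mod

        class FakeClf:
            def __init__(self, **kw):
                seen.append(kw["max_features"])

            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        monkeypatch.setattr(core_mod, "RandomForestClassifier", FakeClf)
        cfg = SimulationConfig(P=10, N=60, seed=4, forest=ForestConfig(ntree=5, seed=4))
        dataset, _ = simulate_logistic(cfg)
        best = cv_feature_fraction(dataset, folds=4, config=cfg.forest)
        # grid {0.2, 0.4, 0.6, 0.8} -> m in {2, 4, 6, 8}; ties -> smallest
        assert sorted(set(seen)) == [2, 4, 6, 8]
        assert best == pytest.approx(0.2)

    def test_cv_is_deterministic(self):
        cfg = SimulationConfig(P=8, N=60, n_seeded=1, effect_size=3.0, seed=6,
                               forest=ForestConfig(ntree=20, seed=6))
        dataset, _ = simulate_logistic(cfg)
        assert cv_feature_fraction(dataset, 3, cfg.forest) == cv_feature_fraction(
            dataset, 3, cfg.forest
        )

    def test_refit_separates_signal_from_noise(self):
        cfg = SimulationConfig(P=30, N=200, n_seeded=3, effect_size=3.0, seed=8,
                               forest=ForestConfig(ntree=150, seed=8))
        dataset, truth = simulate_logistic(cfg)
        err_signal = refit_and_score(dataset, truth.mains, cfg.forest)
        err_noise = refit_and_score(dataset, [10, 11, 12], cfg.forest)
        assert err_signal < 0.25
        assert err_noise > err_signal + 0.1

    def test_empty_selection_rejected(self):
        cfg = SimulationConfig(P=5, N=40, seed=1, forest=ForestConfig(ntree=5, seed=1))
        dataset, _ = simulate_logistic(cfg)
        with pytest.raises(ValidationError):
            refit_and_score(dataset, [])


class TestDataset:
    def test_label_encoding_and_validation(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        ds = Dataset(X, np.array(["a", "b", "a", "b", "a", "b"]))
        assert set(ds.y) == {0, 1}
        with pytest.raises(ValidationError):
            Dataset(X, np.array(["a", "b", "c", "a", "b", "c"]))
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError):
            Dataset(bad, np.array([0, 1, 0, 1, 0, 1]))
        with pytest.raises(ValidationError):
            Dataset(X, np.array([0, 1] * 3), feature_names=["dup", "dup"])
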