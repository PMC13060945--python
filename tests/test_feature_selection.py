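"""Forward selection, CV-RFE, and the importance measures."""


import numpy as np
import pandas as pd
import pytest

from repelscreen.feature_selection import (
    cv_rfe,
    filterwise_importance,
    permutation_importance,
    sfs_select,
)
from repelscreen.models import ModelSpec, fit_learner
from repelscreen.synthetic_data import (
    SyntheticConfig,
    generate_descriptor_matrix,
    generate_repellency_response,
    make_dataset,
    noise_sd_for_r2,
)


def _exhaustive_greedy(df: pd.DataFrame, y: np.ndarray, n_select: int):
    """Independent oracle: brute-force the greedy argmax at every step."""
    selected = []
    path = []
    for _ in range(n_select):
        best = None
        for name in df.columns:
            if name in selected:
                continue
            cols = df[selected + [name]].to_numpy()
            A = np.column_stack([np.ones(len(y)), cols])
            fitted = A @ np.linalg.lstsq(A, y, rcond=None)[0]
            r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0
            if best is None or r > best[0] + 1e-15:
                best = (r, name)
        selected.append(best[1])
        path.append(best[0])
    return selected, path


class TestSFS:
    def test_single_informative_feature_found_first(self):
        cfg = SyntheticConfig(n_chemicals=60, n_features=8, n_informative=1,
                              effect_sizes=[2.0], noise_sd=0.0, seed=3)
        X = generate_descriptor_matrix(cfg)
        y = generate_repellency_response(X, cfg)
        res = sfs_select(X, y, max_features=1)
        assert res.selected == ["F0"]
        # affine up to range clipping of the rare >3-sigma tail
        assert res.correlation_path[0] > 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(40, 10)),
                          columns=[f"g{i}" for i in range(10)])
        y = rng.normal(size=40)
        oracle_sel, oracle_path = _exhaustive_greedy(df, y, 3)
        res = sfs_select(df, y, max_features=3)
        assert res.selected == oracle_sel
        assert res.correlation_path == pytest.approx(oracle_path)

    def test_correlation_path_non_decreasing(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(50, 12)),
                          columns=[f"g{i}" for i in range(12)])
        y = rng.normal(size=50)
        res = sfs_select(df, y, max_features=6)
        assert all(b >= a - 1e-12 for a, b in
                   zip(res.correlation_path, res.correlation_path[1:]))

    def test_tolerance_stops_early(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(200, 6)),
                          columns=[f"g{i}" for i in range(6)])
        y = df["g0"].to_numpy()  # one perfect feature, rest pure noise
        res = sfs_select(df, y, max_features=6, tol=0.01)
        assert res.stop_reason == "tolerance"
        assert res.selected[0] == "g0"
        assert len(res.selected) < 6

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            sfs_select(df, np.ones(3), max_features=1)

    def test_planted_majority_recovered_at_study_geometry(self):
        # n=201, p=500, 18 planted at moderate noise: the greedy forward
        # search should pick up most of the planted set in its first 18
        recoveries = []
        eff = np.ones(18)
        for seed in range(10):
            cfg = SyntheticConfig(201, 500, 18, eff, 0.3,
                                  noise_sd_for_r2(eff, 0.8), seed=seed)
            ds = make_dataset(cfg)
            res = sfs_select(ds.descriptors, ds.response, max_features=18)
            recoveries.append(
                len(set(res.selected) & set(ds.informative_feature_ids))
            )
        assert np.median(recoveries) >= 14


class TestCvRfe:
    def test_strong_planted_pair_dominates_frequency(self):
        eff = np.array([3.0, 3.0])
        cfg = SyntheticConfig(n_chemicals=300, n_features=5, n_informative=2,
                              effect_sizes=eff, nuisance_correlation=0.2,
                              noise_sd=noise_sd_for_r2(eff, 0.9), seed=8)
        ds = make_dataset(cfg)
        rank = cv_rfe(ds.descriptors, ds.response, learner="random_forest",
                      subset_sizes=[5, 3, 2], k=5, repeats=2,
                      task="regression", seed=8,
                      hyperparameters={"trees": 60})
        planted = set(ds.informative_feature_ids)
        assert planted <= set(rank.top_features(rank.optimal_n))
        for f in planted:
            assert rank.frequency[f] >= 0.9 * rank.n_rounds

    def test_shuffled_labels_score_at_chance(self):
        cfg = SyntheticConfig(n_chemicals=120, n_features=6, n_informative=2,
                              effect_sizes=[2.0, 2.0], noise_sd=1.0, seed=10)
        ds = make_dataset(cfg, binary_top_fraction=0.4)
        rng = np.random.default_rng(0)
        y_null = rng.permutation(ds.labels)
        rank = cv_rfe(ds.descriptors, y_null, learner="random_forest",
                      subset_sizes=[6, 3], k=5, repeats=4,
                      task="classification", seed=10,
                      hyperparameters={"trees": 60})
        null_auc = rank.performance_by_n[rank.optimal_n]
        assert abs(null_auc - 0.5) <= 0.07

    def test_no_elimination_reduces_to_repeated_cv(self):
        cfg = SyntheticConfig(n_chemicals=100, n_features=4, n_informative=2,
                              effect_sizes=[2.0, 2.0], noise_sd=1.0, seed=11)
        ds = make_dataset(cfg)
        rank = cv_rfe(ds.descriptors, ds.response, learner="random_forest",
                      subset_sizes=[4], k=4, repeats=2, task="regression",
                      seed=11, hyperparameters={"trees": 40})
        assert rank.optimal_n == 4
        assert list(rank.performance_by_n) == [4]
        assert (rank.frequency == rank.n_rounds).all()

    def test_oversized_subset_rejected(self):
        cfg = SyntheticConfig(n_chemicals=30, n_features=4, n_informative=2,
                              effect_sizes=[1.0, 1.0], noise_sd=1.0, seed=0)
        ds = make_dataset(cfg)
        with pytest.raises(ValueError, match="subset size"):
            cv_rfe(ds.descriptors, ds.response, subset_sizes=[10])

    def test_frequency_mass_conserved_under_column_permutation(self):
        cfg = SyntheticConfig(n_chemicals=80, n_features=6, n_informative=2,
                              effect_sizes=[2.0, 2.0], noise_sd=1.0, seed=12)
        ds = make_dataset(cfg)
        shuffled = ds.descriptors.data[list(np.random.default_rng(1).permutation(
            ds.descriptors.feature_names))]
        kw = dict(learner="random_forest", subset_sizes=[6, 3], k=4, repeats=1,
                  task="regression", seed=12, hyperparameters={"trees": 40})
        a = cv_rfe(ds.descriptors, ds.response, **kw)
        b = cv_rfe(shuffled, ds.response, **kw)
        assert a.frequency.sum() == a.optimal_n * a.n_rounds
        assert b.frequency.sum() == b.optimal_n * b.n_rounds


@pytest.fixture(scope="module")
def fitted():
    # held-out evaluation: importance is about generalization error
    rng = np.random.default_rng(2)
    n = 1000
    X = pd.DataFrame({"signal": rng.normal(size=2 * n),
                      "noise": rng.normal(size=2 * n)})
    y = 3.0 * X["signal"].to_numpy()
    spec = ModelSpec("random_forest", "regression",
                     {"trees": 100, "variables_per_split": 2})
    model = fit_learner(spec, X.iloc[:n], y[:n])
    return model, X.iloc[n:], y[n:]


class TestPermutationImportance:

    def test_irrelevant_feature_near_zero(self, fitted):
        model, X_test, y_test = fitted
        imp = permutation_importance(model, X_test, y_test, "noise",
                                     metric="rmse", seed=0)
        assert abs(imp) < 5.0

    def test_sole_informative_feature_large_positive(self, fitted):
        model, X_test, y_test = fitted
        imp = permutation_importance(model, X_test, y_test, "signal",
                                     metric="rmse", seed=0)
        assert imp > 100.0

    def test_redundant_copies_share_importance(self):
        rng = np.random.default_rng(3)
        n = 600
        x = rng.normal(size=2 * n)
        junk = rng.normal(size=2 * n)
        y = 2.0 * x + rng.normal(size=2 * n) * 0.3
        spec = ModelSpec("random_forest", "regression",
                         {"trees": 150, "variables_per_split": 1})
        single_df = pd.DataFrame({"x": x, "junk": junk})
        single = fit_learner(spec, single_df.iloc[:n], y[:n])
        imp_single = permutation_importance(
            single, single_df.iloc[n:], y[n:], "x", metric="rmse", seed=0)
        dup_df = pd.DataFrame({"x": x, "x_copy": x})
        dup = fit_learner(spec, dup_df.iloc[:n], y[:n])
        imp_dup = permutation_importance(
            dup, dup_df.iloc[n:], y[n:], "x", metric="rmse", seed=0)
        # the copy absorbs part of the splits, diluting each copy's share
        assert imp_dup < imp_single

    def test_zero_baseline_error_flagged(self):
        class Identity:
            def predict(self, df):
                return df["f"].to_numpy()

        df = pd.DataFrame({"f": np.arange(50, dtype=float)})
        y = df["f"].to_numpy()
        imp = permutation_importance(Identity(), df, y, "f", metric="rmse", seed=1)
        assert imp == float("inf")
        const = pd.DataFrame({"f": np.ones(50)})
        imp0 = permutation_importance(Identity(), const, np.ones(50), "f",
                                      metric="rmse", seed=1)
        assert imp0 == 0.0


class TestFilterwiseImportance:
    def test_perfect_regression_feature(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        df = pd.DataFrame({"f": y})
        assert filterwise_importance(df, y, "f", "regression") > 0.99

    def test_independent_feature_near_chance(self):
        rng = np.random.default_rng(5)
        n = 2000
        df = pd.DataFrame({"f": rng.normal(size=n)})
        labels = rng.integers(0, 2, size=n)
        auc = filterwise_importance(df, labels, "f", "classification")
        assert 0.5 <= auc <= 0.53

    def test_anticorrelated_perfect_classifier_folds_to_one(self):
        df = pd.DataFrame({"f": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]})
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert filterwise_importance(df, labels, "f", "classification") == 1.0

    def test_constant_feature_scores_zero(self):
        df = pd.DataFrame({"f": np.ones(50)})
        y = np.arange(50.0)
        assert filterwise_importance(df, y, "f", "regression") == 0.0
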