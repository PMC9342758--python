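import numpy as np
import pandas as pd
import pytest

from habsel.forest_model import (
    PREDICTORS,
    ForestConfig,
    default_grid,
    fit_forest,
    permutation_importance,
    predict_propensity,
    tune,
)


def make_table(n=1000, seed=0, signal=None, ratio_used=0.5, extra_noise=None):
    """Synthetic 9-predictor table; ``signal`` maps predictor -> coefficient
    on the log-odds of being labelled 'used'."""
    rng = np.random.default_rng(seed)
    data = {name: rng.normal(size=n) for name in PREDICTORS if name != "sex"}
    data["sex"] = rng.choice(["M", "F"], size=n)
    df = pd.DataFrame(data)
    if signal:
        logit = np.log(ratio_used / (1 - ratio_used)) * np.ones(n)
        for name, coef in signal.items():
            logit += coef * df[name].to_numpy()
        p = 1 / (1 + np.exp(-logit))
        used = rng.uniform(size=n) < p
    else:
        used = rng.uniform(size=n) < ratio_used
    df["label"] = np.where(used, "used", "available")
    if extra_noise:
        for name in extra_noise:
            df[name] = rng.normal(size=n)
    return df


class TestForestConfig:
    def test_bad_mtry(self):
        with pytest.raises(ValueError):
            ForestConfig(mtry=0)
        with pytest.raises(ValueError):
            ForestConfig(mtry=10)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            ForestConfig(sample_fraction=1.0)

    def test_too_few_trees(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=5)


class TestFitForest:
    def test_separable_table_low_oob(self):
        df = make_table(n=1000, seed=1)
        # one covariate fully separates the labels
        df["dist_agriculture"] = np.where(df["label"] == "used", 5.0, -5.0)
        df["dist_agriculture"] += np.random.default_rng(2).normal(0, 0.1, len(df))
        fitted = fit_forest(df, ForestConfig(n_trees=50, mtry=4, seed=0))
        assert fitted.oob_error <= 0.02

    def test_null_table_majority_class_behaviour(self):
        df = make_table(n=1100, seed=3, ratio_used=1 / 11)  # 1:10 design
        fitted = fit_forest(df, ForestConfig(n_trees=100, mtry=3, seed=0))
        assert fitted.oob_error <= 0.12
        props = predict_propensity(fitted, df)
        assert np.median(props) < 0.5

    def test_determinism(self):
        df = make_table(n=300, seed=4, signal={"evenness": 1.0})
        cfg = ForestConfig(n_trees=30, mtry=3, seed=9)
        p1 = predict_propensity(fit_forest(df, cfg), df)
        p2 = predict_propensity(fit_forest(df, cfg), df)
        np.testing.assert_array_equal(p1, p2)

    def test_single_label_rejected(self):
        df = make_table(n=100, seed=5)
        df["label"] = "used"
        with pytest.raises(ValueError, match="both"):
            fit_forest(df, ForestConfig(n_trees=20, mtry=3))

    def test_never_oob_rejected(self):
        df = make_table(n=40, seed=6)
        cfg = ForestConfig(n_trees=10, mtry=3, sample_fraction=0.99, seed=0)
        with pytest.raises(ValueError, match="out-of-bag"):
            fit_forest(df, cfg)


class TestPredictPropensity:
    def test_replicated_rows_identical(self):
        df = make_table(n=200, seed=7, signal={"dist_water": 1.5})
        fitted = fit_forest(df, ForestConfig(n_trees=20, mtry=3, seed=0))
        row = pd.concat([df.iloc[[0]]] * 5, ignore_index=True)
        vals = predict_propensity(fitted, row)
        assert len(set(vals)) == 1

    def test_vote_arithmetic_bounds(self):
        df = make_table(n=200, seed=8, signal={"dist_water": 1.5})
        fitted = fit_forest(
            df, ForestConfig(n_trees=20, mtry=3, sample_fraction=0.4, seed=0)
        )
        props = predict_propensity(fitted, df)
        assert props.min() >= 0.0 and props.max() <= 1.0
        # vote granularity: multiples of 1/n_trees
        np.testing.assert_allclose(props * 20, np.round(props * 20), atol=1e-12)

    def test_calibration_under_null(self):
        df = make_table(n=2000, seed=9, ratio_used=1 / 11)
        fitted = fit_forest(df, ForestConfig(n_trees=100, mtry=3, seed=0))
        mean_prop = predict_propensity(fitted, df).mean()
        assert abs(mean_prop - fitted.class_prior) < 0.05

    def test_missing_predictor_rejected(self):
        df = make_table(n=200, seed=10)
        fitted = fit_forest(df, ForestConfig(n_trees=20, mtry=3, seed=0))
        with pytest.raises(ValueError, match="missing"):
            predict_propensity(fitted, df.drop(columns=["evenness"]))


class TestTune:
    def test_single_config_chosen(self):
        df = make_table(n=300, seed=11, signal={"evenness": 1.0})
        cfg = ForestConfig(n_trees=30, mtry=3, seed=0)
        result = tune(df, [cfg])
        assert result.chosen == cfg

    def test_tie_breaks_toward_fewer_trees(self):
        df = make_table(n=200, seed=12)
        df["dist_forest_signed"] = np.where(df["label"] == "used", 3.0, -3.0)
        a = ForestConfig(n_trees=500, mtry=3, seed=0)
        b = ForestConfig(n_trees=100, mtry=3, seed=0)
        result = tune(df, [a, b])
        # perfectly separable: both OOB errors are 0, tie-break on trees
        assert result.oob_per_config[0] == result.oob_per_config[1]
        assert result.chosen.n_trees == 100

    def test_chosen_attains_grid_minimum(self):
        df = make_table(n=400, seed=13, signal={"dist_grassland": 2.0})
        grid = [
            ForestConfig(n_trees=50, mtry=m, sample_fraction=f, seed=5)
            for m in (2, 6) for f in (0.4, 0.623)
        ]
        result = tune(df, grid)
        chosen_oob = min(
            oob for cfg, oob in zip(result.grid, result.oob_per_config)
            if cfg == result.chosen
        )
        assert chosen_oob <= min(result.oob_per_config) + 1e-12

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune(make_table(50), [])

    def test_default_grid_shape(self):
        grid = default_grid(seed=3)
        assert len(grid) == 48
        assert all(cfg.seed == 3 for cfg in grid)


class TestPermutationImportance:
    def test_informative_predictor_ranks_first(self):
        df = make_table(n=800, seed=14, signal={"dist_major_road": 2.5})
        fitted = fit_forest(df, ForestConfig(n_trees=60, mtry=3, seed=0))
        imp = permutation_importance(fitted, df, n_reps=3, seed=1)
        top = imp.loc[imp["rank"] == 1, "predictor"].iloc[0]
        assert top == "dist_major_road"

    def test_noise_predictor_near_zero(self):
        df = make_table(n=800, seed=15, signal={"dist_water": 2.0},
                        extra_noise=["dist_minor_road"])
        fitted = fit_forest(df, ForestConfig(n_trees=60, mtry=3, seed=0))
        reps = []
        for s in range(5):
            imp = permutation_importance(fitted, df, n_reps=2, seed=s)
            reps.append(imp.set_index("predictor")["importance"]["dist_minor_road"])
        mean, se = np.mean(reps), np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(mean) < max(2 * se, 0.01)

    def test_constant_column_importance_exactly_zero(self):
        df = make_table(n=300, seed=16, signal={"evenness": 2.0})
        df["dist_developed"] = 1.0
        fitted = fit_forest(df, ForestConfig(n_trees=30, mtry=3, seed=0))
        imp = permutation_importance(fitted, df, n_reps=2, seed=0)
        val = imp.set_index("predictor")["importance"]["dist_developed"]
        assert val == 0.0

    def test_ranks_are_permutation(self):
        df = make_table(n=300, seed=17, signal={"evenness": 1.0})
        fitted = fit_forest(df, ForestConfig(n_trees=30, mtry=3, seed=0))
        imp = permutation_importance(fitted, df, n_reps=1, seed=0)
        assert sorted(imp["rank"]) == list(range(1, 10))

    def test_duplicated_uninformative_preserves_top_rank(self):
        df = make_table(n=600, seed=18, signal={"dist_grassland": 2.5})
        fitted = fit_forest(df, ForestConfig(n_trees=50, mtry=3, seed=0))
        imp = permutation_importance(fitted, df, n_reps=2, seed=1)
        top_before = imp.loc[imp["rank"] == 1, "predictor"].iloc[0]

        df2 = df.copy()
        df2["noise_copy"] = df2["dist_minor_road"].to_numpy()
        features = tuple(PREDICTORS) + ("noise_copy",)
        fitted2 = fit_forest(df2, ForestConfig(n_trees=50, mtry=3, seed=0),
                             feature_names=features)
        imp2 = permutation_importance(fitted2, df2, n_reps=2, seed=1)
        top_after = imp2.loc[imp2["rank"] == 1, "predictor"].iloc[0]
        assert top_before == top_after == "dist_grassland"

    def test_bad_n_reps(self):
        df = make_table(n=100, seed=19)
        fitted = fit_forest(df, ForestConfig(n_trees=20, mtry=3, seed=0))
        with pytest.raises(ValueError):
            permutation_importance(fitted, df, n_reps=0)


class TestStrongScenarioInvariant:
    @staticmethod
    def _matched_prior_table(seed, coef):
        """1:10 table with exactly 100 used rows; selection strength ``coef``
        on two covariates, so the class prior matches the null exactly."""
        rng = np.random.default_rng(seed)
        n = 1100
        df = pd.DataFrame({
            name: rng.normal(size=n) for name in PREDICTORS if name != "sex"
        })
        df["sex"] = rng.choice(["M", "F"], size=n)
        score = coef * (df["dist_agriculture"] - df["evenness"]).to_numpy()
        w = np.exp(score - score.max())
        used_idx = rng.choice(n, size=100, replace=False, p=w / w.sum())
        labels = np.full(n, "available")
        labels[used_idx] = "used"
        df["label"] = labels
        return df

    def test_strong_selection_halves_null_oob(self):
        cfg = ForestConfig(n_trees=80, mtry=4, seed=0)
        null_oob = np.mean([
            fit_forest(self._matched_prior_table(s, 0.0), cfg).oob_error
            for s in (1, 2, 3)
        ])
        strong_oob = np.mean([
            fit_forest(self._matched_prior_table(s, 6.0), cfg).oob_error
            for s in (1, 2, 3)
        ])
        assert strong_oob <= 0.5 * null_oob
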