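import numpy as np
import pandas as pd
import pytest

from plantedmap import (
    combine_bounds,
    compare_candidates,
    default_hyperparams,
    fit_bound_ensemble,
    override_with_national_maps,
    predict_percent,
    tune_forest,
)
from plantedmap.classify import BoundEnsemble, _balanced_indices, select_converged

FEATURES = ("modis_01", "modis_02")


def make_training(n_per_class, sep, seed=0, features=FEATURES, noise="normal"):
    """Binary training table: class means +-sep/2 on every feature.

    ``noise="uniform"`` bounds each class in a +-0.5 box, so with sep > 1
    the class supports are disjoint and any sane learner is exact."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean in (("planted", sep / 2), ("natural", -sep / 2)):
        if noise == "uniform":
            X = mean + rng.uniform(-0.5, 0.5, size=(n_per_class, len(features)))
        else:
            X = rng.normal(mean, 1.0, size=(n_per_class, len(features)))
        df = pd.DataFrame(X, columns=list(features))
        df["label"] = label
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestCompareCandidates:
    def test_separable_data_scores_perfectly(self):
        tr = make_training(60, sep=12.0, noise="uniform")
        rep = compare_candidates(tr, "mid", n_iter=3, seed=1, sample_per_class=30,
                                 feature_names=FEATURES)
        assert set(rep["model"]) == {"random-forest", "support-vector", "gradient-boosted-trees"}
        assert (rep["accuracy"] == 1.0).all()
        assert (rep["f1"] == 1.0).all()

    def test_pure_noise_scores_at_chance_on_balanced_test(self):
        tr = make_training(300, sep=0.0, seed=7)
        rep = compare_candidates(tr, "upper", n_iter=5, seed=2, sample_per_class=150,
                                 feature_names=FEATURES)
        assert (rep["accuracy_balanced"] - 0.5).abs().max() < 0.1

    def test_report_carries_both_metrics_with_intervals(self):
        tr = make_training(40, sep=3.0)
        rep = compare_candidates(tr, "lower", n_iter=3, seed=0, feature_names=FEATURES)
        for metric in ("accuracy", "f1", "accuracy_balanced", "f1_balanced"):
            assert {metric, f"{metric}_ci_low", f"{metric}_ci_high"} <= set(rep.columns)
            assert rep[metric].between(0, 1).all()

    def test_single_class_rejected(self):
        tr = make_training(20, sep=1.0)
        with pytest.raises(ValueError, match="single class"):
            compare_candidates(tr[tr.label == "planted"], "mid", feature_names=FEATURES)


class TestTuneForest:
    def test_plateau_rule_picks_plateau_start(self):
        acc = {2: 0.80, 50: 0.95, 100: 0.999, 200: 1.0, 500: 1.0}
        f1 = dict(acc)
        assert select_converged(acc, f1, tol=0.002) == 100
        # a flat curve collapses to the smallest (cheapest) value
        flat = {g: 0.9 for g in acc}
        assert select_converged(flat, flat, tol=0.002) == 2

    def test_separable_data_gives_smallest_grid_values(self):
        tr = make_training(50, sep=12.0, noise="uniform")
        n_trees, n_pred = tune_forest(tr, [5, 25], [1, 2], n_iter=2, seed=3,
                                      sample_per_class=25, feature_names=FEATURES)
        assert (n_trees, n_pred) == (5, 1)

    def test_empty_grid_rejected(self):
        tr = make_training(20, sep=1.0)
        with pytest.raises(ValueError, match="empty"):
            tune_forest(tr, [], [7], feature_names=FEATURES)

    def test_default_mtry_is_floor_sqrt_of_57(self):
        assert default_hyperparams("upper", "Tropical Forest and Savanna") == (100, 7)
        assert default_hyperparams("mid", "Tropical Forest and Savanna") == (100, 42)
        assert default_hyperparams("lower", "Temperate Forest and Grassland") == (200, 20)


class TestBoundEnsemble:
    def test_twenty_members_and_balanced_member_samples(self):
        tr = make_training(60, sep=2.0)
        ens = fit_bound_ensemble(tr, "mid", hyperparams=(10, 2), seed=4,
                                 feature_names=FEATURES)
        assert ens.n_members == 20
        # undersample-to-minority rule, checked on the index helper directly
        y = np.array([1] * 100 + [0] * 1000)
        idx = _balanced_indices(y, np.random.default_rng(0))
        assert len(idx) == 200
        assert y[idx].sum() == 100

    def test_fixed_seed_reproduces_predictions(self):
        tr = make_training(50, sep=2.0)
        cells = tr.loc[:20, list(FEATURES)]
        p = [
            predict_percent(
                fit_bound_ensemble(tr, "upper", hyperparams=(10, 2), seed=11,
                                   n_members=5, feature_names=FEATURES),
                cells,
            )
            for _ in range(2)
        ]
        assert np.array_equal(p[0], p[1])

    def test_empty_class_rejected(self):
        tr = make_training(30, sep=1.0)
        with pytest.raises(ValueError, match="single class"):
            fit_bound_ensemble(tr[tr.label == "natural"], "mid", feature_names=FEATURES)

    def test_label_swap_flips_predictions(self):
        tr = make_training(150, sep=6.0, seed=5)
        swapped = tr.assign(label=tr["label"].map({"planted": "natural", "natural": "planted"}))
        cells = make_training(50, sep=6.0, seed=6).loc[:, list(FEATURES)]
        p = predict_percent(fit_bound_ensemble(tr, "mid", hyperparams=(20, 2), seed=1,
                                               feature_names=FEATURES), cells)
        q = predict_percent(fit_bound_ensemble(swapped, "mid", hyperparams=(20, 2), seed=1,
                                               feature_names=FEATURES), cells)
        assert np.abs(p + q - 1.0).mean() < 0.05


class FakeTree:
    def __init__(self, vote):
        self.vote = vote

    def predict(self, X):
        return np.full(len(X), self.vote, dtype=float)


class FakeMember:
    classes_ = np.array([0, 1])

    def __init__(self, votes):
        self.estimators_ = [FakeTree(v) for v in votes]


class TestPredictPercent:
    def toy_ensemble(self, member_votes):
        return BoundEnsemble(
            level="mid", biome_group=None, n_trees=3, n_predictors=2,
            feature_names=FEATURES, members=[FakeMember(v) for v in member_votes],
        )

    def test_vote_fraction_of_toy_forest(self):
        cells = pd.DataFrame({"modis_01": [0.0], "modis_02": [0.0]})
        ens = self.toy_ensemble([[1, 1, 0]])  # planted, planted, natural
        assert predict_percent(ens, cells)[0] == pytest.approx(2 / 3)

    def test_unanimous_and_split_votes(self):
        cells = pd.DataFrame({"modis_01": [0.0], "modis_02": [0.0]})
        assert predict_percent(self.toy_ensemble([[1, 1, 1, 1]]), cells)[0] == 1.0
        assert predict_percent(self.toy_ensemble([[1, 1, 0, 0]]), cells)[0] == 0.5

    def test_equal_member_weighting(self):
        cells = pd.DataFrame({"modis_01": [0.0], "modis_02": [0.0]})
        ens = self.toy_ensemble([[1, 1, 1], [0, 0, 0]])
        assert predict_percent(ens, cells)[0] == pytest.approx(0.5)

    def test_missing_predictor_directs_to_imputation(self):
        cells = pd.DataFrame({"modis_01": [np.nan], "modis_02": [0.0]})
        with pytest.raises(ValueError, match="imputation"):
            predict_percent(self.toy_ensemble([[1, 0, 1]]), cells)


class TestCombineBounds:
    def test_mean_and_inclusive_threshold(self):
        out = combine_bounds([1.0, 0.6, 0.4], [1.0, 0.5, 0.4], [1.0, 0.4, 0.4])
        assert out["p_mean"].tolist() == pytest.approx([1.0, 0.5, 0.4])
        assert out["type"].tolist() == ["planted", "planted", "natural"]

    def test_mean_not_clamped_to_bound_interval(self):
        out = combine_bounds([0.2], [0.9], [0.9])
        assert out["p_mean"][0] == pytest.approx(2.0 / 3.0)
        assert out["p_mean"][0] > out["p_upper"][0]

    def test_threshold_applied_to_each_bound(self):
        out = combine_bounds([0.5], [0.2], [0.49])
        assert out["type_upper"][0] == "planted"
        assert out["type_lower"][0] == "natural"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            combine_bounds([1.2], [0.5], [0.5])


class TestNationalMapOverride:
    def records(self):
        recs = combine_bounds([0.9, 0.2, 0.6], [0.8, 0.3, 0.6], [0.7, 0.1, 0.6])
        recs.index = pd.Index([10, 11, 12], name="cell_id")
        return recs

    def test_masked_cells_take_map_label_and_lose_percents(self):
        recs = self.records()
        mask = pd.Series([True, True, False], index=recs.index)
        labels = pd.Series(["planted", "natural", "planted"], index=recs.index)
        out = override_with_national_maps(recs, mask, labels)
        assert out.loc[10, "type"] == "planted"
        assert out.loc[11, "type"] == "natural"
        assert out.loc[[10, 11], ["p_mean", "p_upper", "p_mid", "p_lower"]].isna().all().all()
        assert (out.loc[[10, 11], "source"] == "national_map").all()
        # unmasked rows untouched
        pd.testing.assert_series_equal(out.loc[12], recs.loc[12])

    def test_masked_cell_without_label_is_natural(self):
        recs = self.records()
        mask = pd.Series([True, False, False], index=recs.index)
        out = override_with_national_maps(recs, mask, pd.Series(dtype=object))
        assert out.loc[10, "type"] == "natural"

    def test_empty_mask_is_identity(self):
        recs = self.records()
        mask = pd.Series(False, index=recs.index)
        out = override_with_national_maps(recs, mask, pd.Series(dtype=object))
        pd.testing.assert_frame_equal(out, recs)

    def test_misaligned_mask_rejected(self):
        recs = self.records()
        with pytest.raises(ValueError, match="misaligned"):
            override_with_national_maps(recs, pd.Series([True], index=[99]), pd.Series(dtype=object))
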