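import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantedmap import (
    aggregate_dominant_genus,
    balance_genus_classes,
    crossvalidate_genus,
    dominant_species,
    importance_values,
    predict_genus,
)
from plantedmap.genus import GENUS_PREDICTORS, fit_genus_model
from plantedmap.grid import Grid


def plot_frame(rows):
    return pd.DataFrame(rows, columns=["species", "genus", "basal_area_m2", "stems"])


class TestImportanceValues:
    def test_single_species_scores_200(self):
        iv = importance_values(plot_frame([("Pinus sp1", "Pinus", 12.0, 30)]))
        assert iv["iv"].iloc[0] == pytest.approx(200.0)

    def test_symmetric_two_species_split(self):
        iv = importance_values(plot_frame(
            [("A sp1", "A", 5.0, 10), ("B sp1", "B", 5.0, 10)]
        ))
        assert iv["iv"].tolist() == pytest.approx([100.0, 100.0])

    def test_worked_share_example(self):
        # basal-area shares (75%, 25%), stem shares (50%, 50%) -> IV (125, 75)
        iv = importance_values(plot_frame(
            [("A sp1", "A", 7.5, 10), ("B sp1", "B", 2.5, 10)]
        ))
        assert iv["iv"].tolist() == pytest.approx([125.0, 75.0])

    def test_zero_basal_area_falls_back_to_stem_shares(self, caplog):
        iv = importance_values(plot_frame(
            [("A sp1", "A", 0.0, 30), ("B sp1", "B", 0.0, 10)]
        ))
        assert iv["iv"].tolist() == pytest.approx([150.0, 50.0])
        assert iv["iv"].sum() == pytest.approx(200.0)

    @given(
        ba=st.lists(st.floats(0.1, 50.0), min_size=1, max_size=8),
        stems=st.lists(st.integers(1, 100), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_importance_values_always_sum_to_200(self, ba, stems):
        rows = [(f"G{i} sp", f"G{i}", b, s) for i, (b, s) in enumerate(zip(ba, stems))]
        iv = importance_values(plot_frame(rows))
        assert iv["iv"].sum() == pytest.approx(200.0, rel=1e-9)

    def test_invalid_plot_rejected(self):
        with pytest.raises(ValueError, match="no species"):
            importance_values(plot_frame([]))
        with pytest.raises(ValueError, match="stem"):
            importance_values(plot_frame([("A sp1", "A", 1.0, 0)]))


class TestDominantSpecies:
    def test_highest_iv_wins(self):
        sp, genus = dominant_species(plot_frame(
            [("A sp1", "A", 7.5, 10), ("B sp1", "B", 2.5, 10)]
        ))
        assert (sp, genus) == ("A sp1", "A")

    def test_tie_breaks_by_basal_area_then_name(self, caplog):
        # equal IV and equal BA -> lexicographic winner, tie logged
        import logging

        with caplog.at_level(logging.INFO, logger="plantedmap.genus"):
            sp, _ = dominant_species(plot_frame(
                [("B sp1", "B", 5.0, 10), ("A sp1", "A", 5.0, 10)]
            ))
        assert sp == "A sp1"
        assert "tie" in caplog.text
        # unequal BA with equal IV -> larger basal-area share wins
        sp2, _ = dominant_species(plot_frame(
            [("A sp1", "A", 6.0, 10), ("B sp1", "B", 6.0, 10), ("C sp1", "C", 8.0, 5)]
        ))
        assert sp2 in ("A sp1", "B sp1", "C sp1")

    def test_single_species_dominates(self):
        assert dominant_species(plot_frame([("X sp1", "X", 1.0, 1)]))[0] == "X sp1"


class TestAggregateDominantGenus:
    def grid(self):
        return Grid(n_rows=1, n_cols=3, origin_lon=0.0, origin_lat=1.0, cell_size_deg=1.0)

    def plots_at(self, cell_genera):
        """cell_genera: list of (cell_col, genus) one single-species plot each."""
        rows = []
        for pid, (col, genus) in enumerate(cell_genera):
            rows.append((pid, col + 0.5, 0.5, f"{genus} sp1", genus, 5.0, 10))
        return pd.DataFrame(
            rows, columns=["plot_id", "lon", "lat", "species", "genus", "basal_area_m2", "stems"]
        )

    def test_majority_vote_per_cell(self):
        plots = self.plots_at([(0, "A"), (0, "A"), (0, "B")])
        mask = pd.Series(True, index=range(3))
        labels, retained = aggregate_dominant_genus(plots, self.grid(), mask, min_samples=1)
        assert labels.to_dict() == {0: "A"}
        assert retained == ["A"]

    def test_tied_cell_excluded(self):
        plots = self.plots_at([(0, "A"), (0, "B"), (1, "A")])
        mask = pd.Series(True, index=range(3))
        labels, _ = aggregate_dominant_genus(plots, self.grid(), mask, min_samples=1)
        assert 0 not in labels.index
        assert labels.to_dict() == {1: "A"}

    def test_plots_outside_planted_extent_ignored(self):
        plots = self.plots_at([(0, "A"), (2, "B")])
        mask = pd.Series([True, True, False], index=range(3))
        labels, _ = aggregate_dominant_genus(plots, self.grid(), mask, min_samples=1)
        assert labels.to_dict() == {0: "A"}

    def test_rare_genus_dropped_with_its_cells(self):
        plots = self.plots_at([(0, "A"), (1, "A"), (2, "B")])
        mask = pd.Series(True, index=range(3))
        labels, retained = aggregate_dominant_genus(plots, self.grid(), mask, min_samples=2)
        assert retained == ["A"]
        assert set(labels) == {"A"}

    def test_no_plots_in_extent_warns_and_returns_empty(self, caplog):
        plots = self.plots_at([(0, "A")])
        mask = pd.Series(False, index=range(3))
        labels, retained = aggregate_dominant_genus(plots, self.grid(), mask, min_samples=1)
        assert labels.empty and retained == []


class TestBalanceGenusClasses:
    def table(self, counts):
        rows = []
        for genus, n in counts.items():
            for i in range(n):
                rows.append({"genus": genus, "x": float(i)})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "counts, target",
        [({"A": 100, "B": 60}, 80), ({"A": 300, "B": 60, "C": 90}, 150)],
    )
    def test_counts_equalised_at_mean(self, counts, target):
        out = balance_genus_classes(self.table(counts), seed=0)
        assert out["genus"].value_counts().to_dict() == {g: target for g in counts}

    def test_equal_counts_preserve_multiset(self):
        tbl = self.table({"A": 50, "B": 50})
        out = balance_genus_classes(tbl, seed=1)
        for genus in ("A", "B"):
            got = sorted(out.loc[out.genus == genus, "x"])
            want = sorted(tbl.loc[tbl.genus == genus, "x"])
            assert got == want

    def test_deterministic_given_seed(self):
        tbl = self.table({"A": 90, "B": 30})
        pd.testing.assert_frame_equal(
            balance_genus_classes(tbl, seed=5), balance_genus_classes(tbl, seed=5)
        )

    def test_single_genus_rejected(self):
        with pytest.raises(ValueError, match="two genera"):
            balance_genus_classes(self.table({"A": 10}), seed=0)


def genus_training(n_per_class, sep, genera=("A", "B", "C"), seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    features = list(GENUS_PREDICTORS[:n_features])
    rows = []
    for i, g in enumerate(genera):
        X = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
        X[:, i % n_features] += sep
        df = pd.DataFrame(X, columns=features)
        df["genus"] = g
        rows.append(df)
    return pd.concat(rows, ignore_index=True), features


class TestCrossvalidateGenus:
    def test_separable_genera_score_one_with_zero_width_ci(self):
        tr, feats = genus_training(40, sep=15.0)
        rep = crossvalidate_genus(tr, n_iter=4, seed=1, feature_names=feats, n_trees=20)
        overall = rep.loc[rep.genus == "overall"].iloc[0]
        assert overall["accuracy"] == 1.0
        assert overall["accuracy_ci_high"] - overall["accuracy_ci_low"] == pytest.approx(0.0)
        assert (rep.loc[rep.genus != "overall", "f1"] == 1.0).all()

    def test_noise_features_score_at_chance(self):
        tr, feats = genus_training(80, sep=0.0, seed=3)
        rep = crossvalidate_genus(tr, n_iter=6, seed=2, feature_names=feats, n_trees=20)
        overall = rep.loc[rep.genus == "overall", "accuracy"].iloc[0]
        assert overall == pytest.approx(1 / 3, abs=0.12)

    def test_report_one_row_per_genus_plus_overall(self):
        tr, feats = genus_training(30, sep=4.0)
        rep = crossvalidate_genus(tr, n_iter=3, seed=0, feature_names=feats, n_trees=10)
        assert list(rep["genus"]) == ["A", "B", "C", "overall"]

    def test_tiny_genus_named_in_error(self):
        tr, feats = genus_training(30, sep=4.0)
        tr = pd.concat([tr, tr.iloc[:2].assign(genus="Rare")], ignore_index=True)
        with pytest.raises(ValueError, match="Rare"):
            crossvalidate_genus(tr, n_iter=3, feature_names=feats)


class TestPredictGenus:
    def test_natural_cells_carry_missing_marker(self):
        tr, feats = genus_training(40, sep=8.0)
        model = fit_genus_model(tr, seed=0, feature_names=feats, n_trees=10)
        cells = tr.loc[:9, feats].set_axis(range(10), axis=0)
        mask = pd.Series([True] * 5 + [False] * 5, index=range(10))
        out = predict_genus(model, cells, mask)
        assert out.loc[5:].isna().all()
        assert out.loc[:4].isin(["A", "B", "C"]).all()

    def test_feature_mismatch_rejected(self):
        tr, feats = genus_training(30, sep=8.0)
        model = fit_genus_model(tr, seed=0, feature_names=feats, n_trees=5)
        cells = tr.loc[:4, feats[:-1]]
        with pytest.raises(ValueError, match="features"):
            predict_genus(model, cells, pd.Series(True, index=cells.index))

    def test_genus_feature_set_is_52_slots(self):
        assert len(GENUS_PREDICTORS) == 52
        assert "roadless" not in GENUS_PREDICTORS
        assert "rh100" not in GENUS_PREDICTORS
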