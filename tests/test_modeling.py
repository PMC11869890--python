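import numpy as np
import pandas as pd
import pytest

from pathsyn.labeling import SynergyLabel
from pathsyn.modeling import (
    SMOTE_MARKER,
    TrainConfig,
    assemble_features,
    cross_validate,
    enumerate_block_subsets,
    evaluate,
    feature_importance_by_block,
    feature_set_search,
    grid_search,
    make_model,
    rebalance,
    split_and_scale,
    top_k_refit,
    unlabeled_keys,
    _fit_eval,
)
from pathsyn.pathway_bridge import all_pairs

TINY_XGB = {"learning_rate": 0.3, "max_depth": 3, "n_estimators": 25}


def toy_blocks_and_labels(rng, n_drugs=7, n_cells=5, signal_block="DDP"):
    """Random pair/cell blocks with the label planted in one block."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    cells = [f"c{j}" for j in range(n_cells)]
    pairs = all_pairs(drugs)
    pair_index = pd.MultiIndex.from_tuples(pairs, names=["drug_a", "drug_b"])
    blocks = {
        "DD_MACCS": pd.DataFrame(
            rng.integers(0, 3, (len(pairs), 6)), index=pair_index,
            columns=[f"m{k}" for k in range(6)],
        ),
        "DDP": pd.DataFrame(
            rng.normal(size=(len(pairs), 4)), index=pair_index,
            columns=[f"p{k}" for k in range(4)],
        ),
        "EXP": pd.DataFrame(
            rng.normal(size=(n_cells, 3)), index=cells,
            columns=[f"e{k}" for k in range(3)],
        ),
    }
    labels = []
    for a, b in pairs:
        for c in cells:
            strength = float(blocks[signal_block].loc[(a, b)].iloc[0])
            score = strength + 0.3 * rng.normal()
            labels.append(
                SynergyLabel(a, b, c, comb_score=score, threshold=0.8,
                             label=int(score > 0.8))
            )
    return blocks, labels


class TestAssemble:
    def test_canonical_order_and_width(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        assert table.width == 6 + 4 + 3
        assert list(table.block_columns) == ["DD_MACCS", "DDP", "EXP"]
        assert table.X.columns[0].startswith("DD_MACCS|")
        assert len(table.X) == len(labels)
        assert table.y.tolist() == [lab.label for lab in labels]

    def test_selection_subsets_width(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels, block_selection=["DDP"])
        assert table.width == 4

    def test_missing_instance_named(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        blocks["EXP"] = blocks["EXP"].drop("c0")
        with pytest.raises(KeyError, match="c0"):
            assemble_features(blocks, labels)


class TestSplitAndScale:
    def test_sizes_scaling_and_determinism(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        train, test, _ = split_and_scale(table, test_fraction=0.2, seed=3)
        assert len(test.X) == round(0.2 * len(table.X))
        means = train.X.mean(axis=0).to_numpy()
        sds = train.X.std(axis=0, ddof=0).to_numpy()
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.allclose(sds[sds > 0], 1.0, atol=1e-9)
        train2, test2, _ = split_and_scale(table, test_fraction=0.2, seed=3)
        pd.testing.assert_frame_equal(train.X, train2.X)
        pd.testing.assert_frame_equal(test.X, test2.X)

    def test_test_partition_uses_train_statistics(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        train, test, scaler = split_and_scale(table, seed=0)
        raw = table.X.loc[test.X.index].to_numpy()
        assert np.allclose(scaler.transform(raw), test.X.to_numpy())


class TestRebalance:
    def _table(self, rng, n_neg, n_pos, width=5):
        X = pd.DataFrame(
            rng.normal(size=(n_neg + n_pos, width)),
            index=pd.MultiIndex.from_tuples(
                [(f"a{i}", f"b{i}", "c") for i in range(n_neg + n_pos)],
                names=["drug_a", "drug_b", "cell_line"],
            ),
        )
        y = pd.Series([0] * n_neg + [1] * n_pos, index=X.index)
        return X, y

    def test_weights_ratio(self, rng):
        X, y = self._table(rng, 40, 10)
        _, _, w = rebalance(X, y, "weights")
        assert w[y.to_numpy() == 1][0] == pytest.approx(4.0)
        assert w[y.to_numpy() == 0][0] == 1.0

    def test_undersample_counts(self, rng):
        X, y = self._table(rng, 100, 30)
        Xr, yr, w = rebalance(X, y, "undersample", ratio=2.0, seed=1)
        assert w is None
        assert int((yr == 0).sum()) == 60
        assert int((yr == 1).sum()) == 30

    def test_oversample_counts_and_provenance(self, rng):
        X, y = self._table(rng, 40, 10)
        Xr, yr, _ = rebalance(X, y, "oversample", ratio=2.0, k_smote=3, seed=1)
        assert int((yr == 1).sum()) == 20
        synth = [k for k in Xr.index if k[0] == SMOTE_MARKER]
        assert len(synth) == 10
        # synthetic points interpolate minority rows: parents recorded in key
        parents = {p for k in synth for p in k[1].split("+")}
        minority = {"/".join(k) for k in X.index[y == 1]}
        assert parents <= minority

    def test_oversample_needs_enough_minority(self, rng):
        X, y = self._table(rng, 40, 4)
        with pytest.raises(ValueError, match="SMOTE"):
            rebalance(X, y, "oversample", k_smote=5)

    @pytest.mark.parametrize("strategy", ["undersample", "oversample"])
    def test_exact_ratio_within_one(self, rng, strategy):
        X, y = self._table(rng, 83, 17)
        Xr, yr, _ = rebalance(X, y, strategy, ratio=2.0, seed=0)
        n_neg, n_pos = int((yr == 0).sum()), int((yr == 1).sum())
        assert abs(n_neg - 2.0 * n_pos) <= 1


class TestEvaluate:
    def test_perfect_ranking(self):
        m = evaluate([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert m.auc == 1.0 and m.aupr == 1.0
        assert m.acc == 1.0 and m.f1 == 1.0

    def test_all_wrong_threshold_calls(self):
        m = evaluate([1, 0], [0.4, 0.6])
        assert m.recall == 0.0 and m.f1 == 0.0 and m.prec == 0.0
        assert m.auc == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            evaluate([1, 1], [0.2, 0.9])

    def test_scores_outside_unit_interval(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1.2, 0.4])


class TestCrossValidate:
    def test_fold_count_and_mean(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        config = TrainConfig(params=TINY_XGB, folds=4, seed=0)
        report = cross_validate(table.X, table.y, config)
        assert len(report.per_fold) == 4
        assert report.mean.aupr == pytest.approx(
            np.mean([m.aupr for m in report.per_fold])
        )

    def test_too_few_positives_for_folds(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        y = pd.Series([1] * 3 + [0] * 17)
        with pytest.raises(ValueError):
            cross_validate(X, y, TrainConfig(params=TINY_XGB, folds=5))


class TestGridSearch:
    def test_singleton_grid(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        config = TrainConfig(
            params=TINY_XGB, folds=3, grid={"max_depth": [2]}, seed=0
        )
        best, results = grid_search(table.X, table.y, config)
        assert best == {"max_depth": 2}
        assert len(results) == 1

    def test_dominant_point_selected_and_deterministic(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        config = TrainConfig(
            params=TINY_XGB,
            folds=3,
            grid={"n_estimators": [1, 40]},
            seed=0,
        )
        best1, res1 = grid_search(table.X, table.y, config)
        best2, _ = grid_search(table.X, table.y, config)
        assert best1 == best2
        # the deeper ensemble dominates a single stump round on planted signal
        assert best1["n_estimators"] == 40
        assert res1["mean_cv_aupr"].idxmax() == 1


class TestFeatureSetSearch:
    def test_subset_enumeration_counts(self):
        assert len(enumerate_block_subsets(["DD_MACCS", "DDP", "EXP"])) == 7
        eight = ["DD_MACCS", "DD_TOX", "DDP", "EXP", "CNV", "METHY", "MUT", "RNAi"]
        assert len(enumerate_block_subsets(eight)) == 255

    def test_search_rows_and_winner_contains_signal_block(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        config = TrainConfig(params=TINY_XGB, seed=0)
        results = feature_set_search(blocks, labels, config)
        assert len(results) == 7
        assert set(results.columns) >= {"blocks", "AUPR", "average_rank"}
        assert "DDP" in results.iloc[0]["blocks"]
        assert results["average_rank"].iloc[0] == results["average_rank"].min()


class TestImportanceAndTopK:
    def _fitted(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels)
        train, test, _ = split_and_scale(table, seed=0)
        config = TrainConfig(params=TINY_XGB, seed=0)
        _, model = _fit_eval(train, test, config)
        return model, train, test, config

    def test_proportions_sum_to_one(self, rng):
        model, train, _, _ = self._fitted(rng)
        proportions, per_feature = feature_importance_by_block(model, train)
        assert proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(per_feature["block"]) <= {"DD_MACCS", "DDP", "EXP"}
        within = per_feature[per_feature["block"] == "DDP"]
        assert within["importance"].is_monotonic_decreasing

    def test_single_block_proportion_is_one(self, rng):
        blocks, labels = toy_blocks_and_labels(rng)
        table = assemble_features(blocks, labels, block_selection=["DDP"])
        train, test, _ = split_and_scale(table, seed=0)
        config = TrainConfig(params=TINY_XGB, seed=0)
        _, model = _fit_eval(train, test, config)
        proportions, _ = feature_importance_by_block(model, train)
        assert proportions.tolist() == pytest.approx([1.0])

    def test_non_tree_model_unsupported(self, rng):
        model = make_model("logistic")
        _, train, _, _ = self._fitted(rng)
        model.fit(train.X.to_numpy(), train.y.to_numpy())
        with pytest.raises(TypeError):
            feature_importance_by_block(model, train)

    def test_top_k_refit_rows_and_capping(self, rng):
        model, train, test, config = self._fitted(rng)
        _, per_feature = feature_importance_by_block(model, train)
        with pytest.warns(UserWarning, match="capped"):
            trend = top_k_refit(train, test, per_feature, config, ks=(1, 2, 10))
        assert trend["k"].tolist() == [1, 2, 10]
        assert trend["width"].tolist() == [3, 6, 13]


class TestUnlabeledPartition:
    def test_toy_partition(self):
        keys = unlabeled_keys(
            ["d1", "d2", "d3"],
            ["c1", "c2"],
            [("d1", "d2", "c1"), ("d1", "d3", "c1"), ("d2", "d3", "c1"), ("d1", "d2", "c2")],
        )
        assert keys == [("d1", "d3", "c2"), ("d2", "d3", "c2")]

    def test_partition_property(self, rng):
        drugs = [f"d{i}" for i in range(5)]
        cells = [f"c{j}" for j in range(3)]
        grid = [(a, b, c) for a, b in all_pairs(drugs) for c in cells]
        labeled = [grid[i] for i in rng.choice(len(grid), size=10, replace=False)]
        unlabeled = unlabeled_keys(drugs, cells, labeled)
        assert len(unlabeled) == len(grid) - 10
        assert set(unlabeled) | set(labeled) == set(grid)
        assert not set(unlabeled) & set(labeled)
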