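"""Labeling rule, forest training/calibration, LOMO metrics and baselines."""

import numpy as np
import pandas as pd
import pytest

import odehybrid as oh
from odehybrid.classifier import (build_training_table, evaluate_lomo,
                                  fold_metrics, heuristic_baseline,
                                  label_by_rule, threshold_sensitivity,
                                  train_partition_model)
from odehybrid.presim import FEATURE_NAMES
from odehybrid.trajectory import Trajectory
from odehybrid.zoo import Corpus, CorpusSpec


def _toy_table(n_models=6, n_species=5, seed=0):
    """Synthetic feature table whose labels follow the quantile rule and are
    determined by q99 alone (single-feature threshold, learnable exactly)."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_models):
        for s in range(n_species):
            low = (s % 2 == 0)
            q99 = rng.uniform(5.0, 100.0) if low else rng.uniform(1000.0, 5000.0)
            feats = {name: 0.0 for name in FEATURE_NAMES}
            feats.update({
                "mean": q99 * 0.8, "q50": q99 * 0.8, "q80": q99 * 0.9,
                "q99": q99, "max": q99, "range": q99,
            })
            rows.append({"model_id": f"toy{m}", "species": f"s{s}", **feats,
                         "label": int(q99 * 0.9 < 200.0 and q99 < 200.0)})
    return pd.DataFrame(rows)


class TestLabelByRule:
    @pytest.mark.parametrize(
        "q80,q99,expected",
        [(80.0, 99.0, 1),      # both quantiles below threshold
         (150.0, 250.0, 0),    # second conjunct fails
         (200.0, 150.0, 0),    # strict inequality at the boundary
         (199.999, 199.999, 1)],
    )
    def test_rule_cases(self, q80, q99, expected):
        row = pd.Series({"q80": q80, "q99": q99})
        assert label_by_rule(row, 200.0) == expected

    def test_vectorized_over_table(self, corpus_table):
        lab = label_by_rule(corpus_table)
        manual = ((corpus_table["q80"] < 200) & (corpus_table["q99"] < 200)).astype(int)
        assert (lab == manual).all()


class TestBuildTrainingTable:
    def test_benchmark_species_labels(self, benchmark_model):
        corpus = Corpus(models=[benchmark_model],
                        metadata=[{"model_id": "benchmark", "family": "benchmark",
                                   "seed_offset": 0, "n_species": 2, "params": {}}],
                        spec=CorpusSpec(n_models=1))
        table = build_training_table(corpus)
        by = table.set_index("species")["label"]
        assert by["M"] == 1    # quantiles ~5 << 200
        assert by["P"] == 0    # q80 ~ 2500 >= 200

    def test_empty_corpus_gives_empty_table(self):
        table = build_training_table(Corpus(models=[], metadata=[],
                                            spec=CorpusSpec(n_models=1)))
        assert len(table) == 0
        assert "label" in table.columns

    def test_one_row_per_species_with_model_ids(self, default_corpus, corpus_table):
        assert len(corpus_table) == default_corpus.total_species
        assert corpus_table["model_id"].nunique() == default_corpus.n_models


class TestFoldMetrics:
    def test_perfect_fold(self):
        m = fold_metrics([0, 0, 1, 1], [0, 0, 1, 1])
        assert m["balanced_accuracy"] == 1.0
        assert m["mcc"] == 1.0

    def test_hand_computed_confusion(self):
        # TP=3, FN=2, TN=4, FP=1: BA = (3/5 + 4/5)/2, MCC = 10/sqrt(600)
        y_true = [1] * 5 + [0] * 5
        y_pred = [1, 1, 1, 0, 0] + [0, 0, 0, 0, 1]
        m = fold_metrics(y_true, y_pred)
        assert m["balanced_accuracy"] == pytest.approx(0.7)
        assert m["mcc"] == pytest.approx(10.0 / np.sqrt(600.0))

    def test_all_wrong_fold(self):
        m = fold_metrics([0, 1], [1, 0])
        assert m["balanced_accuracy"] == 0.0
        assert m["mcc"] == -1.0

    def test_single_class_truth_flagged_and_mcc_undefined(self):
        m = fold_metrics([1, 1, 1], [1, 1, 0])
        assert m["single_class_truth"]
        assert np.isnan(m["mcc"])
        assert m["balanced_accuracy"] == pytest.approx(2.0 / 3.0)


class TestTrainPartitionModel:
    def test_separable_toy_is_learned_exactly(self):
        table = _toy_table()
        report = evaluate_lomo(table, n_trees=100, seed=1, calibration_n_trees=50)
        assert report.mean_balanced_accuracy == 1.0
        pm = train_partition_model(table, n_trees=100, seed=1)
        prob = pm.predict_proba(table)
        lab = table["label"].to_numpy()
        assert np.all(prob[lab == 1] >= 0.9)   # calibrator pushed to extremes
        assert np.all(prob[lab == 0] <= 0.1)

    def test_seeded_determinism(self):
        table = _toy_table()
        p1 = train_partition_model(table, n_trees=50, seed=3).predict_proba(table)
        p2 = train_partition_model(table, n_trees=50, seed=3).predict_proba(table)
        np.testing.assert_array_equal(p1, p2)

    def test_decision_threshold_is_half(self, partition_model):
        assert partition_model.decision_threshold == 0.5

    def test_single_class_table_rejected(self):
        table = _toy_table()
        table["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            train_partition_model(table, n_trees=10, seed=0)

    def test_calibrator_is_monotone(self, partition_model):
        grid = np.linspace(0.0, 1.0, 501)
        cal = partition_model.calibrator.predict(grid)
        assert np.all(np.diff(cal) >= -1e-12)
        assert np.all((cal >= 0.0) & (cal <= 1.0))

    def test_feature_name_mismatch_rejected(self, partition_model):
        with pytest.raises(ValueError, match="missing"):
            partition_model.predict_proba(pd.DataFrame({"q99": [1.0]}))


class TestPredictPartition:
    def test_benchmark_partition(self, benchmark_model, partition_model):
        part = oh.predict_partition(benchmark_model, partition_model)
        assert part.loc["M", "label"] == 1
        assert part.loc["P", "label"] == 0
        assert ((part["probability"] >= 0.0) & (part["probability"] <= 1.0)).all()

    def test_mrna_more_stochastic_than_proteins(self, partition_model):
        """With the protein tier amplified above the rule threshold and the
        mRNA tier below it, mRNAs must receive the higher stochastic
        probability."""
        rep = oh.make_repressilator(protein_scale=50.0)
        part = oh.predict_partition(rep, partition_model)
        p_mrna = part.loc[["m1", "m2", "m3"], "probability"].min()
        p_prot = part.loc[["p1", "p2", "p3"], "probability"].max()
        assert p_mrna > p_prot


class TestThresholdSensitivity:
    def test_baseline_against_itself_is_zero(self, corpus_table):
        sens = threshold_sensitivity(corpus_table, [200.0])
        assert sens["flip_fraction"].iloc[0] == 0.0

    def test_single_boundary_species_flips_at_300(self):
        feats = {name: 0.0 for name in FEATURE_NAMES}
        rows = []
        for i in range(40):
            q = 250.0 if i == 0 else (50.0 if i % 2 else 5000.0)
            rows.append({"model_id": f"m{i}", "species": "s",
                         **{**feats, "q80": q, "q99": q},
                         "label": int(q < 200)})
        table = pd.DataFrame(rows)
        sens = threshold_sensitivity(table, [150.0, 300.0])
        by = sens.set_index("threshold")["flip_fraction"]
        assert by[300.0] == pytest.approx(1.0 / 40.0)
        assert by[150.0] == 0.0

    def test_relabeling_is_monotone_in_threshold(self, corpus_table):
        """Raising the threshold can only move labels 0 -> 1, never 1 -> 0."""
        prev = label_by_rule(corpus_table, 150.0).to_numpy()
        for tau in (175.0, 200.0, 250.0, 300.0, 1000.0):
            cur = label_by_rule(corpus_table, tau).to_numpy()
            assert np.all(cur >= prev)
            prev = cur


class TestHeuristicBaseline:
    def test_burst_series_splits_rule_and_mean_heuristic(self):
        """A transient spike: trajectory mean below 200 but q99 far above, so
        the quantile rule says deterministic while the mean heuristic says
        stochastic."""
        y = np.full(500, 20.0)
        y[:10] = 5000.0
        traj = Trajectory(times=np.arange(500.0), states=y[:, None],
                          species_names=["s"])
        f = oh.extract_features(traj).loc["s"]
        assert f["mean"] < 200.0 < f["q99"]
        assert label_by_rule(f) == 0
        assert int(f["mean"] < 200.0) == 1  # the mean heuristic disagrees

    def test_constant_features_score_half_on_balanced_fold(self):
        feats = {name: 1.0 for name in FEATURE_NAMES}
        rows = [{"model_id": "m0", "species": f"s{i}", **feats, "label": i % 2}
                for i in range(10)]
        rep = heuristic_baseline(pd.DataFrame(rows), "mean")
        assert rep.mean_balanced_accuracy == pytest.approx(0.5)

    def test_invalid_statistic_rejected(self, corpus_table):
        with pytest.raises(ValueError):
            heuristic_baseline(corpus_table, "mode")
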