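"""Training protocol: splits, bag sampling, optimization, experiment design."""

import numpy as np
import pytest
from scipy import stats

from slidemil.mil import AttentionMILModel, MILModelConfig
from slidemil.synthetic import FeatureBagSpec, generate_feature_bags
from slidemil.train import (
    TABLE_BAG_BATCH, SearchSpace, SlideBagDataset, TrainConfig, ablation,
    cross_validate, evaluate, hyperparameter_search, repeated_training,
    resolution_sweep, sample_bag_indices, sampling_coverage, split_train_test,
    train,
)


def feature_dataset(n_bags=60, bag_size=16, dim=16, separation=3.0, seed=0,
                    witness_rate=0.3):
    spec = FeatureBagSpec(n_bags=n_bags, bag_size=bag_size, feature_dim=dim,
                          witness_rate=witness_rate,
                          class_separation=separation, seed=seed)
    return SlideBagDataset.from_feature_bags(generate_feature_bags(spec))


def small_model(dim=16, pooling="attention", seed=0):
    return AttentionMILModel(
        MILModelConfig(encoder_name="identity", feature_dim=dim,
                       attention_hidden=8, classifier_hidden=16,
                       pooling=pooling), seed=seed)


def quick_config(**kw):
    base = dict(learning_rate=1e-3, epochs=5, level=3, bag_size=16,
                batch_size=8, seed=0)
    base.update(kw)
    return TrainConfig(**base)


MODEL_CONFIG = MILModelConfig(encoder_name="identity", feature_dim=16,
                              attention_hidden=8, classifier_hidden=16)


class TestConfig:
    @pytest.mark.parametrize("level,bag,batch", [(0, 256, 4), (1, 64, 12),
                                                 (2, 64, 12), (3, 32, 24)])
    def test_per_level_defaults(self, level, bag, batch):
        config = TrainConfig(level=level)
        assert (config.bag_size, config.batch_size) == (bag, batch)
        assert TABLE_BAG_BATCH[level] == (bag, batch)

    def test_protocol_defaults(self):
        config = TrainConfig()
        assert config.learning_rate == 1e-4
        assert config.epochs == 60


class TestSplit:
    def test_ninety_ten_split(self):
        labels = [1] * 82 + [0] * 18
        tr, te = split_train_test(labels, seed=0)
        assert len(tr) == 90 and len(te) == 10

    def test_deterministic(self):
        labels = [1] * 50 + [0] * 50
        a = split_train_test(labels, seed=3)
        b = split_train_test(labels, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_stratified_small_test_keeps_both_classes(self):
        labels = np.array([1] * 82 + [0] * 18)
        for seed in range(10):
            _, te = split_train_test(labels, seed=seed)
            assert {0, 1} <= set(labels[te])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([1] * 10)


class TestBagSampling:
    def test_without_replacement_when_enough(self, rng):
        idx = sample_bag_indices(300, 64, rng)
        assert len(idx) == 64 and len(set(idx)) == 64

    def test_cycling_counts_differ_by_at_most_one(self, rng):
        idx = sample_bag_indices(10, 32, rng)
        counts = np.bincount(idx, minlength=10)
        assert counts.min() >= 3 and counts.max() - counts.min() <= 1
        # every tile is used before any fourth reuse
        assert set(idx[:10]) == set(range(10))

    def test_deterministic_per_stream(self):
        a = sample_bag_indices(20, 8, np.random.default_rng(1))
        b = sample_bag_indices(20, 8, np.random.default_rng(1))
        assert np.array_equal(a, b)

    def test_zero_tiles_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_bag_indices(0, 4, rng)


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        dataset = feature_dataset(n_bags=12)
        model = small_model()
        before = [p.copy() for p, _ in model.params_and_grads]
        train(model, dataset, quick_config(learning_rate=0.0, epochs=2))
        for (p, _), b in zip(model.params_and_grads, before):
            assert np.array_equal(p, b)

    def test_bit_reproducible_given_seed(self):
        dataset = feature_dataset(n_bags=20)
        histories = []
        scores_list = []
        for _ in range(2):
            model = small_model(seed=4)
            h = train(model, dataset, quick_config(seed=4, epochs=3))
            s, _ = evaluate(model, dataset)
            histories.append(h["train_loss"])
            scores_list.append(s)
        assert histories[0] == histories[1]
        assert np.array_equal(scores_list[0], scores_list[1])

    def test_separable_bags_reach_high_auroc_within_20_epochs(self):
        dataset = feature_dataset(n_bags=150, bag_size=32, dim=32,
                                  separation=3.0, seed=1)
        tr, va = split_train_test(dataset.labels, test_fraction=0.2, seed=1)
        model = AttentionMILModel(
            MILModelConfig(encoder_name="identity", feature_dim=32,
                           attention_hidden=32, classifier_hidden=128), seed=1)
        history = train(model, dataset.subset(tr),
                        quick_config(epochs=20, bag_size=32, seed=1),
                        val_set=dataset.subset(va))
        assert history["val_metrics"][-1].auroc >= 0.95

    def test_validation_history_recorded(self):
        dataset = feature_dataset(n_bags=16)
        model = small_model()
        history = train(model, dataset, quick_config(epochs=3),
                        val_set=dataset)
        assert len(history["train_loss"]) == 3
        assert len(history["val_loss"]) == 3


class TestCrossValidate:
    def test_every_bag_validated_exactly_once(self):
        dataset = feature_dataset(n_bags=50)
        reports, summary = cross_validate(
            dataset, quick_config(epochs=1), MODEL_CONFIG, k=5)
        assert len(reports) == 5
        assert set(summary) >= {"mcc", "auroc", "bce_loss"}
        assert summary["bce_loss"]["sd"] >= 0

    def test_k_larger_than_class_rejected(self):
        dataset = feature_dataset(n_bags=8)
        with pytest.raises(ValueError):
            cross_validate(dataset, quick_config(), MODEL_CONFIG, k=6)


class TestRepeatedTraining:
    def test_ci_halfwidth_formula(self):
        dataset = feature_dataset(n_bags=24)
        runs, out = repeated_training(dataset, dataset,
                                      quick_config(epochs=1), MODEL_CONFIG,
                                      n_runs=3)
        vals = np.array([r.auroc for r in runs])
        expected = 1.96 * np.std(vals, ddof=1) / np.sqrt(3)
        assert out["auroc"]["ci95_halfwidth"] == pytest.approx(expected)
        assert set(out) == {"bce_loss", "precision_macro", "recall_macro",
                            "f1_macro", "auroc", "mcc"}

    def test_requires_at_least_two_runs(self):
        dataset = feature_dataset(n_bags=12)
        with pytest.raises(ValueError):
            repeated_training(dataset, dataset, quick_config(), MODEL_CONFIG,
                              n_runs=1)


class TestSearch:
    def test_learning_rates_log_uniform_within_bounds(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        draws = [space.sample(rng, 16)[0].learning_rate for _ in range(500)]
        assert min(draws) >= 1e-5 and max(draws) <= 1e-1
        u = (np.log10(draws) + 5) / 4  # map log10 lr to [0, 1]
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_budget_one_returns_single_config(self):
        dataset = feature_dataset(n_bags=20)
        results = hyperparameter_search(SearchSpace(bag_sizes=(16,)), 1,
                                        dataset, 16, k=2, seed=0,
                                        epochs_cap=1)
        assert len(results) == 1

    def test_ties_prefer_fewer_parameters(self, monkeypatch):
        import importlib
        train_mod = importlib.import_module("slidemil.train")
        calls = iter([0.5, 0.5, 0.9])
        monkeypatch.setattr(
            train_mod, "cross_validate",
            lambda *a, **k: ([], {"bce_loss": {"mean": next(calls)}}))
        dataset = feature_dataset(n_bags=12)
        results = train_mod.hyperparameter_search(SearchSpace(), 3, dataset,
                                                  16, k=2, seed=1)
        assert results[0]["val_loss"] == results[1]["val_loss"] == 0.5
        assert results[0]["n_params"] <= results[1]["n_params"]
        assert results[2]["val_loss"] == 0.9

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search(SearchSpace(), 0, feature_dataset(12), 16)


class TestSweepAndAblation:
    def test_single_level_sweep_has_one_row(self):
        dataset = feature_dataset(n_bags=30)
        table = resolution_sweep({1: dataset}, quick_config(epochs=1),
                                 MODEL_CONFIG, k=2)
        assert list(table) == [1]
        assert "mcc" in table[1]

    def test_ablation_arms_share_data_and_report_all_poolings(self):
        dataset = feature_dataset(n_bags=30, seed=2)
        tr, te = split_train_test(dataset.labels, test_fraction=0.3, seed=2)
        reports = ablation(dataset.subset(tr), dataset.subset(te),
                           quick_config(epochs=2), MODEL_CONFIG)
        assert set(reports) == {"attention", "mean", "max"}
        for rep in reports.values():
            assert np.isfinite(rep.bce_loss)


class TestCoverage:
    def test_native_coverage_arithmetic(self):
        assert sampling_coverage(100, 1e5) == pytest.approx(1e-3)

    def test_full_coverage_caps_at_one(self):
        assert sampling_coverage(64, 30) == 1.0

    def test_invalid_tile_count_rejected(self):
        with pytest.raises(ValueError):
            sampling_coverage(10, 0)
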