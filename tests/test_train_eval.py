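"""End-to-end training, prediction, metrics, and the experiment drivers."""

import numpy as np
import pytest

from trustomics import (MultiOmicsDataset, RunConfig, SyntheticSpec,
                        ablation_run, compute_metrics, cross_validate,
                        feature_importance, generate, noise_experiment,
                        predict, train_model)
from trustomics.evidential import one_hot, opinion_t
from trustomics.hgcn import forward_t
from trustomics.train_eval import (_fused_alpha_t, _predict_from_evidence,
                                   cv_splits)
from trustomics import evidential, hgcn
from trustomics.autodiff import Tensor
from trustomics.hypergraph import build_hypergraph


def _train_test(dataset, fraction=0.2, seed=0):
    from sklearn.model_selection import train_test_split
    idx = np.arange(dataset.n_samples)
    tr, te = train_test_split(idx, test_size=fraction,
                              stratify=dataset.labels, random_state=seed)
    return np.sort(tr), np.sort(te)


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1],
                            np.array([[0.9, .1], [.1, .9], [.8, .2], [.2, .8]]))
        assert m["ACC"] == 1.0 and m["F1"] == 1.0 and m["AUC"] == 1.0

    def test_perfect_ranking_auc(self):
        m = compute_metrics([0, 0, 1, 1], [0, 0, 1, 1],
                            np.array([0.1, 0.2, 0.8, 0.9]))
        assert m["AUC"] == 1.0

    def test_all_wrong(self):
        assert compute_metrics([0, 1], [1, 0])["ACC"] == 0.0

    def test_multiclass_metric_names(self):
        m = compute_metrics([0, 1, 2], [0, 1, 2])
        assert set(m) == {"ACC", "F1_weighted", "F1_macro"}


class TestTraining:
    def test_loss_trace_finite_and_decreasing_overall(self, tiny_dataset,
                                                      fast_config):
        dataset, _ = tiny_dataset
        tr, _ = _train_test(dataset)
        model = train_model(dataset, tr, fast_config)
        trace = np.array(model.loss_trace)
        assert np.isfinite(trace).all()
        assert trace[-1] < trace[0]

    def test_same_seed_identical_parameters(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        tr, _ = _train_test(dataset)
        m1 = train_model(dataset, tr, fast_config)
        m2 = train_model(dataset, tr, fast_config)
        for p1, p2 in zip(m1.params, m2.params):
            for a, b in zip(p1.all(), p2.all()):
                np.testing.assert_array_equal(a.data, b.data)

    def test_missing_class_in_training_split_raises(self, tiny_dataset,
                                                    fast_config):
        dataset, _ = tiny_dataset
        only_two = np.flatnonzero(dataset.labels != 2)
        with pytest.raises(ValueError, match=r"classes \[2\]"):
            train_model(dataset, only_two, fast_config)

    def test_separable_data_reaches_high_training_accuracy(self):
        dataset, _ = generate(SyntheticSpec(seed=17))  # generator defaults
        tr = np.arange(dataset.n_samples)
        model = train_model(dataset, tr,
                            RunConfig(epochs=150, seed=5))
        result = predict(model, dataset)
        assert (result.y_pred == dataset.labels).mean() >= 0.99


class TestPrediction:
    def test_vacuous_evidence_predicts_class_zero_with_full_uncertainty(self):
        evidence = [np.zeros((4, 3)), np.zeros((4, 3))]
        result = _predict_from_evidence(evidence, RunConfig(), 3)
        assert (result.y_pred == 0).all()
        np.testing.assert_allclose(result.uncertainty, 1.0)

    def test_predictions_in_class_range(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        tr, te = _train_test(dataset)
        model = train_model(dataset, tr, fast_config)
        result = predict(model, dataset, te)
        assert set(result.y_pred) <= set(range(dataset.n_classes))
        assert result.confidence.shape == (len(te), dataset.n_classes)
        assert ((result.uncertainty > 0) & (result.uncertainty <= 1)).all()

    def test_separable_test_accuracy(self, tiny_dataset):
        dataset, _ = tiny_dataset
        tr, te = _train_test(dataset)
        model = train_model(dataset, tr,
                            RunConfig(epochs=100, k_neighbors=6,
                                      learning_rate=5e-3, seed=2))
        result = predict(model, dataset, te)
        assert (result.y_pred == dataset.labels[te]).mean() >= 0.9


class TestGradientFlow:
    def test_backprop_matches_finite_differences_through_full_loss(self):
        """Finite-difference check of the complete training objective
        (convolutions, evidence head, DS fusion, annealed losses)."""
        rng = np.random.default_rng(0)
        n, b = 8, 2
        labels = np.array([0, 1] * 4)
        y = one_hot(labels, b)
        mask = np.ones(n, dtype=bool)
        Xs = [rng.normal(size=(n, 5)), rng.normal(size=(n, 4))]
        Ls = [build_hypergraph(X, 3).laplacian for X in Xs]
        specs = [hgcn.HGCNSpec(input_dim=X.shape[1], n_classes=b,
                               hidden_dims=(4, 3)) for X in Xs]
        params = [hgcn.init_params(s, seed=i) for i, s in enumerate(specs)]
        config = RunConfig(seed=0)

        def loss_value():
            evid = [forward_t(Tensor(X), Tensor(L), s, p)
                    for X, L, s, p in zip(Xs, Ls, specs, params)]
            alphas = [F + 1.0 for F in evid]
            fused = _fused_alpha_t(evid, config, b)
            return evidential.overall_loss_t(alphas, fused, y, mask,
                                             epoch=5, annealing_step=10)

        loss = loss_value()
        loss.backward()
        h = 1e-6
        rng_pick = np.random.default_rng(1)
        for prm in params:
            for tensor in prm.all():
                flat = tensor.data.reshape(-1)
                grad = tensor.grad.reshape(-1)
                for idx in rng_pick.choice(flat.size,
                                           size=min(4, flat.size),
                                           replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    up = loss_value().item()
                    flat[idx] = orig - h
                    down = loss_value().item()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * h)
                    assert abs(numeric - grad[idx]) <= 1e-4 * max(
                        1.0, abs(numeric)), (numeric, grad[idx])


class TestCrossValidation:
    def test_splits_partition_and_depend_only_on_seed(self, tiny_dataset):
        dataset, _ = tiny_dataset
        splits = cv_splits(dataset.labels, seed=3, n_folds=5)
        test_sets = [set(te) for _, te in splits]
        all_test = sorted(i for s in test_sets for i in s)
        assert all_test == list(range(dataset.n_samples))  # exactly once each
        sizes = [len(s) for s in test_sets]
        assert max(sizes) - min(sizes) <= 1
        again = cv_splits(dataset.labels, seed=3, n_folds=5)
        for (tr1, te1), (tr2, te2) in zip(splits, again):
            np.testing.assert_array_equal(te1, te2)

    def test_report_structure_and_determinism(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        r1 = cross_validate(dataset, fast_config, n_folds=3)
        r2 = cross_validate(dataset, fast_config, n_folds=3)
        assert len(r1.per_fold) == 3
        assert set(r1.mean) == {"ACC", "F1_weighted", "F1_macro"}
        assert all(0 <= v <= 1 for v in r1.mean.values())
        assert r1.per_fold == r2.per_fold


class TestExperiments:
    def test_noise_experiment_table_and_signal_destruction(self):
        dataset, _ = generate(SyntheticSpec(
            n_samples=90, n_classes=3, n_features=(20,),
            informative_fraction=0.3, effect_size=3.0, seed=4))
        config = RunConfig(epochs=40, k_neighbors=6, learning_rate=5e-3,
                           seed=8)
        table = noise_experiment(dataset, config, [0.0, 8.0], n_repeats=1)
        assert list(table.columns) == ["sigma", "repeat", "ACC",
                                       "mean_uncertainty"]
        acc = table.set_index("sigma")["ACC"]
        assert acc[8.0] <= acc[0.0]  # big noise on the only omics kills signal
        again = noise_experiment(dataset, config, [0.0, 8.0], n_repeats=1)
        assert table.equals(again)

    def test_noise_requires_baseline_sigma(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        with pytest.raises(ValueError, match="0"):
            noise_experiment(dataset, fast_config, [0.5, 1.0], n_repeats=1)

    def test_k_sweep_row_count(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        cfg = fast_config.replace(epochs=5)
        table = ablation_run(dataset, cfg, "k_sweep", ks=(1, 5, 10),
                             n_folds=2)
        assert list(table["variant"]) == ["k=1", "k=5", "k=10"]

    def test_omics_subsets_enumerates_power_set(self, tiny_dataset,
                                                fast_config):
        dataset, _ = tiny_dataset
        cfg = fast_config.replace(epochs=5)
        table = ablation_run(dataset, cfg, "omics_subsets", n_folds=2)
        assert len(table) == 7  # 2^3 - 1 nonempty subsets of 3 omics
        assert "+".join(dataset.omics_names) in set(table["variant"])

    def test_structure_variants_share_folds(self, tiny_dataset):
        dataset, _ = tiny_dataset
        a = cv_splits(dataset.labels, seed=5, n_folds=3)
        b = cv_splits(dataset.labels, seed=5, n_folds=3)
        for (_, te1), (_, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_invalid_axis_rejected(self, tiny_dataset, fast_config):
        dataset, _ = tiny_dataset
        with pytest.raises(ValueError):
            ablation_run(dataset, fast_config, "bogus")


@pytest.fixture(scope="module")
def fitted():
    dataset, manifest = generate(SyntheticSpec(
        n_samples=100, n_classes=3, n_features=(8,),
        informative_fraction=0.25, effect_size=5.0, seed=6))
    # append a constant column to probe the zero-importance case
    X = np.column_stack([dataset.matrices[0], np.ones(100)])
    dataset = MultiOmicsDataset(dataset.omics_names, [X], dataset.labels,
                                dataset.sample_ids, dataset.n_classes)
    config = RunConfig(epochs=60, k_neighbors=8, learning_rate=5e-3, seed=9)
    tr, _ = _train_test(dataset, seed=1)
    model = train_model(dataset, tr, config)
    return dataset, manifest, config, model


class TestFeatureImportance:
    def test_every_feature_listed_once_with_ranks(self, fitted):
        dataset, _, config, model = fitted
        table = feature_importance(model, dataset, config, n_repeats=2)
        assert len(table) == 9
        assert sorted(table["feature"]) == list(range(9))
        assert sorted(table["rank"]) == list(range(1, 10))

    def test_constant_column_has_zero_importance(self, fitted):
        dataset, _, config, model = fitted
        table = feature_importance(model, dataset, config, n_repeats=2)
        const_row = table[table["feature"] == 8]
        assert const_row["importance"].iloc[0] == 0.0

    def test_planted_features_outrank_noise(self, fitted):
        dataset, manifest, config, model = fitted
        table = feature_importance(model, dataset, config, n_repeats=3)
        informative = set(manifest[dataset.omics_names[0]]
                          ["informative_features"])
        inf_scores = table[table["feature"].isin(informative)]["importance"]
        noise_scores = table[~table["feature"].isin(informative)]["importance"]
        assert inf_scores.mean() > noise_scores.mean()
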