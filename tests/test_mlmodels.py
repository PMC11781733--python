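"""Stratified splits, GA descriptor selection, ANNE/SVM training, ranking."""

import numpy as np
import pytest

import phenobar as pb
from phenobar.errors import ValidationError
from phenobar.metrics import MetricSet
from phenobar.mlmodels import ModelReport

AD, AP, AX, CI = (pb.ClassLabel.AD, pb.ClassLabel.AP, pb.ClassLabel.AX,
                  pb.ClassLabel.CI)


def _labeled_matrix(counts=(7, 7, 4, 5), p=6, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    labels = []
    for c, n in zip((AD, AP, AX, CI), counts):
        labels += [c] * n
    n_tot = len(labels)
    X = rng.normal(size=(n_tot, p))
    if separation:
        codes = np.array([l.code for l in labels])
        X[:, 0] += codes * separation
        X[:, 1] -= codes * separation
    return pb.FeatureMatrix([f"r{i}" for i in range(n_tot)],
                            [f"c{j}" for j in range(p)], X,
                            class_labels=labels)


class TestStratifiedSplit:
    def test_largest_remainder_quotas(self):
        """23 entities (7/7/4/5), test 5: per-class counts follow the
        largest-remainder rule."""
        m = _labeled_matrix()
        split = pb.stratified_split(m, test_count=5, seed=0)
        assert len(split.test_ids) == 5
        labels = dict(zip(m.row_ids, m.class_labels))
        per_class = {c: sum(labels[r] is c for r in split.test_ids)
                     for c in (AD, AP, AX, CI)}
        assert per_class in ({AD: 2, AP: 1, AX: 1, CI: 1},
                             {AD: 1, AP: 2, AX: 1, CI: 1})

    def test_zero_test_count(self):
        m = _labeled_matrix()
        split = pb.stratified_split(m, test_count=0, seed=0)
        assert split.test_ids == () and len(split.train_ids) == 23

    def test_deterministic(self):
        m = _labeled_matrix()
        assert pb.stratified_split(m, 5, seed=3) == pb.stratified_split(m, 5, seed=3)

    def test_partition(self):
        m = _labeled_matrix()
        split = pb.stratified_split(m, test_count=6, seed=1)
        assert set(split.train_ids) | set(split.test_ids) == set(m.row_ids)
        assert not set(split.train_ids) & set(split.test_ids)

    def test_oversized_test_rejected(self):
        with pytest.raises(ValidationError):
            pb.stratified_split(_labeled_matrix(), test_count=23, seed=0)


class TestGASelect:
    def test_planted_features_recovered(self):
        """Two informative descriptors among 20 noise ones are found in
        most seeds."""
        hits = 0
        for seed in range(10):
            m = _labeled_matrix(counts=(8, 8, 8), p=22, seed=seed,
                                separation=0.0)
            # both columns are needed: c0 isolates AD, c1 separates AP vs AX
            is_ad = np.array([l is AD for l in m.class_labels])
            is_ap = np.array([l is AP for l in m.class_labels])
            m.values[:, 0] += is_ad * 6.0
            m.values[:, 1] += is_ap * 6.0
            sel = pb.ga_select(m, m.class_labels, pb.svm_builder(),
                               subset_cap=6, seed=seed)
            if {"c0", "c1"} <= set(sel):
                hits += 1
        assert hits >= 8

    def test_cap_one_selects_the_single_informative_feature(self):
        m = _labeled_matrix(counts=(8, 8), p=5, seed=1)
        codes = np.array([l.code for l in m.class_labels])
        m.values[:, 2] += codes * 6.0
        sel = pb.ga_select(m, m.class_labels, pb.svm_builder(),
                           subset_cap=1, generations=10, seed=2)
        assert sel == ["c2"]

    def test_zero_generations_well_defined(self):
        m = _labeled_matrix(counts=(6, 6), p=4, seed=2)
        sel = pb.ga_select(m, m.class_labels, pb.svm_builder(),
                           generations=0, seed=3)
        assert 1 <= len(sel) <= 10

    def test_bad_cap_rejected(self):
        m = _labeled_matrix()
        with pytest.raises(ValidationError):
            pb.ga_select(m, m.class_labels, pb.svm_builder(), subset_cap=0,
                         seed=0)


class TestANNE:
    def _blobs(self, n=12, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
        labels = [AD] * n + [AP] * n
        return X, labels

    def test_separable_blobs_perfect_training_accuracy(self):
        X, labels = self._blobs()
        model = pb.train_anne(X, labels, ["a", "b", "c"], seed=0)
        assert model.predict(X) == labels

    def test_pure_noise_near_chance(self):
        """No-signal features give roughly chance-level generalization."""
        rng = np.random.default_rng(1)
        accs = []
        for seed in range(10):
            X, labels = self._blobs(sep=0.0, seed=seed)
            model = pb.train_anne(X, labels, ["a", "b", "c"], seed=seed)
            X_new = rng.normal(0, 1, (40, 3))
            y_new = [AD] * 20 + [AP] * 20
            accs.append(np.mean([p == t for p, t in
                                 zip(model.predict(X_new), y_new)]) * 100)
        assert abs(np.mean(accs) - 50.0) <= 15.0

    def test_deterministic_for_fixed_seed(self):
        X, labels = self._blobs()
        a = pb.train_anne(X, labels, ["a", "b", "c"], seed=5)
        b = pb.train_anne(X, labels, ["a", "b", "c"], seed=5)
        np.testing.assert_array_equal(a.submodels[0].net.W1,
                                      b.submodels[0].net.W1)
        assert [s.score for s in a.submodels] == [s.score for s in b.submodels]

    def test_submodel_scores_recorded(self):
        X, labels = self._blobs()
        model = pb.train_anne(X, labels, ["a", "b", "c"], seed=0)
        assert len(model.submodels) == 10
        assert all(np.isfinite(s.score) for s in model.submodels)
        assert all(2 <= s.hidden_size <= 5 for s in model.submodels)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            pb.train_anne(np.zeros((4, 2)), [AD, AD, AP, AP][:4], ["a", "b"],
                          seed=0)


class TestSVM:
    def test_separable_blobs_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(8, 1, (10, 2))])
        labels = [AD] * 10 + [AP] * 10
        model = pb.train_svm(X, labels, ["a", "b"])
        assert model.predict(X) == labels

    def test_xor_linear_kernel_fails(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 4, dtype=float)
        labels = [AD, AP, AP, AD] * 4
        model = pb.train_svm(X, labels, ["a", "b"], kernel="linear")
        acc = np.mean([p == t for p, t in zip(model.predict(X), labels)])
        assert acc < 1.0

    def test_xor_rbf_kernel_succeeds(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 4, dtype=float)
        labels = [AD, AP, AP, AD] * 4
        model = pb.train_svm(X, labels, ["a", "b"], kernel="rbf", C=10.0)
        assert model.predict(X) == labels

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pb.train_svm(np.zeros((4, 2)), [AD] * 4, ["a", "b"])


class TestEvaluate:
    def test_perfect_model_scores_100_everywhere(self):
        m = _labeled_matrix(counts=(6, 6), p=3, seed=3, separation=5.0)
        split = pb.stratified_split(m, test_count=3, seed=0)
        train = m.select_rows(list(split.train_ids))
        model = pb.train_svm(train.values, train.class_labels, m.column_names)
        report = pb.evaluate(model, split, m)
        for ms in (report.metrics_train, report.metrics_test, report.metrics_all):
            assert ms.accuracy == 100.0 and ms.youden_j == pytest.approx(100.0)
        assert report.misclassified_ids == ()

    def test_empty_test_set_flagged_absent(self):
        m = _labeled_matrix(counts=(6, 6), p=3, seed=3, separation=5.0)
        split = pb.stratified_split(m, test_count=0, seed=0)
        train = m.select_rows(list(split.train_ids))
        model = pb.train_svm(train.values, train.class_labels, m.column_names)
        report = pb.evaluate(model, split, m)
        assert report.metrics_test is None

    def test_majority_class_constant_model_on_balanced_four_class(self):
        """Hand computation: constant predictor on balanced 4-class data has
        Acc_all = 25 and J_all = 0."""
        class Constant:
            descriptor_names = ("c0",)
            n_descriptors = 1

            def predict(self, X):
                return [AD] * len(X)

        m = _labeled_matrix(counts=(5, 5, 5, 5), p=2, seed=0)
        split = pb.stratified_split(m, test_count=4, seed=0)
        report = pb.evaluate(Constant(), split, m)
        assert report.metrics_all.accuracy == 25.0
        assert report.metrics_all.youden_j == pytest.approx(0.0)


def _report(model_id, train, test, n_neurons, n_desc) -> ModelReport:
    ms = lambda v: MetricSet(youden_j=v, mcc=v, accuracy=v)
    return ModelReport(model_id, "anne", ms(train), ms(test), ms(train),
                       n_neurons, n_desc, tuple(f"d{i}" for i in range(n_desc)),
                       (), ("t1",), seed=0)


class TestRanking:
    def test_parsimony_prefers_fewer_descriptors(self):
        """Identical metrics, D = {5, 10}: the smaller model gets +100 vs +50
        on the descriptor term and ranks first."""
        a = _report("small", 90.0, 90.0, 3, 5)
        b = _report("large", 90.0, 90.0, 3, 10)
        table = pb.rank_models([a, b], "anne")
        s_small = 6 * 90 + 100 + 100
        s_large = 6 * 90 + 100 + 50
        assert table.scores == [s_small, s_large]
        assert table.best_model_id == "small"

    def test_identical_models_tie_at_average_rank(self):
        reports = [_report(f"m{i}", 80.0, 80.0, 2, 4) for i in range(3)]
        table = pb.rank_models(reports, "anne")
        assert table.ranks == [2.0, 2.0, 2.0]

    def test_single_model_ranks_first(self):
        table = pb.rank_models([_report("only", 70.0, 70.0, 2, 4)], "anne")
        assert table.ranks == [1.0] and table.best_model_id == "only"

    def test_svm_ranking_omits_neuron_term(self):
        a = _report("a", 90.0, 90.0, None, 5)
        table = pb.rank_models([a], "svm")
        assert table.scores == [6 * 90 + 100]

    def test_score_strictly_decreasing_in_n_and_d(self):
        base = _report("base", 85.0, 85.0, 2, 4)
        more_n = _report("more_n", 85.0, 85.0, 4, 4)
        more_d = _report("more_d", 85.0, 85.0, 2, 8)
        table = pb.rank_models([base, more_n, more_d], "anne")
        scores = dict(zip(table.model_ids, table.scores))
        assert scores["base"] > scores["more_n"] > 0
        assert scores["base"] > scores["more_d"] > 0

    def test_missing_test_metrics_excluded(self, caplog):
        a = _report("ok", 90.0, 90.0, 2, 4)
        b = ModelReport("broken", "anne", a.metrics_train, None, a.metrics_all,
                        2, 4, ("d0",), (), (), seed=0)
        with caplog.at_level("INFO"):
            table = pb.rank_models([a, b], "anne")
        assert table.model_ids == ["ok"]

    def test_coverage_note_when_top_test_set_misses_a_class(self):
        a = _report("top", 95.0, 95.0, 2, 4)
        object.__setattr__ if False else None
        a.test_covers_all_classes = False
        b = _report("covered", 90.0, 90.0, 2, 4)
        table = pb.rank_models([a, b], "anne")
        assert table.best_model_id == "top"
        assert "covered" in table.note


class TestBattery:
    def test_battery_deterministic_and_distinct_seeds(self, prepped_drugs):
        r1 = pb.run_model_battery(prepped_drugs, "svm", 3, master_seed=4)
        r2 = pb.run_model_battery(prepped_drugs, "svm", 3, master_seed=4)
        assert [r.seed for r in r1] == [r.seed for r in r2]
        assert len({r.seed for r in r1}) == 3
        assert [r.metrics_all.accuracy for r in r1] == \
            [r.metrics_all.accuracy for r in r2]
        assert [r.descriptor_names for r in r1] == \
            [r.descriptor_names for r in r2]

    def test_summary_means_and_se(self, prepped_drugs):
        reports = pb.run_model_battery(prepped_drugs, "svm", 3, master_seed=4)
        summary = pb.battery_summary(reports)
        assert set(summary) >= {"train_accuracy", "test_accuracy", "all_mcc"}
        mean, se = summary["train_accuracy"]
        assert 0 <= mean <= 100 and se >= 0

    def test_unknown_model_type_rejected(self, prepped_drugs):
        with pytest.raises(ValidationError):
            pb.run_model_battery(prepped_drugs, "forest", 2, master_seed=0)
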