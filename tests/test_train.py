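import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragscreen.chem import MoleculeRecord
from fragscreen.train import (GapReport, MetricsReport, SplitSpec, TrainConfig,
                              evaluate, generalization_gap,
                              metrics_from_confusion, predict_proba,
                              stratified_split, train_model)


def _toy_dataset():
    """Linearly separable: label = molecule carries chlorine."""
    actives = ["Clc1ccccc1", "ClCCO", "ClC(C)C", "Clc1ccncc1", "ClCCN",
               "ClCc1ccccc1", "ClCCCC", "Clc1ccccc1O"]
    inactives = ["c1ccccc1", "CCO", "CC(C)C", "c1ccncc1", "NCC",
                 "Cc1ccccc1", "CCCC", "Oc1ccccc1"]
    return ([MoleculeRecord(id=f"a{i}", smiles=s, label=1)
             for i, s in enumerate(actives)] +
            [MoleculeRecord(id=f"i{i}", smiles=s, label=0)
             for i, s in enumerate(inactives)])


class TestStratifiedSplit:
    def test_exact_stratification_arithmetic(self):
        records = ([MoleculeRecord(id=f"p{i}", smiles="CCO", label=1)
                    for i in range(60)] +
                   [MoleculeRecord(id=f"n{i}", smiles="CCN", label=0)
                    for i in range(40)])
        train, test = stratified_split(
            records, SplitSpec(test_fraction=0.25, rng_seed=0,
                               group_by_parent=False))
        test_labels = [r.label for r in test]
        assert len(test) == 25
        assert test_labels.count(1) == 15 and test_labels.count(0) == 10
        assert len(train) + len(test) == 100
        assert {r.id for r in train}.isdisjoint({r.id for r in test})

    def test_deterministic(self, small_sar):
        spec = SplitSpec(test_fraction=0.25, rng_seed=3)
        a = [r.id for r in stratified_split(small_sar, spec)[0]]
        b = [r.id for r in stratified_split(small_sar, spec)[0]]
        assert a == b

    def test_group_by_parent_no_straddle(self, small_sar, fragment_library,
                                         aug_config):
        from fragscreen.augment import augment_dataset
        data = augment_dataset(small_sar, fragment_library, aug_config)
        train, test = stratified_split(
            data, SplitSpec(test_fraction=0.3, rng_seed=1,
                            group_by_parent=True))
        test_ids = {r.id for r in test}
        for r in test:
            if r.provenance == "augmented":
                assert r.parent_id in test_ids
        train_parents = {r.id for r in train if r.provenance != "augmented"}
        for r in train:
            if r.provenance == "augmented":
                assert r.parent_id in train_parents

    def test_tiny_class_errors(self):
        records = [MoleculeRecord(id="a", smiles="CCO", label=1),
                   MoleculeRecord(id="b", smiles="CCN", label=0),
                   MoleculeRecord(id="c", smiles="CCC", label=0)]
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(records, SplitSpec(test_fraction=0.5))


class TestTrainModel:
    def test_separable_toy_perfect_training_accuracy(self):
        data = _toy_dataset()
        cfg = TrainConfig(cv_folds=2, grid={"n_estimators": [50]})
        bundle = train_model(data, cfg, rng_seed=0)
        report = evaluate(bundle, data)
        assert report.accuracy == 1.0
        proba = predict_proba(bundle, data)
        labels = np.array([r.label for r in data])
        assert np.all((proba >= 0.5) == (labels == 1))

    def test_deterministic_selection_and_cv_table_shape(self):
        data = _toy_dataset()
        cfg = TrainConfig(cv_folds=3, grid={"n_estimators": [20, 50],
                                            "max_depth": [2, None]})
        b1 = train_model(data, cfg, rng_seed=7)
        b2 = train_model(data, cfg, rng_seed=7)
        assert b1.best_params == b2.best_params
        assert len(b1.cv_results) == 4 * 3  # grid points x folds

    def test_single_class_errors(self):
        data = [MoleculeRecord(id=str(i), smiles=s, label=1)
                for i, s in enumerate(["CCO", "CCN", "CCC", "CCCC"])]
        with pytest.raises(ValueError, match="single class"):
            train_model(data, TrainConfig(cv_folds=2), rng_seed=0)

    def test_order_equivariance_of_predictions(self):
        data = _toy_dataset()
        bundle = train_model(data, TrainConfig(cv_folds=2,
                                               grid={"n_estimators": [30]}),
                             rng_seed=0)
        proba = predict_proba(bundle, data)
        perm = np.random.RandomState(0).permutation(len(data))
        proba_perm = predict_proba(bundle, [data[i] for i in perm])
        assert np.allclose(proba[perm], proba_perm)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_unfeaturizable_gets_nan(self):
        data = _toy_dataset()
        bundle = train_model(data, TrainConfig(cv_folds=2,
                                               grid={"n_estimators": [30]}),
                             rng_seed=0)
        with pytest.warns(UserWarning, match="unfeaturizable"):
            proba = predict_proba(bundle, ["CCO", "C1CC"])
        assert np.isfinite(proba[0]) and np.isnan(proba[1])


class TestMetrics:
    def test_worked_confusion_example(self):
        acc, mcc, f1 = metrics_from_confusion(tn=2, fp=1, fn=1, tp=3)
        assert acc == pytest.approx(5 / 7)
        assert f1 == pytest.approx(0.75)
        assert mcc == pytest.approx(5 / 12)

    def test_constant_classifier_mcc_zero(self):
        _, mcc, _ = metrics_from_confusion(tn=0, fp=5, fn=0, tp=5)
        assert mcc == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*(st.integers(0, 40),) * 4))
    def test_matches_sklearn(self, confusion):
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef
        tn, fp, fn, tp = confusion
        if tn + fp + fn + tp == 0:
            return
        acc, mcc, f1 = metrics_from_confusion(tn, fp, fn, tp)
        y = [0] * (tn + fp) + [1] * (fn + tp)
        pred = [0] * tn + [1] * fp + [0] * fn + [1] * tp
        assert acc == pytest.approx(accuracy_score(y, pred))
        assert mcc == pytest.approx(matthews_corrcoef(y, pred))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert f1 == pytest.approx(f1_score(y, pred, zero_division=0))

    def test_single_class_eval_reports_null(self):
        data = _toy_dataset()
        bundle = train_model(data, TrainConfig(cv_folds=2,
                                               grid={"n_estimators": [30]}),
                             rng_seed=0)
        actives = [r for r in data if r.label == 1]
        with pytest.warns(UserWarning, match="single-class"):
            report = evaluate(bundle, actives)
        assert report.mcc is None and report.roc_auc is None


class TestGapReport:
    def test_pure_subtraction(self):
        train = MetricsReport(accuracy=1.0, mcc=1.0, f1=1.0, roc_auc=1.0,
                              confusion=(1, 0, 0, 1))
        test = MetricsReport(accuracy=0.59, mcc=0.11, f1=0.57, roc_auc=0.6,
                             confusion=(1, 1, 1, 1))
        gap = generalization_gap(train, test)
        assert gap.delta_accuracy == pytest.approx(0.41)
        assert gap.delta_mcc == pytest.approx(0.89)
        assert gap.delta_f1 == pytest.approx(0.43)

    def test_identical_reports_zero_gap(self):
        rep = MetricsReport(accuracy=0.8, mcc=0.5, f1=0.7, roc_auc=0.9,
                            confusion=(2, 1, 1, 3))
        gap = generalization_gap(rep, rep)
        assert gap == GapReport(0.0, 0.0, 0.0)
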