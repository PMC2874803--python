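"""SVM training, cross-validation and the majority-vote ensemble."""

import numpy as np
import pandas as pd
import pytest

from apis.evaluation import metrics
from apis.models import (
    CVConfig,
    EnsembleModel,
    SVMParams,
    build_apis,
    cross_validate,
    cross_validate_ensemble,
    fit,
    majority_vote,
)
from apis.selection import HOT, NON_HOT, FeatureMatrix
from apis.synthetic import make_feature_table


@pytest.fixture
def separable():
    """1-D data with a 10-SD class gap: trivially separable."""
    return make_feature_table(40, 40, gaps=[10.0], sds=1.0, seed=8,
                              feature_names=["x"])


class TestFit:
    def test_separable_training_accuracy_is_one(self, separable):
        model = fit(separable, ["x"])
        preds = model.predict(separable.X)
        assert (preds == separable.y).mean() == 1.0

    def test_stored_normalization_equals_training_stats(self, separable):
        model = fit(separable, ["x"])
        col = separable.X["x"].to_numpy()
        assert model.norm_mean[0] == pytest.approx(col.mean())
        assert model.norm_sd[0] == pytest.approx(col.std(ddof=0))

    def test_default_gamma_is_one_over_n_features(self, separable):
        model = fit(separable, ["x"])
        assert model.svm.gamma == pytest.approx(1.0)
        assert model.svm.C == 1.0

    def test_refit_same_seed_is_deterministic(self, separable):
        held_out = make_feature_table(10, 10, gaps=[10.0], seed=99,
                                      feature_names=["x"])
        p1 = fit(separable, ["x"], seed=3).predict(held_out.X)
        p2 = fit(separable, ["x"], seed=3).predict(held_out.X)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        fm = FeatureMatrix(
            X=pd.DataFrame({"x": [1.0, 2.0, 3.0]}),
            y=pd.Series([HOT, HOT, HOT]),
        )
        with pytest.raises(ValueError):
            fit(fm, ["x"])

    def test_constant_feature_named_in_error(self):
        fm = FeatureMatrix(
            X=pd.DataFrame({"flat": [1.0] * 6, "x": np.arange(6.0)}),
            y=pd.Series([HOT] * 3 + [NON_HOT] * 3),
        )
        with pytest.raises(ValueError, match="flat"):
            fit(fm, ["flat", "x"])


class TestPredict:
    def test_missing_value_imputed_with_warning(self, separable):
        model = fit(separable, ["x"])
        rows = pd.DataFrame({"x": [np.nan]})
        with pytest.warns(UserWarning, match="imputed"):
            label = model.predict(rows).iloc[0]
        assert label in (HOT, NON_HOT)

    def test_prediction_invariant_to_row_order(self, separable):
        model = fit(separable, ["x"])
        rows = make_feature_table(8, 8, gaps=[10.0], seed=5, feature_names=["x"]).X
        fwd = model.predict(rows).to_numpy()
        rev = model.predict(rows.iloc[::-1]).to_numpy()[::-1]
        assert (fwd == rev).all()

    def test_save_load_round_trip(self, separable, tmp_path):
        model = fit(separable, ["x"])
        path = tmp_path / "m.model"
        model.save(path)
        loaded = type(model).load(path)
        assert (loaded.predict(separable.X) == model.predict(separable.X)).all()


class TestCrossValidate:
    def test_confusion_counts_partition_the_data(self, separable):
        cm = cross_validate(separable, ["x"], CVConfig(k=10, seed=0))
        assert cm.total == separable.n

    def test_separable_data_high_accuracy(self):
        data = make_feature_table(100, 100, gaps=[10.0], seed=17,
                                  feature_names=["x"])
        cm = cross_validate(data, ["x"], CVConfig(k=10, seed=0))
        assert metrics(cm).accuracy >= 0.98

    def test_fixed_seed_reproduces_confusion_matrix(self, separable):
        cm1 = cross_validate(separable, ["x"], CVConfig(k=5, seed=4))
        cm2 = cross_validate(separable, ["x"], CVConfig(k=5, seed=4))
        assert cm1 == cm2

    def test_k_larger_than_n_rejected(self, separable):
        with pytest.raises(ValueError):
            cross_validate(separable, ["x"], CVConfig(k=1000, seed=0))

    def test_stratified_folds_preserve_class_ratio(self):
        from apis.models import _folds

        data = make_feature_table(40, 60, gaps=[1.0], seed=0)
        for _, test_idx in _folds(data, CVConfig(k=10, seed=0)):
            labels = data.y.iloc[test_idx]
            assert abs((labels == HOT).sum() - 4) <= 1


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [
            ([[HOT], [HOT], [NON_HOT]], HOT),
            ([[NON_HOT], [NON_HOT], [NON_HOT]], NON_HOT),
            ([[HOT], [NON_HOT]], HOT),  # even tie favors hot
            ([[HOT]], HOT),
        ],
    )
    def test_examples(self, votes, expected):
        assert majority_vote(votes) == [expected]

    def test_empty_committee_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_minority_flip_never_changes_outcome(self):
        rng = np.random.default_rng(0)
        votes = [
            list(rng.choice([HOT, NON_HOT], size=50)) for _ in range(5)
        ]
        base = majority_vote(votes)
        for i in range(50):
            counts = sum(v[i] == base[i] for v in votes)
            if counts >= 4:  # strict minority exists
                flipped = [list(v) for v in votes]
                for v in flipped:
                    if v[i] != base[i]:
                        v[i] = base[i]  # flip a dissenter toward majority
                assert majority_vote(flipped)[i] == base[i]


class TestEnsemble:
    def test_identical_members_equal_single_member(self, separable):
        member = fit(separable, ["x"])
        ensemble = EnsembleModel(members=[member, member, member])
        assert (ensemble.predict(separable.X) == member.predict(separable.X)).all()

    def test_build_apis_top_k_member_counts(self):
        data = make_feature_table(40, 60, gaps=[2.0] * 9, seed=13)
        ens3 = build_apis(data, data.features, member_rule="top_k", k=3,
                          cv=CVConfig(k=5, seed=0))
        assert len(ens3.members) == 3
        ens9 = build_apis(data, data.features, member_rule="top_k", k=9,
                          cv=CVConfig(k=5, seed=0))
        assert len(ens9.members) == 9

    def test_build_apis_f1_threshold_rule(self):
        data = make_feature_table(40, 60, gaps=[3.0, 3.0, 3.0, 0.0], seed=7)
        ens = build_apis(data, data.features, member_rule="f1_threshold",
                         f1_threshold=0.70, cv=CVConfig(k=5, seed=0))
        assert len(ens.members) % 2 == 1
        assert all(f1 > 0.70 for f1 in ens.member_cv_f1.values())

    def test_even_qualifying_set_reduced_to_odd(self):
        data = make_feature_table(40, 60, gaps=[3.0, 3.0, 3.0, 3.0], seed=7)
        ens = build_apis(data, data.features, member_rule="top_k", k=4,
                         cv=CVConfig(k=5, seed=0))
        assert len(ens.members) == 3

    def test_external_scores_override_member_selection(self):
        data = make_feature_table(40, 60, gaps=[2.0] * 4, seed=3)
        external = {"f00": 0.62, "f01": 0.61, "f02": 0.59, "f03": 0.40}
        ens = build_apis(data, data.features, member_rule="f1_threshold",
                         f1_threshold=0.50, cv=CVConfig(k=5, seed=0),
                         scores=external)
        assert ens.member_features == ["f00", "f01", "f02"]

    def test_no_qualifying_member_rejected(self):
        data = make_feature_table(40, 60, gaps=[0.0], seed=7)
        with pytest.raises(ValueError):
            build_apis(data, data.features, member_rule="f1_threshold",
                       f1_threshold=0.999, cv=CVConfig(k=5, seed=0))

    def test_three_independent_members_beat_each_alone(self):
        """Majority vote over 3 conditionally independent 80%-accurate
        voters approaches 0.896 accuracy; assert clearly above 0.84."""
        rng = np.random.default_rng(77)
        n = 1000
        truth = rng.choice([HOT, NON_HOT], size=n)
        votes = []
        for _ in range(3):
            flip = rng.random(n) < 0.2
            noisy = np.where(
                flip, np.where(truth == HOT, NON_HOT, HOT), truth
            )
            votes.append(noisy)
        combined = np.array(majority_vote(votes))
        acc = (combined == truth).mean()
        member_accs = [(v == truth).mean() for v in votes]
        assert acc > 0.84
        assert all(acc > a for a in member_accs)

    def test_multi_feature_svm_runs_end_to_end(self):
        """A single SVM over 9 selected features trains and cross-validates."""
        data = make_feature_table(62, 92, gaps=[1.5] * 9 + [0.0] * 3, seed=11)
        nine = data.features[:9]
        cm = cross_validate(data, nine, CVConfig(k=10, seed=0))
        assert cm.total == 154
        model = fit(data, nine)
        assert set(model.predict(data.X).unique()) <= {HOT, NON_HOT}

    def test_ensemble_cv_and_save_load(self, tmp_path):
        data = make_feature_table(30, 40, gaps=[2.0, 2.0, 2.0], seed=19)
        cm = cross_validate_ensemble(data, data.features, CVConfig(k=5, seed=1))
        assert cm.total == data.n
        ens = build_apis(data, data.features, k=3, cv=CVConfig(k=5, seed=1))
        path = tmp_path / "ens.model"
        ens.save(path)
        loaded = EnsembleModel.load(path)
        assert (loaded.predict(data.X) == ens.predict(data.X)).all()


def test_svm_params_class_weight_flag():
    data = make_feature_table(20, 80, gaps=[2.0], seed=23, feature_names=["x"])
    balanced = fit(data, ["x"], params=SVMParams(class_weight="balanced"))
    assert balanced.svm.class_weight == "balanced"
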