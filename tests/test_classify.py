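"""Learner contracts, boosting, fusion, metrics, CV and feature selection."""

import numpy as np
import pytest

from nits.classify import (
    AdaBoostM1,
    BaseLearnerSpec,
    EnsembleConfig,
    EnsembleMember,
    correlation_rank,
    evaluate,
    evaluate_counts,
    fuse,
    hybrid13,
    kfold_cv,
    leave_subjects_out_split,
    evaluate_holdout,
    pca_vc,
    train_base,
    wrapper_subset,
)
from nits.feature_table import FeatureVector


def _blobs(n=60, d=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < 0.5).astype(int)
    X[y == 1, 0] += sep
    return X, y


class TestTrainBase:
    def test_separable_data_fits_perfectly(self):
        X, y = _blobs(sep=8.0)
        model = train_base(BaseLearnerSpec("svm_linear"), X, y)
        assert (model.predict(X) == y).mean() == 1.0

    @pytest.mark.parametrize("name", [
        "svm_linear", "svm_rbf", "knn", "random_forest", "decision_stump",
        "naive_bayes", "bayes_net", "lwl", "flda", "logistic", "j48_tree",
        "lmt", "voted_perceptron", "sgd_linear", "lstm_seq", "mlp",
    ])
    def test_probability_contract(self, name):
        X, y = _blobs(n=40)
        model = train_base(BaseLearnerSpec(name), X, y, seed=1)
        p = model.predict_proba(X)
        assert p.shape == (40, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= -1e-12)

    def test_knn_k1_memorizes_training_labels(self):
        X, y = _blobs(n=30, sep=0.0)  # even unseparable data is memorized
        model = train_base(BaseLearnerSpec("knn", (("n_neighbors", 1),)), X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_base(BaseLearnerSpec("knn"), X, np.zeros(10))

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("quantum_forest")

    def test_pca_preprocessor_bounds(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("svm_linear", pca_vc=1.5)


class TestAdaBoostM1:
    def test_perfect_round_one_stops_with_single_model(self):
        X, y = _blobs(sep=8.0)
        ab = AdaBoostM1(BaseLearnerSpec("j48_tree"), rounds=10, seed=0).fit(X, y)
        assert len(ab.models_) == 1
        assert (ab.predict(X) == y).all()

    def test_chance_learner_halts_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 1))
        y = np.array([0, 1] * 20)
        X[:, 0] = np.where(y == 0, 1.0, 1.0)  # featureless: stump at chance
        with pytest.warns(UserWarning, match="chance"):
            ab = AdaBoostM1(BaseLearnerSpec("decision_stump"), rounds=5, seed=0).fit(X, y)
        assert len(ab.models_) == 1

    def test_hand_computed_weight_update_on_four_points(self):
        # stump errs on exactly one of four points: eps = 1/4, beta = 1/3,
        # correct weights 1/4 -> 1/12, renormalized -> wrong point at 1/2
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 0])
        ab = AdaBoostM1(BaseLearnerSpec("decision_stump"), rounds=2, seed=0).fit(X, y)
        w1 = ab.weight_history_[1]
        np.testing.assert_allclose(sorted(w1), [1 / 6, 1 / 6, 1 / 6, 1 / 2])
        assert ab.alphas_[0] == pytest.approx(np.log(3.0))

    def test_training_error_non_increasing_on_separable_data(self):
        X, y = _blobs(n=80, sep=2.0, seed=3)
        errs = []
        for rounds in (1, 3, 6):
            ab = AdaBoostM1(BaseLearnerSpec("decision_stump"), rounds=rounds, seed=0).fit(X, y)
            errs.append((ab.predict(X) != y).mean())
        assert errs[0] >= errs[1] >= errs[2]

    def test_resampling_fallback_for_weightless_learner(self):
        X, y = _blobs(n=40)
        ab = AdaBoostM1(BaseLearnerSpec("knn"), rounds=3, seed=0).fit(X, y)
        assert len(ab.models_) >= 1
        p = ab.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class _Const:
    def __init__(self, p1):
        self.p1 = p1

    def predict_proba(self, X):
        return np.tile([1 - self.p1, self.p1], (len(np.atleast_2d(X)), 1))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


class TestFusion:
    def test_average_of_probabilities(self):
        r = fuse([_Const(0.6), _Const(0.8)], np.zeros(3))
        assert r.predicted == 1
        assert r.confidence == pytest.approx(0.7)

    def test_probability_tie_breaks_to_class_zero(self):
        r = fuse([_Const(0.5)], np.zeros(2))
        assert r.predicted == 0

    def test_majority_vote_seven_of_thirteen(self):
        members = [_Const(0.9)] * 7 + [_Const(0.1)] * 6
        r = fuse(members, np.zeros(2), rule="majority_vote")
        assert r.predicted == 1
        assert r.confidence == pytest.approx(7 / 13)

    def test_identical_members_equal_single(self):
        single = fuse([_Const(0.73)], np.zeros(2))
        triple = fuse([_Const(0.73)] * 3, np.zeros(2))
        assert single.predicted == triple.predicted
        assert single.confidence == pytest.approx(triple.confidence)

    def test_ensemble_config_validation(self):
        with pytest.raises(ValueError):
            EnsembleConfig(members=())
        with pytest.raises(ValueError):
            EnsembleConfig(members=(EnsembleMember(BaseLearnerSpec("knn")),),
                           fusion="median")


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.mcc == 1.0
        assert rep.f1 == 1.0

    def test_chance_predictions_have_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        pred = rng.integers(0, 2, 4000)
        rep = evaluate(y, pred)
        assert abs(rep.kappa) < 0.05
        assert abs(rep.mcc) < 0.05

    def test_rates_bounded(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        rep = evaluate(y, pred)
        for v in (rep.tpr, rep.tnr, rep.precision, rep.f1, rep.auc_roc, rep.auc_prc):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= rep.kappa <= 1.0
        assert -1.0 <= rep.mcc <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])

    def test_counts_expansion_matches_direct_arrays(self):
        rep = evaluate_counts(8, 2, 7, 3)
        assert rep.confusion.tolist() == [[8, 2], [3, 7]]
        assert rep.accuracy == pytest.approx(15 / 20)


class TestCrossValidation:
    config = EnsembleConfig(members=(
        EnsembleMember(BaseLearnerSpec("flda")),
        EnsembleMember(BaseLearnerSpec("knn")),
    ))

    def test_same_seed_same_result(self):
        X, y = _blobs(n=50, sep=1.0)
        a = kfold_cv(self.config, X, y, k=5, seed=11)
        b = kfold_cv(self.config, X, y, k=5, seed=11)
        assert a.confusion.tolist() == b.confusion.tolist()

    def test_separable_data_scores_high(self):
        X, y = _blobs(n=60, sep=5.0)
        rep = kfold_cv(self.config, X, y, k=5, seed=0)
        assert rep.accuracy > 0.9

    def test_k_larger_than_n_rejected(self):
        X, y = _blobs(n=10)
        with pytest.raises(ValueError):
            kfold_cv(self.config, X, y, k=20)


def _vectors(n_subjects=6, per_subject=4, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        label = s % 2
        for r in range(per_subject):
            vals = rng.normal(size=238) + label * 3.0
            out.append(FeatureVector(values=vals, label=label,
                                     subject_id=f"sub{s}", round_index=r % 5 + 1))
    return out


class TestLeaveSubjectsOut:
    def test_train_and_test_subjects_disjoint(self):
        vecs = _vectors()
        train, th, ts = leave_subjects_out_split(vecs, ["sub0", "sub1"])
        train_ids = {v.subject_id for v in train}
        assert train_ids.isdisjoint({"sub0", "sub1"})
        assert all(v.label == 0 for v in th)
        assert all(v.label == 1 for v in ts)

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError):
            leave_subjects_out_split(_vectors(), ["ghost"])

    def test_emptying_a_class_rejected(self):
        vecs = _vectors(n_subjects=2)
        with pytest.raises(ValueError):
            leave_subjects_out_split(vecs, ["sub0"])

    def test_holdout_error_count_and_confidence(self):
        vecs = _vectors(n_subjects=8, per_subject=5, seed=2)
        train, th, ts = leave_subjects_out_split(vecs, ["sub0", "sub1"])
        config = EnsembleConfig(members=(EnsembleMember(BaseLearnerSpec("flda")),))
        rep = evaluate_holdout(config, train, th, ts, seed=0)
        assert rep.ec_healthy == 0 and rep.ec_impaired == 0  # separable cohort
        assert 0.5 <= rep.mean_prc_healthy <= 1.0
        assert 0.5 <= rep.mean_prc_impaired <= 1.0


class TestFeatureSelection:
    def test_correlation_rank_finds_the_label_copy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 10))
        y = rng.integers(0, 2, 80)
        X[:, 7] = y.astype(float)
        assert correlation_rank(X, y, k=1) == [7]

    def test_correlation_rank_k_bounds(self):
        with pytest.raises(ValueError):
            correlation_rank(np.zeros((5, 3)), np.zeros(5), k=4)

    def test_pca_vc_full_variance_keeps_all_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        p = pca_vc(X, vc=1.0)
        assert p.n_components_ == 5

    def test_pca_vc_partial_variance_truncates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 6))
        X[:, 0] *= 20.0  # dominant direction
        p = pca_vc(X, vc=0.5)
        assert p.n_components_ < 6

    def test_wrapper_selects_the_informative_feature(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 6))
        y = (X[:, 3] > 0).astype(int)
        sel = wrapper_subset(X, y, BaseLearnerSpec("flda"), cv=3, seed=0, max_features=3)
        assert 3 in sel


class TestHybridPreset:
    def test_has_exactly_thirteen_members(self):
        cfg = hybrid13()
        assert len(cfg.members) == 13
        assert cfg.fusion == "average_of_probabilities"

    def test_seven_members_are_boosted(self):
        cfg = hybrid13()
        boosted = [m for m in cfg.members if m.boost_rounds is not None]
        assert len(boosted) == 7

    def test_four_members_use_pca(self):
        cfg = hybrid13()
        assert sum(m.spec.pca_vc is not None for m in cfg.members) == 4
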