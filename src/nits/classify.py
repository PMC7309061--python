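"""Classification layer: learners, boosting, fusion, metrics, CV, selection.

The healthy-vs-impaired decision layer: a registry of base learners (each
exposing calibrated per-class probabilities), an AdaBoost.M1 implementation
for accuracy tuning, probability fusion across a 13-member hybrid ensemble
(average-of-probabilities or majority vote), a WEKA-style metric suite,
stratified k-fold and leave-subjects-out evaluation protocols, and four
feature-selection strategies.
"""

from __future__ import annotations

import inspect
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from nits.bilstm import BiLSTMClassifier, BiLSTMTabular, majority_vote
from nits.feature_table import FeatureVector
from nits.speech import WstConfig, wst_features
from nits.session_io import AudioClip

# ---------------------------------------------------------------------------
# Custom learners


class VotedPerceptron(BaseEstimator, ClassifierMixin):
    """Voted perceptron: every intermediate weight vector votes.

    Probabilities are the vote-weighted fraction of perceptrons predicting
    each class.
    """

    def __init__(self, n_epochs: int = 10, random_state: int = 0):
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        t = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        rng = np.random.default_rng(self.random_state)
        w = np.zeros(X.shape[1] + 1)
        Xb = np.hstack([X, np.ones((len(X), 1))])
        survived = 0
        self._ws, self._cs = [], []
        for _ in range(self.n_epochs):
            for i in rng.permutation(len(Xb)):
                if np.sign(Xb[i] @ w) == t[i] and w.any():
                    survived += 1
                else:
                    if survived > 0 or w.any():
                        self._ws.append(w.copy())
                        self._cs.append(survived + 1)
                    w = w + t[i] * Xb[i]
                    survived = 0
        self._ws.append(w.copy())
        self._cs.append(survived + 1)
        self._W = np.array(self._ws)
        self._C = np.array(self._cs, dtype=float)
        return self

    def predict_proba(self, X):
        Xb = np.hstack([np.asarray(X, dtype=float), np.ones((len(X), 1))])
        votes = np.sign(Xb @ self._W.T)  # (n, n_perceptrons)
        score = (votes * self._C).sum(axis=1) / self._C.sum()
        p1 = (score + 1.0) / 2.0
        p1 = np.clip(p1, 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


class LocallyWeightedLearner(BaseEstimator, ClassifierMixin):
    """Lazy locally weighted classification.

    Class probabilities of a query are the Gaussian-distance-weighted class
    frequencies of its k nearest training points (a locally weighted
    nearest-neighbor scheme).
    """

    def __init__(self, k: int = 25, bandwidth: float = 1.0):
        self.k = k
        self.bandwidth = bandwidth

    def fit(self, X, y, sample_weight=None):
        self._X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._yi = np.searchsorted(self.classes_, y)
        self._w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        k = min(self.k, len(self._X))
        out = np.empty((len(X), len(self.classes_)))
        for i, x in enumerate(X):
            d = np.linalg.norm(self._X - x, axis=1)
            nn = np.argsort(d)[:k]
            scale = max(d[nn][-1], 1e-12) * self.bandwidth
            w = np.exp(-0.5 * (d[nn] / scale) ** 2) * self._w[nn]
            p = np.bincount(self._yi[nn], weights=w, minlength=len(self.classes_))
            s = p.sum()
            out[i] = p / s if s > 0 else np.full(len(self.classes_), 1 / len(self.classes_))
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class LogisticModelTree(BaseEstimator, ClassifierMixin):
    """Shallow decision tree with a logistic model in each leaf."""

    def __init__(self, max_depth: int = 3, min_samples_leaf: int = 15, random_state: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._tree = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y, sample_weight=sample_weight)
        leaves = self._tree.apply(X)
        self._leaf_models: dict[int, object] = {}
        self._leaf_priors: dict[int, np.ndarray] = {}
        for leaf in np.unique(leaves):
            m = leaves == leaf
            prior = np.array([(y[m] == c).mean() for c in self.classes_])
            self._leaf_priors[leaf] = prior
            if len(np.unique(y[m])) == 2 and m.sum() >= 2 * len(self.classes_):
                lr = LogisticRegression(max_iter=500)
                sw = None if sample_weight is None else sample_weight[m]
                self._leaf_models[leaf] = lr.fit(X[m], y[m], sample_weight=sw)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        leaves = self._tree.apply(X)
        out = np.empty((len(X), len(self.classes_)))
        for i, leaf in enumerate(leaves):
            model = self._leaf_models.get(leaf)
            if model is not None:
                out[i] = model.predict_proba(X[i : i + 1])[0]
            else:
                out[i] = self._leaf_priors.get(leaf, np.full(len(self.classes_), 0.5))
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Learner registry


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Named base learner + hyperparameters + optional PCA preprocessor."""

    name: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    pca_vc: Optional[float] = None  # variance fraction retained by PCA

    def __post_init__(self) -> None:
        if self.name not in LEARNER_REGISTRY:
            raise ValueError(f"unknown learner {self.name!r}")
        if self.pca_vc is not None and not 0 < self.pca_vc <= 1:
            raise ValueError("pca_vc must be in (0, 1]")

    def hp(self) -> dict:
        return dict(self.hyperparameters)


def _make_svc(kernel):
    def build(hp, seed):
        return SVC(kernel=kernel, probability=True, random_state=seed, **hp)
    return build


LEARNER_REGISTRY: dict[str, Callable[[dict, int], object]] = {
    "svm_linear": _make_svc("linear"),
    "svm_rbf": _make_svc("rbf"),
    "svm_sigmoid": _make_svc("sigmoid"),
    "svm_poly3": lambda hp, seed: SVC(kernel="poly", degree=3, probability=True,
                                      random_state=seed, **hp),
    "smo": _make_svc("linear"),
    "knn": lambda hp, seed: KNeighborsClassifier(**{"n_neighbors": 5, **hp}),
    "random_forest": lambda hp, seed: RandomForestClassifier(
        **{"n_estimators": 100, **hp}, random_state=seed),
    "mlp": lambda hp, seed: MLPClassifier(
        **{"hidden_layer_sizes": (32,), "max_iter": 500,
           "early_stopping": True, "n_iter_no_change": 3, **hp}, random_state=seed),
    "decision_stump": lambda hp, seed: DecisionTreeClassifier(
        max_depth=1, random_state=seed, **hp),
    "lwl": lambda hp, seed: LocallyWeightedLearner(**hp),
    "bayes_net": lambda hp, seed: Pipeline([
        ("disc", KBinsDiscretizer(**{"n_bins": 5, "encode": "ordinal",
                                     "strategy": "uniform", **hp})),
        ("nb", CategoricalNB(min_categories=hp.get("n_bins", 5))),
    ]),
    "naive_bayes": lambda hp, seed: GaussianNB(**hp),
    "j48_tree": lambda hp, seed: DecisionTreeClassifier(random_state=seed, **hp),
    "lmt": lambda hp, seed: LogisticModelTree(random_state=seed, **hp),
    "flda": lambda hp, seed: LinearDiscriminantAnalysis(**hp),
    "lda": lambda hp, seed: LinearDiscriminantAnalysis(**hp),
    "logistic": lambda hp, seed: LogisticRegression(**{"max_iter": 1000, **hp}),
    "voted_perceptron": lambda hp, seed: VotedPerceptron(random_state=seed, **hp),
    "sgd_linear": lambda hp, seed: SGDClassifier(
        **{"loss": "log_loss", **hp}, random_state=seed),
    "lstm_seq": lambda hp, seed: BiLSTMTabular(**{"hidden": 32, "n_layers": 1,
                                                  "seed": seed, **hp}),
}


def train_base(spec: BaseLearnerSpec, X, y, seed: int = 0):
    """Fit a registered learner (optionally behind scaling + PCA).

    Every returned model exposes ``predict_proba`` with per-instance class
    probabilities summing to 1.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    est = LEARNER_REGISTRY[spec.name](spec.hp(), seed)
    steps = [("scale", StandardScaler())]
    if spec.pca_vc is not None:
        steps.append(("pca", PCA(n_components=spec.pca_vc, svd_solver="full",
                                 random_state=seed)))
    steps.append(("clf", est))
    pipe = Pipeline(steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(np.asarray(X, dtype=float), y)
    return pipe


# ---------------------------------------------------------------------------
# AdaBoost.M1


class AdaBoostM1:
    """AdaBoost.M1 over any registered weak learner.

    Uniform initial instance weights; each round fits on the weighted data
    (delegating ``sample_weight`` when supported, otherwise weighted
    resampling), computes the weighted error eps, stops on eps = 0 or
    eps >= 0.5, multiplies correct-instance weights by beta = eps/(1-eps),
    renormalizes, and gives the round's model vote weight log(1/beta).
    """

    def __init__(self, spec: BaseLearnerSpec, rounds: int = 10, seed: int = 0):
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        self.spec = spec
        self.rounds = rounds
        self.seed = seed
        self.models_: list = []
        self.alphas_: list[float] = []

    def fit(self, X, y) -> "AdaBoostM1":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n = len(y)
        w = np.full(n, 1.0 / n)
        rng = np.random.default_rng(self.seed)
        self.models_, self.alphas_ = [], []
        self.weight_history_: list[np.ndarray] = [w.copy()]
        for r in range(self.rounds):
            model = self._fit_weighted(X, y, w, seed=self.seed + r, rng=rng)
            pred = model.predict(X)
            eps = float(w[pred != y].sum())
            if eps == 0.0:
                self.models_.append(model)
                self.alphas_.append(np.log(1e12))  # effectively a perfect vote
                break
            if eps >= 0.5:
                if not self.models_:
                    warnings.warn("weak learner no better than chance; keeping single model")
                    self.models_.append(model)
                    self.alphas_.append(1.0)
                break
            beta = eps / (1.0 - eps)
            self.models_.append(model)
            self.alphas_.append(float(np.log(1.0 / beta)))
            w[pred == y] *= beta
            w /= w.sum()
            self.weight_history_.append(w.copy())
        return self

    def _fit_weighted(self, X, y, w, seed: int, rng: np.random.Generator):
        est = LEARNER_REGISTRY[self.spec.name](self.spec.hp(), seed)
        steps = [("scale", StandardScaler())]
        if self.spec.pca_vc is not None:
            steps.append(("pca", PCA(n_components=self.spec.pca_vc, svd_solver="full",
                                     random_state=seed)))
        steps.append(("clf", est))
        pipe = Pipeline(steps)
        fit_sig = inspect.signature(est.fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if "sample_weight" in fit_sig.parameters:
                pipe.fit(X, y, clf__sample_weight=w * len(w))
            else:  # weighted-resampling fallback
                idx = rng.choice(len(y), size=len(y), p=w / w.sum())
                if len(np.unique(y[idx])) < 2:  # keep both classes present
                    idx[0] = int(np.flatnonzero(y != y[idx[1]])[0])
                pipe.fit(X[idx], y[idx])
        return pipe

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)))
        for model, a in zip(self.models_, self.alphas_):
            pred = model.predict(X)
            for ci, c in enumerate(self.classes_):
                votes[pred == c, ci] += a
        s = votes.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return votes / s

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Ensembles & fusion


@dataclass(frozen=True)
class EnsembleMember:
    spec: BaseLearnerSpec
    boost_rounds: Optional[int] = None  # None = no boosting


@dataclass(frozen=True)
class EnsembleConfig:
    members: tuple[EnsembleMember, ...]
    fusion: str = "average_of_probabilities"

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if self.fusion not in ("average_of_probabilities", "majority_vote"):
            raise ValueError(f"unknown fusion rule {self.fusion!r}")


def hybrid13(boost_rounds: int = 10) -> EnsembleConfig:
    """The 13-member hybrid preset.

    Seven boosted learners (decision stump, random forest, MLP, SMO, kNN,
    locally weighted learner, Bayes net), a sigmoid-kernel SVM + PCA, two
    linear SVMs + PCA, Fisher LDA, an LSTM-style learner, and a voted
    perceptron + PCA, fused by the average of probabilities.
    """
    b = boost_rounds
    m = EnsembleMember
    s = BaseLearnerSpec
    return EnsembleConfig(members=(
        m(s("decision_stump"), b),
        m(s("random_forest"), b),
        m(s("mlp"), b),
        m(s("smo"), b),
        m(s("knn"), b),
        m(s("lwl"), b),
        m(s("bayes_net"), b),
        m(s("svm_sigmoid", pca_vc=0.95)),
        m(s("svm_linear", pca_vc=0.95)),
        m(s("svm_linear", pca_vc=0.9)),
        m(s("flda")),
        m(s("lstm_seq")),
        m(s("voted_perceptron", pca_vc=0.95)),
    ))


def train_ensemble(config: EnsembleConfig, X, y, seed: int = 0) -> list:
    models = []
    for i, member in enumerate(config.members):
        mseed = (seed * 1000 + i) % (2**31)
        if member.boost_rounds is not None:
            models.append(AdaBoostM1(member.spec, rounds=member.boost_rounds,
                                     seed=mseed).fit(X, y))
        else:
            models.append(train_base(member.spec, X, y, seed=mseed))
    return models


@dataclass
class PredictionResult:
    predicted: int
    confidence: float  # probability of the predicted class (PrC)
    member_probabilities: np.ndarray  # (n_members, n_classes)


def fuse(models: Sequence, x: np.ndarray, rule: str = "average_of_probabilities") -> PredictionResult:
    """Combine member probabilities for one instance.

    average_of_probabilities: argmax of the member-mean class probabilities;
    majority_vote: modal member argmax.  Exact ties go to class 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    probs = np.vstack([m.predict_proba(x)[0] for m in models])
    if rule == "average_of_probabilities":
        p = probs.mean(axis=0)
        cls = int(np.argmax(p > p.max() - 1e-12))  # first max -> class 0 on tie
        conf = float(p[cls])
    elif rule == "majority_vote":
        votes = np.argmax(probs, axis=1)
        counts = np.bincount(votes, minlength=probs.shape[1])
        cls = int(np.argmax(counts))
        conf = float(counts[cls] / counts.sum())
    else:
        raise ValueError(f"unknown fusion rule {rule!r}")
    return PredictionResult(predicted=cls, confidence=conf, member_probabilities=probs)


def fuse_batch(models: Sequence, X: np.ndarray, rule: str = "average_of_probabilities"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fusion: (predictions, fused probabilities)."""
    X = np.asarray(X, dtype=float)
    probs = np.stack([m.predict_proba(X) for m in models])  # (M, n, C)
    if rule == "average_of_probabilities":
        p = probs.mean(axis=0)
    else:
        votes = np.argmax(probs, axis=2)  # (M, n)
        p = np.stack([(votes == c).mean(axis=0) for c in range(probs.shape[2])], axis=1)
    return np.argmax(p, axis=1), p


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """Confusion counts plus the full WEKA-style metric suite.

    Rates are support-weighted aggregates over the two one-vs-rest views,
    matching the reporting convention of the toolkit the battery's
    published results were produced with.
    """

    confusion: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    tpr: float
    tnr: float
    fpr: float
    precision: float
    recall: float
    f1: float
    mcc: float
    kappa: float
    auc_roc: float
    auc_prc: float
    mae: float
    rmse: float
    rae: float
    rrse: float

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "accuracy", "tpr", "tnr", "fpr", "precision", "recall", "f1",
            "mcc", "kappa", "auc_roc", "auc_prc", "mae", "rmse", "rae", "rrse")}
        d["confusion"] = self.confusion.tolist()
        return d


def evaluate(y_true, y_pred, y_proba: Optional[np.ndarray] = None) -> MetricsReport:
    """Full metric suite from aligned prediction arrays.

    ``y_proba`` is (n, 2) with columns ordered [class 0, class 1]; when it
    is omitted, hard one-hot probabilities are used for the error and AUC
    measures.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction/label length mismatch")
    n = len(y_true)
    classes = (0, 1)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    support = cm.sum(axis=1)
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total

    # one-vs-rest rates, support-weighted
    tprs, tnrs, precs, f1s, fprs = [], [], [], [], []
    for c in classes:
        tp = cm[c, c]
        fn = support[c] - tp
        fp = cm[1 - c, c]
        tn = total - tp - fn - fp
        tpr_c = tp / support[c] if support[c] else 0.0
        tnr_c = tn / (tn + fp) if (tn + fp) else 0.0
        prec_c = tp / (tp + fp) if (tp + fp) else 0.0
        f1_c = 2 * prec_c * tpr_c / (prec_c + tpr_c) if (prec_c + tpr_c) else 0.0
        tprs.append(tpr_c)
        tnrs.append(tnr_c)
        precs.append(prec_c)
        f1s.append(f1_c)
        fprs.append(1.0 - tnr_c)
    wts = support / total

    def wavg(vals):
        return float(np.dot(wts, vals))

    # chance-corrected agreement
    pe = float(np.dot(cm.sum(axis=1), cm.sum(axis=0))) / total ** 2
    kappa = (accuracy - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    tp, fn = cm[1, 1], cm[1, 0]
    fp, tn = cm[0, 1], cm[0, 0]
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0

    if y_proba is None:
        y_proba = np.zeros((n, 2))
        y_proba[np.arange(n), y_pred] = 1.0
    y_proba = np.asarray(y_proba, dtype=float)

    auc_rocs, auc_prcs = [], []
    from sklearn.metrics import average_precision_score, roc_auc_score

    for c in classes:
        yt = (y_true == c).astype(int)
        sc = y_proba[:, c]
        if yt.min() == yt.max():
            auc_rocs.append(1.0)
            auc_prcs.append(1.0)
        else:
            auc_rocs.append(float(roc_auc_score(yt, sc)))
            auc_prcs.append(float(average_precision_score(yt, sc)))
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y_true] = 1.0
    resid = y_proba - onehot
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid ** 2).mean()))
    # baseline: the class-prior constant predictor
    prior = cm.sum(axis=0).astype(float)
    prior = (support / total)  # prior from the true-label frequencies
    base = np.tile(prior, (n, 1)) - onehot
    mae_base = float(np.abs(base).mean())
    rmse_base = float(np.sqrt((base ** 2).mean()))
    return MetricsReport(
        confusion=cm,
        accuracy=accuracy,
        tpr=wavg(tprs),
        tnr=wavg(tnrs),
        fpr=wavg(fprs),
        precision=wavg(precs),
        recall=wavg(tprs),
        f1=wavg(f1s),
        mcc=float(mcc),
        kappa=float(kappa),
        auc_roc=wavg(auc_rocs),
        auc_prc=wavg(auc_prcs),
        mae=mae,
        rmse=rmse,
        rae=100.0 * mae / mae_base if mae_base > 0 else 0.0,
        rrse=100.0 * rmse / rmse_base if rmse_base > 0 else 0.0,
    )


def evaluate_counts(correct0: int, wrong0: int, correct1: int, wrong1: int) -> MetricsReport:
    """Metric suite from per-class correct/incorrect counts alone.

    Expands the counts into label/prediction arrays (class 0 errors are
    predicted 1 and vice versa) and scores them with hard probabilities.
    """
    y_true = np.concatenate([
        np.zeros(correct0 + wrong0, dtype=int),
        np.ones(correct1 + wrong1, dtype=int),
    ])
    y_pred = np.concatenate([
        np.zeros(correct0, dtype=int), np.ones(wrong0, dtype=int),
        np.ones(correct1, dtype=int), np.zeros(wrong1, dtype=int),
    ])
    return evaluate(y_true, y_pred)


# ---------------------------------------------------------------------------
# Cross-validation protocols


def kfold_cv(config: EnsembleConfig, X, y, k: int = 10, seed: int = 0) -> MetricsReport:
    """Stratified k-fold CV; metrics pooled over the held-out predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > len(y):
        raise ValueError("k must be <= n")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    y_proba = np.empty((len(y), 2))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        models = train_ensemble(config, X[tr], y[tr], seed=seed + fold)
        pred, proba = fuse_batch(models, X[te], config.fusion)
        y_pred[te] = pred
        y_proba[te] = proba
    return evaluate(y, y_pred, y_proba)


@dataclass
class HoldoutReport:
    """Leave-subjects-out protocol: per-test-set error count and mean PrC."""

    ec_healthy: int
    ec_impaired: int
    mean_prc_healthy: float
    mean_prc_impaired: float


def leave_subjects_out_split(
    vectors: Sequence[FeatureVector], held_out_subject_ids: Sequence[str]
) -> tuple[list[FeatureVector], list[FeatureVector], list[FeatureVector]]:
    """Remove all records of the held-out subjects from training.

    Returns (train, test_healthy, test_impaired); the test sets are the
    held-out subjects' records partitioned by ground-truth label, so no
    subject contributes to both training and testing.
    """
    held = set(held_out_subject_ids)
    known = {v.subject_id for v in vectors}
    unknown = held - known
    if unknown:
        raise ValueError(f"unknown held-out subject ids {sorted(unknown)}")
    train = [v for v in vectors if v.subject_id not in held]
    test_h = [v for v in vectors if v.subject_id in held and v.label == 0]
    test_s = [v for v in vectors if v.subject_id in held and v.label == 1]
    train_labels = {v.label for v in train}
    if train_labels != {0, 1}:
        raise ValueError("held-out set empties a training class")
    return train, test_h, test_s


def evaluate_holdout(
    config: EnsembleConfig,
    train: Sequence[FeatureVector],
    test_h: Sequence[FeatureVector],
    test_s: Sequence[FeatureVector],
    seed: int = 0,
) -> HoldoutReport:
    Xtr = np.array([v.values for v in train])
    ytr = np.array([v.label for v in train], dtype=int)
    models = train_ensemble(config, Xtr, ytr, seed=seed)

    def run(vs):
        if not vs:
            return 0, float("nan")
        X = np.array([v.values for v in vs])
        y = np.array([v.label for v in vs], dtype=int)
        results = [fuse(models, x, config.fusion) for x in X]
        ec = int(sum(r.predicted != t for r, t in zip(results, y)))
        prc = float(np.mean([r.confidence for r in results]))
        return ec, prc

    ec_h, prc_h = run(test_h)
    ec_s, prc_s = run(test_s)
    return HoldoutReport(ec_healthy=ec_h, ec_impaired=ec_s,
                         mean_prc_healthy=prc_h, mean_prc_impaired=prc_s)


# ---------------------------------------------------------------------------
# Feature selection


def correlation_rank(X, y, k: int) -> list[int]:
    """Top-k feature indices by absolute Pearson correlation with the label."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    y = np.asarray(y, dtype=float)
    rs = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0:
            rs.append(0.0)
        else:
            rs.append(abs(pearsonr(col, y)[0]))
    order = np.argsort(rs)[::-1]
    return sorted(order[:k].tolist(), key=lambda j: -rs[j])


def pca_vc(X, vc: float, seed: int = 0) -> PCA:
    """PCA keeping the minimal leading components reaching variance >= vc."""
    if not 0 < vc <= 1:
        raise ValueError("vc must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    n_comp = vc if vc < 1.0 else min(X.shape)
    return PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit(X)


def _cv_accuracy(spec: BaseLearnerSpec, X, y, cols, cv: int, seed: int) -> float:
    est = LEARNER_REGISTRY[spec.name](spec.hp(), seed)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clone_safe(est))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(
            pipe, X[:, cols], y,
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed))
    return float(scores.mean())


def clone_safe(est):
    try:
        return clone(est)
    except Exception:
        return est


def wrapper_subset(
    X, y, spec: BaseLearnerSpec, cv: int = 3, seed: int = 0,
    max_features: Optional[int] = None, tol: float = 1e-4, patience: int = 2,
) -> list[int]:
    """Forward best-first subset search scored by CV accuracy.

    Greedy forward selection that tolerates up to ``patience`` consecutive
    non-improving expansions before stopping (limited backtracking), and
    returns the best-scoring subset seen.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]
    max_features = max_features or n_features
    selected: list[int] = []
    best_subset: list[int] = []
    best_score = -np.inf
    stale = 0
    remaining = list(range(n_features))
    while remaining and len(selected) < max_features:
        trial_scores = [
            (_cv_accuracy(spec, X, y, selected + [j], cv, seed), j) for j in remaining
        ]
        score, j = max(trial_scores)
        selected.append(j)
        remaining.remove(j)
        if score > best_score + tol:
            best_score = score
            best_subset = selected.copy()
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
    return best_subset


def bgwopso(
    X, y, spec: BaseLearnerSpec, n_agents: int = 8, n_iter: int = 20,
    cv: int = 3, seed: int = 0, cardinality_penalty: float = 0.01,
) -> list[int]:
    """Binary hybrid grey-wolf / particle-swarm feature-subset search.

    Agents hold binary masks; the three best agents (alpha, beta, delta)
    steer the rest with PSO-style velocity blending and a sigmoid transfer
    back to bits.  Fitness = CV accuracy minus a small cardinality penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    nf = X.shape[1]
    rng = np.random.default_rng(seed)
    pos = rng.random((n_agents, nf)) > 0.5
    for a in range(n_agents):
        if not pos[a].any():
            pos[a, rng.integers(nf)] = True
    vel = np.zeros((n_agents, nf))

    def fitness(mask):
        cols = np.flatnonzero(mask).tolist()
        if not cols:
            return -np.inf
        acc = _cv_accuracy(spec, X, y, cols, cv, seed)
        return acc - cardinality_penalty * len(cols) / nf

    fits = np.array([fitness(p) for p in pos])
    for it in range(n_iter):
        order = np.argsort(fits)[::-1]
        alpha, beta, delta = pos[order[0]], pos[order[1 % n_agents]], pos[order[2 % n_agents]]
        a_coef = 2.0 * (1.0 - it / n_iter)
        for i in range(n_agents):
            x1 = np.where(rng.random(nf) < _sigmoid_arr(
                -a_coef * (2 * rng.random(nf) - 1) * np.abs(
                    2 * rng.random(nf) * alpha - pos[i])), alpha, pos[i])
            x2 = np.where(rng.random(nf) < 0.5, beta, x1)
            x3 = np.where(rng.random(nf) < 0.5, delta, x2)
            vel[i] = 0.5 * vel[i] + rng.random(nf) * (x3.astype(float) - pos[i].astype(float))
            prob = _sigmoid_arr(2.0 * vel[i])
            newpos = rng.random(nf) < prob
            if not newpos.any():
                newpos[rng.integers(nf)] = True
            newfit = fitness(newpos)
            if newfit > fits[i]:
                pos[i], fits[i] = newpos, newfit
    best = pos[int(np.argmax(fits))]
    return np.flatnonzero(best).tolist()


def _sigmoid_arr(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def select_features(X, y, method: str, **params):
    """Dispatch to the four selection strategies by name."""
    if method == "correlation_rank":
        return correlation_rank(X, y, **params)
    if method == "pca_vc":
        return pca_vc(X, **params)
    if method == "wrapper_subset":
        return wrapper_subset(X, y, **params)
    if method == "bgwopso":
        return bgwopso(X, y, **params)
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# Sequence & scattering classifiers (speech path)


def train_sequence_classifier(
    sequences: Sequence[np.ndarray], labels, config: Optional[dict] = None, seed: int = 0
) -> BiLSTMClassifier:
    """Train the bidirectional recurrent speech classifier.

    Defaults follow the published configuration: two bidirectional layers
    of 100 units, softmax output, RMSProp, at most 10 epochs, batch 128,
    shuffling each epoch, piecewise learning-rate drops by 0.1.
    """
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    if any(s.size == 0 for s in seqs):
        raise ValueError("empty sequence in training data")
    kwargs = {"hidden": 100, "n_layers": 2, "seed": seed}
    if config:
        kwargs.update(config)
    model = BiLSTMClassifier(**kwargs)
    model.fit(seqs, np.asarray(labels))
    return model


class WstClassifier:
    """Scattering-feature classifier: per-window SVM + clip majority vote.

    Each clip contributes one training instance per scattering time window
    (channels vector); a third-order polynomial-kernel maximum-margin
    classifier is trained on the windows, and a clip is labeled by the
    majority vote of its windows' predictions.
    """

    def __init__(self, wst: Optional[WstConfig] = None, seed: int = 0):
        self.wst = wst or WstConfig()
        self.seed = seed

    def fit(self, clips: Sequence[AudioClip], labels) -> "WstClassifier":
        X, y = [], []
        for clip, lab in zip(clips, labels):
            S = wst_features(clip, self.wst)  # (channels, windows)
            for w in range(S.shape[1]):
                X.append(S[:, w])
                y.append(lab)
        self.classes_ = np.unique(labels)
        self._svm = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="poly", degree=3, probability=True,
                        random_state=self.seed)),
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._svm.fit(np.array(X), np.array(y))
        return self

    def predict(self, clips: Sequence[AudioClip]) -> np.ndarray:
        out = []
        for clip in clips:
            S = wst_features(clip, self.wst)
            window_pred = self._svm.predict(S.T)
            out.append(majority_vote(window_pred))
        return np.array(out)


def train_wst_classifier(clips, labels, wst: Optional[WstConfig] = None,
                         seed: int = 0) -> WstClassifier:
    return WstClassifier(wst=wst, seed=seed).fit(clips, labels)
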