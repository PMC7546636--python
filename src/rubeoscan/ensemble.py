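"""Ensemble classification of video segments and majority-vote fusion.

Segment-level features are the fitted GP tail parameters (k, sigma) of a
segment's largest-eigenvalue sample.  A cross-validated optimally weighted
ensemble (COWE) combines the class-1 probabilities of pre-tuned base
learners with simplex weights chosen to minimize the cross-validated mean
squared prediction error.  Subject-level evaluation is leave-one-subject-out
cross-validation with majority-vote fusion of the six segment labels
(4 of 6 required; an exact tie is "undecided").

The reference base configuration is a boosting ensemble of 10 weak shallow
decision trees with learning rate 0.469 and at most 38 splits per tree; a
random-undersampling boosting variant (39 splits) handles the 2:1 class
imbalance, and a 52-learner / 0.107-learning-rate alternative is exposed as
a named configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

C_LABEL = "C"
DM_LABEL = "DM"
UNDECIDED = "undecided"

REFERENCE_CONFIG = {"n_learners": 10, "learning_rate": 0.469, "max_splits": 38}
ALT52_CONFIG = {"n_learners": 52, "learning_rate": 0.107, "max_splits": 38}
RUSBOOST_MAX_SPLITS = 39


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost (SAMME) on per-round random undersamples of the majority class.

    Each boosting round draws a balanced bootstrap: all minority-class
    samples plus an equally sized, boosting-weighted draw from the majority
    class; a shallow tree is fitted and the usual SAMME weight update is
    applied on the full training set.
    """

    def __init__(
        self,
        n_estimators: int = 10,
        learning_rate: float = 0.469,
        max_splits: int = RUSBOOST_MAX_SPLITS,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_splits = max_splits
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("RUSBoost here is a binary classifier")
        rng = np.random.RandomState(self.random_state)
        n = y_enc.size
        sample_weight = np.full(n, 1.0 / n)
        minority = int(np.argmin(np.bincount(y_enc)))
        min_idx = np.flatnonzero(y_enc == minority)
        maj_idx = np.flatnonzero(y_enc != minority)
        self.estimators_ = []
        self.estimator_weights_ = []
        for _ in range(self.n_estimators):
            p_maj = sample_weight[maj_idx] / sample_weight[maj_idx].sum()
            drawn = rng.choice(maj_idx, size=min_idx.size, replace=True, p=p_maj)
            idx = np.concatenate([min_idx, drawn])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1, random_state=rng.randint(2**31 - 1)
            )
            tree.fit(X[idx], y_enc[idx])
            pred = tree.predict(X)
            miss = pred != y_enc
            err = float(np.average(miss, weights=sample_weight))
            if err >= 0.5:
                continue
            err = max(err, 1e-10)
            alpha = self.learning_rate * np.log((1.0 - err) / err)
            sample_weight *= np.exp(alpha * miss)
            sample_weight /= sample_weight.sum()
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
        if not self.estimators_:  # degenerate: fall back to a single tree
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1, random_state=self.random_state
            )
            tree.fit(X, y_enc)
            self.estimators_ = [tree]
            self.estimator_weights_ = [1.0]
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = validate_data(self, X, reset=False)
        total = np.zeros(X.shape[0])
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            total += alpha * (2.0 * tree.predict(X) - 1.0)
        return total / sum(self.estimator_weights_)

    def predict_proba(self, X) -> np.ndarray:
        score = self.decision_scores(X)
        p1 = 1.0 / (1.0 + np.exp(-4.0 * score))  # squash margin to (0, 1)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_scores(X) >= 0).astype(int)]


def default_base_learners(random_state: int | None = None) -> list[tuple[str, BaseEstimator]]:
    """Pre-tuned base learners combined by COWE (reference configuration)."""
    return [
        (
            "boosted_trees",
            GradientBoostingClassifier(
                n_estimators=REFERENCE_CONFIG["n_learners"],
                learning_rate=REFERENCE_CONFIG["learning_rate"],
                max_leaf_nodes=REFERENCE_CONFIG["max_splits"] + 1,
                random_state=random_state,
            ),
        ),
        (
            "rusboost",
            RUSBoostClassifier(
                n_estimators=REFERENCE_CONFIG["n_learners"],
                learning_rate=REFERENCE_CONFIG["learning_rate"],
                max_splits=RUSBOOST_MAX_SPLITS,
                random_state=random_state,
            ),
        ),
        ("lda", LinearDiscriminantAnalysis()),
        ("knn", KNeighborsClassifier(n_neighbors=5)),
    ]


def alt52_base_learners(random_state: int | None = None) -> list[tuple[str, BaseEstimator]]:
    """The 52-learner / 0.107-learning-rate alternative configuration."""
    learners = default_base_learners(random_state)
    learners[0] = (
        "boosted_trees",
        GradientBoostingClassifier(
            n_estimators=ALT52_CONFIG["n_learners"],
            learning_rate=ALT52_CONFIG["learning_rate"],
            max_leaf_nodes=ALT52_CONFIG["max_splits"] + 1,
            random_state=random_state,
        ),
    )
    return learners


def _simplex_project(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort algorithm)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u + (1.0 - css) / np.arange(1, v.size + 1) > 0)[-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _mse(P: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    return float(np.mean((P.T @ w - y) ** 2))


def _projected_gradient(P: np.ndarray, y: np.ndarray, w0: np.ndarray,
                        max_iter: int = 2000, tol: float = 1e-12) -> np.ndarray:
    n = y.size
    G = P @ P.T / n
    b = P @ y / n
    lip = max(float(np.linalg.eigvalsh(G).max()), 1e-12)
    step = 1.0 / (2.0 * lip)
    w = w0.copy()
    for _ in range(max_iter):
        grad = 2.0 * (G @ w - b)
        w_new = _simplex_project(w - step * grad)
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def _simplex_grid(m: int, resolution: float = 0.01):
    steps = int(round(1.0 / resolution))
    if m == 1:
        yield np.array([1.0])
    elif m == 2:
        for i in range(steps + 1):
            yield np.array([i, steps - i]) / steps
    elif m == 3:
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                yield np.array([i, j, steps - i - j]) / steps
    else:
        raise ValueError("exhaustive grid supported only for m <= 3")


def cowe_weights(
    base_predictions: np.ndarray,
    labels: np.ndarray,
    solver: str = "auto",
    n_starts: int = 16,
    random_state: int | None = 0,
) -> np.ndarray:
    """Simplex weights minimizing the MSE of the weighted ensemble prediction.

    ``base_predictions`` is an (n_learners, n_samples) matrix of
    cross-validated class-1 probabilities; ``labels`` are 0/1.  The solver
    is projected gradient with multistart (vertex starts plus random
    starts, always including the uniform start, which also breaks exact
    ties toward uniformity), or an exhaustive 0.01-resolution simplex grid
    for up to three learners (``solver="grid"``).
    """
    P = np.atleast_2d(np.asarray(base_predictions, dtype=np.float64))
    y = np.asarray(labels, dtype=np.float64).ravel()
    if P.shape[1] != y.size:
        raise ValueError(f"predictions ({P.shape}) and labels ({y.size}) disagree")
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")
    m = P.shape[0]
    if m == 1:
        return np.array([1.0])
    if solver == "grid":
        best_w, best_mse = None, np.inf
        for w in _simplex_grid(m):
            cur = _mse(P, y, w)
            if cur < best_mse - 1e-15:
                best_mse, best_w = cur, w
        return best_w
    uniform = np.full(m, 1.0 / m)
    w_best = _projected_gradient(P, y, uniform)
    mse_best = _mse(P, y, w_best)
    starts = [np.eye(m)[i] for i in range(m)]
    rng = np.random.RandomState(random_state)
    for _ in range(max(0, n_starts - m - 1)):
        raw = rng.dirichlet(np.ones(m))
        starts.append(raw)
    for w0 in starts:
        w = _projected_gradient(P, y, w0)
        cur = _mse(P, y, w)
        if cur < mse_best - 1e-9:  # keep uniform-start solution on ties
            mse_best, w_best = cur, w
    return w_best


class COWEClassifier(BaseEstimator, ClassifierMixin):
    """Cross-validated optimally weighted ensemble of base learners.

    Out-of-fold class-1 probabilities of each base learner are collected
    with stratified k-fold cross-validation; simplex weights minimizing the
    cross-validated MSE are found by projected gradient; the learners are
    then refitted on the full training set.  A weighted score >= 0.5 maps
    to the positive (DM) class.

    Parameters
    ----------
    base_learners : list of (name, estimator), or "reference"/"alt52"
    cv : int
        Number of stratified folds for weight estimation (5 by default).
    random_state : int or None
    """

    def __init__(self, base_learners="reference", cv: int = 5, random_state: int | None = 0):
        self.base_learners = base_learners
        self.cv = cv
        self.random_state = random_state

    def _make_learners(self):
        if self.base_learners == "reference":
            return default_base_learners(self.random_state)
        if self.base_learners == "alt52":
            return alt52_base_learners(self.random_state)
        return [(name, clone(est)) for name, est in self.base_learners]

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("COWEClassifier is a binary classifier")
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            raise ValueError("need at least 2 training samples per class")
        learners = self._make_learners()
        n_folds = int(min(self.cv, counts.min()))
        oof = np.zeros((len(learners), y_enc.size))
        if n_folds >= 2:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
            for train_idx, test_idx in skf.split(X, y_enc):
                for row, (_, est) in enumerate(learners):
                    model = clone(est)
                    model.fit(X[train_idx], y_enc[train_idx])
                    oof[row, test_idx] = model.predict_proba(X[test_idx])[:, 1]
        else:  # too few samples to cross-validate: use resubstitution scores
            for row, (_, est) in enumerate(learners):
                model = clone(est)
                model.fit(X, y_enc)
                oof[row] = model.predict_proba(X)[:, 1]
        self.weights_ = cowe_weights(oof, y_enc, random_state=self.random_state)
        self.cv_mse_ = _mse(oof, y_enc.astype(float), self.weights_)
        self.learner_names_ = [name for name, _ in learners]
        self.learners_ = []
        for _, est in learners:
            model = clone(est)
            model.fit(X, y_enc)
            self.learners_.append(model)
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Weighted ensemble class-1 probability in [0, 1]."""
        check_is_fitted(self, "learners_")
        X = validate_data(self, X, reset=False)
        probs = np.stack([m.predict_proba(X)[:, 1] for m in self.learners_])
        return probs.T @ self.weights_

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        # score exactly 0.5 resolves to the positive (DM) class
        return self.classes_[(self.decision_scores(X) >= 0.5).astype(int)]


def classify_segment(model: COWEClassifier, features) -> tuple[str, float]:
    """Label one segment's (k, sigma) feature vector; score >= 0.5 -> DM."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    score = float(model.decision_scores(features)[0])
    label = model.classes_[int(score >= 0.5)]
    return str(label), score


@dataclass
class SubjectDecision:
    """Fused subject-level decision from per-segment labels."""

    subject_id: str
    segment_labels: list[str]
    final: str
    votes: dict = field(default_factory=dict)


def majority_vote(segment_labels: list[str], subject_id: str = "") -> SubjectDecision:
    """Fuse 1-6 segment labels into a subject decision.

    With six segments the winning class needs at least four votes; with
    fewer segments a strict majority suffices.  An exact tie (or a
    six-segment 3-3 split) is "undecided".
    """
    labels = list(segment_labels)
    if not labels:
        raise ValueError("no segment labels to fuse")
    if len(labels) > 6:
        raise ValueError(f"at most 6 segments per subject, got {len(labels)}")
    votes = Counter(labels)
    top, top_count = votes.most_common(1)[0]
    threshold = 4 if len(labels) == 6 else len(labels) // 2 + 1
    runner_up = max((c for lbl, c in votes.items() if lbl != top), default=0)
    if top_count >= threshold and top_count > runner_up:
        final = top
    else:
        final = UNDECIDED
    return SubjectDecision(
        subject_id=subject_id, segment_labels=labels, final=final, votes=dict(votes)
    )


def _metrics_from_decisions(decisions: list[SubjectDecision], truth: dict[str, str]) -> dict:
    tp = sum(1 for d in decisions if truth[d.subject_id] == DM_LABEL and d.final == DM_LABEL)
    tn = sum(1 for d in decisions if truth[d.subject_id] == C_LABEL and d.final == C_LABEL)
    n_dm = sum(1 for s in truth.values() if s == DM_LABEL)
    n_c = sum(1 for s in truth.values() if s == C_LABEL)
    undecided = sum(1 for d in decisions if d.final == UNDECIDED)
    decided_correct = tp + tn
    return {
        "n_subjects": len(decisions),
        "n_dm": n_dm,
        "n_c": n_c,
        "sensitivity": 100.0 * tp / n_dm if n_dm else float("nan"),
        "specificity": 100.0 * tn / n_c if n_c else float("nan"),
        "accuracy": 100.0 * decided_correct / len(decisions) if decisions else float("nan"),
        "undecided": undecided,
    }


def loo_xv(
    features: pd.DataFrame,
    base_learners="reference",
    cv: int = 5,
    random_state: int | None = 0,
    feature_columns: list[str] | None = None,
) -> dict:
    """Leave-one-subject-out cross-validation with majority-vote fusion.

    ``features`` must have columns subject, segment, k, sigma, label
    (label in {"C", "DM"}); optional extra feature columns can be selected
    with ``feature_columns``.  Every fold holds out all segments of one
    subject (a leakage assertion verifies this), classifies them with a
    COWE ensemble trained on the remaining subjects, and fuses the segment
    labels by majority vote.  Undecided subjects count against
    sensitivity/specificity and are also reported separately.
    """
    required = {"subject", "segment", "k", "sigma", "label"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features missing columns: {sorted(missing)}")
    cols = feature_columns or ["k", "sigma"]
    subjects = features["subject"].unique()
    truth = features.groupby("subject")["label"].first().to_dict()
    labels = pd.Series(truth)
    if (labels == DM_LABEL).sum() < 2 or (labels == C_LABEL).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    decisions: list[SubjectDecision] = []
    pooled_scores: list[float] = []
    pooled_truth: list[int] = []
    for held_out in subjects:
        train = features[features["subject"] != held_out]
        test = features[features["subject"] == held_out]
        assert held_out not in set(train["subject"]), "subject leakage across the fold split"
        model = COWEClassifier(base_learners=base_learners, cv=cv, random_state=random_state)
        model.fit(train[cols].to_numpy(), (train["label"] == DM_LABEL).astype(int).to_numpy())
        scores = model.decision_scores(test[cols].to_numpy())
        seg_labels = [DM_LABEL if s >= 0.5 else C_LABEL for s in scores]
        decisions.append(majority_vote(seg_labels, subject_id=str(held_out)))
        pooled_scores.extend(scores.tolist())
        pooled_truth.extend((test["label"] == DM_LABEL).astype(int).tolist())
    metrics = _metrics_from_decisions(decisions, truth)
    seg_pred = np.asarray(pooled_scores) >= 0.5
    seg_true = np.asarray(pooled_truth, dtype=bool)
    metrics["segment_accuracy"] = 100.0 * float(np.mean(seg_pred == seg_true))
    metrics["segment_sensitivity"] = (
        100.0 * float(np.mean(seg_pred[seg_true])) if seg_true.any() else float("nan")
    )
    metrics["segment_specificity"] = (
        100.0 * float(np.mean(~seg_pred[~seg_true])) if (~seg_true).any() else float("nan")
    )
    fpr, tpr, _ = roc_curve(pooled_truth, pooled_scores)
    return {
        "decisions": decisions,
        "metrics": metrics,
        "n_folds": len(subjects),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(auc(fpr, tpr))},
    }


class SgnKVoteClassifier(BaseEstimator, ClassifierMixin):
    """Unsupervised tail-sign rule: k >= 0 -> C, k < 0 -> DM.

    ``fit`` only records the feature layout (the rule has no parameters);
    it exists so the classifier composes with scikit-learn tooling.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X)
        self.classes_ = np.array([C_LABEL, DM_LABEL])
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = validate_data(self, X, reset=False)
        k = X[:, 0]
        return np.where(k >= 0, C_LABEL, DM_LABEL)


def unsupervised_sgn_classifier(subject_reports: dict[str, list]) -> list[SubjectDecision]:
    """Subject decisions from per-segment tail verdicts, no training.

    ``subject_reports`` maps subject id to that subject's list of
    TailFitReport (one per segment).  Each SOC_powerlaw verdict votes C,
    each TW_random verdict votes DM; fusion uses the same majority rule as
    the supervised path.
    """
    from .tails import SOC_POWERLAW

    if not subject_reports:
        raise ValueError("no subjects supplied")
    decisions = []
    for subject_id, reports in subject_reports.items():
        if not reports:
            raise ValueError(f"subject {subject_id} has no tail fits")
        seg_labels = [
            C_LABEL if r.verdict == SOC_POWERLAW else DM_LABEL for r in reports
        ]
        decisions.append(majority_vote(seg_labels, subject_id=subject_id))
    return decisions
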