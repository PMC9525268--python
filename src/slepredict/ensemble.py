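"""Bagged majority-voting ensemble for the Differential approach.

One sub-ensemble of six non-temporal base learners (decision tree, random
forest, logistic regression, Gaussian naive Bayes, feed-forward neural
network, RBF support-vector machine) is fitted per balanced bag; an
instance's score is the mean over bags of the bag's per-learner class-1
probability (soft voting, default) or vote fraction (hard voting).
Distance- and gradient-based learners see standardized features; tree
learners see the raw panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import PanelScaler
from .imbalance import make_bags

SIX_FAMILIES = ("tree", "forest", "logreg", "gnb", "mlp", "svm")
#: families that receive unscaled features
TREE_FAMILIES = frozenset({"tree", "forest"})


def _make_learner(family: str, params: dict, seed: int):
    if family == "tree":
        base = DecisionTreeClassifier(max_depth=5, random_state=seed)
    elif family == "forest":
        base = RandomForestClassifier(n_estimators=100, max_depth=5, random_state=seed)
    elif family == "logreg":
        base = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    elif family == "gnb":
        base = GaussianNB()
    elif family == "mlp":
        base = MLPClassifier(hidden_layer_sizes=(16,), max_iter=300, random_state=seed)
    elif family == "svm":
        # RBF SVM with Platt-scaled probability outputs
        svc = SVC(C=1.0, kernel="rbf", random_state=seed)
        if params:
            svc.set_params(**params)
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    else:
        raise ValueError(f"unknown base-learner family {family!r}")
    if params:
        base.set_params(**params)
    return base


def default_grids() -> dict[str, list[dict]]:
    """Small per-family hyperparameter grids for nested-CV selection."""
    return {
        "tree": [{"max_depth": d} for d in (3, 5, 10)],
        "forest": [{"n_estimators": 100, "max_depth": d} for d in (5, None)],
        "logreg": [{"C": c} for c in (0.1, 1.0, 10.0)],
        "gnb": [{}],
        "mlp": [{"hidden_layer_sizes": (h,)} for h in (16, 64)],
        "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    }


@dataclass(frozen=True)
class EnsembleSpec:
    """Declarative description of the six-learner voting ensemble."""

    families: tuple[str, ...] = SIX_FAMILIES
    grids: dict[str, list[dict]] = dc_field(default_factory=default_grids)
    voting: str = "soft"
    seed: int | None = None

    def __post_init__(self) -> None:
        if tuple(sorted(self.families)) != tuple(sorted(SIX_FAMILIES)):
            raise ValueError("an EnsembleSpec requires exactly the six base-learner families")
        if self.voting not in ("soft", "hard"):
            raise ValueError("voting must be 'soft' or 'hard'")


class BaggedDifferentialClassifier(ClassifierMixin, BaseEstimator):
    """Six-learner voting ensemble trained on balanced undersampled bags.

    Parameters
    ----------
    n_bags : number of balanced bags (each holds all minority instances
        plus an equal number of majority instances drawn with replacement).
    voting : 'soft' averages the six learners' class-1 probabilities within
        a bag; 'hard' uses the fraction of learners voting class 1.
    scale : standardize continuous columns (fitted on the training data
        only); tree-family learners always receive unscaled features.
    learner_params : mapping family name -> sklearn parameter overrides,
        e.g. ``{"logreg": {"C": 0.1}, "mlp": {"hidden_layer_sizes": (64,)}}``.
    families : subset of the six families to use (defaults to all six);
        useful for degenerate/diagnostic configurations.
    binary_mask : optional per-column pass-through mask for the scaler
        (auto-detected from the data when omitted).
    """

    def __init__(
        self,
        n_bags: int = 100,
        voting: str = "soft",
        scale: bool = True,
        learner_params: dict | None = None,
        families: tuple[str, ...] | None = None,
        binary_mask: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.n_bags = n_bags
        self.voting = voting
        self.scale = scale
        self.learner_params = learner_params
        self.families = families
        self.binary_mask = binary_mask
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("BaggedDifferentialClassifier requires binary labels")
        if self.voting not in ("soft", "hard"):
            raise ValueError("voting must be 'soft' or 'hard'")
        self.n_features_in_ = X.shape[1]
        y01 = (y == self.classes_[1]).astype(int)

        rng = np.random.default_rng(self.random_state)
        bag_seed = int(rng.integers(2**31))
        self.bags_ = make_bags(y01, n_bags=self.n_bags, seed=bag_seed)

        if self.scale:
            self.scaler_ = PanelScaler(binary_mask=self.binary_mask).fit(X)
            X_scaled = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            X_scaled = X

        families = tuple(self.families) if self.families is not None else SIX_FAMILIES
        lp = self.learner_params or {}
        self.submodels_ = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for bag in self.bags_.bags:
                fitted = {}
                for fam in families:
                    seed = int(rng.integers(2**31))
                    learner = _make_learner(fam, lp.get(fam, {}), seed)
                    Xb = X[bag] if fam in TREE_FAMILIES else X_scaled[bag]
                    fitted[fam] = learner.fit(Xb, y01[bag])
                self.submodels_.append(fitted)
        return self

    def _bag_scores(self, X_raw: np.ndarray, X_scaled: np.ndarray) -> np.ndarray:
        """n_bags x n_instances matrix of per-bag class-1 scores."""
        scores = np.empty((len(self.submodels_), X_raw.shape[0]))
        for b, fitted in enumerate(self.submodels_):
            per_learner = []
            for fam, learner in fitted.items():
                Xp = X_raw if fam in TREE_FAMILIES else X_scaled
                if self.voting == "soft":
                    pos = list(learner.classes_).index(1)
                    per_learner.append(learner.predict_proba(Xp)[:, pos])
                else:
                    per_learner.append((learner.predict(Xp) == 1).astype(float))
            scores[b] = np.mean(per_learner, axis=0)
        return scores

    def decision_scores(self, X) -> np.ndarray:
        """Mean over bags of bag scores, in [0, 1]."""
        check_is_fitted(self, "submodels_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was fitted with {self.n_features_in_}"
            )
        X_scaled = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self._bag_scores(X, X_scaled).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return self.classes_[(s >= 0.5).astype(int)]
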