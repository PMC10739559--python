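"""Seven-classifier case/control prediction ensemble.

Five probabilistic base learners — random forest, RBF-kernel SVM,
XGBoost, k-nearest neighbours and a multi-layer perceptron — are trained
on a shared standardized matrix of the selected biomarkers, then
aggregated by a soft (mean-probability) and a hard (majority-label)
voter. Standardization parameters are fitted on training rows only; trees
are scale-invariant so the single shared matrix is harmless for them.

Hyperparameters are fixed, sensible defaults (exposed in
:class:`EnsembleConfig`); there is no tuning loop. Tie conventions are
asymmetric and deliberate: the soft voter calls a 0.5 probability a case
(the ``>= 0.5`` rule), while a hard-vote tie — only possible when a user
disables members, leaving an even count — resolves to control and is
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cigt import CIGTDataset
from .select import FeatureSet

logger = logging.getLogger(__name__)

BASE_MEMBERS = ("rf", "svm", "xgb", "knn", "mlp")
VOTERS = ("soft_vote", "hard_vote")


@dataclass(frozen=True)
class EnsembleConfig:
    """Fixed hyperparameters of the base learners."""

    enabled: tuple[str, ...] = BASE_MEMBERS
    rf_n_estimators: int = 100
    svm_c: float = 1.0
    knn_k: int = 5
    mlp_hidden: int = 100
    mlp_max_iter: int = 500

    def __post_init__(self) -> None:
        unknown = sorted(set(self.enabled) - set(BASE_MEMBERS))
        if unknown:
            raise ValueError(f"unknown ensemble members: {unknown}")
        if not self.enabled:
            raise ValueError("at least one base member must be enabled")


def _build_members(cfg: EnsembleConfig, seed: int) -> dict[str, object]:
    builders = {
        "rf": lambda: RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators, random_state=seed, n_jobs=1
        ),
        "svm": lambda: SVC(
            C=cfg.svm_c, kernel="rbf", probability=True, random_state=seed
        ),
        "xgb": lambda: XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        ),
        "knn": lambda: KNeighborsClassifier(n_neighbors=cfg.knn_k),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(cfg.mlp_hidden,),
            max_iter=cfg.mlp_max_iter,
            random_state=seed,
        ),
    }
    return {name: builders[name]() for name in cfg.enabled}


@dataclass
class EnsembleModel:
    """Fitted ensemble sharing one biomarker list and one training seed."""

    members: dict[str, object]
    feature_names: tuple[str, ...]
    scaler: StandardScaler
    seed: int
    config: EnsembleConfig
    train_matrix_: np.ndarray | None = field(default=None, repr=False)

    @property
    def enabled(self) -> tuple[str, ...]:
        return tuple(self.members)

    def transform(self, ds: CIGTDataset) -> np.ndarray:
        """Standardize the selected features of a cohort with train-fitted params."""
        return self.scaler.transform(ds.matrix(self.feature_names))

    def member_probabilities(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Case-probability of every base member on standardized rows."""
        return {
            name: clf.predict_proba(X)[:, 1] for name, clf in self.members.items()
        }

    def predict_table(self, ds: CIGTDataset) -> pd.DataFrame:
        """Per-patient labels and case-probabilities for all seven classifiers."""
        X = self.transform(ds)
        probs = self.member_probabilities(X)
        out = pd.DataFrame(index=pd.Index(ds.sample_ids, name="sample_id"))
        for name in self.enabled:
            out[f"{name}_probability"] = probs[name]
            out[f"{name}_label"] = (probs[name] >= 0.5).astype(int)
        member_labels = np.column_stack([out[f"{n}_label"] for n in self.enabled])
        member_probs = np.column_stack([probs[n] for n in self.enabled])
        sv = [soft_vote(row) for row in member_probs]
        out["soft_vote_probability"] = [p for _, p in sv]
        out["soft_vote_label"] = [lab for lab, _ in sv]
        out["hard_vote_probability"] = member_labels.mean(axis=1)
        out["hard_vote_label"] = [hard_vote(row) for row in member_labels]
        return out


def soft_vote(probabilities: Sequence[float]) -> tuple[int, float]:
    """Mean of member case-probabilities; label 1 iff the mean is >= 0.5."""
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.size == 0:
        raise ValueError("soft vote needs at least one member probability")
    p = float(probabilities.mean())
    return (1 if p >= 0.5 else 0), p


def hard_vote(labels: Sequence[int]) -> int:
    """Majority label; an exact tie resolves to control (0) and is logged."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("hard vote needs at least one member label")
    ones = int(labels.sum())
    zeros = labels.size - ones
    if ones == zeros:
        logger.info("hard-vote tie (%d vs %d); resolving to control", ones, zeros)
        return 0
    return 1 if ones > zeros else 0


def train_ensemble(
    train: CIGTDataset,
    features: FeatureSet | Sequence[str],
    seed: int,
    config: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Fit the enabled base classifiers on standardized selected features.

    Raises if the training cohort is single-class or names a feature the
    cohort lacks. Refitting with identical inputs and seed reproduces
    identical predictions.
    """
    config = config or EnsembleConfig()
    names = tuple(features.features if isinstance(features, FeatureSet) else features)
    missing = [f for f in names if f not in train.feature_names]
    if missing:
        raise KeyError(f"features absent from training cohort: {missing}")
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(
            f"training requires >=2 samples of each class; got {dict(zip(classes, counts))}"
        )
    X_raw = train.matrix(names)
    scaler = StandardScaler().fit(X_raw)
    X = scaler.transform(X_raw)
    members = _build_members(config, seed)
    for name, clf in members.items():
        clf.fit(X, train.labels)
    return EnsembleModel(
        members=members,
        feature_names=names,
        scaler=scaler,
        seed=seed,
        config=config,
        train_matrix_=X,
    )


def evaluate(
    model: EnsembleModel, test: CIGTDataset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predictions plus accuracy / F1 / ROC-AUC for all seven classifiers.

    On a single-class evaluation set ROC-AUC is undefined and reported as
    NaN with a warning; accuracy and F1 are still computed.
    """
    preds = model.predict_table(test)
    y = test.labels
    single_class = len(np.unique(y)) < 2
    if single_class:
        logger.warning("evaluation set contains a single class; ROC-AUC undefined")
    rows = []
    for clf in list(model.enabled) + list(VOTERS):
        labels = preds[f"{clf}_label"].to_numpy()
        probs = preds[f"{clf}_probability"].to_numpy()
        auc = np.nan if single_class else roc_auc_score(y, probs)
        rows.append(
            {
                "classifier": clf,
                "accuracy": accuracy_score(y, labels),
                "f1": f1_score(y, labels, zero_division=0),
                "roc_auc": auc,
                "n_eval": len(y),
            }
        )
    return preds, pd.DataFrame(rows)
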