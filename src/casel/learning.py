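"""Model training, cross-validation and repeat-averaged consensus predictions.

Ten standard classification algorithms are used with library defaults:
logistic regression (LR), linear discriminant analysis (LDA), k-nearest
neighbours (KNN), a decision tree (CART), Gaussian naive Bayes (NB), a
support vector machine (SVM), AdaBoost (AB), gradient boosting (GBM),
random forest (RF) and extra trees (ET).  Scale-sensitive learners
(LR, LDA, KNN, SVM) are wrapped in a standardisation step; the SVM exposes
class probabilities through its built-in Platt calibration layer.

Every prediction carries a probability score: the larger of the two class
membership probabilities, hence a value in [0.5, 1].  Training is repeated
R times (default 10) with per-repeat random states derived from a master
seed; labels and scores are averaged over repeats, the final label is the
rounded mean label (a 0.5 tie breaks to inactive, the conservative choice
for screening), and the mean score places the prediction in a probability
bin for confidence-stratified reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import (
    MetricSet,
    compute_metrics,
    confusion_from_labels,
    probability_bin,
)

#: The ten algorithm abbreviations, in canonical order.
ALGORITHMS: Tuple[str, ...] = (
    "LR", "LDA", "KNN", "CART", "NB", "SVM", "AB", "GBM", "RF", "ET",
)

#: Learners that require feature standardisation.
_SCALED = {"LR", "LDA", "KNN", "SVM"}

#: Default number of independent repeats.
DEFAULT_REPEATS = 10
#: Default cross-validation folds.
DEFAULT_K = 10
#: Default held-out test fraction (75:25 split).
DEFAULT_TEST_FRACTION = 0.25


@dataclass(frozen=True)
class AlgorithmSpec:
    """An algorithm choice with optional setting overrides."""

    abbreviation: str
    settings: Mapping[str, object] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.abbreviation not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.abbreviation!r}; choose from {ALGORITHMS}"
            )


def make_estimator(
    algorithm: str | AlgorithmSpec, seed: Optional[int] = None
):
    """Build a fresh estimator exposing ``predict_proba``.

    Settings are library defaults unless overridden through an
    :class:`AlgorithmSpec`; deterministic learners ignore the seed.
    """
    spec = algorithm if isinstance(algorithm, AlgorithmSpec) else AlgorithmSpec(algorithm)
    settings = dict(spec.settings or {})
    abbrev = spec.abbreviation
    if abbrev == "LR":
        est = LogisticRegression(max_iter=1000, random_state=seed, **settings)
    elif abbrev == "LDA":
        est = LinearDiscriminantAnalysis(**settings)
    elif abbrev == "KNN":
        est = KNeighborsClassifier(**settings)
    elif abbrev == "CART":
        est = DecisionTreeClassifier(random_state=seed, **settings)
    elif abbrev == "NB":
        est = GaussianNB(**settings)
    elif abbrev == "SVM":
        # margin-based learner: probabilities via an explicit calibration layer
        est = CalibratedClassifierCV(
            SVC(random_state=seed, **settings), ensemble=False
        )
    elif abbrev == "AB":
        est = AdaBoostClassifier(random_state=seed, **settings)
    elif abbrev == "GBM":
        est = GradientBoostingClassifier(random_state=seed, **settings)
    elif abbrev == "RF":
        est = RandomForestClassifier(random_state=seed, **settings)
    elif abbrev == "ET":
        est = ExtraTreesClassifier(random_state=seed, **settings)
    else:  # pragma: no cover - guarded by AlgorithmSpec
        raise ValueError(abbrev)
    if abbrev in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split, deterministic given the seed.

    Returns ``(train_idx, test_idx, y_train, y_test)`` — indices, so callers
    can carry compound ids alongside the feature matrix.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 members for a stratified split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return train_idx, test_idx, y[train_idx], y[test_idx]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str | AlgorithmSpec,
    k: int = DEFAULT_K,
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Stratified k-fold cross-validation with per-fold metrics and mean +- SD.

    Folds are disjoint and their union is the whole set.  Population SD is
    reported across folds.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    minority = int(np.bincount(y).min())
    if k > minority:
        raise ValueError(f"k={k} exceeds minority class size {minority}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: List[MetricSet] = []
    covered = np.zeros(len(y), dtype=bool)
    for fold_seed, (train_ix, test_ix) in enumerate(splitter.split(X, y)):
        est = make_estimator(algorithm, seed=None if seed is None else seed + fold_seed)
        est.fit(X[train_ix], y[train_ix])
        pred = est.predict(X[test_ix])
        covered[test_ix] = True
        fold_metrics.append(compute_metrics(confusion_from_labels(y[test_ix], pred)))
    assert covered.all()
    summary: Dict[str, object] = {"folds": fold_metrics, "k": k}
    for name in ("accuracy", "mcc", "precision", "recall"):
        vals = [getattr(m, name) for m in fold_metrics]
        defined = [v for v in vals if v is not None]
        summary[f"{name}_mean"] = float(np.mean(defined)) if defined else None
        summary[f"{name}_sd"] = float(np.std(defined)) if defined else None
    return summary


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    algorithm: str | AlgorithmSpec,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Train on one set, predict labels + probability scores on another.

    The retained score per instance is the larger of the two class
    probabilities (hence in [0.5, 1]); at an exact 0.5 tie the label breaks
    to inactive (0).
    """
    X_train = np.asarray(X_train)
    X_eval = np.asarray(X_eval)
    if X_train.shape[1] != X_eval.shape[1]:
        raise ValueError(
            f"feature mismatch: train has {X_train.shape[1]} columns, "
            f"evaluation set has {X_eval.shape[1]}"
        )
    est = make_estimator(algorithm, seed=seed)
    est.fit(X_train, y_train)
    proba = est.predict_proba(X_eval)
    classes = list(est.classes_)
    p_active = proba[:, classes.index(1)]
    labels = (p_active > 0.5).astype(int)  # ties -> inactive
    scores = np.maximum(p_active, 1.0 - p_active)
    return labels, scores


@dataclass
class ConsensusPrediction:
    """Repeat-averaged prediction for one instance."""

    compound_id: str
    isoform: str
    repeat_labels: np.ndarray
    repeat_scores: np.ndarray
    mean_label: float
    sd_label: float
    mean_score: float
    sd_score: float
    final_label: int
    probability_bin: float


def repeat_consensus(
    repeat_labels: np.ndarray,
    repeat_scores: np.ndarray,
    compound_ids: Sequence[str],
    isoform: str = "",
) -> List[ConsensusPrediction]:
    """Average per-repeat predictions into consensus predictions.

    ``repeat_labels`` and ``repeat_scores`` are (R x n) arrays over the same
    n instances.  The final label is round(mean label) with a 0.5 tie
    breaking to inactive; the probability bin comes from the mean score.
    """
    labels = np.atleast_2d(np.asarray(repeat_labels, dtype=float))
    scores = np.atleast_2d(np.asarray(repeat_scores, dtype=float))
    if labels.shape != scores.shape:
        raise ValueError("repeat labels and scores must have the same shape")
    if labels.shape[1] != len(compound_ids):
        raise ValueError(
            f"repeats cover {labels.shape[1]} instances but "
            f"{len(compound_ids)} ids were given"
        )
    out: List[ConsensusPrediction] = []
    for j, cid in enumerate(compound_ids):
        mean_label = float(labels[:, j].mean())
        mean_score = float(scores[:, j].mean())
        out.append(ConsensusPrediction(
            compound_id=cid,
            isoform=isoform,
            repeat_labels=labels[:, j].astype(int),
            repeat_scores=scores[:, j],
            mean_label=mean_label,
            sd_label=float(labels[:, j].std()),
            mean_score=mean_score,
            sd_score=float(scores[:, j].std()),
            final_label=int(mean_label > 0.5),  # 0.5 tie -> inactive
            probability_bin=probability_bin(mean_score),
        ))
    return out


def repeat_seeds(master_seed: int, repeats: int = DEFAULT_REPEATS) -> List[int]:
    """Independent per-repeat random states derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(repeats)]


def run_repeated(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    eval_ids: Sequence[str],
    algorithm: str | AlgorithmSpec,
    repeats: int = DEFAULT_REPEATS,
    master_seed: int = 0,
    isoform: str = "",
) -> List[ConsensusPrediction]:
    """R independent train/predict experiments averaged into consensus calls."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    seeds = repeat_seeds(master_seed, repeats)
    all_labels = np.empty((repeats, len(eval_ids)))
    all_scores = np.empty((repeats, len(eval_ids)))
    for r, seed in enumerate(seeds):
        labels, scores = fit_predict(X_train, y_train, X_eval, algorithm, seed=seed)
        all_labels[r] = labels
        all_scores[r] = scores
    return repeat_consensus(all_labels, all_scores, eval_ids, isoform=isoform)
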