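"""Leakage-safe five-fold movement-vs-idle classification.

The same stratified folds are reused across classifiers and feature
subsets; per fold, the template and the feature standardization are fit
on the training epochs only.  Classifiers: Random Forest (128 trees),
linear SVM, LDA, and KNN with K = round(sqrt(n_train)).  The reported
accuracy is the median across folds; the chance level is the upper
95%-confidence bound of a balanced binomial guesser for the test size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .epochs import EpochSet
from .features import (
    FeatureMatrix,
    Template,
    assemble_features,
    band_power,
    build_template,
    template_xcorr,
    temporal_means,
)

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("rf", "svm", "lda", "knn")
MOVEMENT, IDLE = 1, 0


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "rf"
    rf_trees: int = 128
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified k-fold assignment, shared across comparisons."""

    assignments: tuple[int, ...]  # fold id per epoch
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) != fold)


@dataclass(frozen=True)
class ChanceLevel:
    n_test: int
    alpha: float
    p0: float
    threshold: float


@dataclass
class FoldArtifacts:
    """Trained per-fold objects, retained for leakage auditing."""

    template: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    model: object


@dataclass
class ResultRecord:
    scenario: str
    electrode_set: str
    feature_subset: str
    classifier: str
    fold_accuracies: tuple[float, ...]
    median_accuracy: float
    n_test_per_fold: tuple[int, ...]
    fold_artifacts: list[FoldArtifacts] = field(default_factory=list)


def knn_k(n_train: int) -> int:
    """K = sqrt(training-set size), rounded to the nearest integer, >= 1."""
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    return max(1, int(np.floor(np.sqrt(n_train) + 0.5)))


def chance_level(n_test: int, alpha: float = 0.05, p0: float = 0.5) -> ChanceLevel:
    """Upper binomial confidence bound on a no-information classifier.

    threshold = (smallest k with Binomial(n_test, p0) CDF >= 1 - alpha)
    divided by n_test; e.g. n_test=100 -> 0.58.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = int(stats.binom.ppf(1.0 - alpha, n_test, p0))
    return ChanceLevel(n_test, alpha, p0, k / n_test)


def plan_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified shuffled k-fold partition, deterministic under seed."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    if labels.size < k:
        raise ValueError(f"need at least k={k} epochs")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return FoldPlan(tuple(int(a) for a in assignment), k, seed)


def make_classifier(spec: ClassifierSpec, n_train: int):
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees, random_state=spec.seed
        )
    if spec.kind == "svm":
        return SVC(kernel="linear", C=spec.svm_c)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    return KNeighborsClassifier(n_neighbors=knn_k(n_train))


def balance_idle(
    movement: EpochSet, idle: EpochSet, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Seeded down-sampling of idle epochs to the movement count."""
    if idle.n_epochs < movement.n_epochs:
        raise ValueError(
            f"only {idle.n_epochs} idle epochs for {movement.n_epochs} movement epochs"
        )
    if idle.n_epochs == movement.n_epochs:
        return movement, idle
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(idle.n_epochs, size=movement.n_epochs, replace=False))
    return movement, idle.subset(keep)


def _feature_parts(
    epochs: EpochSet,
    template: Template,
    interval: float,
    normalized_xcorr: bool,
    welch_segment_s: float,
    welch_overlap: float,
) -> list[FeatureMatrix]:
    return [
        temporal_means(epochs, interval),
        template_xcorr(epochs, template, normalized_xcorr),
        band_power(epochs, segment_s=welch_segment_s, overlap=welch_overlap),
    ]


def cross_validate(
    epochs: EpochSet,
    labels: np.ndarray,
    spec: ClassifierSpec,
    plan: FoldPlan,
    feature_subset: str = "all",
    interval: float = 0.5,
    normalized_xcorr: bool = True,
    welch_segment_s: float = 1.0,
    welch_overlap: float = 0.5,
    keep_fold_artifacts: bool = False,
) -> ResultRecord:
    """Five-fold CV over a combined epoch set with {0: idle, 1: movement} labels.

    Per fold: the template is the mean of the *training* movement epochs;
    standardization is fit on training features only; the classifier never
    sees held-out epochs.  Temporal means and band powers are precomputed
    (they are per-epoch quantities); the template correlation is fold-
    dependent and recomputed.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != epochs.n_epochs:
        raise ValueError("one label per epoch required")
    tmeans = temporal_means(epochs, interval)
    bpow = band_power(epochs, segment_s=welch_segment_s, overlap=welch_overlap)

    accuracies, n_tests, artifacts = [], [], []
    for fold in range(plan.k):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        if np.unique(labels[tr]).size < 2:
            raise ValueError(f"fold {fold}: a class is absent from training")
        mov_tr = tr[labels[tr] == MOVEMENT]
        template = build_template(epochs, mov_tr)
        xc = template_xcorr(epochs, template, normalized_xcorr)
        feats = assemble_features(feature_subset, [tmeans, xc, bpow])

        scaler = StandardScaler().fit(feats.values[tr])
        x_tr = scaler.transform(feats.values[tr])
        x_te = scaler.transform(feats.values[te])
        clf = make_classifier(spec, n_train=tr.size)
        clf.fit(x_tr, labels[tr])
        acc = float(np.mean(clf.predict(x_te) == labels[te]))
        accuracies.append(acc)
        n_tests.append(int(te.size))
        if keep_fold_artifacts:
            artifacts.append(
                FoldArtifacts(
                    template.waveform.copy(),
                    scaler.mean_.copy(),
                    scaler.scale_.copy(),
                    clf,
                )
            )
    return ResultRecord(
        scenario="",
        electrode_set="",
        feature_subset=feature_subset,
        classifier=spec.kind,
        fold_accuracies=tuple(accuracies),
        median_accuracy=float(np.median(accuracies)),
        n_test_per_fold=tuple(n_tests),
        fold_artifacts=artifacts,
    )


def combine_epochs(movement: EpochSet, idle: EpochSet) -> tuple[EpochSet, np.ndarray]:
    """Stack movement and idle epochs into one set with integer labels."""
    if movement.data.shape[1:] != idle.data.shape[1:]:
        raise ValueError("movement and idle epochs must share channels and window")
    data = np.concatenate([movement.data, idle.data])
    labels = np.concatenate(
        [np.full(movement.n_epochs, MOVEMENT), np.full(idle.n_epochs, IDLE)]
    )
    t0s = np.concatenate([movement.t0s, idle.t0s])
    combined = EpochSet(
        data,
        np.where(labels == MOVEMENT, "movement", "idle").astype(object),
        movement.alignment,
        movement.window,
        movement.channel_names,
        movement.fs,
        t0s,
    )
    return combined, labels


def run_scenario(
    movement: EpochSet,
    idle: EpochSet,
    feature_subset: str = "all",
    spec: ClassifierSpec = ClassifierSpec(),
    plan: FoldPlan | None = None,
    seed: int = 0,
    scenario: str = "",
    electrode_set: str = "",
    keep_fold_artifacts: bool = False,
    **cv_kwargs,
) -> ResultRecord:
    """Balance idle to the movement count, plan folds and cross-validate."""
    movement, idle = balance_idle(movement, idle, seed)
    combined, labels = combine_epochs(movement, idle)
    if plan is None:
        plan = plan_folds(labels, k=5, seed=seed)
    record = cross_validate(
        combined,
        labels,
        spec,
        plan,
        feature_subset,
        keep_fold_artifacts=keep_fold_artifacts,
        **cv_kwargs,
    )
    record.scenario = scenario
    record.electrode_set = electrode_set
    logger.info(
        "%s/%s/%s/%s: median accuracy %.3f",
        scenario,
        electrode_set,
        feature_subset,
        spec.kind,
        record.median_accuracy,
    )
    return record
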