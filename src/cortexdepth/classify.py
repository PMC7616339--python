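"""Random-forest classification of patients from gradient maps.

Whole-brain qT1 and qT2 intracortical-gradient maps are concatenated per
subject, residualized for age and sex with coefficients fitted on the
training stratum only, and fed to a 100-tree random forest (Gini
impurity, sqrt(n_features) candidates per split, bootstrap resampling —
scikit-learn defaults).  Evaluation is strictly held-out: one stratum
(e.g. radiologically MRI-positive patients plus part of the controls)
trains, the disjoint stratum tests, in either direction.  Chance level is
assessed by permuting training labels and re-running the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "build_feature_matrix",
    "residualize_features",
    "train_rf",
    "evaluate",
    "classify_heldout",
    "permutation_pvalue",
]

POSITIVE = "patient"


@dataclass
class FeatureMatrix:
    """Subjects-by-features table with labels, strata and covariates."""

    values: np.ndarray  # (n, 2 * n_valid_vertices)
    labels: np.ndarray  # {"patient", "control"}
    stratum: np.ndarray  # e.g. {"positive", "negative", "control"}
    age: np.ndarray
    sex: np.ndarray  # binary {0, 1}
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")


def build_feature_matrix(feature_sets: dict[str, list], table) -> FeatureMatrix:
    """Concatenate whole-brain qT1 and qT2 gradient maps per subject.

    Vertices flagged invalid in any subject are dropped cohort-wide
    before concatenation so no missing values remain; feature order
    (modality-major, then hemisphere, then vertex) is recorded.
    """
    from .features import HEMI_ORDER

    modalities = list(feature_sets)
    blocks = []
    names: list[str] = []
    for mod in modalities:
        fs = feature_sets[mod]
        grads = np.vstack([f.stacked_gradient() for f in fs])
        valid = np.all(
            np.vstack([np.concatenate([f.valid[h] for h in HEMI_ORDER]) for f in fs]),
            axis=0,
        ) & np.all(np.isfinite(grads), axis=0)
        blocks.append(grads[:, valid])
        names += [f"{mod}_grad_{i}" for i in np.flatnonzero(valid)]
    return FeatureMatrix(
        values=np.hstack(blocks),
        labels=table["group"].values.astype(str),
        stratum=table["mri_status"].values.astype(str),
        age=table["age"].values.astype(float),
        sex=(table["sex"].values == "M").astype(float),
        feature_names=names,
    )


def residualize_features(
    features: FeatureMatrix, fit_subjects: np.ndarray
) -> FeatureMatrix:
    """Remove age and sex effects by linear regression.

    Coefficients are estimated on ``fit_subjects`` (the training stratum)
    only and applied to every subject, so no information can flow from
    held-out subjects into the fitted de-confounding.  Constant features
    residualize to 0 and are retained.
    """
    fit_idx = np.asarray(fit_subjects)
    D = np.column_stack(
        [np.ones(len(features.age)), features.age, features.sex]
    )
    coef, *_ = np.linalg.lstsq(D[fit_idx], features.values[fit_idx], rcond=None)
    resid = features.values - D @ coef
    return FeatureMatrix(
        values=resid,
        labels=features.labels,
        stratum=features.stratum,
        age=features.age,
        sex=features.sex,
        feature_names=features.feature_names,
    )


def train_rf(
    values: np.ndarray, labels: np.ndarray, seed: int = 0, n_trees: int = 100
) -> RandomForestClassifier:
    """100-tree random forest with default split settings.

    Gini impurity, sqrt(n_features) candidates per split, bootstrap
    resampling; deterministic under a fixed seed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    clf.fit(values, y)
    return clf


@dataclass
class ClassifierReport:
    """Held-out performance at the 0.5 probability operating point."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: dict
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    roc: tuple | None = None  # (fpr, tpr, thresholds)

    def as_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "confusion": self.confusion,
        }
        if self.permutation_p is not None:
            d["permutation_p"] = self.permutation_p
            d["n_permutations"] = self.n_permutations
        return d


def evaluate(
    model: RandomForestClassifier,
    test_values: np.ndarray,
    test_labels: np.ndarray,
    threshold: float = 0.5,
) -> ClassifierReport:
    """ROC/AUC from predicted probabilities; rates at the 0.5 threshold.

    The patient class is positive.  A single-class test set leaves the
    AUC undefined (NaN), flagged rather than silently dropped.
    """
    y = np.asarray(test_labels)
    pos_col = list(model.classes_).index(POSITIVE)
    prob = model.predict_proba(test_values)[:, pos_col]
    y_bin = (y == POSITIVE).astype(int)
    single_class = len(np.unique(y_bin)) < 2
    auc = float("nan") if single_class else float(roc_auc_score(y_bin, prob))
    pred = (prob >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_bin, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    roc = None if single_class else roc_curve(y_bin, prob)
    return ClassifierReport(
        auc=auc,
        accuracy=float((pred == y_bin).mean()),
        sensitivity=float(sens),
        specificity=float(spec),
        f1=float(f1),
        confusion={"tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)},
        roc=roc,
    )


def classify_heldout(
    features: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int = 0,
    n_perm: int = 0,
) -> ClassifierReport:
    """Full held-out protocol: residualize -> train -> evaluate.

    ``train_idx`` and ``test_idx`` must be disjoint.  With ``n_perm`` > 0
    a permutation p-value for the AUC is computed by shuffling the class
    labels (independently within the training and the held-out stratum,
    preserving each stratum's class balance) and re-running the whole
    pipeline with the partition fixed:
    p = (1 + #{AUC_perm >= AUC_obs}) / (1 + n_perm).  Permuting the
    labels end to end tests the global null of no feature-label
    association; permuting only training labels would leave the held-out
    labels informative and saturate the null near a strong effect.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("test stratum must be disjoint from training stratum")

    def run(labels_train: np.ndarray, labels_test: np.ndarray) -> ClassifierReport:
        resid = residualize_features(features, train_idx)
        model = train_rf(resid.values[train_idx], labels_train, seed=seed)
        return evaluate(model, resid.values[test_idx], labels_test)

    report = run(features.labels[train_idx], features.labels[test_idx])
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm_train = features.labels[train_idx][rng.permutation(len(train_idx))]
            perm_test = features.labels[test_idx][rng.permutation(len(test_idx))]
            if len(np.unique(perm_train)) < 2:  # pragma: no cover
                count += 1
                continue
            if run(perm_train, perm_test).auc >= report.auc - 1e-12:
                count += 1
        report.permutation_p = (1.0 + count) / (1.0 + n_perm)
        report.n_permutations = n_perm
    report.seed = seed
    return report


def permutation_pvalue(
    features: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value of the held-out AUC (see
    :func:`classify_heldout` for the label-permutation scheme)."""
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    return classify_heldout(
        features, train_idx, test_idx, seed=seed, n_perm=n_perm
    ).permutation_p
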