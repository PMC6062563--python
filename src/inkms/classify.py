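"""Document-grouped cross-validated kernel classification with pooled ROC.

The evaluation mimics casework: a classifier trained on documents of known
provenance is asked about a new, unseen document.  Cross-validation folds
therefore hold out *all* technical replicates of one document together, so
replicates of the same physical sample never straddle the train/test
split.  A hard-margin RBF-kernel support vector machine (emulated with a
very large misclassification penalty) scores each held-out sample; pooled
out-of-fold decision values across all folds give one ROC curve and AUC.

By default the presence/blank feature-inclusion rule is recomputed inside
every fold from the training samples only (no test-set peeking).  The
``global_filter`` switch instead filters once on the full matrix before
cross-validation, reproducing the study-style global filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics
from sklearn.svm import SVC

from .alignment import PeakMatrix
from .errors import ValidationError
from .screening import ScreenParams, impute_and_log
from .spectra_io import SampleMeta


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel / margin parameters.

    gamma_mode
        ``auto``: gamma = 1 / (n_features x variance of the training
        slice); ``fixed``: use ``gamma_value``.
    margin_hardness
        Misclassification penalty C; the default 1e8 emulates a hard
        margin while staying numerically solvable.
    """

    gamma_mode: str = "auto"
    gamma_value: float | None = None
    margin_hardness: float = 1e8

    def __post_init__(self) -> None:
        if self.gamma_mode not in ("auto", "fixed"):
            raise ValidationError("gamma_mode must be 'auto' or 'fixed'")
        if self.gamma_mode == "fixed" and (
            self.gamma_value is None or self.gamma_value <= 0
        ):
            raise ValidationError("fixed gamma requires gamma_value > 0")
        if self.margin_hardness <= 0:
            raise ValidationError("margin_hardness must be > 0")

    @property
    def sklearn_gamma(self) -> object:
        return "scale" if self.gamma_mode == "auto" else self.gamma_value


@dataclass
class FoldPlan:
    """Cross-validation folds grouped by document id."""

    folds: list[tuple[list[str], list[str]]]
    documents: list[str]


@dataclass
class CVResult:
    """Pooled out-of-fold classification scores.

    ``scores[i]`` is the decision value of ``sample_ids[i]``; positive
    values favour ``positive_label``.  ``fold_features`` records, per
    fold, which feature indices of the input matrix entered the model.
    """

    sample_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    fold_of: dict[str, int]
    positive_label: str
    fold_features: list[np.ndarray] = field(default_factory=list)
    fold_accuracy: list[float] = field(default_factory=list)


@dataclass
class RocCurve:
    """ROC points (monotone, (0,0) to (1,1)) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def make_folds_by_document(manifest: list[SampleMeta]) -> FoldPlan:
    """One fold per document; blanks excluded.

    Each fold's test set is every sample of exactly one document, so all
    technical replicates are held out together.  Raises if any fold's
    training set would contain a single author class (needs >= 2 documents
    per author).
    """
    real = [s for s in manifest if not s.is_blank]
    if not real:
        raise ValidationError("no non-blank samples in manifest")
    docs: dict[str, list[SampleMeta]] = {}
    for s in real:
        docs.setdefault(s.document_id, []).append(s)
    doc_ids = sorted(docs)
    folds = []
    for doc in doc_ids:
        test = [s.sample_id for s in docs[doc]]
        train_meta = [s for s in real if s.document_id != doc]
        train_authors = {s.author for s in train_meta}
        if len(train_authors) < 2:
            raise ValidationError(
                f"holding out document {doc!r} leaves a single author class "
                f"{sorted(train_authors)} in training; need >= 2 documents "
                "per author"
            )
        folds.append(([s.sample_id for s in train_meta], test))
    return FoldPlan(folds=folds, documents=doc_ids)


def train_margin_classifier(
    X: np.ndarray, labels: np.ndarray, params: KernelParams = KernelParams()
) -> SVC:
    """Fit the (quasi-)hard-margin RBF SVM; returns the fitted estimator.

    ``decision_function`` of the result is the real-valued score; its sign
    separates the two classes on separable training data.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("training requires both classes present")
    if X.size == 0 or float(X.var()) == 0.0:
        raise ValidationError("degenerate training matrix: zero overall variance")
    clf = SVC(
        kernel="rbf", C=params.margin_hardness, gamma=params.sklearn_gamma
    )
    clf.fit(X, labels)
    return clf


def _fold_feature_mask(
    matrix: PeakMatrix, train_ids: list[str], screen: ScreenParams
) -> np.ndarray:
    """Inclusion rule evaluated on the training samples of one fold.

    Presence counts use training (non-blank) columns only; the blank rule
    uses the manifest's blank columns, which never belong to any fold.
    """
    presence = matrix.presence()
    n_present = presence[train_ids].sum(axis=1).to_numpy()
    blanks = matrix.blank_ids()
    n_blank = (
        presence[blanks].sum(axis=1).to_numpy()
        if blanks
        else np.zeros(matrix.n_features)
    )
    return (n_present >= screen.min_present) & (n_blank == 0)


def crossval(
    matrix: PeakMatrix,
    plan: FoldPlan,
    params: KernelParams = KernelParams(),
    screen: ScreenParams = ScreenParams(),
    global_filter: bool = False,
    calibrate_scores: bool = True,
) -> CVResult:
    """Grouped cross-validation over the fold plan; pooled decision scores.

    Per fold: select features (per-fold rule, or the global rule when
    ``global_filter``), impute + log, fit on the training samples, score
    the held-out document.  Every non-blank sample is scored exactly once.

    Holding out one document leaves the training classes unbalanced, which
    shifts every decision value of that fold by a class-imbalance offset;
    pooling raw values across folds would then rank held-out samples by
    fold composition rather than evidence.  With ``calibrate_scores`` (the
    default) each fold's test scores are centred by the fold model's mean
    decision value over its own training samples, removing that offset.
    """
    authors = {s.sample_id: s.author for s in matrix.samples}
    classes = sorted({a for sid, a in authors.items() if not matrix.meta_of(sid).is_blank})
    if len(classes) != 2:
        raise ValidationError(f"need exactly two author classes, got {classes}")
    positive = classes[1]

    logged = impute_and_log(matrix, screen)
    global_mask = None
    if global_filter:
        global_mask = _fold_feature_mask(matrix, matrix.nonblank_ids(), screen)

    ids: list[str] = []
    scores: list[float] = []
    labels: list[str] = []
    fold_of: dict[str, int] = {}
    fold_features: list[np.ndarray] = []
    fold_accuracy: list[float] = []
    for k, (train_ids, test_ids) in enumerate(plan.folds):
        mask = (
            global_mask
            if global_mask is not None
            else _fold_feature_mask(matrix, train_ids, screen)
        )
        feat_idx = np.flatnonzero(mask)
        if len(feat_idx) == 0:
            raise ValidationError(f"fold {k}: no features pass the inclusion rule")
        X_train = logged.values[train_ids].to_numpy()[feat_idx].T
        X_test = logged.values[test_ids].to_numpy()[feat_idx].T
        y_train = np.array([authors[sid] for sid in train_ids])
        clf = train_margin_classifier(X_train, y_train, params)
        s = clf.decision_function(X_test)
        if calibrate_scores:
            s = s - float(clf.decision_function(X_train).mean())
        # sklearn orients decision_function toward classes_[1]; flip if needed
        if list(clf.classes_) != classes:
            s = -s
        y_test = np.array([authors[sid] for sid in test_ids])
        pred = clf.predict(X_test)
        fold_accuracy.append(float(np.mean(pred == y_test)))
        fold_features.append(feat_idx)
        for sid, score, label in zip(test_ids, s, y_test):
            ids.append(sid)
            scores.append(float(score))
            labels.append(label)
            fold_of[sid] = k
    return CVResult(
        sample_ids=ids,
        scores=np.asarray(scores),
        labels=np.asarray(labels, dtype=object),
        fold_of=fold_of,
        positive_label=positive,
        fold_features=fold_features,
        fold_accuracy=fold_accuracy,
    )


def roc_auc(result: CVResult) -> RocCurve:
    """Pooled ROC curve and trapezoidal AUC from out-of-fold scores.

    Tied scores are grouped into single thresholds; the trapezoidal area
    then equals the tie-corrected Mann–Whitney statistic
    U / (n_positive x n_negative).
    """
    y = np.asarray(result.labels == result.positive_label, dtype=int)
    if y.all() or not y.any():
        raise ValidationError("ROC requires both classes among the scored samples")
    fpr, tpr, thresholds = _skmetrics.roc_curve(y, result.scores)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(_skmetrics.auc(fpr, tpr)),
    )
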