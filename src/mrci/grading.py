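"""LGG/HGG grading from log class-ratio features.

A linear soft-margin SVM (libsvm via scikit-learn) separates low- from
high-grade subjects. The cost parameter C is chosen by a two-step grid
search (coarse powers of two, then a fine grid around the winner) scored by
stratified inner cross-validation. Performance is assessed by leave-one-out
cross-validation over subjects, repeated with different inner-fold draws;
decision values feed ROC/AUC with stratified bootstrap confidence
intervals. HGG is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import EmptyInputError, FoldError, GradeError
from .labeling import ClassRatioFeatures

GRADE_TO_INT = {"LGG": -1, "HGG": 1}

#: libsvm iteration cap. Converged solutions on cohort-sized problems need
#: well under 10^5 iterations; the cap only binds for huge C on
#: label-noise data, where libsvm would otherwise crawl through millions of
#: iterations toward a degenerate optimum.
LIBSVM_MAX_ITER = 200_000


@dataclass
class SVMSpec:
    """Linear-SVM model-selection protocol.

    ``coarse_grid`` are log2(C) exponents; the fine search spans +/-2 around
    the coarse winner at ``fine_step`` resolution. Inner model selection is
    stratified ``inner_cv_folds``-fold accuracy; ties go to the smallest C.
    """

    kernel: str = "linear"
    coarse_grid: tuple[float, ...] = tuple(range(-5, 16, 2))
    fine_step: float = 0.25
    fine_span: float = 2.0
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if not self.coarse_grid:
            raise ValueError("coarse grid must be non-empty")
        if self.inner_cv_folds < 2:
            raise ValueError("need >= 2 inner folds")


@dataclass
class LinearDecision:
    """Trained linear decision function f(x) = w.x + b; positive = HGG."""

    w: np.ndarray
    b: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) > 0, 1, -1)


@dataclass
class RepeatMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass
class CohortResult:
    """Repeated-LOOCV output: per-subject decision values and summaries."""

    subject_ids: list[str]
    grades: np.ndarray  # +1 HGG / -1 LGG
    decision_values: np.ndarray  # (repeats, n_subjects) held-out values
    predictions: np.ndarray  # (repeats, n_subjects) in {-1, +1}
    per_repeat: list[RepeatMetrics]
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def metric_samples(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.per_repeat])

    def to_dict(self) -> dict:
        return {
            "subject_ids": self.subject_ids,
            "grades": self.grades.tolist(),
            "decision_values": self.decision_values.tolist(),
            "predictions": self.predictions.tolist(),
            "per_repeat": [vars(m) for m in self.per_repeat],
            "summaries": self.summaries,
        }


class UnitIntervalScaler:
    """Linear rescale of each feature to [-1, 1], fit on training data only.

    A feature constant on the training fold maps to 0.
    """

    def fit(self, X: np.ndarray) -> "UnitIntervalScaler":
        X = np.asarray(X, dtype=float)
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        span = self.hi_ - self.lo_
        self.scale_ = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.lo_) * self.scale_ - np.where(
            self.scale_ > 0, 1.0, 0.0
        )

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> LinearDecision:
    """Fit a soft-margin linear SVM; y in {-1 (LGG), +1 (HGG)}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise GradeError("both classes must be present")
    clf = SVC(kernel="linear", C=C, max_iter=LIBSVM_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    # sklearn orders classes_ ascending, so decision > 0 means class +1 (HGG)
    return LinearDecision(w=clf.coef_.ravel().copy(), b=float(clf.intercept_[0]))


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, folds) -> float:
    accs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise FoldError("training fold lost a class")
        model = fit_svm(X[tr], y[tr], C)
        accs.append(float((model.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def select_C(
    X: np.ndarray, y: np.ndarray, spec: SVMSpec, rng: np.random.Generator
) -> float:
    """Two-step C grid search scored by stratified inner-CV accuracy.

    Step 1 scans the coarse powers-of-two grid; step 2 refines around the
    winner at ``fine_step`` in log2. Ties always resolve to the smallest C.
    """
    y = np.asarray(y)
    class_counts = np.bincount((y > 0).astype(int), minlength=2)
    n_splits = int(min(spec.inner_cv_folds, class_counts.min()))
    if n_splits < 2:
        raise FoldError("too few subjects per class for stratified folds")
    folds = None
    for _ in range(10):
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        cand = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in cand):
            folds = cand
            break
    if folds is None:
        raise FoldError("could not build non-degenerate stratified folds")

    def best_over(exponents: np.ndarray) -> float:
        best_exp, best_acc = None, -1.0
        for e in exponents:  # ascending -> ties keep the smallest C
            acc = _cv_accuracy(X, y, 2.0**e, folds)
            if acc > best_acc + 1e-12:
                best_exp, best_acc = e, acc
        return best_exp

    coarse = best_over(np.asarray(sorted(spec.coarse_grid), dtype=float))
    fine = np.arange(
        coarse - spec.fine_span, coarse + spec.fine_span + spec.fine_step / 2,
        spec.fine_step,
    )
    return float(2.0 ** best_over(fine))


def roc_auc(decision_values, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC with HGG (+1) positive; ties count one half.

    The AUC equals the Mann–Whitney probability that a random HGG decision
    value exceeds a random LGG one (ties counted 1/2).
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise GradeError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, d, pos_label=1)
    auc = float(roc_auc_score((y > 0).astype(int), d))
    return fpr, tpr, auc


def _threshold_metrics(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    pred = np.where(d > 0, 1, -1)
    pos, neg = y == 1, y == -1
    sens = float((pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((pred[neg] == -1).mean()) if neg.any() else np.nan
    acc = float((pred == y).mean())
    return acc, sens, spec


def bootstrap_ci(
    decision_values,
    labels,
    replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Stratified bootstrap percentile CIs for AUC and threshold-0 metrics.

    Resampling is with replacement within each class, so every replicate
    retains both classes.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == -1)[0]
    if len(pos) < 2 or len(neg) < 2:
        raise GradeError("need >= 2 subjects per class")
    rng = np.random.default_rng(seed)
    stats = {"auc": [], "accuracy": [], "sensitivity": [], "specificity": []}
    for _ in range(replicates):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        db, yb = d[idx], y[idx]
        stats["auc"].append(float(roc_auc_score((yb > 0).astype(int), db)))
        acc, sens, spc = _threshold_metrics(db, yb)
        stats["accuracy"].append(acc)
        stats["sensitivity"].append(sens)
        stats["specificity"].append(spc)
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    return {
        name: tuple(np.percentile(np.asarray(vals), q)) for name, vals in stats.items()
    }


def loocv(
    cohort: list[ClassRatioFeatures],
    spec: SVMSpec | None = None,
    repeats: int = 100,
    seed: int = 0,
) -> CohortResult:
    """Repeated leave-one-out cross-validation over subjects.

    Per repeat r (seeded ``seed + r``) each subject is held out in turn;
    feature scaling, the two-step C search and the SVM fit all use only the
    remaining subjects. Across repeats only the inner-CV fold draws vary.
    Summaries are means with percentile 95% CIs over repeats.
    """
    spec = spec or SVMSpec()
    if len(cohort) < 4:
        raise EmptyInputError("need at least 4 subjects")
    X = np.vstack([f.log_ratios for f in cohort])
    try:
        y = np.array([GRADE_TO_INT[f.grade] for f in cohort])
    except KeyError as e:
        raise GradeError(f"subject with unknown grade: {e}") from None
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise GradeError("need >= 2 subjects per grade")
    n = len(cohort)
    # per-subject RNG keyed by the subject's rank in id order, so results are
    # invariant to the order subjects are passed in
    rank = {sid: k for k, sid in enumerate(sorted(f.subject_id for f in cohort))}
    dec = np.empty((repeats, n))
    pred = np.empty((repeats, n), dtype=int)
    per_repeat: list[RepeatMetrics] = []
    for r in range(repeats):
        for i in range(n):
            rng = np.random.default_rng([seed + r, rank[cohort[i].subject_id]])
            tr = np.delete(np.arange(n), i)
            scaler = UnitIntervalScaler().fit(X[tr])
            Xtr = scaler.transform(X[tr])
            C = select_C(Xtr, y[tr], spec, rng)
            model = fit_svm(Xtr, y[tr], C)
            dv = float(model.decision_values(scaler.transform(X[i : i + 1]))[0])
            dec[r, i] = dv
            pred[r, i] = 1 if dv > 0 else -1
        acc, sens, spc = _threshold_metrics(dec[r], y)
        _, _, auc = roc_auc(dec[r], y)
        per_repeat.append(
            RepeatMetrics(accuracy=acc, sensitivity=sens, specificity=spc, auc=auc)
        )
    result = CohortResult(
        subject_ids=[f.subject_id for f in cohort],
        grades=y,
        decision_values=dec,
        predictions=pred,
        per_repeat=per_repeat,
    )
    for name in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = result.metric_samples(name)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        result.summaries[name] = {
            "mean": float(vals.mean()), "ci_low": float(lo), "ci_high": float(hi),
        }
    return result
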