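"""Classifier training and multi-protocol evaluation.

Metrics (positive class = interacting):

    SE  = 100 * TP / (TP + FN)                    sensitivity, %
    SP  = 100 * TN / (TN + FP)                    specificity, %
    ACC = 100 * (TP + TN) / (TP + FP + TN + FN)   accuracy, %
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    AUC = rank-based (Mann-Whitney) area under the ROC curve
    g-means = sqrt(SE * SP)                       on the 0-100 scale

Undefined metrics (zero denominator, single-class truth) return NaN and are
excluded from averages with a warning, never silently zeroed.

Protocols: leave-one-out CV, repeated stratified k-fold (default 10 x 10-fold)
and repeated stratified 70/30 train/test splits. Metrics are computed on the
pooled held-out predictions of each run; averages are arithmetic over runs.

Classifiers follow a minimal plugin contract — fit(X, y), predict(X) and
optionally a continuous score for AUC — with a shipped registry approximating
the usual Weka-default learners via scikit-learn defaults: naive Bayes,
SVMs with RBF, polynomial and Pearson-VII (PUK) kernels, 1-nearest-neighbour,
bagged trees, and random forest. An averaged one-dependence estimator has no
scikit-learn counterpart and is therefore not shipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pair_space import NEGATIVE_LABEL, POSITIVE_LABEL, PairTable
from .sampling import Method, sample

METRIC_NAMES = ("SE", "SP", "ACC", "MCC", "AUC", "g_means")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ConfusionCounts:
    """Standard 2x2 counts; positive class = interacting."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    valid = {POSITIVE_LABEL, NEGATIVE_LABEL}
    if not set(y_true) <= valid or not set(y_pred) <= valid:
        raise ValueError(f"labels must be in {sorted(valid)}")
    tp = sum(t == POSITIVE_LABEL and p == POSITIVE_LABEL
             for t, p in zip(y_true, y_pred))
    tn = sum(t == NEGATIVE_LABEL and p == NEGATIVE_LABEL
             for t, p in zip(y_true, y_pred))
    fp = sum(t == NEGATIVE_LABEL and p == POSITIVE_LABEL
             for t, p in zip(y_true, y_pred))
    fn = sum(t == POSITIVE_LABEL and p == NEGATIVE_LABEL
             for t, p in zip(y_true, y_pred))
    return ConfusionCounts(tp, tn, fp, fn)


def metric_se(c: ConfusionCounts) -> float:
    den = c.TP + c.FN
    return 100.0 * c.TP / den if den else float("nan")


def metric_sp(c: ConfusionCounts) -> float:
    den = c.TN + c.FP
    return 100.0 * c.TN / den if den else float("nan")


def metric_acc(c: ConfusionCounts) -> float:
    return 100.0 * (c.TP + c.TN) / c.total if c.total else float("nan")


def metric_mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; any zero factor in the radicand
    yields 0 by convention."""
    rad = (
        (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if rad == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(rad))


def metric_gmeans(se: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity (0-100 scale)."""
    return float(np.sqrt(se * sp))


def metric_auc(y_true: Sequence[str], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half."""
    from scipy.stats import rankdata

    y = np.asarray([t == POSITIVE_LABEL for t in y_true])
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return float(
        (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def metrics_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: Sequence[float] | None = None,
) -> dict[str, float]:
    c = confusion(y_true, y_pred)
    se, sp = metric_se(c), metric_sp(c)
    return {
        "SE": se,
        "SP": sp,
        "ACC": metric_acc(c),
        "MCC": metric_mcc(c),
        "AUC": metric_auc(y_true, scores) if scores is not None else float("nan"),
        "g_means": metric_gmeans(se, sp),
    }


# --- classifier plugin registry --------------------------------------------

def puk_kernel(
    X: np.ndarray, Y: np.ndarray, omega: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """Pearson-VII universal kernel (PUK):
    k(x, y) = 1 / (1 + (2 sqrt(2^(1/omega) - 1) ||x-y|| / sigma)^2)^omega."""
    d = cdist(np.atleast_2d(X), np.atleast_2d(Y))
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + (scale * d) ** 2) ** omega


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier factory; ``seeded`` marks stochastic learners."""

    id: str
    factory: Callable[[int], object]
    seeded: bool = True

    def build(self, seed: int = 0):
        return self.factory(seed)


REGISTRY: dict[str, ClassifierSpec] = {
    "nb": ClassifierSpec("nb", lambda s: GaussianNB(), seeded=False),
    "svm-rbf": ClassifierSpec(
        "svm-rbf", lambda s: SVC(kernel="rbf", random_state=s)
    ),
    "svm-poly": ClassifierSpec(
        "svm-poly", lambda s: SVC(kernel="poly", random_state=s)
    ),
    "svm-puk": ClassifierSpec(
        "svm-puk", lambda s: SVC(kernel=puk_kernel, random_state=s)
    ),
    "1nn": ClassifierSpec(
        "1nn", lambda s: KNeighborsClassifier(n_neighbors=1), seeded=False
    ),
    "bagging": ClassifierSpec(
        "bagging",
        lambda s: BaggingClassifier(DecisionTreeClassifier(), random_state=s),
    ),
    "rf": ClassifierSpec(
        "rf", lambda s: RandomForestClassifier(random_state=s)
    ),
}


def _scores_of(model, X: np.ndarray) -> np.ndarray | None:
    """A continuous score for ranking, oriented toward the positive class."""
    classes = list(getattr(model, "classes_", []))
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, classes.index(POSITIVE_LABEL)]
    if hasattr(model, "decision_function"):
        df = model.decision_function(X)
        # sklearn orients decision_function toward classes_[1]
        return df if classes and classes[1] == POSITIVE_LABEL else -df
    return None


@dataclass(frozen=True)
class EvalReport:
    """Per-run and averaged metrics for one classifier under one protocol."""

    protocol: str
    classifier_id: str
    runs: tuple[dict[str, float], ...]
    averages: dict[str, float]
    sampling_method: str | None = None
    seeds: tuple[int, ...] = ()
    degenerate_runs: tuple[int, ...] = ()


def _average_runs(runs: list[dict[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = np.array([r[m] for r in runs], dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) < len(vals):
            warnings.warn(
                f"metric {m}: {len(vals) - len(finite)} undefined run(s) "
                "excluded from the average"
            )
        out[m] = float(finite.mean()) if len(finite) else float("nan")
    return out


def _fit_predict(
    spec: ClassifierSpec,
    X_train, y_train, X_test,
    seed: int,
) -> tuple[np.ndarray, np.ndarray | None]:
    model = spec.build(seed)
    model.fit(X_train, y_train)
    return model.predict(X_test), _scores_of(model, X_test)


def run_loocv(
    spec: ClassifierSpec, X: np.ndarray, y: Sequence[str], seed: int = 0
) -> EvalReport:
    """Leave-one-out CV: n held-out predictions pooled into one run."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    preds = np.empty(n, dtype=object)
    scores = np.full(n, np.nan)
    have_scores = True
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        p, s = _fit_predict(spec, X[mask], y[mask], X[i:i + 1], seed)
        preds[i] = p[0]
        if s is None:
            have_scores = False
        else:
            scores[i] = s[0]
    run = metrics_from_predictions(
        list(y), list(preds), scores if have_scores else None
    )
    return EvalReport("loocv", spec.id, (run,), _average_runs([run]),
                      seeds=(seed,))


def run_repeated_kfold(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold CV; one metric set per full pass."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs, degenerate = [], []
    for rep in range(reps):
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed + rep)
        preds = np.empty(len(y), dtype=object)
        scores = np.full(len(y), np.nan)
        have_scores = True
        for train_idx, test_idx in splitter.split(X, y):
            if len(set(y[train_idx])) < 2:
                degenerate.append(rep)
                continue
            p, s = _fit_predict(spec, X[train_idx], y[train_idx],
                                X[test_idx], seed + rep)
            preds[test_idx] = p
            if s is None:
                have_scores = False
            else:
                scores[test_idx] = s
        runs.append(metrics_from_predictions(
            list(y), list(preds), scores if have_scores else None))
    return EvalReport(
        "repeated_kfold", spec.id, tuple(runs), _average_runs(runs),
        seeds=tuple(seed + r for r in range(reps)),
        degenerate_runs=tuple(sorted(set(degenerate))),
    )


def run_split(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    train_frac: float = 0.7,
    reps: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified train/test splits (default 70/30)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs = []
    for rep in range(reps):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y,
            random_state=seed + rep,
        )
        p, s = _fit_predict(spec, X_tr, y_tr, X_te, seed + rep)
        runs.append(metrics_from_predictions(list(y_te), list(p), s))
    return EvalReport(
        "split", spec.id, tuple(runs), _average_runs(runs),
        seeds=tuple(seed + r for r in range(reps)),
    )


PROTOCOLS = {
    "loocv": run_loocv,
    "kfold": run_repeated_kfold,
    "split": run_split,
}


def build_balanced_dataset(
    positives: PairTable, pool: PairTable, selection: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack positive rows over the selected negatives into (X, y)."""
    neg = pool.subset(selection)
    X = np.vstack([positives.vectors, neg.vectors])
    y = np.array(
        [POSITIVE_LABEL] * len(positives) + [NEGATIVE_LABEL] * len(neg)
    )
    return X, y


def benchmark(
    positives: PairTable,
    pool: PairTable,
    classifiers: Sequence[ClassifierSpec],
    sampling_methods: Sequence[Method | str],
    protocol: str = "loocv",
    reps: int = 10,
    seed: int = 0,
    protocol_kwargs: dict | None = None,
) -> dict[tuple[str, str], EvalReport]:
    """Evaluate every classifier under every sampling method.

    For each method, ``reps`` negative sets of size len(positives) are drawn
    from the pool; each classifier is evaluated once per negative set under
    the chosen protocol and the per-set runs are averaged. Keyed by
    (classifier id, sampling method).
    """
    run_protocol = PROTOCOLS[protocol]
    protocol_kwargs = protocol_kwargs or {}
    results: dict[tuple[str, str], EvalReport] = {}
    for method in sampling_methods:
        method = Method(method)
        selections = [
            sample(pool, method, len(positives), seed=seed + rep).selected
            for rep in range(reps)
        ]
        for spec in classifiers:
            runs: list[dict[str, float]] = []
            for rep, sel in enumerate(selections):
                X, y = build_balanced_dataset(positives, pool, sel)
                report = run_protocol(spec, X, y, seed=seed + rep,
                                      **protocol_kwargs)
                runs.extend(report.runs)
            results[(spec.id, method.value)] = EvalReport(
                protocol, spec.id, tuple(runs), _average_runs(runs),
                sampling_method=method.value,
                seeds=tuple(seed + r for r in range(reps)),
            )
    return results
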