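"""Classifier construction, LOOCV, and independent validation.

Five model families are compared: L2 logistic regression (LR), an RBF-kernel
support vector machine (SVM), a single-hidden-layer feed-forward network
(SNN), a random forest with 1000 trees (RF), and Gaussian naive Bayes (NB).
Hyper-parameters (except NB, which has none) are tuned by the same protocol
as the selection stage: seeded stratified five-times five-fold CV maximizing
mean AUC, then a refit on the full training set.  The per-algorithm
optimizers come from scikit-learn; the tuning protocol, CV plumbing, scoring
and all metrics are implemented here.

Evaluation convention: grade IV is the positive class.  AUC uses the
rank/pair formulation with ties contributing 1/2; hard labels come from
thresholding probability-scale scores at 0.5.  SVM scores go through the
monotone probability calibration scikit-learn fits on the training data
(``probability=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as _sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .exceptions import EmptyIntersection, SelectionEmpty
from .extract import FeatureTable
from .selection import Standardizer, _stratified_folds, select_features

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "default_model_specs",
    "desk_model_specs",
    "roc_auc",
    "metrics_at_threshold",
    "tune_and_fit",
    "loocv",
    "independent_validation",
    "summarize",
    "EvaluationReport",
]


# ---------------------------------------------------------------------------
# model zoo


@dataclass(frozen=True)
class ModelSpec:
    """One algorithm plus its hyper-parameter grid.

    ``factory(seed, **params)`` must return an unfitted estimator exposing
    ``fit`` and ``predict_proba``.  An empty grid means no tuning.
    """

    name: str
    factory: object
    grid: tuple[tuple[str, tuple], ...] = ()

    def grid_points(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = [k for k, _ in self.grid]
        return [dict(zip(keys, combo)) for combo in product(*[v for _, v in self.grid])]


def default_model_specs(rf_trees: int = 1000) -> list[ModelSpec]:
    """The five study algorithms with their tuning grids."""
    return [
        ModelSpec(
            "LR",
            lambda seed, C=1.0: LogisticRegression(C=C, max_iter=2000),
            (("C", (0.01, 0.1, 1.0, 10.0)),),
        ),
        ModelSpec(
            "SVM",
            lambda seed, C=1.0, gamma="scale": SVC(
                kernel="rbf", C=C, gamma=gamma, probability=True, random_state=seed
            ),
            (("C", (0.1, 1.0, 10.0)), ("gamma", ("scale", 0.01, 0.1))),
        ),
        ModelSpec(
            "SNN",
            lambda seed, hidden=50, alpha=1e-4: MLPClassifier(
                hidden_layer_sizes=(hidden,), alpha=alpha, max_iter=500, random_state=seed
            ),
            (("hidden", (10, 50, 100)), ("alpha", (1e-4, 1e-2))),
        ),
        ModelSpec(
            "RF",
            lambda seed, max_features="sqrt": RandomForestClassifier(
                n_estimators=rf_trees, max_features=max_features, random_state=seed
            ),
            (("max_features", ("sqrt", 0.333)),),
        ),
        ModelSpec("NB", lambda seed: GaussianNB(), ()),
    ]


def desk_model_specs(rf_trees: int = 100) -> list[ModelSpec]:
    """Untuned, lighter variants of the five algorithms for desk-scale
    studies (fixed hyper-parameters, smaller forest)."""
    return [
        ModelSpec("LR", lambda seed: LogisticRegression(C=1.0, max_iter=2000)),
        ModelSpec("SVM", lambda seed: SVC(kernel="rbf", probability=True, random_state=seed)),
        ModelSpec(
            "SNN",
            lambda seed: MLPClassifier(hidden_layer_sizes=(20,), max_iter=300, random_state=seed),
        ),
        ModelSpec(
            "RF",
            lambda seed: RandomForestClassifier(n_estimators=rf_trees, random_state=seed),
        ),
        ModelSpec("NB", lambda seed: GaussianNB()),
    ]


class PriorClassifier:
    """Intercept-only fallback when LASSO keeps no slope.

    Scores every subject 0.5: an intercept-only model carries no ranking
    information, and a constant score makes that explicit.  (Scoring the
    training base rate instead would anti-correlate with the held-out label
    in leave-one-out folds — removing one grade-IV subject lowers the rate —
    and bias the pooled AUC below 0.5.)
    """

    def fit(self, X, y):
        self.rate_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        p = np.full(len(X), 0.5)
        return np.column_stack([1 - p, p])


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels):
    """AUC by the rank/pair formulation (ties count 1/2) plus ROC points.

    Returns ``(auc, points)`` with ``points`` an ordered array of
    (FPR, TPR) pairs over all score thresholds.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = _sstats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # empirical ROC: sweep thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    ys = labels[order]
    ss = scores[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    # keep the last point of each tied-score block
    last = np.r_[ss[1:] != ss[:-1], True]
    points = np.column_stack([fp[last] / n_neg, tp[last] / n_pos])
    points = np.vstack([[0.0, 0.0], points])
    return float(auc), points


def metrics_at_threshold(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / AUC with grade IV positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    auc, _ = roc_auc(scores, labels)
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "auc": auc,
    }


# ---------------------------------------------------------------------------
# tuning


def tune_and_fit(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 5,
):
    """Grid-search ``spec`` by repeated stratified CV mean AUC, refit on all.

    Returns ``(fitted_estimator, best_params)``.  Deterministic for a fixed
    seed.  Raises on a single-class training set.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training set")
    if X.shape[1] == 0:
        return PriorClassifier().fit(X, y), {}
    points = spec.grid_points()
    if len(points) == 1:
        est = spec.factory(seed, **points[0])
        return est.fit(X, y), points[0]
    n_splits = min(folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few subjects per class for tuning CV")
    fold_sets = [
        f for r in range(repeats) for f in _stratified_folds(y, n_splits, seed * 1000 + r)
    ]
    mean_aucs = []
    for params in points:
        scores = []
        for tr, te in fold_sets:
            est = spec.factory(seed, **params).fit(X[tr], y[tr])
            s = est.predict_proba(X[te])[:, 1]
            scores.append(roc_auc(s, y[te])[0])
        mean_aucs.append(float(np.mean(scores)))
    best = points[int(np.argmax(mean_aucs))]
    est = spec.factory(seed, **best)
    return est.fit(X, y), best


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluationReport:
    """Per-model metrics plus ROC points and out-of-fold (or validation)
    scores; ``fold_selected`` holds the per-fold selected descriptor sets
    for LOOCV runs."""

    metrics: dict[str, dict[str, float]]
    roc: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    labels: np.ndarray
    fold_selected: list[list] = field(default_factory=list)
    failed_folds: int = 0
    summary: dict = field(default_factory=dict)

    @property
    def selected_intersection(self) -> list:
        if not self.fold_selected:
            return []
        sets = [set(map(str, s)) for s in self.fold_selected]
        inter = set.intersection(*sets)
        # preserve the order of the first fold
        return [d for d in self.fold_selected[0] if str(d) in inter]

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "summary": self.summary,
            "failed_folds": self.failed_folds,
            "selected_intersection": [str(d) for d in self.selected_intersection],
            "n_selected_per_fold": [len(s) for s in self.fold_selected],
        }


def summarize(metrics: dict[str, dict[str, float]]) -> dict:
    """Across-model mean, sample SD, and t-based 95% CI per metric."""
    models = list(metrics)
    if len(models) < 2:
        raise ValueError("summary needs >= 2 models")
    out = {}
    k = len(models)
    tcrit = _sstats.t.ppf(0.975, k - 1)
    for metric in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = np.array([metrics[m][metric] for m in models])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        half = tcrit * sd / np.sqrt(k)
        out[metric] = {
            "mean": mean,
            "sd": sd,
            "ci95": (mean - half, mean + half),
            "low_n": k < 5,
        }
    return out


# ---------------------------------------------------------------------------
# LOOCV


def loocv(
    table: FeatureTable,
    specs: list[ModelSpec] | None = None,
    seed: int = 0,
    selection_kwargs: dict | None = None,
    tuning_folds: int = 5,
    tuning_repeats: int = 5,
) -> EvaluationReport:
    """Leave-one-out cross-validation with full per-fold refitting.

    For each held-out subject the remaining rows go through screening,
    lambda tuning, the final LASSO fit, and per-model hyper-parameter
    tuning; no information flows from the held-out subject into its fold.
    Folds whose screening is empty are recorded as failed; their held-out
    subjects receive the uninformative score 0.5 (a pure ROC tie) so the
    pooled out-of-fold evaluation stays defined.
    """
    specs = specs if specs is not None else default_model_specs()
    selection_kwargs = selection_kwargs or {}
    n = table.n_subjects
    y = table.labels
    oof = {s.name: np.full(n, np.nan) for s in specs}
    fold_selected: list[list] = []
    failed = 0
    for i in range(n):
        tr = np.r_[0:i, i + 1 : n]
        sub = table.subset_rows(tr)
        try:
            sel = select_features(sub, seed=seed * 100_000 + i, **selection_kwargs)
        except SelectionEmpty:
            failed += 1
            log.warning("fold %d: empty screening, recorded as failed", i)
            for spec in specs:
                oof[spec.name][i] = 0.5
            continue
        fold_selected.append(sel.selected)
        cols = sel.selected_idx
        scaler = Standardizer.fit(sub.values[:, cols]) if len(cols) else None
        Xtr = scaler.transform(sub.values[:, cols]) if len(cols) else sub.values[:, cols]
        Xte = (
            scaler.transform(table.values[i : i + 1, cols])
            if len(cols)
            else table.values[i : i + 1, cols]
        )
        for spec in specs:
            est, _ = tune_and_fit(
                spec, Xtr, y[tr], seed=seed * 100_000 + i,
                folds=tuning_folds, repeats=tuning_repeats,
            )
            oof[spec.name][i] = est.predict_proba(Xte)[0, 1]
    metrics, roc, scores = {}, {}, {}
    for name, s in oof.items():
        ok = ~np.isnan(s)
        metrics[name] = metrics_at_threshold(s[ok], y[ok])
        roc[name] = roc_auc(s[ok], y[ok])[1]
        scores[name] = s
    report = EvaluationReport(metrics, roc, scores, y, fold_selected, failed)
    if len(specs) >= 2:
        report.summary = summarize(metrics)
    return report


def independent_validation(
    primary: FeatureTable,
    validation: FeatureTable,
    loocv_report: EvaluationReport,
    specs: list[ModelSpec] | None = None,
    seed: int = 0,
    tuning_folds: int = 5,
    tuning_repeats: int = 5,
) -> EvaluationReport:
    """Evaluate on a held-out cohort with the all-folds-selected features.

    The feature set is the intersection of the per-fold LOOCV selections;
    standardization and model fitting use the full primary cohort only.
    """
    specs = specs if specs is not None else default_model_specs()
    inter = loocv_report.selected_intersection
    if not inter:
        raise EmptyIntersection(
            "no feature was selected in every LOOCV fold; "
            "an independent validation needs a non-empty intersection"
        )
    desc_str = [str(d) for d in primary.descriptors]
    cols = np.array([desc_str.index(str(d)) for d in inter])
    scaler = Standardizer.fit(primary.values[:, cols])
    Xtr = scaler.transform(primary.values[:, cols])
    Xte = scaler.transform(validation.values[:, cols])
    y_tr, y_te = primary.labels, validation.labels
    metrics, roc, scores = {}, {}, {}
    for spec in specs:
        est, _ = tune_and_fit(spec, Xtr, y_tr, seed=seed, folds=tuning_folds, repeats=tuning_repeats)
        s = est.predict_proba(Xte)[:, 1]
        metrics[spec.name] = metrics_at_threshold(s, y_te)
        roc[spec.name] = roc_auc(s, y_te)[1]
        scores[spec.name] = s
    report = EvaluationReport(metrics, roc, scores, y_te, [inter], 0)
    if len(specs) >= 2:
        report.summary = summarize(metrics)
    return report
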