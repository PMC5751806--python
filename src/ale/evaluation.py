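"""Evaluation machinery: experiment-stratified CV, precision-recall,
age error statistics, and ontology-distance error profiles.

Samples from one GEO series are far more similar to each other than to the
rest of the archive, so ordinary cross-validation lets a classifier score
well by recognizing the experiment rather than the label.  All evaluation
here therefore assigns folds at the SERIES level: every sample of a series
lands in the same fold (greedy size balancing, largest series first into the
currently smallest fold).  A non-stratified mode exists purely to
demonstrate how much that leakage inflates accuracy.

Precision/recall conventions: an abstention (no prediction) is excluded from
precision denominators but counts against recall — the extractors are built
to abstain rather than guess, and this scoring reflects that.  Micro
averaging pools all predictions; macro averaging takes the unweighted mean
over classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import EvaluationError
from .expression_ml import (
    DEFAULT_ML_CONFIG,
    ExpressionMatrix,
    MLConfig,
    dummy_baseline,
    predict,
    train,
)
from .tissue_ontology import OntologyGraph, random_distance_baseline

logger = logging.getLogger(__name__)

ABSTAIN_VALUES = {"", "none", None}


@dataclass(frozen=True)
class FoldAssignment:
    """Series -> fold index map for k-fold experiment-stratified CV."""

    k: int
    series_to_fold: dict[str, int]
    seed: int

    def sample_folds(self, series_by_sample: pd.Series) -> pd.Series:
        return series_by_sample.map(self.series_to_fold)


def make_folds(series_by_sample: Mapping[str, str] | pd.Series, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign whole series to folds, balancing fold sizes greedily.

    Series are taken largest first (ties shuffled deterministically under
    *seed*) and dropped into the currently smallest fold.  Fails if there are
    fewer distinct series than folds.
    """
    series_by_sample = pd.Series(series_by_sample)
    counts = series_by_sample.value_counts()
    if len(counts) < k:
        raise EvaluationError(
            f"need at least k={k} distinct series, got {len(counts)}"
        )
    rng = np.random.default_rng(seed)
    order = counts.index.to_numpy()[rng.permutation(len(counts))]
    sizes = counts.loc[order].to_numpy()
    order = order[np.argsort(-sizes, kind="stable")]
    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for series in order:
        fold = int(np.argmin(fold_sizes))
        assignment[str(series)] = fold
        fold_sizes[fold] += counts[series]
    return FoldAssignment(k=k, series_to_fold=assignment, seed=seed)


# ---------------------------------------------------------------------------
# precision / recall

def _is_abstain(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.lower() in {"", "none"}


@dataclass
class PRReport:
    per_class: pd.DataFrame  # precision, recall, support per class
    micro_precision: float
    micro_recall: float
    macro_precision: float
    macro_recall: float
    n_samples: int
    n_abstained: int
    undefined_precision_classes: list[str] = field(default_factory=list)


def precision_recall(
    y_true: Sequence[object],
    y_pred: Sequence[object],
    top_m: int | None = None,
    support_floor: int | None = None,
) -> PRReport:
    """Per-class, micro and macro precision/recall with abstentions.

    *top_m* restricts scoring to the m most frequent true classes, and
    *support_floor* to classes with at least that many true samples (both
    optional).  Precision of a class nobody predicted is undefined and is
    reported as NaN (flagged); macro averages skip NaNs.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise EvaluationError("y_true and y_pred must have equal length")
    if not y_true:
        raise EvaluationError("empty input")
    true_counts = pd.Series([str(v) for v in y_true]).value_counts()
    kept = true_counts
    if support_floor is not None:
        kept = kept[kept >= support_floor]
    if top_m is not None:
        kept = kept.iloc[:top_m]
    classes = sorted(kept.index)
    pairs = [
        (str(t), None if _is_abstain(p) else str(p))
        for t, p in zip(y_true, y_pred)
        if str(t) in kept.index
    ]
    if not pairs:
        raise EvaluationError("no samples left after class restriction")
    rows = []
    undefined = []
    for cls_ in classes:
        tp = sum(1 for t, p in pairs if t == cls_ and p == cls_)
        n_pred = sum(1 for _, p in pairs if p == cls_)
        support = sum(1 for t, _ in pairs if t == cls_)
        precision = tp / n_pred if n_pred else float("nan")
        if not n_pred:
            undefined.append(cls_)
        rows.append((cls_, precision, tp / support if support else float("nan"), support))
    per_class = pd.DataFrame(rows, columns=["class", "precision", "recall", "support"]).set_index("class")
    n_predicted = sum(1 for _, p in pairs if p is not None)
    n_correct = sum(1 for t, p in pairs if p == t)
    micro_p = n_correct / n_predicted if n_predicted else float("nan")
    micro_r = n_correct / len(pairs)
    prec_vals = per_class["precision"].to_numpy()
    rec_vals = per_class["recall"].to_numpy()
    macro_p = float(np.nanmean(prec_vals)) if not np.isnan(prec_vals).all() else float("nan")
    macro_r = float(np.nanmean(rec_vals)) if not np.isnan(rec_vals).all() else float("nan")
    return PRReport(
        per_class=per_class,
        micro_precision=micro_p,
        micro_recall=micro_r,
        macro_precision=macro_p,
        macro_recall=macro_r,
        n_samples=len(pairs),
        n_abstained=len(pairs) - n_predicted,
        undefined_precision_classes=undefined,
    )


def confusion_matrix(
    y_true: Sequence[object], y_pred: Sequence[object], top_m: int | None = None
) -> pd.DataFrame:
    """Rows true class, columns predicted class plus ``(abstain)``; restricted
    to the *top_m* most frequent true classes if given."""
    true_s = pd.Series([str(v) for v in y_true])
    pred_s = pd.Series(["(abstain)" if _is_abstain(v) else str(v) for v in y_pred])
    kept = true_s.value_counts().index
    if top_m is not None:
        kept = kept[:top_m]
    mask = true_s.isin(kept).to_numpy()
    table = pd.crosstab(true_s[mask], pred_s[mask], dropna=False)
    table.index.name = "true"
    table.columns.name = "predicted"
    return table.sort_index()


# ---------------------------------------------------------------------------
# age error

@dataclass(frozen=True)
class AgeErrorReport:
    mad_years: float
    mse_years2: float
    within_one_month: float  # fraction with |error| <= 1/12 year
    n_pairs: int
    n_missing: int


def age_error(
    true_years: Sequence[float], predicted_years: Sequence[float | None]
) -> AgeErrorReport:
    """MAD, MSE and the within-1-month fraction over paired ages in years.

    Pairs whose prediction is missing (None/NaN) are excluded and counted."""
    true_arr = np.asarray(list(true_years), dtype=float)
    pred_list = [np.nan if p is None else float(p) for p in predicted_years]
    pred_arr = np.asarray(pred_list, dtype=float)
    if true_arr.shape != pred_arr.shape:
        raise EvaluationError("paired vectors must have equal length")
    mask = ~np.isnan(pred_arr) & ~np.isnan(true_arr)
    if not mask.any():
        raise EvaluationError("no usable (true, predicted) age pairs")
    delta = pred_arr[mask] - true_arr[mask]
    return AgeErrorReport(
        mad_years=float(np.mean(np.abs(delta))),
        mse_years2=float(np.mean(delta**2)),
        within_one_month=float(np.mean(np.abs(delta) <= 1.0 / 12.0)),
        n_pairs=int(mask.sum()),
        n_missing=int((~mask).sum()),
    )


# ---------------------------------------------------------------------------
# ontology distance profile

@dataclass
class DistanceProfile:
    distances: list[float]  # prediction -> gold distances
    baseline: list[float]  # random-pair distances
    n_skipped: int

    def histogram(self) -> pd.DataFrame:
        """Counts per integer distance for both distributions (inf -> 'inf')."""
        bins = sorted(
            {d for d in self.distances + self.baseline}, key=lambda d: (d == float("inf"), d)
        )
        rows = []
        for b in bins:
            rows.append(
                (
                    "inf" if b == float("inf") else int(b),
                    sum(1 for d in self.distances if d == b),
                    sum(1 for d in self.baseline if d == b),
                )
            )
        return pd.DataFrame(rows, columns=["distance", "predicted", "random"])

    def mannwhitney_less(self) -> float:
        """p-value that predicted distances are stochastically smaller than
        the random baseline (one-sided Mann-Whitney U)."""
        return float(
            mannwhitneyu(self.distances, self.baseline, alternative="less").pvalue
        )


def distance_profile(
    graph: OntologyGraph,
    true_terms: Sequence[str],
    predicted_terms: Sequence[str],
    n_random: int | None = None,
    seed: int = 0,
) -> DistanceProfile:
    """Distances between predicted and gold terms, plus a random-pair null.

    Pairs with a term missing from the graph (or an abstention) are skipped
    with a warning and counted."""
    distances: list[float] = []
    skipped = 0
    for t, p in zip(true_terms, predicted_terms):
        if _is_abstain(t) or _is_abstain(p) or t not in graph or p not in graph:
            skipped += 1
            continue
        distances.append(graph.distance(str(t), str(p)))
    if skipped:
        logger.warning("distance_profile: skipped %d pairs (missing term or abstention)", skipped)
    if not distances:
        raise EvaluationError("no scorable (true, predicted) term pairs")
    baseline = random_distance_baseline(graph, n_random or len(distances), seed)
    return DistanceProfile(distances=distances, baseline=baseline, n_skipped=skipped)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class EvaluationReport:
    """Pooled cross-validation scores for one label type."""

    label_type: str
    k: int
    stratified: bool
    n_samples: int
    accuracy: float
    micro_precision: float
    micro_recall: float
    macro_precision: float
    macro_recall: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame
    dummy_accuracy: float
    dummy_macro_auc: float
    fold_sizes: list[int]
    missing_class_folds: list[tuple[int, str]] = field(default_factory=list)
    y_true: pd.Series | None = None
    y_pred: pd.Series | None = None

    def to_json(self) -> str:
        doc = {
            "label_type": self.label_type,
            "k": self.k,
            "stratified": self.stratified,
            "n_samples": self.n_samples,
            "accuracy": self.accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "per_class": self.per_class.reset_index().to_dict(orient="records"),
            "confusion": {
                "true_classes": list(self.confusion.index),
                "predicted_classes": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "dummy_accuracy": self.dummy_accuracy,
            "dummy_macro_auc": self.dummy_macro_auc,
            "fold_sizes": self.fold_sizes,
            "missing_class_folds": self.missing_class_folds,
        }
        return json.dumps(doc, indent=1)

    def summary(self) -> str:
        lines = [
            f"{self.label_type} {self.k}-fold CV "
            f"({'experiment-stratified' if self.stratified else 'NOT stratified'}), "
            f"n={self.n_samples}",
            f"  accuracy            {self.accuracy:.3f}",
            f"  micro P/R           {self.micro_precision:.3f} / {self.micro_recall:.3f}",
            f"  macro P/R           {self.macro_precision:.3f} / {self.macro_recall:.3f}",
            f"  dummy accuracy      {self.dummy_accuracy:.3f}",
            f"  dummy macro AUC     {self.dummy_macro_auc:.3f}",
        ]
        return "\n".join(lines)


def _macro_auc_onehot(y_true: np.ndarray, onehot: pd.DataFrame) -> float:
    from sklearn.metrics import roc_auc_score

    aucs = []
    for cls_ in onehot.columns:
        truth = (y_true == cls_).astype(int)
        if truth.min() == truth.max():
            continue  # class absent (or universal); AUC undefined
        aucs.append(roc_auc_score(truth, onehot[cls_].to_numpy()))
    if not aucs:
        raise EvaluationError("macro AUC undefined: no class with both outcomes")
    return float(np.mean(aucs))


def cross_validate(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    label_type: str,
    cfg: MLConfig = DEFAULT_ML_CONFIG,
    k: int = 10,
    seed: int = 0,
    stratify_by_series: bool = True,
    top_m: int | None = None,
) -> EvaluationReport:
    """K-fold CV with feature selection and training inside each fold.

    Folds are experiment-stratified by default; ``stratify_by_series=False``
    shuffles samples into folds directly (the leakage-prone design, kept to
    measure the leakage).  Test samples of a class absent from a fold's
    training data are scored as errors and flagged in the report.
    """
    labels = pd.Series(labels).dropna()
    common = [s for s in matrix.sample_ids if s in labels.index]
    if not common:
        raise EvaluationError("no labeled samples in the matrix")
    labels = labels.loc[common]
    series = matrix.series_ids.loc[common]
    if stratify_by_series:
        assignment = make_folds(series, k=k, seed=seed)
        folds = assignment.sample_folds(series)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(common))
        folds = pd.Series(np.empty(len(common), dtype=int), index=common)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds.iloc[chunk] = f
    y_true_parts: list[pd.Series] = []
    y_pred_parts: list[pd.Series] = []
    dummy_parts: list[pd.DataFrame] = []
    dummy_label_parts: list[pd.Series] = []
    missing_class_folds: list[tuple[int, str]] = []
    fold_sizes = []
    for f in range(k):
        test_ids = [s for s in common if folds[s] == f]
        train_ids = [s for s in common if folds[s] != f]
        fold_sizes.append(len(test_ids))
        if not test_ids:
            continue
        train_matrix = matrix.copy_with(matrix.data[train_ids])
        test_matrix = matrix.copy_with(matrix.data[test_ids])
        model = train(train_matrix, labels.loc[train_ids], label_type, cfg)
        for cls_ in set(labels.loc[test_ids]) - set(model.classes):
            missing_class_folds.append((f, str(cls_)))
            logger.warning("fold %d: class %r absent from training; its test samples count as errors", f, cls_)
        _, pred = predict(model, test_matrix)
        y_true_parts.append(labels.loc[test_ids])
        y_pred_parts.append(pred)
        dummy = dummy_baseline(labels.loc[train_ids], seed=seed + f)
        dummy_parts.append(dummy.predict_onehot(test_matrix))
        dummy_label_parts.append(dummy.predict(test_matrix))
    y_true = pd.concat(y_true_parts)
    y_pred = pd.concat(y_pred_parts)
    dummy_onehot = pd.concat(dummy_parts).fillna(0.0)
    dummy_labels = pd.concat(dummy_label_parts)
    pr = precision_recall(y_true.to_numpy(), y_pred.to_numpy(), top_m=top_m)
    return EvaluationReport(
        label_type=label_type,
        k=k,
        stratified=stratify_by_series,
        n_samples=len(y_true),
        accuracy=float((y_true.to_numpy() == y_pred.to_numpy()).mean()),
        micro_precision=pr.micro_precision,
        micro_recall=pr.micro_recall,
        macro_precision=pr.macro_precision,
        macro_recall=pr.macro_recall,
        per_class=pr.per_class,
        confusion=confusion_matrix(y_true.to_numpy(), y_pred.to_numpy(), top_m=top_m),
        dummy_accuracy=float((y_true.to_numpy() == dummy_labels.to_numpy()).mean()),
        dummy_macro_auc=_macro_auc_onehot(y_true.to_numpy(), dummy_onehot),
        fold_sizes=fold_sizes,
        missing_class_folds=missing_class_folds,
        y_true=y_true,
        y_pred=y_pred,
    )
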