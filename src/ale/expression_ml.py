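"""Expression-based label prediction.

When the metadata text yields no label, a classifier fills the gap from the
sample's expression vector.  The processing chain mirrors standard
microarray practice: log-transform (if needed), collapse probes to genes by
keeping each gene's highest-mean probe, quantile-normalize between arrays,
impute missing values with k-nearest neighbours (k = 5).  Training then
drops (near-)zero-variance genes, keeps the 100 genes with the largest
one-way ANOVA F statistic against the label, and fits one L2-regularized
logistic regression per class (one-vs-rest).  Per-sample class probabilities
are the per-class sigmoids normalized to sum to one.

Sex and tissue are supported; age is deliberately NOT predicted from
expression — continuous age regression from microarrays is a different
problem and the text extractor is the only age source here.

A seeded dummy classifier (predicts by sampling the training label
distribution, ignoring expression) serves as the chance baseline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.dummy import DummyClassifier
from sklearn.feature_selection import VarianceThreshold, f_classif
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression

from .errors import ExpressionError

logger = logging.getLogger(__name__)

PREDICTABLE_LABEL_TYPES = ("sex", "tissue")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, features x samples.

    ``data`` is a DataFrame indexed by feature id with one column per sample;
    ``series_ids`` maps each sample to its experiment (series) accession and
    is what experiment-stratified cross-validation groups on.
    """

    data: pd.DataFrame
    series_ids: pd.Series
    is_gene_level: bool = False

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ExpressionError(f"duplicate sample ids: {dups}")
        self.series_ids = pd.Series(self.series_ids)
        missing = self.data.columns.difference(self.series_ids.index)
        if len(missing):
            raise ExpressionError(f"samples without a series id: {list(missing)[:5]}")
        self.series_ids = self.series_ids.loc[self.data.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def copy_with(self, data: pd.DataFrame, is_gene_level: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data,
            self.series_ids.loc[data.columns],
            self.is_gene_level if is_gene_level is None else is_gene_level,
        )


def maybe_log_transform(matrix: ExpressionMatrix, threshold: float = 30.0) -> ExpressionMatrix:
    """Apply log2(x+1) if the matrix looks linear-scale (max > *threshold*)."""
    if np.nanmax(matrix.data.to_numpy()) > threshold:
        logger.info("matrix max exceeds %g; applying log2(x+1)", threshold)
        return matrix.copy_with(np.log2(matrix.data + 1.0))
    return matrix


@dataclass(frozen=True)
class MLConfig:
    n_features: int = 100
    variance_threshold: float = 0.0  # drop variance <= this (0: zero-variance only)
    regularization_strength: float = 1.0  # C of LogisticRegression
    knn_k: int = 5
    min_class_size: int = 10
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.knn_k < 1:
            raise ValueError("n_features and knn_k must be >= 1")


DEFAULT_ML_CONFIG = MLConfig()


# ---------------------------------------------------------------------------
# normalization chain

def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to gene rows.

    Each gene keeps the row of its probe with the highest mean expression
    across samples (ties: lexicographically smallest probe id).  Probes
    absent from the map are dropped, with a count logged.
    """
    probes = [p for p in matrix.data.index if p in probe_map]
    dropped = len(matrix.data.index) - len(probes)
    if dropped:
        logger.info("collapse_probes: %d probes not in map, dropped", dropped)
    if not probes:
        raise ExpressionError("no probe ids in common between matrix and probe map")
    sub = matrix.data.loc[probes]
    means = sub.mean(axis=1)
    choice = (
        pd.DataFrame(
            {"probe": probes, "gene": [probe_map[p] for p in probes], "mean": means.to_numpy()}
        )
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .groupby("gene", sort=True)
        .first()
    )
    gene_data = sub.loc[choice["probe"]].copy()
    gene_data.index = choice.index
    return matrix.copy_with(gene_data, is_gene_level=True)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic between-array quantile normalization.

    The reference distribution is the mean over samples of each sorted
    value vector; each sample's value of rank r is replaced by reference[r].
    Tied values within a sample receive the mean of their tied reference
    values, so the map is well defined and order preserving.
    """
    values = matrix.data.to_numpy(dtype=float)
    n_features, n_samples = values.shape
    if n_samples < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy_with(matrix.data.copy())
    if np.isnan(values).any():
        raise ExpressionError("quantile_normalize requires a complete matrix; impute first")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_features)
        assigned[order] = reference
        # average the reference values over tied input values
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(col, sort=False).transform("mean").to_numpy()
    return matrix.copy_with(pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns))


def knn_impute(matrix: ExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """Impute missing entries from the k nearest samples.

    Distances are Euclidean over mutually observed genes; a missing entry is
    the mean of the gene's values in the k nearest samples observing it, or
    the gene's global mean if no neighbour observes it.  All-missing genes
    are dropped with a warning.
    """
    data = matrix.data
    values = data.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return matrix.copy_with(data.copy())
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        logger.warning("knn_impute: dropping %d all-missing features", int(all_missing.sum()))
        data = data.loc[~all_missing]
        values = data.to_numpy(dtype=float)
    n_samples = values.shape[1]
    imputer = KNNImputer(n_neighbors=max(1, min(k, n_samples - 1)))
    filled = imputer.fit_transform(values.T).T  # samples are the neighbour space
    return matrix.copy_with(pd.DataFrame(filled, index=data.index, columns=data.columns))


def normalize_chain(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str] | None = None,
    cfg: MLConfig = DEFAULT_ML_CONFIG,
) -> ExpressionMatrix:
    """log -> collapse (if probe map given) -> quantile -> impute."""
    matrix = maybe_log_transform(matrix)
    if probe_map is not None and not matrix.is_gene_level:
        matrix = collapse_probes(matrix, probe_map)
    matrix = knn_impute(matrix, cfg.knn_k)
    matrix = quantile_normalize(matrix)
    return matrix


# ---------------------------------------------------------------------------
# feature selection and the one-vs-rest model

def _aligned_labels(matrix: ExpressionMatrix, labels: Mapping[str, str] | pd.Series) -> pd.Series:
    labels = pd.Series(labels).dropna()
    common = [s for s in matrix.sample_ids if s in labels.index]
    if not common:
        raise ExpressionError("no labeled samples present in the expression matrix")
    return labels.loc[common]


def anova_f(
    matrix: ExpressionMatrix, labels: Mapping[str, str] | pd.Series
) -> pd.Series:
    """One-way ANOVA F statistic of every gene against the label classes.

    F = between-group mean square / within-group mean square; for two
    classes this equals the squared pooled-variance t statistic.
    """
    y = _aligned_labels(matrix, labels)
    X = matrix.data[y.index].to_numpy(dtype=float).T  # samples x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        f_scores, _ = f_classif(X, y.to_numpy())
    return pd.Series(f_scores, index=matrix.feature_ids)


def select_features(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    cfg: MLConfig = DEFAULT_ML_CONFIG,
) -> list[str]:
    """Variance filter, then top-``n_features`` genes by one-way ANOVA F.

    Ties are broken toward the smaller gene id.  If fewer genes survive the
    variance filter than requested, all survivors are returned with a
    warning.
    """
    y = _aligned_labels(matrix, labels)
    classes, counts = np.unique(y.to_numpy(), return_counts=True)
    if len(classes) < 2 or (counts < 2).any():
        raise ExpressionError("need >= 2 classes with >= 2 samples each for selection")
    X = matrix.data[y.index].to_numpy(dtype=float).T  # samples x genes
    vt = VarianceThreshold(threshold=cfg.variance_threshold)
    X_kept = vt.fit_transform(X)
    kept_ids = np.asarray(matrix.feature_ids)[vt.get_support()]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_scores, _ = f_classif(X_kept, y.to_numpy())
    f_scores = np.nan_to_num(f_scores, nan=-np.inf, posinf=np.inf)
    order = sorted(range(len(kept_ids)), key=lambda i: (-f_scores[i], kept_ids[i]))
    if len(kept_ids) < cfg.n_features:
        logger.warning(
            "select_features: only %d genes survive the variance filter (requested %d)",
            len(kept_ids), cfg.n_features,
        )
    return [kept_ids[i] for i in order[: cfg.n_features]]


@dataclass
class TrainedModel:
    """One-vs-rest logistic regression over the selected genes."""

    label_type: str
    classes: list[str]
    selected_genes: list[str]
    coef: np.ndarray  # n_classes x n_genes
    intercept: np.ndarray  # n_classes
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "label_type": self.label_type,
            "classes": self.classes,
            "selected_genes": self.selected_genes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        return cls(
            label_type=doc["label_type"],
            classes=doc["classes"],
            selected_genes=doc["selected_genes"],
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=np.asarray(doc["intercept"], dtype=float),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def train(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    label_type: str,
    cfg: MLConfig = DEFAULT_ML_CONFIG,
) -> TrainedModel:
    """Fit the OVR logistic-regression model (selection done in here, on the
    training samples only, so cross-validation never leaks test data)."""
    if label_type not in PREDICTABLE_LABEL_TYPES:
        raise ExpressionError(
            f"label type {label_type!r} is not predicted from expression "
            f"(supported: {PREDICTABLE_LABEL_TYPES})"
        )
    y = _aligned_labels(matrix, labels)
    classes, counts = np.unique(y.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ExpressionError("training requires at least two classes")
    small = classes[counts < cfg.min_class_size]
    if len(small):
        raise ExpressionError(
            f"classes below the {cfg.min_class_size}-sample floor: {list(small)}"
        )
    genes = select_features(matrix, y, cfg)
    X = matrix.data.loc[genes, y.index].to_numpy(dtype=float).T
    coef = np.zeros((len(classes), len(genes)))
    intercept = np.zeros(len(classes))
    for i, cls_ in enumerate(classes):
        clf = LogisticRegression(
            C=cfg.regularization_strength,
            solver="lbfgs",
            max_iter=cfg.max_iter,
            random_state=cfg.seed,
        )
        clf.fit(X, (y.to_numpy() == cls_).astype(int))
        coef[i] = clf.coef_[0]
        intercept[i] = clf.intercept_[0]
    config_doc = asdict(cfg)
    return TrainedModel(
        label_type=label_type,
        classes=[str(c) for c in classes],
        selected_genes=list(genes),
        coef=coef,
        intercept=intercept,
        metadata={
            "n_samples": int(len(y)),
            "seed": cfg.seed,
            "config": config_doc,
            "config_hash": hashlib.sha256(
                json.dumps(config_doc, sort_keys=True).encode()
            ).hexdigest()[:12],
        },
    )


def predict(model: TrainedModel, matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Class probabilities (rows samples, columns classes) and argmax labels.

    Per-class sigmoid scores are normalized to sum to one per sample; ties
    resolve to the first class in model order.  Genes the model needs but the
    matrix lacks are a named error listing them.
    """
    missing = [g for g in model.selected_genes if g not in matrix.data.index]
    if missing:
        raise ExpressionError(f"matrix lacks {len(missing)} model genes: {missing[:10]}")
    X = matrix.data.loc[model.selected_genes].to_numpy(dtype=float).T
    z = X @ model.coef.T + model.intercept
    scores = 1.0 / (1.0 + np.exp(-z))
    probs = scores / scores.sum(axis=1, keepdims=True)
    prob_df = pd.DataFrame(probs, index=matrix.sample_ids, columns=model.classes)
    labels = pd.Series(
        [model.classes[i] for i in np.argmax(probs, axis=1)], index=matrix.sample_ids
    )
    return prob_df, labels


# ---------------------------------------------------------------------------
# chance baseline and text/ML combination

@dataclass
class DummyModel:
    """Predicts by sampling the empirical training label distribution."""

    classes: list[str]
    _clf: DummyClassifier

    def predict(self, matrix: ExpressionMatrix) -> pd.Series:
        n = len(matrix.sample_ids)
        out = self._clf.predict(np.zeros((n, 1)))
        return pd.Series(out, index=matrix.sample_ids)

    def predict_onehot(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        labels = self.predict(matrix)
        onehot = pd.DataFrame(0.0, index=labels.index, columns=self.classes)
        for cls_ in self.classes:
            onehot.loc[labels == cls_, cls_] = 1.0
        return onehot


def dummy_baseline(labels: Mapping[str, str] | pd.Series, seed: int = 0) -> DummyModel:
    y = pd.Series(labels).dropna().to_numpy()
    if len(y) == 0:
        raise ExpressionError("dummy baseline needs at least one labeled sample")
    clf = DummyClassifier(strategy="stratified", random_state=seed)
    clf.fit(np.zeros((len(y), 1)), y)
    return DummyModel(classes=[str(c) for c in clf.classes_], _clf=clf)


def combine_labels(
    text_label: object | None,
    ml_prediction: tuple[str, float] | None,
    threshold: float = 0.5,
) -> object | None:
    """Text label wins whenever present; otherwise the ML argmax is used iff
    its probability reaches *threshold*.  Returns the winning label object,
    the (class, probability) tuple, or None."""
    if text_label is not None:
        return text_label
    if ml_prediction is not None and ml_prediction[1] >= threshold:
        return ml_prediction
    return None


# ---------------------------------------------------------------------------
# expression I/O (TSV dense, MTX sparse triplet)

def read_expression(
    path: str | Path, series: Mapping[str, str] | pd.Series | None = None
) -> ExpressionMatrix:
    """Read a features-x-samples matrix.

    TSV: header row of sample ids, first column feature ids.  MTX: a
    MatrixMarket triplet file with ``<stem>.rows`` / ``<stem>.cols`` id lists
    alongside.  *series* maps sample -> series id (defaults to one
    pseudo-series per sample, which disables stratification).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        data = pd.DataFrame(np.asarray(mmread(path).todense()), index=rows, columns=cols)
    else:
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
    if series is None:
        series = pd.Series({s: f"series_of_{s}" for s in data.columns})
    return ExpressionMatrix(data, pd.Series(series))


def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV probe_id<TAB>gene_id (header optional)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or parts[0] in {"probe_id", "probe"}:
            continue
        out[parts[0]] = parts[1]
    return out


def read_series_map(path: str | Path) -> pd.Series:
    """Two-column TSV sample_id<TAB>series_id (header optional)."""
    pairs: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or parts[0] in {"sample_id", "sample"}:
            continue
        pairs[parts[0]] = parts[1]
    return pd.Series(pairs)
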