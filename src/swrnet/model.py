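"""Driver-gene classification on proximity features.

Training data pair known driver genes (positives) with degree-matched
non-driver negatives drawn at a configurable negative:positive ratio
(default 19:1, i.e. 5% prevalence, which also fixes the precision-recall
baseline at 0.05). Six classifier families are supported, each with a small
hyperparameter grid searched by inner cross-validation on the training folds
only; extremely randomized trees are the default family. Performance is
summarized by AUROC (rank-based, half-credit for ties) and AUPRC (step-wise
precision-recall integration), and two correlated ROC curves computed on the
same labels are compared with DeLong's test in its fast midrank formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier, RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .netgraph import DegreeMatchError, sample_degree_matched

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

DEFAULT_FAMILY = "extra_trees"
DEFAULT_RATIO = 19
DEFAULT_FOLDS = 5

#: Deliberately small grids — one refinement step around library defaults.
DEFAULT_GRIDS = {
    "extra_trees": {"n_estimators": [100, 300], "max_depth": [None, 8],
                    "min_samples_leaf": [1, 5]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 8],
                      "min_samples_leaf": [1, 5]},
    "gradient_boosting": {"n_estimators": [100, 300], "learning_rate": [0.1, 1.0]},
    "adaboost": {"n_estimators": [100, 300], "learning_rate": [0.1, 1.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
}


class TrainingAssemblyError(RuntimeError):
    """Raised when the degree-matched negative pool is exhausted."""


class MetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class labels)."""


class DegenerateVarianceError(RuntimeError):
    """Raised when the DeLong variance estimate is zero with a nonzero delta."""


@dataclass
class LabeledSet:
    genes: list
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("labeled genes must be unique")
        if len(self.genes) != len(self.labels):
            raise ValueError("genes and labels must align")

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


@dataclass
class ModelSpec:
    family: str = DEFAULT_FAMILY
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {sorted(DEFAULT_GRIDS)}")

    @property
    def effective_grid(self) -> dict:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]


@dataclass
class MetricsRecord:
    auroc: float
    auprc: float
    fold_auroc: list
    fold_auprc: list
    prevalence: float


@dataclass
class TrainedModel:
    estimator: object
    spec: ModelSpec
    feature_names: list
    version: int = MODEL_FORMAT_VERSION


def _make_estimator(family: str, seed: int, params: dict):
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", probability=True, random_state=seed, **params)),
        ])
    if family == "logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed, **params)),
        ])
    raise ValueError(f"unknown model family {family!r}")


def assemble_training(graph, positives, ratio: int = DEFAULT_RATIO,
                      max_tolerance: int | None = None, seed: int = 0) -> LabeledSet:
    """Positives plus ``ratio`` x as many degree-matched negatives.

    Negatives are drawn in ``ratio`` passes over the positive list (one
    matched control per positive per pass), without replacement and excluding
    the positives. ``max_tolerance=None`` lets the degree window widen as far
    as needed; pass 1 for strict +-1 matching. Prevalence of the result is
    exactly 1/(1+ratio).
    """
    node_set = set(graph.nodes)
    pos = sorted(set(positives) & node_set)
    dropped = len(set(positives)) - len(pos)
    if dropped:
        logger.info("assemble_training: %d positive(s) not in network dropped", dropped)
    if not pos:
        raise ValueError("no positives present in the network")
    negatives: list = []
    used = set(pos)
    for i in range(ratio):
        try:
            batch = sample_degree_matched(graph, pos, exclude=used,
                                          max_tolerance=max_tolerance,
                                          seed=seed * 10_007 + i)
        except DegreeMatchError as exc:
            raise TrainingAssemblyError(
                f"negative pool exhausted after {i} of {ratio} passes "
                f"({len(negatives)} negatives drawn): {exc}") from exc
        used.update(batch)
        negatives.extend(batch)
    genes = pos + negatives
    labels = np.array([1] * len(pos) + [0] * len(negatives))
    provenance = {"n_positives": len(pos), "ratio": ratio, "seed": seed,
                  "max_tolerance": max_tolerance}
    return LabeledSet(genes=genes, labels=labels, provenance=provenance)


def _design_matrix(features: pd.DataFrame, genes) -> np.ndarray:
    X = features.loc[list(genes)].to_numpy(dtype=float)
    n_nan = int(np.isnan(X).sum())
    if n_nan:
        logger.info("imputing %d missing feature value(s) to 0", n_nan)
        X = np.nan_to_num(X, nan=0.0)
    return X


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney with half-credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise integration."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() in (0, len(labels)):
        raise MetricError("both classes must be present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _select_params(X, y, spec: ModelSpec, seed: int, inner_folds: int = 3) -> dict:
    """Grid selection by mean inner-fold AUROC; ties keep the first-listed config."""
    grid = list(ParameterGrid(spec.effective_grid))
    if len(grid) <= 1:
        return grid[0] if grid else {}
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in grid:
        fold_scores = []
        for tr, va in inner.split(X, y):
            est = _make_estimator(spec.family, spec.seed, params)
            est.fit(X[tr], y[tr])
            fold_scores.append(auroc(est.predict_proba(X[va])[:, 1], y[va]))
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:  # strict: ties keep the earlier config
            best_score, best_params = mean_score, params
    return best_params


def cross_validate(features: pd.DataFrame, labeled: LabeledSet,
                   spec: ModelSpec | None = None, folds: int = DEFAULT_FOLDS,
                   seed: int = 0) -> MetricsRecord:
    """Stratified k-fold evaluation with inner grid selection.

    Hyperparameters are selected per outer fold by inner cross-validation on
    the training portion only, so outer test labels never inform selection.
    Reported AUROC/AUPRC are means over the outer folds.
    """
    spec = spec or ModelSpec()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = _design_matrix(features, labeled.genes)
    y = labeled.labels
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_auroc, fold_auprc = [], []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {k} contains a single class")
        params = _select_params(X[tr], y[tr], spec, seed=seed * 31 + k)
        est = _make_estimator(spec.family, spec.seed, params)
        est.fit(X[tr], y[tr])
        prob = est.predict_proba(X[te])[:, 1]
        fold_auroc.append(auroc(prob, y[te]))
        fold_auprc.append(auprc(prob, y[te]))
    return MetricsRecord(auroc=float(np.mean(fold_auroc)),
                         auprc=float(np.mean(fold_auprc)),
                         fold_auroc=fold_auroc, fold_auprc=fold_auprc,
                         prevalence=labeled.prevalence)


def fit(features: pd.DataFrame, labeled: LabeledSet,
        spec: ModelSpec | None = None) -> TrainedModel:
    """Grid-select on the full labeled data, then fit on all of it."""
    spec = spec or ModelSpec()
    X = _design_matrix(features, labeled.genes)
    y = labeled.labels
    params = _select_params(X, y, spec, seed=spec.seed)
    est = _make_estimator(spec.family, spec.seed, params)
    est.fit(X, y)
    return TrainedModel(estimator=est, spec=spec,
                        feature_names=list(features.columns))


def score_all(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score every feature row; deterministic rank (score desc, gene asc).

    Refuses feature matrices whose columns mismatch the model's by name or
    order.
    """
    if list(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the model "
                         f"(expected {model.feature_names}, got {list(features.columns)})")
    X = _design_matrix(features, features.index)
    prob = model.estimator.predict_proba(X)[:, 1]
    table = pd.DataFrame({"gene": list(features.index), "score": prob})
    table = table.sort_values(["score", "gene"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"version": model.version,
                 "spec": {"family": model.spec.family, "grid": model.spec.grid,
                          "seed": model.spec.seed},
                 "feature_names": model.feature_names,
                 "estimator": model.estimator}, path)


def load_model(path) -> TrainedModel:
    bundle = joblib.load(path)
    if bundle.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {bundle.get('version')}")
    spec = ModelSpec(**bundle["spec"])
    return TrainedModel(estimator=bundle["estimator"], spec=spec,
                        feature_names=bundle["feature_names"],
                        version=bundle["version"])


def _delong_components(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise MetricError("both classes must be present")
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n          # structural components over positives
    v01 = 1.0 - (tz[m:] - ty) / m    # ... over negatives
    return float(auc), v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong's test for two correlated ROC AUCs on the same labels.

    Returns (delta_auc, two-sided p) where delta_auc = AUC(a) - AUC(b); the
    covariance of the paired AUCs is estimated from the midrank structural
    components.
    """
    labels = np.asarray(labels, dtype=int)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    delta = auc_a - auc_b
    if delta == 0.0:
        return 0.0, 1.0
    m, n = len(v10_a), len(v01_a)
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    if var <= 0:
        raise DegenerateVarianceError(
            f"zero DeLong variance with delta_auc={delta:.4g}")
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(p)


def build_gold_set(lists, min_lists: int = 2) -> set:
    """Genes appearing in at least ``min_lists`` of the input gene lists."""
    if isinstance(lists, dict):
        lists = list(lists.values())
    lists = [set(l) for l in lists]
    if len(lists) < min_lists:
        logger.warning("build_gold_set: fewer lists (%d) than min_lists=%d",
                       len(lists), min_lists)
    counts: dict = {}
    for s in lists:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_lists}


def select_extremes(scores: pd.DataFrame, exclude=(), n: int = 2000):
    """Top-n and bottom-n genes by deterministic rank after exclusions.

    ``scores`` is a ScoreTable frame (gene, score, rank). Both lists preserve
    rank order (descending score); they are disjoint by construction.
    """
    exclude = set(exclude)
    remaining = scores[~scores["gene"].isin(exclude)]
    remaining = remaining.sort_values("rank", kind="mergesort")
    if len(remaining) < 2 * n:
        raise ValueError(f"need >= {2 * n} genes after exclusion, "
                         f"have {len(remaining)}")
    high = list(remaining["gene"].head(n))
    low = list(remaining["gene"].tail(n))
    return high, low


def evaluate_benchmark(model: TrainedModel, features: pd.DataFrame, graph,
                       benchmark_positives, exclude=(),
                       max_tolerance: int | None = None,
                       seed: int = 0) -> float:
    """AUROC of a trained model on an external positive list.

    Negatives are freshly degree-matched to the benchmark positives (one per
    positive) and both groups are scored with the trained model. ``exclude``
    removes further genes from the negative pool — typically the union of
    all known driver lists, so that negatives are genes absent from every
    benchmark.
    """
    node_set = set(graph.nodes) & set(features.index)
    pos = sorted(set(benchmark_positives) & node_set)
    if not pos:
        raise ValueError("no benchmark positives present in network/features")
    neg = sample_degree_matched(graph, pos, exclude=set(pos) | set(exclude),
                                max_tolerance=max_tolerance, seed=seed)
    neg = [g for g in neg if g in set(features.index)]
    genes = pos + neg
    table = score_all(model, features.loc[genes])
    score_of = dict(zip(table["gene"], table["score"]))
    labels = [1] * len(pos) + [0] * len(neg)
    return auroc([score_of[g] for g in genes], labels)
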