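"""Gradient-boosted screening model for gastric cancer.

A stochastic gradient boosting classifier (Bernoulli deviance, shallow
trees) is fit on microbial protein abundances; features are ranked by
normalized reduction-in-loss importance and the top-k are refit into the
final screening model, evaluated with accuracy (exact binomial CI),
sensitivity, specificity at a 0.5 probability cutoff, and trapezoidal AUC.
A t-SNE embedding plus pairwise Euclidean distances serve as diagnostics
of the selected feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from statsmodels.stats.proportion import proportion_confint

from .quantify import CohortMetadata, QuantTable

__all__ = [
    "ModelConfig",
    "EvaluationReport",
    "split_cohort",
    "design_matrix",
    "rank_features",
    "train_and_evaluate",
    "embedding_diagnostics",
]

POSITIVE_CLASS = "cancer"


@dataclass
class ModelConfig:
    """Boosting hyperparameters mirroring the gbm-style parameterization.

    depth / n_trees / learning_rate / min_node_size are the classic
    ``interaction.depth`` / ``n.trees`` / ``shrinkage`` / ``n.minobsinnode``
    quartet; ``cv_folds=0`` skips the cross-validated error estimate.
    """

    depth: int = 3
    n_trees: int = 150
    learning_rate: float = 0.1
    min_node_size: int = 10
    cv_folds: int = 10
    top_k: int = 50
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("depth", "n_trees", "learning_rate", "min_node_size", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def estimator(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            loss="log_loss",  # Bernoulli deviance
            max_depth=self.depth,
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            min_samples_leaf=self.min_node_size,
            random_state=self.seed,
        )


@dataclass
class EvaluationReport:
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict[str, int]  # tp, fp, tn, fn
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def split_cohort(
    meta: CohortMetadata, train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of sample ids, reproducible by seed.

    Each class contributes ``round(train_fraction * n_class)`` training
    samples; the partition is exact and disjoint.
    """
    groups = meta.df["group"]
    classes = sorted(groups.unique())
    if len(classes) < 2:
        raise ValueError("split requires both outcome classes")
    rng = np.random.RandomState(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in classes:
        members = sorted(groups.index[groups == cls])
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return sorted(train), sorted(test)


def design_matrix(table: QuantTable, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Samples x features matrix of log2(intensity + 1); missing -> 0."""
    vals = table.values if samples is None else table.values[list(samples)]
    X = np.log2(vals.fillna(0.0).to_numpy(dtype=float).T + 1.0)
    return pd.DataFrame(X, index=vals.columns, columns=vals.index)


def _labels(meta: CohortMetadata, samples: Sequence[str]) -> np.ndarray:
    return (meta.group_labels(samples) == POSITIVE_CLASS).astype(int).to_numpy()


def rank_features(
    train_table: QuantTable, meta: CohortMetadata, config: ModelConfig
) -> pd.DataFrame:
    """Rank features by boosted-ensemble relative influence on training data.

    Fits the full-feature ensemble on the training samples, estimating the
    prediction error by stratified k-fold cross-validation when
    ``config.cv_folds > 0``, and returns a frame (index = feature) with
    ``influence`` normalized to sum 100, sorted by decreasing influence
    with ties broken by feature id.  The frame carries the CV accuracy
    estimate in ``.attrs["cv_accuracy"]``.
    """
    X = design_matrix(train_table)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite intensities in training table")
    y = _labels(meta, X.index)
    counts = np.bincount(y, minlength=2)
    if config.cv_folds > 0 and counts.min() < config.cv_folds:
        raise ValueError("each class needs at least cv_folds samples for cross-validation")
    est = config.estimator()
    cv_accuracy = None
    if config.cv_folds > 0:
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        cv_accuracy = float(cross_val_score(est, X.to_numpy(), y, cv=cv).mean())
    est.fit(X.to_numpy(), y)
    importance = est.feature_importances_
    total = importance.sum()
    influence = importance / total * 100.0 if total > 0 else np.zeros_like(importance)
    out = pd.DataFrame({"influence": influence}, index=X.columns)
    out = out.sort_values("influence", ascending=False, kind="mergesort")
    # mergesort is stable; enforce feature-id order inside ties explicitly
    out = (
        out.reset_index()
        .sort_values(["influence", "index"], ascending=[False, True])
        .set_index("index")
    )
    out.index.name = None
    out.attrs["cv_accuracy"] = cv_accuracy
    return out


def _evaluate(y_true: np.ndarray, prob: np.ndarray, threshold: float = 0.5) -> EvaluationReport:
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    n = len(y_true)
    acc = (tp + tn) / n
    lo, hi = proportion_confint(tp + tn, n, alpha=0.05, method="beta")  # Clopper-Pearson
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(y_true, prob)) if len(np.unique(y_true)) == 2 else float("nan")
    return EvaluationReport(
        accuracy=float(acc),
        accuracy_ci=(float(lo), float(hi)),
        sensitivity=float(sens),
        specificity=float(spec),
        auc=auc,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        n=n,
    )


def train_and_evaluate(
    train_table: QuantTable,
    meta: CohortMetadata,
    features: Sequence[str],
    test_sets: Mapping[str, tuple[QuantTable, CohortMetadata]],
    config: ModelConfig,
) -> tuple[GradientBoostingClassifier, dict[str, EvaluationReport]]:
    """Refit on the selected features and score every evaluation dataset.

    ``features`` is the fixed, pre-selected list (typically the top-k of
    :func:`rank_features` on the training data alone — no test-set
    leakage).  Each entry of ``test_sets`` maps a dataset name to a
    (table, metadata) pair; missing features in any table raise a schema
    error naming them.
    """
    features = list(features)
    missing = [f for f in features if f not in set(train_table.features)]
    if missing:
        raise KeyError(f"selected feature(s) absent from training table: {missing}")
    Xtr = design_matrix(train_table.subset_features(features))
    ytr = _labels(meta, Xtr.index)
    est = config.estimator()
    est.fit(Xtr.to_numpy(), ytr)
    reports: dict[str, EvaluationReport] = {}
    for name, (table, tmeta) in test_sets.items():
        missing = [f for f in features if f not in set(table.features)]
        if missing:
            raise KeyError(f"selected feature(s) absent from dataset {name!r}: {missing}")
        X = design_matrix(table.subset_features(features))
        y = _labels(tmeta, X.index)
        prob = est.predict_proba(X.to_numpy())[:, 1]
        reports[name] = _evaluate(y, prob)
    return est, reports


def embedding_diagnostics(
    table: QuantTable,
    meta: CohortMetadata,
    seed: int = 0,
    perplexity: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """t-SNE embedding and Euclidean distances over the selected features.

    Features are log2(x+1)-transformed and z-scored before both the
    embedding and the distance computation.  Returns the 2-D coordinates,
    the symmetric zero-diagonal distance matrix, and mean distances from
    healthy controls to the gastritis, stage I-II and stage III-IV strata
    (where those strata are present in the metadata).
    """
    if len(table.samples) < 3:
        raise ValueError("embedding needs at least 3 samples")
    X = design_matrix(table).to_numpy()
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all selected features are constant; embedding is degenerate")
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n = Xz.shape[0]
    eff_perplexity = min(perplexity, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        random_state=seed,
        init="pca",
    )
    coords = pd.DataFrame(tsne.fit_transform(Xz), index=table.samples, columns=["tsne1", "tsne2"])
    dist = pd.DataFrame(
        squareform(pdist(Xz, metric="euclidean")), index=table.samples, columns=table.samples
    )

    df = meta.df.loc[table.samples]
    strata = {
        "control": (df["group"] == "non_cancer") & (df["stage"].isin(["none", ""])),
        "gastritis": df["stage"] == "gastritis",
        "stage_I_II": (df["group"] == "cancer") & df["stage"].isin(["I", "II"]),
        "stage_III_IV": (df["group"] == "cancer") & df["stage"].isin(["III", "IV"]),
    }
    control = list(df.index[strata["control"]])
    group_distances: dict[str, float] = {}
    for name in ("gastritis", "stage_I_II", "stage_III_IV"):
        members = list(df.index[strata[name]])
        if control and members:
            group_distances[f"control_vs_{name}"] = float(
                dist.loc[control, members].to_numpy().mean()
            )
    return coords, dist, group_distances
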