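"""Random-Forest classification of plant parts (RFp) and taxon-part classes
(RFtp) from band-aggregate features.

Workflow: stratified 80/20 split; exhaustive hyperparameter grid search
(mtry x ntree x maxnodes x nodesize) scored by mean 10-fold cross-validated
accuracy on the training part; refit on the full training part with the
winning combination; evaluation on the held-out test part with confusion
matrix, overall accuracy and its exact binomial CI, Cohen's kappa, per-class
sensitivity / specificity / balanced accuracy, out-of-bag error, and
permutation importance (mean decrease in accuracy).

Hyperparameter names follow the conventions of classic random-forest
implementations: mtry = candidate features per split, ntree = number of trees,
maxnodes = maximum terminal nodes per tree, nodesize = minimum samples per
terminal node. Ties in the grid search break deterministically toward the
cheaper model: smaller ntree, then mtry, then maxnodes, then nodesize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import DataError, StratificationError, ValidationError
from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Split, tuning grid and seed for one Random-Forest model."""

    split_fraction: float = 0.8
    cv_folds: int = 10
    mtry_grid: tuple[int, ...] = (5, 10, 20)
    ntree_grid: tuple[int, ...] = (100, 300, 500)
    maxnodes_grid: tuple[int, ...] = (50, 100)
    nodesize_grid: tuple[int, ...] = (1, 5, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        for name in ("mtry_grid", "ntree_grid", "maxnodes_grid", "nodesize_grid"):
            grid = getattr(self, name)
            if len(grid) == 0 or any(v < 1 for v in grid):
                raise ValidationError(f"{name} must be non-empty with positive values")


@dataclass
class TrainResult:
    """A tuned, refitted forest plus the grid-search audit trail."""

    model: RandomForestClassifier
    chosen_hyperparameters: dict
    cv_table: pd.DataFrame


@dataclass
class EvalReport:
    """Test-set evaluation of one classifier.

    ``confusion[i, j]`` counts test samples of true class ``labels[i]``
    predicted as ``labels[j]``; labels are sorted lexicographically.
    """

    labels: list[str]
    confusion: np.ndarray
    overall_accuracy: float
    ci95: tuple[float, float]
    kappa: float
    per_class: dict[str, dict[str, float]]
    oob_error_pct: float | None = None
    importances: dict[str, float] = field(default_factory=dict)
    chosen_hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "overall_accuracy": float(self.overall_accuracy),
            "ci95_lo": float(self.ci95[0]),
            "ci95_hi": float(self.ci95[1]),
            "kappa": float(self.kappa),
            "per_class": {
                c: {k: float(v) for k, v in stats.items()}
                for c, stats in self.per_class.items()
            },
            "oob_error_pct": None if self.oob_error_pct is None else float(self.oob_error_pct),
            "importances": {k: float(v) for k, v in self.importances.items()},
            "chosen_hyperparameters": dict(self.chosen_hyperparameters),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            labels=list(d["labels"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            overall_accuracy=float(d["overall_accuracy"]),
            ci95=(float(d["ci95_lo"]), float(d["ci95_hi"])),
            kappa=float(d["kappa"]),
            per_class={
                c: {k: float(v) for k, v in stats.items()}
                for c, stats in d["per_class"].items()
            },
            oob_error_pct=None if d.get("oob_error_pct") is None else float(d["oob_error_pct"]),
            importances={k: float(v) for k, v in d.get("importances", {}).items()},
            chosen_hyperparameters=dict(d.get("chosen_hyperparameters", {})),
        )


# ---------------------------------------------------------------------------
# splitting


def stratified_split(
    labels: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split.

    Per class, ``round(fraction * n_class)`` samples (clipped so both sides get
    at least one) go to training. Classes are processed in lexicographic order;
    within a class the assignment is a seeded permutation. Returns sorted
    train and test index arrays forming a partition of ``range(len(labels))``.
    """
    labels = np.asarray(labels)
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise StratificationError(
                f"class {cls!r} has {idx.size} sample(s); need >= 2 to stratify"
            )
        perm = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return np.array(sorted(train)), np.array(sorted(test))


# ---------------------------------------------------------------------------
# tuning


def _make_forest(
    ntree: int, mtry: int, maxnodes: int, nodesize: int, seed: int, oob: bool
) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        max_leaf_nodes=maxnodes,
        min_samples_leaf=nodesize,
        bootstrap=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def tune_and_train(features: FeatureTable, config: RFConfig) -> TrainResult:
    """Exhaustive grid search by mean CV accuracy, then refit on all rows.

    ``features`` holds the *training* part only. mtry values exceeding the
    number of features are clipped (and logged). The cv table has one row per
    grid combination in evaluation order.
    """
    X = features.matrix
    y = np.asarray(features.class_labels)
    if not np.all(np.isfinite(X)):
        raise DataError("feature table contains missing/non-finite values")
    n_features = X.shape[1]
    cv = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**32)
    )
    folds = list(cv.split(X, y))
    rows = []
    best = None  # (mean_acc, row_index)
    combo_idx = 0
    for ntree in config.ntree_grid:
        for mtry in config.mtry_grid:
            mtry_eff = min(mtry, n_features)
            if mtry_eff != mtry:
                logger.info("mtry=%d clipped to %d (only %d features)", mtry, mtry_eff, n_features)
            for maxnodes in config.maxnodes_grid:
                for nodesize in config.nodesize_grid:
                    accs = []
                    for k, (tr, va) in enumerate(folds):
                        forest = _make_forest(
                            ntree, mtry_eff, maxnodes, nodesize,
                            seed=(config.seed * 1000003 + combo_idx * 101 + k) % (2**31),
                            oob=False,
                        )
                        forest.fit(X[tr], y[tr])
                        accs.append(float(np.mean(forest.predict(X[va]) == y[va])))
                    mean_acc = float(np.mean(accs))
                    rows.append(
                        {
                            "ntree": ntree,
                            "mtry": mtry,
                            "mtry_effective": mtry_eff,
                            "maxnodes": maxnodes,
                            "nodesize": nodesize,
                            "mean_cv_accuracy": mean_acc,
                            "sd_cv_accuracy": float(np.std(accs, ddof=1)),
                        }
                    )
                    # strict > keeps the first (cheapest) of tied combos
                    if best is None or mean_acc > best[0]:
                        best = (mean_acc, len(rows) - 1)
                    combo_idx += 1
    chosen = {
        k: rows[best[1]][k]
        for k in ("ntree", "mtry", "mtry_effective", "maxnodes", "nodesize")
    }
    chosen["mean_cv_accuracy"] = rows[best[1]]["mean_cv_accuracy"]
    logger.info("chosen hyperparameters: %s", chosen)
    final = _make_forest(
        chosen["ntree"], chosen["mtry_effective"], chosen["maxnodes"],
        chosen["nodesize"], seed=config.seed % (2**31), oob=True,
    )
    final.fit(X, y)
    return TrainResult(model=final, chosen_hyperparameters=chosen, cv_table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# metrics


def cohen_kappa(confusion: np.ndarray) -> float:
    """Cohen's chance-corrected agreement from a square count matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginal
    products. The degenerate all-one-class table (p_e = 1) returns 1 when the
    observed agreement is also perfect.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if (c < 0).any():
        raise DataError("confusion matrix entries must be >= 0")
    total = c.sum()
    if total == 0:
        raise DataError("confusion matrix is empty")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via beta quantiles."""
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes}/{n}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    lo = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def _tree_oob_masks(model: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    """Per-tree boolean out-of-bag masks, reconstructed from each tree's
    bootstrap seed (bootstrap draws n_samples indices with replacement)."""
    if not model.bootstrap:
        raise DataError("model was not trained with bootstrap resampling")
    masks = []
    for est in model.estimators_:
        sampled = np.random.RandomState(est.random_state).randint(0, n_samples, n_samples)
        masks.append(np.bincount(sampled, minlength=n_samples) == 0)
    return masks


def oob_error(model: RandomForestClassifier, X=None, y=None) -> float:
    """Out-of-bag misclassification rate in percent.

    With ``X, y`` given (the training data), the OOB majority-vote prediction
    is recomputed from the fitted forest's per-tree records; otherwise the
    score stored at fit time (``oob_score=True``) is used.
    """
    if X is not None and y is not None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not hasattr(model, "estimators_"):
            raise DataError("model is not fitted")
        n = X.shape[0]
        votes = np.zeros((n, len(model.classes_)))
        cls_index = {c: i for i, c in enumerate(model.classes_)}
        for est, oob_mask in zip(model.estimators_, _tree_oob_masks(model, n)):
            if not oob_mask.any():
                continue
            pred = model.classes_[np.argmax(est.predict_proba(X[oob_mask]), axis=1)]
            for row, p in zip(np.flatnonzero(oob_mask), pred):
                votes[row, cls_index[p]] += 1
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise DataError("no sample has out-of-bag votes")
        pred = model.classes_[np.argmax(votes[covered], axis=1)]
        return float(np.mean(pred != y[covered]) * 100.0)
    if getattr(model, "oob_score_", None) is None:
        raise DataError("model has no out-of-bag records (fit with oob_score=True)")
    return float((1.0 - model.oob_score_) * 100.0)


def permutation_importance(
    model: RandomForestClassifier,
    features,
    labels: Sequence[str],
    n_repeats: int = 5,
    seed: int = 0,
    mode: Literal["oob", "holdout"] = "oob",
    feature_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Permutation importance: mean decrease in accuracy per feature.

    ``mode='oob'`` (default) scores each tree on its own out-of-bag samples —
    ``features``/``labels`` must then be the training data — matching the
    classic random-forest importance. ``mode='holdout'`` scores the whole
    forest on the data given (any set disjoint from training is sensible).
    Returned dict is sorted by descending importance.
    """
    X = np.asarray(features.matrix if isinstance(features, FeatureTable) else features, dtype=float)
    if isinstance(features, FeatureTable) and feature_names is None:
        feature_names = features.aggregate_names
    y = np.asarray(labels)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    if mode == "holdout":
        baseline = float(np.mean(model.predict(X) == y))
        for j in range(p):
            acc = 0.0
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(n), j]
                acc += float(np.mean(model.predict(Xp) == y))
            drops[j] = baseline - acc / n_repeats
    elif mode == "oob":
        masks = _tree_oob_masks(model, n)
        per_tree = []
        for est, mask in zip(model.estimators_, masks):
            if mask.sum() < 2:
                continue
            Xo, yo = X[mask], y[mask]
            base = float(np.mean(_tree_predict(model, est, Xo) == yo))
            tree_drop = np.zeros(p)
            for j in range(p):
                d = 0.0
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, j] = Xp[rng.permutation(Xo.shape[0]), j]
                    d += base - float(np.mean(_tree_predict(model, est, Xp) == yo))
                tree_drop[j] = d / n_repeats
            per_tree.append(tree_drop)
        if not per_tree:
            raise DataError("no tree has enough out-of-bag samples")
        drops = np.mean(per_tree, axis=0)
    else:
        raise ValidationError(f"unknown importance mode {mode!r}")
    order = np.argsort(-drops)
    return {names[j]: float(drops[j]) for j in order}


def _tree_predict(model: RandomForestClassifier, est, X: np.ndarray) -> np.ndarray:
    return model.classes_[np.argmax(est.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    model: RandomForestClassifier,
    test_features,
    test_labels: Sequence[str],
    oob_error_pct: float | None = None,
    importances: dict[str, float] | None = None,
    chosen_hyperparameters: dict | None = None,
) -> EvalReport:
    """Score a fitted model on held-out data and assemble the full report.

    Per-class sensitivity is the true-class recall (diagonal / row total),
    specificity the true-negative rate, balanced accuracy their mean.
    """
    X = np.asarray(test_features.matrix if isinstance(test_features, FeatureTable) else test_features, dtype=float)
    y = np.asarray(test_labels)
    known = set(model.classes_.tolist())
    unknown = sorted(set(y.tolist()) - known)
    if unknown:
        raise DataError(f"test labels absent from training: {unknown}")
    labels = sorted(known)
    pred = model.predict(X)
    k = len(labels)
    index = {c: i for i, c in enumerate(labels)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        confusion[index[t], index[p]] += 1
    n = int(confusion.sum())
    correct = int(np.trace(confusion))
    accuracy = correct / n
    per_class: dict[str, dict[str, float]] = {}
    for c in labels:
        i = index[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        per_class[c] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "balanced_accuracy": float((sens + spec) / 2.0),
        }
    if oob_error_pct is None and getattr(model, "oob_score_", None) is not None:
        oob_error_pct = float((1.0 - model.oob_score_) * 100.0)
    return EvalReport(
        labels=labels,
        confusion=confusion,
        overall_accuracy=float(accuracy),
        ci95=clopper_pearson(correct, n),
        kappa=cohen_kappa(confusion),
        per_class=per_class,
        oob_error_pct=oob_error_pct,
        importances=importances or {},
        chosen_hyperparameters=chosen_hyperparameters or {},
    )


def run_classification(
    features: FeatureTable,
    config: RFConfig | None = None,
    importance_repeats: int = 3,
) -> tuple[EvalReport, TrainResult, tuple[np.ndarray, np.ndarray]]:
    """Split, tune, refit and evaluate one model end to end.

    Returns the evaluation report, the tuned model and the (train, test) index
    arrays. Importances are computed in OOB mode on the training part.
    """
    config = config or RFConfig()
    train_idx, test_idx = stratified_split(
        features.class_labels, config.split_fraction, config.seed
    )
    sub = lambda idx: FeatureTable(
        sample_ids=[features.sample_ids[i] for i in idx],
        class_labels=[features.class_labels[i] for i in idx],
        matrix=features.matrix[idx],
        aggregate_names=features.aggregate_names,
    )
    train_ft, test_ft = sub(train_idx), sub(test_idx)
    result = tune_and_train(train_ft, config)
    imps = permutation_importance(
        result.model,
        train_ft,
        train_ft.class_labels,
        n_repeats=importance_repeats,
        seed=config.seed,
        mode="oob",
    )
    report = evaluate(
        result.model,
        test_ft,
        test_ft.class_labels,
        importances=imps,
        chosen_hyperparameters=result.chosen_hyperparameters,
    )
    return report, result, (train_idx, test_idx)
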