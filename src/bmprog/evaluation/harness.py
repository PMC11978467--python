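"""Bootstrap experiment harness: 250-iteration evaluation of the forest.

One iteration = bootstrap split -> correlation filter -> Bayesian tuning ->
forest fit -> test AUC / AU-PRC / sensitivity & specificity at the training
operating point -> per-feature importance (zeros at filtered features,
min-max normalized). Every training artifact is a function of training rows
only. An experiment aggregates the per-iteration metrics (mean and normal
95% CI of the mean) and the importance vectors (mean then renormalized to
[0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .bootstrap import BootstrapSplit, bootstrap_split
from .filtering import correlation_filter
from .metrics import (
    au_prc,
    baseline_auprc,
    roc_auc,
    sensitivity_specificity,
    training_operating_point,
)
from .tuning import HyperparamSpace, tune_hyperparameters

logger = logging.getLogger(__name__)

METRIC_KEYS = ("auc", "auprc", "sensitivity", "specificity")


@dataclass
class HarnessConfig:
    n_iterations: int = 250
    correlation_cutoff: float = 0.8
    tune_budget: int = 25
    inner_cv: int = 5
    space: HyperparamSpace = field(default_factory=HyperparamSpace)
    bootstrap_unit: str = "patient"  # or "lesion"
    importance_kind: str = "impurity"  # or "permutation"
    max_redraws: int = 50


def iteration_seed(master_seed: int, iteration: int, attempt: int = 0) -> int:
    """Counter-based per-iteration seed so any iteration is replayable."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration, attempt))
    return int(ss.generate_state(1)[0] % (2**31))


def fit_forest(
    x: np.ndarray, y: np.ndarray, hyperparams: tuple[int, int], seed: int
) -> RandomForestClassifier:
    """Random decision forest honoring (n_trees, max_depth); seeded."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain NaN/inf")
    n_trees, max_depth = hyperparams
    clf = RandomForestClassifier(
        n_estimators=int(n_trees), max_depth=int(max_depth), random_state=seed, n_jobs=1
    )
    clf.fit(x, np.asarray(y, dtype=int))
    return clf


@dataclass
class IterationResult:
    auc: float
    auprc: float
    sensitivity: float
    specificity: float
    threshold: float
    n_trees: int
    max_depth: int
    test_fraction: float
    seed: int
    importance: np.ndarray  # length n_features, zeros at filtered, in [0, 1]
    retained: np.ndarray
    test_records: pd.DataFrame  # lesion_id, prob, label, pred


def _normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; an all-equal vector maps to all zeros."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def iteration_importance(
    raw_scores: np.ndarray, retained: np.ndarray, n_features: int
) -> np.ndarray:
    """Per-iteration importance step: zeros at filtered features, then min-max.

    ``raw_scores`` are the forest's scores for the retained features only.
    """
    raw = np.zeros(n_features)
    raw[np.asarray(retained)] = raw_scores
    out = _normalize_importance(raw)
    out[np.setdiff1d(np.arange(n_features), retained)] = 0.0
    return out


def run_iteration(
    features: np.ndarray,
    labels: np.ndarray,
    split: BootstrapSplit,
    seed: int,
    config: HarnessConfig,
    lesion_ids: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> IterationResult:
    """Run one bootstrap iteration on a prepared split."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    tr, te = split.train_rows, split.test_rows
    x_tr, y_tr = x[tr], y[tr]
    x_te, y_te = x[te], y[te]

    retained = correlation_filter(x_tr, config.correlation_cutoff)
    if len(retained) == 0:
        raise ValueError("correlation filter removed every feature")
    x_tr_f, x_te_f = x_tr[:, retained], x_te[:, retained]

    hyper = tune_hyperparameters(
        x_tr_f,
        y_tr,
        config.space,
        budget=config.tune_budget,
        seed=seed,
        inner_cv=config.inner_cv,
        # group-aware inner folds: bootstrap duplicates of a unit stay together
        groups=None if groups is None else np.asarray(groups)[tr],
    )
    clf = fit_forest(x_tr_f, y_tr, hyper, seed)

    train_probs = clf.predict_proba(x_tr_f)[:, 1]
    threshold = training_operating_point(train_probs, y_tr)
    test_probs = clf.predict_proba(x_te_f)[:, 1]

    sens, spec = sensitivity_specificity(test_probs, y_te, threshold)
    if config.importance_kind == "permutation":
        perm = permutation_importance(
            clf, x_tr_f, y_tr, n_repeats=5, random_state=seed, scoring="roc_auc"
        )
        raw_retained = np.clip(perm.importances_mean, 0.0, None)
    else:
        raw_retained = clf.feature_importances_
    importance = iteration_importance(raw_retained, retained, x.shape[1])

    ids = lesion_ids[te] if lesion_ids is not None else te
    records = pd.DataFrame(
        {
            "lesion_id": ids,
            "prob": test_probs,
            "label": y_te,
            "pred": (test_probs >= threshold).astype(int),
        }
    )
    return IterationResult(
        auc=roc_auc(test_probs, y_te),
        auprc=au_prc(test_probs, y_te),
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
        n_trees=hyper[0],
        max_depth=hyper[1],
        test_fraction=len(te) / len(y),
        seed=seed,
        importance=importance,
        retained=retained,
        test_records=records,
    )


def aggregate_importance(per_iteration: list[np.ndarray]) -> np.ndarray:
    """Mean of per-iteration normalized importances, renormalized to [0, 1]."""
    if not per_iteration:
        raise ValueError("need at least one iteration")
    mean = np.mean(np.vstack(per_iteration), axis=0)
    return _normalize_importance(mean)


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(len(values)) if len(values) > 1 else 0.0
    return mean, mean - half, mean + half


@dataclass
class ExperimentResult:
    metrics: dict[str, tuple[float, float, float]]  # (mean, ci_low, ci_high)
    aggregated_importance: np.ndarray
    mean_test_fraction_pct: float
    baseline_auprc: float
    n_iterations: int
    n_redraws: int
    iteration_table: pd.DataFrame
    test_records: pd.DataFrame  # pooled across iterations
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {
            "metrics": {
                k: {"mean": m, "ci_low": lo, "ci_high": hi}
                for k, (m, lo, hi) in self.metrics.items()
            },
            "mean_test_fraction_pct": self.mean_test_fraction_pct,
            "baseline_auprc": self.baseline_auprc,
            "n_iterations": self.n_iterations,
            "n_redraws": self.n_redraws,
        }


def run_experiment(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    config: HarnessConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Full bootstrap experiment; deterministic under the master seed.

    Splits where either partition holds a single class are redrawn with a
    fresh counter-derived seed (and logged); features/labels/groups must be
    row-aligned.
    """
    config = config or HarnessConfig()
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        lesion_ids = features.index.to_numpy()
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i:03d}" for i in range(x.shape[1])]
        lesion_ids = np.arange(x.shape[0])
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    if not (len(x) == len(y) == len(g)):
        raise ValueError("features, labels and groups must be row-aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("experiment is degenerate: a single class overall")

    iterations: list[IterationResult] = []
    n_redraws = 0
    for it in range(config.n_iterations):
        for attempt in range(config.max_redraws):
            s = iteration_seed(seed, it, attempt)
            split = bootstrap_split(g, s, unit=config.bootstrap_unit)
            ok = (
                len(split.test_rows) > 0
                and len(np.unique(y[split.train_rows])) == 2
                and len(np.unique(y[split.test_rows])) == 2
            )
            if ok:
                break
            n_redraws += 1
            logger.info("iteration %d: degenerate split, redrawing (attempt %d)", it, attempt + 1)
        else:
            raise RuntimeError(f"iteration {it}: no usable split in {config.max_redraws} draws")
        res = run_iteration(x, y, split, s, config, lesion_ids=lesion_ids, groups=g)
        res.test_records.insert(0, "iteration", it)
        iterations.append(res)

    table = pd.DataFrame(
        {
            "iteration": np.arange(len(iterations)),
            "seed": [r.seed for r in iterations],
            "auc": [r.auc for r in iterations],
            "auprc": [r.auprc for r in iterations],
            "sensitivity": [r.sensitivity for r in iterations],
            "specificity": [r.specificity for r in iterations],
            "threshold": [r.threshold for r in iterations],
            "n_trees": [r.n_trees for r in iterations],
            "max_depth": [r.max_depth for r in iterations],
            "test_fraction": [r.test_fraction for r in iterations],
        }
    )
    metrics = {k: _mean_ci(table[k].to_numpy()) for k in METRIC_KEYS}
    return ExperimentResult(
        metrics=metrics,
        aggregated_importance=aggregate_importance([r.importance for r in iterations]),
        mean_test_fraction_pct=float(table["test_fraction"].mean() * 100.0),
        baseline_auprc=baseline_auprc(y),
        n_iterations=len(iterations),
        n_redraws=n_redraws,
        iteration_table=table,
        test_records=pd.concat([r.test_records for r in iterations], ignore_index=True),
        feature_names=names,
    )
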