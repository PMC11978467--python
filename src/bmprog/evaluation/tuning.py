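"""Bayesian hyperparameter search for the random decision forest.

The two tuned hyperparameters are the number of trees (10..1000, log scale)
and the maximum tree depth (1..n_train). The objective is the mean AUC of a
stratified inner cross-validation on the training rows only. Candidate points
are proposed by expected improvement under a Gaussian-process surrogate
(Matern 5/2) after an initial random design; if the surrogate cannot be fit,
the search degrades to pure random sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from scipy import stats

from .metrics import roc_auc


@dataclass(frozen=True)
class HyperparamSpace:
    n_trees_range: tuple[int, int] = (10, 1000)
    max_depth_max: int | None = None  # None = n_train, resolved at tune time

    def resolve_depth_max(self, n_train: int) -> int:
        return min(self.max_depth_max or n_train, n_train)


@dataclass(frozen=True)
class TuningResult:
    n_trees: int
    max_depth: int
    best_score: float
    n_evaluations: int

    def __iter__(self):
        return iter((self.n_trees, self.max_depth))


def _decode(x: np.ndarray, space: HyperparamSpace, depth_max: int) -> tuple[int, int]:
    # both axes are scale parameters: search them log-uniformly
    lo, hi = space.n_trees_range
    n_trees = int(round(math.exp(math.log(lo) + x[0] * (math.log(hi) - math.log(lo)))))
    depth = int(round(math.exp(x[1] * math.log(depth_max))))
    return max(lo, min(hi, n_trees)), max(1, min(depth_max, depth))


def _cv_auc(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    depth: int,
    n_splits: int,
    seed: int,
    groups: np.ndarray | None = None,
) -> float:
    # Bootstrap training multisets repeat rows; group-aware folds keep all
    # copies of a unit on one side so the CV score cannot reward memorization.
    if groups is not None:
        skf = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = skf.split(x, y, groups)
    else:
        folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed).split(x, y)
    aucs = []
    for tr, va in folds:
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_depth=depth, random_state=seed, n_jobs=1
        )
        clf.fit(x[tr], y[tr])
        aucs.append(roc_auc(clf.predict_proba(x[va])[:, 1], y[va]))
    if not aucs:
        raise ValueError("no valid inner-CV folds")
    return float(np.mean(aucs))


def tune_hyperparameters(
    x,
    y,
    space: HyperparamSpace = HyperparamSpace(),
    budget: int = 25,
    seed: int = 0,
    inner_cv: int = 5,
    groups=None,
    full_result: bool = False,
) -> tuple[int, int] | TuningResult:
    """Pick (n_trees, max_depth) maximizing inner-CV AUC on training data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in y")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    n_splits = max(2, min(inner_cv, int(counts.min())))
    depth_max = space.resolve_depth_max(len(y))
    rng = np.random.default_rng(seed)

    evaluated: dict[tuple[int, int], float] = {}
    xs: list[np.ndarray] = []
    ys: list[float] = []

    g = None if groups is None else np.asarray(groups)

    def evaluate(u: np.ndarray) -> None:
        params = _decode(u, space, depth_max)
        if params in evaluated:
            return
        score = _cv_auc(x, y, params[0], params[1], n_splits, seed, groups=g)
        evaluated[params] = score
        xs.append(u)
        ys.append(score)

    # Deterministic initial design. Depth is probed on a doubling ladder from
    # 1 (test-error curves bend in the first few doublings, so that is where
    # resolution matters) with the last point pinned at full depth; the tree
    # axis is stratified, giving shallow candidates the larger ensembles they
    # need. The surrogate refines from there.
    n_init = min(budget, max(3, budget // 3)) if budget > 2 else budget
    depth_levels = [min(2**i, depth_max) for i in range(n_init)]
    if n_init > 1:
        depth_levels[-1] = depth_max
    log_dmax = math.log(depth_max) if depth_max > 1 else 1.0
    u1_levels = (np.arange(n_init)[::-1] + 0.5) / n_init
    for u1, depth in zip(u1_levels, depth_levels):
        evaluate(np.array([u1, math.log(depth) / log_dmax]))

    while len(evaluated) < budget:
        proposed = None
        if len(xs) >= 3 and np.ptp(ys) > 0:
            try:
                gp = GaussianProcessRegressor(
                    kernel=Matern(nu=2.5, length_scale=0.3),
                    alpha=1e-4,
                    normalize_y=True,
                    random_state=int(rng.integers(2**31)),
                )
                with warnings.catch_warnings():
                    # few noisy points routinely pin the length-scale bound
                    warnings.simplefilter("ignore")
                    gp.fit(np.vstack(xs), np.asarray(ys))
                    cands = rng.uniform(size=(256, 2))
                    mu, sd = gp.predict(cands, return_std=True)
                best_y = max(ys)
                sd = np.maximum(sd, 1e-9)
                z = (mu - best_y) / sd
                ei = (mu - best_y) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
                proposed = cands[int(np.argmax(ei))]
            except Exception:
                proposed = None
        if proposed is None:
            proposed = rng.uniform(size=2)
        before = len(evaluated)
        evaluate(proposed)
        if len(evaluated) == before:  # duplicate grid point; take a random step
            evaluate(rng.uniform(size=2))
            if len(evaluated) == before:
                break

    best_params = max(evaluated, key=evaluated.get)
    result = TuningResult(
        n_trees=best_params[0],
        max_depth=best_params[1],
        best_score=evaluated[best_params],
        n_evaluations=len(evaluated),
    )
    return result if full_result else (result.n_trees, result.max_depth)
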