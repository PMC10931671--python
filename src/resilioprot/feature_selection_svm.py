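"""Masked greedy forward feature selection with a linear L1 SVM.

Starting from the empty set, the feature whose addition yields the highest
stratified 7-fold cross-validation accuracy is added, step by step, until
accuracy reaches 1.0 or no candidate improves it.  The score (gain) of a
feature is the increase in CV accuracy its addition brought about; the
baseline accuracy of the empty set is 0, so the first pick's score equals
its full CV accuracy.  Class-separating features are masked out before the
search — on their own they end the search at 100% accuracy in one step and
would hide jointly-informative feature sets.

The whole procedure is repeated (default 100x) with the candidate
evaluation order shuffled and the CV fold assignment reseeded each
repetition; per-feature results are aggregated as mean gain, gain SD
(population), and the number of repetitions in which the feature was
selected.

CV accuracy is the *unweighted mean of per-fold accuracies*.  On 16 samples
in 7 stratified folds (sizes 3,3,2,2,2,2,2) this convention produces the
characteristic values (6 + 2/3)/7 = 0.952 and its complement gain 0.048.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

DEFAULT_FOLDS = 7
DEFAULT_REPS = 100
DEFAULT_C = 1.0

try:  # fast path: call liblinear directly, skipping estimator overhead
    from sklearn.svm._base import _fit_liblinear as _liblinear_fit
except ImportError:  # pragma: no cover - depends on sklearn internals
    _liblinear_fit = None


@dataclass
class SfsRunResult:
    """One repetition of the greedy search."""

    repetition_index: int
    selected: list[str]
    gains: list[float]
    final_cv_accuracy: float
    order_seed: int
    fold_seed: int


def child_seeds(master_seed: int, stream: int, rep: int, n: int = 2) -> list[int]:
    """Deterministic per-repetition seeds: SeedSequence(master, key=(stream, rep))."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, rep))
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def make_classifier(C: float = DEFAULT_C) -> LinearSVC:
    """The base learner: linear SVM, L1 penalty, squared hinge, deterministic."""
    return LinearSVC(penalty="l1", loss="squared_hinge", dual=False, C=C,
                     tol=1e-4, random_state=0)


def fold_mean_accuracy(per_fold_accuracies) -> float:
    """Unweighted mean of per-fold test accuracies (the CV score convention)."""
    return float(np.mean(np.asarray(per_fold_accuracies, dtype=float)))


def stratified_folds(y: np.ndarray, n_folds: int, fold_seed: int
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified K-fold assignment, deterministic given fold_seed."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def cv_accuracy(X: np.ndarray, y: np.ndarray, feature_idx,
                n_folds: int = DEFAULT_FOLDS, fold_seed: int = 0,
                C: float = DEFAULT_C) -> float:
    """Fold-mean CV accuracy of the linear L1 SVM on a feature subset.

    ``X`` is samples x features, ``y`` binary labels.  Deterministic given
    ``fold_seed``.
    """
    folds = stratified_folds(y, n_folds, fold_seed)
    cols = np.atleast_1d(np.asarray(feature_idx, dtype=int))
    acc = _cv_accuracy_on_folds(X[:, cols], y, folds, make_classifier(C))
    assert acc is not None
    return acc


def _fold_accuracy(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                   yte: np.ndarray, clf) -> float:
    """Accuracy of the linear L1 SVM on one fold.

    Uses liblinear directly when available (identical coefficients to
    ``LinearSVC.fit``, verified in the test suite); falls back to the public
    estimator otherwise.
    """
    if _liblinear_fit is not None:
        coef, intercept, _ = _liblinear_fit(
            Xtr, ytr, C=clf.C, fit_intercept=True, intercept_scaling=1.0,
            class_weight=None, penalty="l1", dual=False, verbose=0,
            max_iter=1000, tol=clf.tol, random_state=0, multi_class="ovr",
            loss="squared_hinge", epsilon=0.1, sample_weight=None)
        classes = np.unique(ytr)
        pred = classes[(Xte @ coef.T + intercept > 0).ravel().astype(int)]
    else:  # pragma: no cover
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
    return float(np.mean(pred == yte))


def _cv_accuracy_on_folds(Xsub: np.ndarray, y: np.ndarray, folds, clf,
                          best_so_far: float | None = None) -> float | None:
    """Fold-mean accuracy; abandons early (returns None) once even perfect
    remaining folds could not strictly beat ``best_so_far``.  The pruning is
    exact with respect to the argmax and preserves first-wins tie-breaking.
    """
    k = len(folds)
    total = 0.0
    for i, (train, test) in enumerate(folds):
        total += _fold_accuracy(Xsub[train], y[train], Xsub[test], y[test], clf)
        if best_so_far is not None and (total + (k - i - 1)) / k <= best_so_far:
            return None
    return total / k


def sfs_once(X: np.ndarray, y: np.ndarray, feature_ids: list[str],
             masked_ids: set[str], order_seed: int, fold_seed: int,
             repetition_index: int = 0, n_folds: int = DEFAULT_FOLDS,
             C: float = DEFAULT_C) -> SfsRunResult:
    """One greedy forward pass over the shuffled, masked candidate pool.

    Ties in accuracy are broken by earliest position in the shuffled order,
    which is what makes re-shuffling across repetitions informative.
    """
    candidates = [i for i, fid in enumerate(feature_ids) if fid not in masked_ids]
    if not candidates:
        raise ValueError("no candidates remain after masking")
    order = np.array(candidates)
    np.random.default_rng(order_seed).shuffle(order)
    folds = stratified_folds(y, n_folds, fold_seed)
    clf = make_classifier(C)

    selected: list[int] = []
    gains: list[float] = []
    current = 0.0  # empty-set baseline
    remaining = list(order)
    while remaining:
        best_acc, best_j = None, None
        for j, cand in enumerate(remaining):
            cols = selected + [cand]
            acc = _cv_accuracy_on_folds(X[:, cols], y, folds, clf,
                                        best_so_far=best_acc)
            if acc is not None and (best_acc is None or acc > best_acc):
                best_acc, best_j = acc, j
        if best_acc is None or best_acc - current <= 0.0:
            break
        selected.append(remaining.pop(best_j))
        gains.append(best_acc - current)
        current = best_acc
        if current >= 1.0:
            break
    return SfsRunResult(
        repetition_index=repetition_index,
        selected=[feature_ids[i] for i in selected],
        gains=gains,
        final_cv_accuracy=current,
        order_seed=order_seed,
        fold_seed=fold_seed,
    )


def aggregate_selections(runs: list[SfsRunResult], feature_ids: list[str],
                         n_repetitions: int) -> pd.DataFrame:
    """Per-feature mean gain, population gain SD and selection count.

    Mean and SD are computed only over the repetitions in which the feature
    was selected; never-selected features carry NaN scores and
    times_selected = 0.  Output is ranked by times_selected descending
    (mean score breaks ties).
    """
    gains: dict[str, list[float]] = {fid: [] for fid in feature_ids}
    for run in runs:
        for fid, g in zip(run.selected, run.gains):
            gains[fid].append(g)
    rows = []
    for fid in feature_ids:
        g = np.asarray(gains[fid], dtype=float)
        rows.append((fid, g.mean() if g.size else np.nan,
                     g.std() if g.size else np.nan, int(g.size)))
    agg = pd.DataFrame(rows, columns=["protein_id", "mean_score", "score_sd",
                                      "times_selected"])
    return agg.sort_values(["times_selected", "mean_score"],
                           ascending=[False, False], kind="stable",
                           na_position="last").reset_index(drop=True)


SFS_STREAM = 1  # seed-derivation stream id for this stage


def sfs_repeated(X: np.ndarray, y: np.ndarray, feature_ids: list[str],
                 masked_ids: set[str], n_repetitions: int = DEFAULT_REPS,
                 master_seed: int = 0, n_folds: int = DEFAULT_FOLDS,
                 C: float = DEFAULT_C) -> tuple[pd.DataFrame, list[SfsRunResult]]:
    """Repeat the greedy search with per-repetition order and fold seeds."""
    runs = []
    for r in range(n_repetitions):
        order_seed, fold_seed = child_seeds(master_seed, SFS_STREAM, r)
        runs.append(sfs_once(X, y, feature_ids, masked_ids, order_seed,
                             fold_seed, repetition_index=r, n_folds=n_folds, C=C))
    agg = aggregate_selections(runs, feature_ids, n_repetitions)
    return agg, runs


def runs_table(runs: list[SfsRunResult]) -> pd.DataFrame:
    """One row per (repetition, selected feature), for the runs TSV."""
    rows = []
    for run in runs:
        for step, (fid, g) in enumerate(zip(run.selected, run.gains)):
            rows.append((run.repetition_index, step, fid, g,
                         run.final_cv_accuracy, run.order_seed, run.fold_seed))
    return pd.DataFrame(rows, columns=["repetition", "step", "protein_id", "gain",
                                       "final_cv_accuracy", "order_seed", "fold_seed"])
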