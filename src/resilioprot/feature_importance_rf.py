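"""Random-forest Gini-importance ranking, OOB-tuned, repeated 100x.

Each repetition trains a random forest (bootstrapped trees, random
subspaces) and records the mean-decrease-in-impurity importances,
normalized to sum to 1.  Hyperparameters are chosen once by maximizing the
out-of-bag accuracy over a small grid.  Across repetitions a feature's "RF
score" is its mean importance, and its selection count is the number of
repetitions in which it ranked inside the top-k importances (default
k = 50) — features that never enter the top-k report times_selected = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_selection_svm import child_seeds

DEFAULT_REPS = 100
DEFAULT_TOP_K = 50
RF_STREAM = 2  # seed-derivation stream id for this stage


@dataclass(frozen=True)
class RfHyperparams:
    n_trees: int = 300
    max_features: object = "sqrt"  # "sqrt" | "log2" | float fraction
    min_leaf: int = 1


@dataclass
class RfRepetition:
    repetition_index: int
    importances: np.ndarray  # per-feature, >= 0, sums to 1 when any split occurred
    oob_score: float
    hyperparams: RfHyperparams
    seed: int


def default_grid() -> list[RfHyperparams]:
    """Small standard grid: tree count x subspace rule x leaf size."""
    return [
        RfHyperparams(n_trees=t, max_features=mf, min_leaf=ml)
        for t in (100, 300, 500)
        for mf in ("sqrt", "log2", 0.1)
        for ml in (1, 2)
    ]


def _forest(hp: RfHyperparams, seed: int, oob: bool) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hp.n_trees, max_features=hp.max_features,
        min_samples_leaf=hp.min_leaf, bootstrap=True, oob_score=oob,
        random_state=seed, n_jobs=1,
    )


def tune_rf_oob(X: np.ndarray, y: np.ndarray, grid: list[RfHyperparams] | None = None,
                seed: int = 0) -> RfHyperparams:
    """Pick the grid point with the highest out-of-bag accuracy.

    Ties are broken by grid order (first wins).  Samples that are never
    out-of-bag are skipped by sklearn's OOB estimate with a warning.
    """
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    best_hp, best_oob = None, -np.inf
    for hp in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rf = _forest(hp, seed, oob=True).fit(X, y)
        if rf.oob_score_ > best_oob:
            best_hp, best_oob = hp, rf.oob_score_
    return best_hp


def rf_importances(X: np.ndarray, y: np.ndarray, hyperparams: RfHyperparams,
                   seed: int, repetition_index: int = 0) -> RfRepetition:
    """Train one forest; return normalized mean-decrease-in-impurity scores."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rf = _forest(hyperparams, seed, oob=True).fit(X, y)
    imp = rf.feature_importances_.astype(float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return RfRepetition(repetition_index=repetition_index, importances=imp,
                        oob_score=float(rf.oob_score_), hyperparams=hyperparams,
                        seed=seed)


def rf_repeated(X: np.ndarray, y: np.ndarray, feature_ids: list[str],
                hyperparams: RfHyperparams | None = None,
                n_repetitions: int = DEFAULT_REPS, master_seed: int = 0,
                top_k: int = DEFAULT_TOP_K
                ) -> tuple[pd.DataFrame, list[RfRepetition]]:
    """Repeat the forest with fresh subspace seeds and aggregate.

    Per feature: mean importance over all repetitions ("RF score"),
    population SD, and times_selected = number of repetitions in which the
    feature ranked inside the top_k importances.  Ranked by times_selected,
    mean score breaking ties.
    """
    if top_k > len(feature_ids):
        raise ValueError(f"top_k={top_k} exceeds feature count {len(feature_ids)}")
    hp = hyperparams if hyperparams is not None else RfHyperparams()
    reps, imps, top_counts = [], [], np.zeros(len(feature_ids), dtype=int)
    for r in range(n_repetitions):
        (seed,) = child_seeds(master_seed, RF_STREAM, r, n=1)
        rep = rf_importances(X, y, hp, seed, repetition_index=r)
        reps.append(rep)
        imps.append(rep.importances)
        # top_k by importance, largest first; ties resolved by feature order
        top = np.argsort(-rep.importances, kind="stable")[:top_k]
        top_counts[top[rep.importances[top] > 0]] += 1
    M = np.vstack(imps)
    agg = pd.DataFrame(
        {
            "protein_id": feature_ids,
            "mean_score": M.mean(axis=0),
            "score_sd": M.std(axis=0),
            "times_selected": top_counts,
        }
    )
    return (
        agg.sort_values(["times_selected", "mean_score"], ascending=[False, False],
                        kind="stable").reset_index(drop=True),
        reps,
    )
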