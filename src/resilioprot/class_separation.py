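"""Class-separating features and their standardized margin score.

A feature is *class-separating* when its lowest value in one class is
strictly higher than its highest value in the other class — i.e. the two
class value supports are disjoint, so the feature classifies the samples
perfectly on its own.  Its score is the absolute difference between the two
nearest standardized values belonging to different classes, which for a
separating feature equals the standardized gap between the class supports.
Separating features are reported ranked by score and are masked out of the
downstream sequential-selection stage, which would otherwise stop on them
after one step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_quant import ProteinQuantTable
from .preprocess import StandardizedMatrix


def _class_bounds(values: np.ndarray, labels: np.ndarray,
                  classes: tuple) -> tuple:
    a, b = (values[labels == c] for c in classes)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"a class in {classes} has no samples")
    return a, b


def is_class_separating(raw_values, labels) -> tuple[bool, str | None, float, float]:
    """Test whether a feature's class value supports are disjoint.

    Returns ``(separating, high_class, low_class_max, high_class_min)``.
    The inequality is strict: a shared boundary value is NOT separating.
    """
    values = np.asarray(raw_values, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    a, b = _class_bounds(values, labels, classes)
    if a.min() > b.max():
        return True, classes[0], float(b.max()), float(a.min())
    if b.min() > a.max():
        return True, classes[1], float(a.max()), float(b.min())
    return False, None, np.nan, np.nan


def class_sep_score(std_values, labels) -> float:
    """Margin of a separating feature on the standardized scale.

    The minimum over all across-class pairs of |v_i - v_j|; for a
    separating feature this is high_class_min - low_class_max.  Calling it
    on a non-separating feature is a contract violation.
    """
    values = np.asarray(std_values, dtype=float)
    labels = np.asarray(labels)
    separating, high_class, _, _ = is_class_separating(values, labels)
    if not separating:
        raise ContractError("class_sep_score requires a class-separating feature")
    high = values[labels == high_class]
    low = values[labels != high_class]
    return float(high.min() - low.max())


def nearest_across_class_gap(values, labels) -> float:
    """Brute-force minimum across-class |difference| (any feature, >= 0)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    return float(np.abs(a[:, None] - b[None, :]).min())


def screen_class_separating(std: StandardizedMatrix, raw: ProteinQuantTable,
                            contrast: tuple[str, str] = ("resilient", "susceptible"),
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Screen every protein of a contrast; rank separating ones by score.

    Returns ``(records, separating_ids)``: one record per protein with the
    separating flag, raw class bounds and standardized margin score
    (separating records first, sorted by score descending, with a rank
    column), plus the ordered id list for masking the selection stage.
    """
    labels = raw.labels_for(contrast)
    sample_ids = list(labels.index)
    lab = labels.to_numpy()
    raw_vals = raw.intensities[sample_ids].to_numpy()
    std_vals = std.values.loc[raw.protein_ids, sample_ids].to_numpy()

    rows = []
    for i, pid in enumerate(raw.protein_ids):
        separating, high_class, low_max, high_min = is_class_separating(raw_vals[i], lab)
        score = class_sep_score(std_vals[i], lab) if separating else np.nan
        rows.append((pid, raw.proteins["gene"].iloc[i], separating, high_class,
                     low_max, high_min, score))
    rec = pd.DataFrame(rows, columns=["protein_id", "gene", "separating", "high_class",
                                      "low_class_max", "high_class_min", "score"])
    sep = rec[rec["separating"]].sort_values("score", ascending=False, kind="stable")
    rest = rec[~rec["separating"]]
    rec = pd.concat([sep, rest], ignore_index=True)
    rec["rank"] = np.where(rec["separating"], np.arange(1, len(rec) + 1), 0)
    return rec, sep["protein_id"].tolist()
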