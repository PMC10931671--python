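"""Per-protein two-group statistics, BH correction, fold-change gates, PCA.

Differential expression is called on the *imputed raw* intensities (not the
standardized values, which erase per-feature group differences by
construction): fold change is the ratio of group mean intensities, the
test is a two-tailed unpaired t-test (pooled-variance Student by default,
Welch optionally), p-values are Benjamini-Hochberg adjusted, and a protein
is called regulated only if FC >= 1.2 or FC <= 0.80 *and* p < 0.05 *and*
q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_quant import ProteinQuantTable
from .preprocess import StandardizedMatrix

logger = logging.getLogger(__name__)

FC_UP = 1.2
FC_DOWN = 0.80
ALPHA = 0.05


@dataclass
class PcaSummary:
    """Sample scores and per-component explained-variance fractions."""

    scores: pd.DataFrame           # samples x components
    explained_fraction: np.ndarray


def group_fold_change(table: ProteinQuantTable, numerator_group: str,
                      denominator_group: str) -> pd.Series:
    """FC = mean(numerator-group intensities) / mean(denominator-group).

    Oriented numerator/denominator, e.g. resilient/susceptible.  Requires an
    imputed table; positive intensities guarantee a positive denominator.
    """
    num = table.intensities[table.samples_in(numerator_group)].mean(axis=1)
    den = table.intensities[table.samples_in(denominator_group)].mean(axis=1)
    if (den <= 0).any():
        raise ZeroDivisionError("denominator group mean is zero for some protein")
    fc = num / den
    fc.name = "fc"
    return fc


def t_test_per_protein(table: ProteinQuantTable, group_a: str, group_b: str,
                       variant: str = "student") -> pd.DataFrame:
    """Two-tailed unpaired t-test per protein; returns columns t, p.

    ``variant="student"`` pools the variance (df = nA + nB - 2);
    ``variant="welch"`` uses the unequal-variance form.  Degenerate
    zero-variance features get p = 1 when the means agree, and p at the
    smallest positive float (with a logged note) when they do not.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = table.intensities[table.samples_in(group_a)].to_numpy()
    b = table.intensities[table.samples_in(group_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t, p = np.asarray(t, float), np.asarray(p, float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    if degenerate.any():
        same = degenerate & np.isclose(a.mean(axis=1), b.mean(axis=1))
        t[same], p[same] = 0.0, 1.0
        diff = degenerate & ~same
        if diff.any():
            logger.info("%d zero-variance features with unequal means: p set to "
                        "the smallest positive float", int(diff.sum()))
            t[diff] = np.sign(a.mean(axis=1) - b.mean(axis=1))[diff] * np.inf
            p[diff] = np.nextafter(0.0, 1.0)
    return pd.DataFrame({"t": t, "p": p}, index=table.intensities.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; every p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(fc, p, q, fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                      alpha: float = ALPHA) -> np.ndarray:
    """Regulation call per protein: 'up', 'down' or 'ns'.

    Thresholds are inclusive on the fold change (>= fc_up, <= fc_down) and
    strict on significance (p < alpha and q < alpha).
    """
    if fc_up <= 0 or fc_down <= 0 or fc_down >= fc_up:
        raise ValueError("need 0 < fc_down < fc_up")
    fc, p, q = (np.asarray(v, dtype=float) for v in (fc, p, q))
    sig = (p < alpha) & (q < alpha)
    call = np.where(sig & (fc >= fc_up), "up",
                    np.where(sig & (fc <= fc_down), "down", "ns"))
    return call


def run_differential(table: ProteinQuantTable, numerator_group: str,
                     denominator_group: str, variant: str = "student",
                     fc_up: float = FC_UP, fc_down: float = FC_DOWN,
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Full differential stage on an imputed table; one record per protein."""
    fc = group_fold_change(table, numerator_group, denominator_group)
    tp = t_test_per_protein(table, numerator_group, denominator_group, variant)
    q = bh_adjust(tp["p"].to_numpy())
    call = call_differential(fc.to_numpy(), tp["p"].to_numpy(), q,
                             fc_up=fc_up, fc_down=fc_down, alpha=alpha)
    rec = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "gene": table.proteins["gene"].values,
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "t_stat": tp["t"].to_numpy(),
            "p": tp["p"].to_numpy(),
            "q": q,
            "call": call,
        }
    )
    logger.info("differential %s vs %s: %d up, %d down of %d",
                numerator_group, denominator_group,
                int((rec["call"] == "up").sum()), int((rec["call"] == "down").sum()),
                len(rec))
    return rec


def volcano_table(records: pd.DataFrame, y: str = "q") -> pd.DataFrame:
    """Plot-ready volcano coordinates: x = log2(FC), y = -log10(p or q)."""
    if y not in ("p", "q"):
        raise ValueError("y must be 'p' or 'q'")
    return pd.DataFrame(
        {
            "protein_id": records["protein_id"],
            "gene": records["gene"],
            "x_log2fc": records["log2fc"],
            "y_neglog10": -np.log10(records[y]),
            "call": records["call"],
        }
    )


def pca_summary(std: StandardizedMatrix, n_components: int = 2) -> PcaSummary:
    """PCA of samples in standardized feature space.

    Samples are the observations; explained fractions are eigenvalue shares
    of the total variance.  n_components is clipped to
    min(n_samples - 1, n_features) with a warning.
    """
    X = std.as_samples_by_features()
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    limit = min(n_samples - 1, n_features)
    if n_components > limit:
        logger.warning("n_components clipped from %d to %d", n_components, limit)
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaSummary(
        scores=pd.DataFrame(scores, index=std.sample_ids,
                            columns=[f"PC{i+1}" for i in range(n_components)]),
        explained_fraction=pca.explained_variance_ratio_.copy(),
    )
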