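"""Evidence filtering, missing-value replacement and per-feature standardization.

The order of operations in the pipeline is: filter proteins by peptide
evidence, replace missing intensities with the feature-wise mean (or
median), then centre and scale every feature to unit variance.
Standardization is fit globally on all samples by default; a train-fold-only
variant is available to callers that want to avoid the (mild) information
leak this implies for cross-validated downstream models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyTableError
from .io_quant import ProteinQuantTable

logger = logging.getLogger(__name__)


@dataclass
class StandardizedMatrix:
    """Per-feature standardized intensities (proteins x samples, no missing).

    ``values`` holds ``(x - feature_mean) / feature_sd`` wherever
    ``feature_sd > 0``; zero-variance features are all-zero with
    ``feature_sd`` recorded as 0.  The SD is the population SD (divisor n).
    """

    values: pd.DataFrame
    feature_mean: pd.Series
    feature_sd: pd.Series

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def as_samples_by_features(self) -> np.ndarray:
        """Samples-as-rows orientation used by the ML stages."""
        return self.values.to_numpy().T


def filter_by_peptide_evidence(table: ProteinQuantTable, min_peptides: int = 2,
                               min_unique: int = 2) -> ProteinQuantTable:
    """Drop proteins identified by too little peptide evidence.

    A protein is retained only if peptides >= min_peptides AND
    unique_peptides >= min_unique: a single peptide match *or* a single
    unique peptide excludes it.  Row order is preserved.
    """
    keep = (table.proteins["peptides"] >= min_peptides) & (
        table.proteins["unique_peptides"] >= min_unique
    )
    if not keep.any():
        raise EmptyTableError("peptide-evidence filter removed every protein")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("evidence filter dropped %d/%d proteins", n_dropped, len(keep))
    return ProteinQuantTable(
        proteins=table.proteins.loc[keep].copy(),
        intensities=table.intensities.loc[keep].copy(),
        sample_group=dict(table.sample_group),
    )


def impute_missing(table: ProteinQuantTable, method: str = "mean") -> ProteinQuantTable:
    """Replace each missing cell with the feature's own non-missing statistic.

    The replacement is computed across ALL samples of that feature (mean by
    default, median via ``method="median"``).  Features with no observed
    value at all cannot be imputed from themselves and are dropped with a
    warning.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown imputation method {method!r}")
    intens = table.intensities
    observed = intens.notna().sum(axis=1)
    dead = observed == 0
    if dead.any():
        logger.warning("dropping %d entirely-missing features: %s",
                       int(dead.sum()), list(intens.index[dead])[:5])
        intens = intens.loc[~dead]
    stat = intens.mean(axis=1) if method == "mean" else intens.median(axis=1)
    filled = intens.where(intens.notna(), stat, axis=0)
    return ProteinQuantTable(
        proteins=table.proteins.loc[filled.index].copy(),
        intensities=filled,
        sample_group=dict(table.sample_group),
    )


def standardize(table: ProteinQuantTable, sd_divisor: str = "n") -> StandardizedMatrix:
    """Centre each feature and scale it to unit variance.

    Uses the population SD (divisor n) by default; ``sd_divisor="n-1"``
    selects the sample SD.  Must be called on an imputed table (no missing
    values).  Zero-variance features map to all-zeros.
    """
    if sd_divisor not in ("n", "n-1"):
        raise ValueError(f"sd_divisor must be 'n' or 'n-1', got {sd_divisor!r}")
    intens = table.intensities
    if intens.isna().any().any():
        raise ContractError("standardize requires an imputed table (missing values present)")
    ddof = 0 if sd_divisor == "n" else 1
    mean = intens.mean(axis=1)
    sd = intens.std(axis=1, ddof=ddof)
    safe_sd = sd.replace(0.0, np.nan)
    values = intens.sub(mean, axis=0).div(safe_sd, axis=0).fillna(0.0)
    return StandardizedMatrix(values=values, feature_mean=mean, feature_sd=sd)


def standardize_train_only(intens: pd.DataFrame, train_samples: list[str],
                           sd_divisor: str = "n") -> pd.DataFrame:
    """Standardize all columns using statistics fit on the training samples only.

    Fold-scoped alternative to :func:`standardize` for leakage-free CV.
    """
    ddof = 0 if sd_divisor == "n" else 1
    mean = intens[train_samples].mean(axis=1)
    sd = intens[train_samples].std(axis=1, ddof=ddof).replace(0.0, np.nan)
    return intens.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
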