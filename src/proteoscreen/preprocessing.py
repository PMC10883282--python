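"""Intensity-matrix container and post-processing steps.

The pipeline's quantitative inputs are feature x sample intensity matrices
(protein groups from the full proteome, phosphorylation sites from the
enriched phosphoproteome). Post-processing follows the standard proteomics
recipe: drop decoy/contaminant hits, log10-transform, median-centre every
sample to the grand median to correct loading differences, and impute
missing values with half of the row-wise lowest observed (linear-scale)
intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("proteoscreen")

LINEAR = "linear"
LOG10 = "log10"


@dataclass
class AbundanceMatrix:
    """Features x samples abundance matrix with explicit missingness.

    Missing cells are NaN. ``scale_tag`` records whether ``values`` holds
    linear intensities (iBAQ-like) or log10-transformed ones; every
    operation states which scale it expects.
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    scale_tag: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale_tag not in (LINEAR, LOG10):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        self.values = self.values.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.scale_tag)

    # -- scale changes -------------------------------------------------------
    def to_log10(self) -> "AbundanceMatrix":
        if self.scale_tag == LOG10:
            return self.copy()
        vals = self.values.where(self.values > 0)
        return AbundanceMatrix(np.log10(vals), LOG10)

    def to_linear(self) -> "AbundanceMatrix":
        if self.scale_tag == LINEAR:
            return self.copy()
        return AbundanceMatrix(10.0 ** self.values, LINEAR)


@dataclass
class ImputationReport:
    """Rows that imputation could not touch (no observed value at all)."""

    fully_missing_features: list[str] = field(default_factory=list)


def filter_decoys_contaminants(
    matrix: AbundanceMatrix, flags: pd.Series
) -> AbundanceMatrix:
    """Remove rows flagged as reverse-database or contaminant hits.

    ``flags`` is a boolean Series aligned to the feature index; True means
    drop. Row order of the survivors is preserved.
    """
    flags = flags.reindex(matrix.values.index)
    if flags.isna().any():
        missing = flags.index[flags.isna()][:5].tolist()
        raise ValueError(f"flags not aligned to feature ids, e.g. {missing}")
    keep = ~flags.astype(bool)
    out = matrix.values.loc[keep]
    if out.shape[0] == 0:
        logger.warning("all %d features flagged; matrix is empty", len(flags))
    return AbundanceMatrix(out, matrix.scale_tag)


def median_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Shift each sample so its median equals the grand median.

    Operates on the log10 scale (additive shift there equals multiplicative
    scaling of linear intensities). The grand median is taken over all
    observed cells of the input; each sample is shifted so that its median
    of observed values matches it.
    """
    if matrix.scale_tag != LOG10:
        raise ValueError("median_center expects a log10-scale matrix")
    vals = matrix.values
    n_obs = vals.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(vals.columns[n_obs == 0])
        raise ValueError(f"samples with no observed values: {empty}")
    grand = np.nanmedian(vals.to_numpy())
    shifts = grand - vals.median(axis=0, skipna=True)
    return AbundanceMatrix(vals.add(shifts, axis=1), LOG10)


def impute_half_min_rowwise(
    matrix: AbundanceMatrix,
) -> tuple[AbundanceMatrix, ImputationReport]:
    """Fill missing cells with half the row's lowest observed intensity.

    Halving is a linear-scale notion: for a row with linear minimum m, every
    missing cell becomes log10(m / 2). Observed cells are untouched
    (bit-identical). Rows without any observed value stay missing and are
    listed in the report.
    """
    if matrix.scale_tag != LOG10:
        raise ValueError("impute_half_min_rowwise expects a log10-scale matrix")
    vals = matrix.values.copy()
    row_min_log = vals.min(axis=1, skipna=True)  # log10 of the linear minimum
    fill = row_min_log + np.log10(0.5)
    report = ImputationReport(
        fully_missing_features=list(vals.index[row_min_log.isna()])
    )
    if report.fully_missing_features:
        logger.warning(
            "%d features have no observed value and were left missing",
            len(report.fully_missing_features),
        )
    mask = vals.isna()
    filled = vals.where(~mask, np.broadcast_to(fill.to_numpy()[:, None], vals.shape))
    # rows with no observations have NaN fill values and remain NaN
    return AbundanceMatrix(filled, LOG10), report
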