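"""Metabolite cleaning and residualisation.

Fixed pipeline order: ln(1+x) transform -> 5 s.d. outlier masking ->
missingness filtering (drop metabolite columns with > 2.5% missing, then
drop incomplete rows) -> OLS residualisation of metabolites on sex, age and
shipment batch.  Symptom columns are never transformed or residualised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variables import (
    BridgenetError,
    CollinearityError,
    CovariateTable,
    MixedDataMatrix,
    SpecificationError,
)

__all__ = [
    "log_transform",
    "mask_outliers",
    "filter_missingness",
    "residualize",
    "preprocess",
    "FilterReport",
    "percent_reduction",
    "DEFAULT_ADJUSTMENT",
]

logger = logging.getLogger(__name__)

DEFAULT_ADJUSTMENT = ("sex", "age", "batch")


class DomainError(BridgenetError):
    """A value outside the transform's domain."""


class EmptyColumnError(BridgenetError):
    """An all-missing column where values were required."""


@dataclass
class FilterReport:
    """Bookkeeping for the missingness filter."""

    dropped_columns: list[str] = field(default_factory=list)
    dropped_rows: int = 0
    n_before: int = 0
    n_after: int = 0

    @property
    def row_reduction_pct(self) -> float:
        return percent_reduction(self.n_before, self.n_after)


def percent_reduction(n_before: int, n_after: int) -> float:
    """Sample-size reduction in percent, e.g. 2981 -> 2498 gives 16.2."""
    if n_before <= 0:
        raise SpecificationError("n_before must be positive")
    return 100.0 * (n_before - n_after) / n_before


def log_transform(values: np.ndarray, name: str = "column") -> np.ndarray:
    """ln(1+x) per non-missing cell; requires all values > -1."""
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if np.any(values[obs] <= -1):
        raise DomainError(f"column {name!r} has values <= -1; ln(1+x) undefined")
    out = values.copy()
    out[obs] = np.log1p(values[obs])
    return out


def mask_outliers(values: np.ndarray, k: float = 5.0, name: str = "column") -> np.ndarray:
    """Mask cells deviating more than ``k`` s.d. from the column mean.

    Mean and s.d. are computed once over the non-missing cells (including
    any outliers) before masking; the inequality is strict.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if obs.sum() == 0:
        raise EmptyColumnError(f"column {name!r} is entirely missing")
    if obs.sum() < 2:
        return values.copy()
    mean = values[obs].mean()
    sd = values[obs].std(ddof=0)
    out = values.copy()
    if sd > 0:
        out[obs & (np.abs(values - mean) > k * sd)] = np.nan
    return out


def filter_missingness(
    data: MixedDataMatrix, column_threshold: float = 0.025
) -> tuple[MixedDataMatrix, FilterReport]:
    """Drop leaky metabolite columns, then incomplete rows.

    A metabolite column is removed when its missing fraction is strictly
    greater than ``column_threshold``; afterwards every row with any
    remaining missing value (symptom or metabolite) is removed
    (complete-case analysis).
    """
    if data.n == 0 or data.p == 0:
        raise SpecificationError("empty data matrix")
    report = FilterReport(n_before=data.n)
    frac = np.mean(np.isnan(data.values), axis=0)
    keep = []
    for j, spec in enumerate(data.specs):
        if spec.is_metabolite and frac[j] > column_threshold:
            report.dropped_columns.append(spec.name)
        else:
            keep.append(spec.name)
    if not keep:
        raise BridgenetError("all columns dropped by missingness filter")
    out = data.select_columns(keep)
    complete = ~np.any(np.isnan(out.values), axis=1)
    report.dropped_rows = int((~complete).sum())
    out = out.select_rows(complete)
    report.n_after = out.n
    if report.dropped_columns or report.dropped_rows:
        logger.info(
            "missingness filter: dropped %d columns %s and %d rows (%d -> %d)",
            len(report.dropped_columns), report.dropped_columns,
            report.dropped_rows, report.n_before, report.n_after,
        )
    return out, report


def residualize(
    data: MixedDataMatrix,
    covariates: CovariateTable,
    adjust_for: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> MixedDataMatrix:
    """Replace each continuous column with its OLS residuals.

    Each metabolite is regressed on an intercept plus the named covariates;
    residuals are the model input downstream.  Symptom columns pass through
    untouched.  Requires complete data (run the missingness filter first).
    """
    if covariates.n != data.n:
        raise SpecificationError(
            f"covariate table has {covariates.n} rows, data has {data.n}"
        )
    covariates.require_complete(adjust_for)
    X = covariates.design(adjust_for)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"rank-deficient adjustment design for covariates {list(adjust_for)}"
        )
    out = data.copy()
    cont_idx = [j for j, s in enumerate(data.specs) if not s.is_categorical]
    if not cont_idx:
        return out
    Y = out.values[:, cont_idx]
    if np.isnan(Y).any():
        raise SpecificationError("residualize requires complete continuous columns")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out.values[:, cont_idx] = Y - X @ beta
    return out


def preprocess(
    data: MixedDataMatrix,
    covariates: CovariateTable,
    k_sd: float = 5.0,
    column_threshold: float = 0.025,
    adjust_for: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> tuple[MixedDataMatrix, FilterReport]:
    """Full cleaning pipeline on metabolite columns, in fixed order."""
    out = data.copy()
    for j, spec in enumerate(out.specs):
        if spec.is_metabolite:
            col = log_transform(out.values[:, j], spec.name)
            out.values[:, j] = mask_outliers(col, k=k_sd, name=spec.name)
    out, report = filter_missingness(out, column_threshold=column_threshold)
    kept_rows = np.isin(data.subject_ids, out.subject_ids)
    cov_kept = covariates.select_rows(np.flatnonzero(kept_rows))
    out = residualize(out, cov_kept, adjust_for=adjust_for)
    return out, report
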