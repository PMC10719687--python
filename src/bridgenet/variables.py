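"""Variable metadata and the mixed-data container shared by all stages.

A study dataset is a subject-by-variable matrix mixing ordinal symptom items
(small categorical, levels coded ``0..L-1``) with continuous metabolite
concentrations, plus a covariate table (sex, age, shipment batch, BMI,
smoking, antidepressant and statin use).  Missing cells are represented as
NaN in a float matrix regardless of variable kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: group labels with special meaning for bridge extraction
SOMATIC = "somatic"
MOOD_COGNITION = "mood_cognition"
SYMPTOM_GROUPS = (SOMATIC, MOOD_COGNITION)

COVARIATE_COLUMNS = ("sex", "age", "batch", "bmi", "smoking", "ad_use", "statin_use")
BINARY_COVARIATES = ("sex", "batch", "smoking", "ad_use", "statin_use")


class BridgenetError(Exception):
    """Base class for package errors."""


class SpecificationError(BridgenetError):
    """A name/shape in a request does not match the data."""


class ParameterError(BridgenetError):
    """An invalid parameter value (negative variance, rate >= 1, ...)."""


class NumericalError(BridgenetError):
    """A non-finite quantity was produced during sampling or fitting."""


class ConvergenceError(BridgenetError):
    """An iterative fit failed to converge (e.g. multinomial separation)."""


class CollinearityError(BridgenetError):
    """A regression design is rank deficient."""


@dataclass(frozen=True)
class VariableSpec:
    """Per-column metadata.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"categorical", "continuous"}
    n_levels : int
        Number of levels for a categorical variable (ignored for continuous).
    group : str
        Display/partition group: ``somatic`` or ``mood_cognition`` for
        symptom items, a metabolite subclass label otherwise, or
        ``"ungrouped"``.
    index : int
        Display index (position in the canonical variable list).
    """

    name: str
    kind: str
    n_levels: int = 0
    group: str = "ungrouped"
    index: int = -1

    def __post_init__(self):
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SpecificationError(f"unknown variable kind {self.kind!r}")
        if self.kind == CATEGORICAL and self.n_levels < 2:
            raise SpecificationError(
                f"categorical variable {self.name!r} needs >= 2 levels"
            )

    @property
    def is_categorical(self) -> bool:
        return self.kind == CATEGORICAL

    @property
    def is_symptom(self) -> bool:
        return self.group in SYMPTOM_GROUPS

    @property
    def is_metabolite(self) -> bool:
        return self.kind == CONTINUOUS and self.group not in SYMPTOM_GROUPS


@dataclass
class MixedDataMatrix:
    """n x p subject-by-variable matrix with NaN as the missing marker."""

    values: np.ndarray
    specs: list[VariableSpec]
    subject_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SpecificationError("values must be a 2-d array")
        if self.values.shape[1] != len(self.specs):
            raise SpecificationError(
                f"{self.values.shape[1]} columns but {len(self.specs)} specs"
            )
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.values.shape[0])
        else:
            self.subject_ids = np.asarray(self.subject_ids)
            if len(self.subject_ids) != self.values.shape[0]:
                raise SpecificationError("subject_ids length mismatch")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SpecificationError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    def spec(self, name: str) -> VariableSpec:
        return self.specs[self.column_index(name)]

    @property
    def categorical_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_categorical]

    @property
    def continuous_names(self) -> list[str]:
        return [s.name for s in self.specs if not s.is_categorical]

    @property
    def metabolite_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_metabolite]

    @property
    def symptom_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_symptom]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "MixedDataMatrix":
        return MixedDataMatrix(
            self.values.copy(), list(self.specs), self.subject_ids.copy()
        )

    def validate(self) -> None:
        """Check categorical cells are integral codes within range."""
        for j, spec in enumerate(self.specs):
            col = self.values[:, j]
            ok = np.isnan(col)
            if spec.is_categorical:
                good = (~ok) & (col == np.round(col)) & (col >= 0) & (col < spec.n_levels)
                if not np.all(good | ok):
                    raise SpecificationError(
                        f"column {spec.name!r} has values outside 0..{spec.n_levels - 1}"
                    )
            else:
                if not np.all(np.isfinite(col) | ok):
                    raise SpecificationError(f"column {spec.name!r} has non-finite values")

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=self.subject_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, specs: Sequence[VariableSpec]
    ) -> "MixedDataMatrix":
        names = [s.name for s in specs]
        missing = [n for n in names if n not in frame.columns]
        if missing:
            raise SpecificationError(f"frame lacks columns {missing}")
        return cls(frame[names].to_numpy(dtype=float), list(specs), frame.index.to_numpy())

    def select_rows(self, mask: np.ndarray) -> "MixedDataMatrix":
        return MixedDataMatrix(self.values[mask], list(self.specs), self.subject_ids[mask])

    def select_columns(self, keep: Iterable[str]) -> "MixedDataMatrix":
        keep = list(keep)
        idx = [self.column_index(n) for n in keep]
        specs = [replace(self.specs[i], index=k) for k, i in enumerate(idx)]
        return MixedDataMatrix(self.values[:, idx], specs, self.subject_ids.copy())


@dataclass
class CovariateTable:
    """Subject-level covariates aligned with a :class:`MixedDataMatrix`."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SpecificationError(f"covariate table lacks columns {missing}")

    @property
    def n(self) -> int:
        return len(self.frame)

    def require_complete(self, columns: Sequence[str]) -> None:
        bad = [c for c in columns if self.frame[c].isna().any()]
        if bad:
            raise SpecificationError(f"missing values in adjustment covariates {bad}")

    def design(self, columns: Sequence[str], rows: np.ndarray | None = None) -> np.ndarray:
        """Intercept + named covariates as a dense design matrix."""
        sub = self.frame if rows is None else self.frame.iloc[rows]
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in columns]
        )
        return X

    def select_rows(self, mask_or_idx: np.ndarray) -> "CovariateTable":
        return CovariateTable(self.frame.iloc[mask_or_idx].copy())

    def copy(self) -> "CovariateTable":
        return CovariateTable(self.frame.copy())
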