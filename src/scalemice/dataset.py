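"""Rectangular survey data with explicit structural missingness.

Cells are one of: a value, *missing* (nonresponse — eligible for
imputation) or *structurally missing* (undefined by design: a gate not
satisfied, a question not fielded).  Values live in a float DataFrame with
NaN holes; a parallel boolean mask distinguishes the structural holes.
Structural cells are excluded from missingness rates, from model fits and
from imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .schema import SurveySchema

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Respondent-by-variable data frame plus structural-missing mask."""

    values: pd.DataFrame
    structural: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.structural is None:
            self.structural = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            self.structural = self.structural.astype(bool).reindex_like(self.values).fillna(False)
        # a structural cell holds no value
        self.values = self.values.mask(self.structural)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.structural.copy())

    def missing_mask(self, column: str | None = None):
        """True where a cell is missing-for-imputation (NaN and not structural)."""
        if column is None:
            return self.values.isna() & ~self.structural
        return self.values[column].isna() & ~self.structural[column]

    def missing_fraction(self, column: str) -> float:
        """Fraction missing among cells that exist by design."""
        eligible = ~self.structural[column]
        denom = int(eligible.sum())
        if denom == 0:
            return 0.0
        return float((self.values[column].isna() & eligible).sum() / denom)

    def n_missing(self) -> int:
        return int(self.missing_mask().to_numpy().sum())

    # ------------------------------------------------------------------
    def with_totals(self, schema: SurveySchema) -> "Dataset":
        """Materialise scale-total columns (sum of items; NaN if any item absent)."""
        out = self.copy()
        for sc in schema.scales:
            items = [it for it in sc.items if it in out.values.columns]
            out.values[sc.total_name] = out.values[items].sum(axis=1, min_count=len(items))
            if sc.total_name not in out.structural.columns:
                out.structural[sc.total_name] = False
        return out

    def equals(self, other: "Dataset") -> bool:
        return self.values.equals(other.values) and self.structural.equals(other.structural)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, structural: pd.DataFrame | None = None) -> "Dataset":
        return cls(df.copy(), structural.copy() if structural is not None else None)

    def observed_values(self, column: str) -> np.ndarray:
        v = self.values[column]
        return v[v.notna()].to_numpy()

    def subset_rows(self, mask: Iterable[bool]) -> "Dataset":
        m = np.asarray(list(mask), dtype=bool)
        return Dataset(self.values.loc[m].copy(), self.structural.loc[m].copy())
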