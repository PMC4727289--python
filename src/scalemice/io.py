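"""CSV readers/writers, provenance sidecars, and imputation diagnostics.

Conventions: RFC 4180 CSV, UTF-8, ``.`` decimal separator; an empty cell
is missing (nonresponse); a configurable sentinel (default ``.s``) marks
structural missingness.  Every writer drops a JSON sidecar next to its
output recording the configuration and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import Dataset
from .engine import CompletedDatasets
from .schema import SurveySchema

__all__ = [
    "STRUCTURAL_SENTINEL",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "write_stacked_imputations",
    "read_stacked_imputations",
    "diagnostic_compare",
    "write_sidecar",
]

STRUCTURAL_SENTINEL = ".s"


class DataValidationError(ValueError):
    """Input data does not conform to its schema."""


def read_dataset(
    path, schema: SurveySchema, sentinel: str = STRUCTURAL_SENTINEL
) -> Dataset:
    """Read a respondent-by-variable CSV against a schema.

    Header must match the schema's non-derived names (order-insensitive;
    derived totals may be present and are recomputed).  Empty cells become
    missing, sentinel cells structural-missing.  Type violations are
    collected and reported with row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(schema.names)
    stray = [c for c in raw.columns if c not in known]
    if stray:
        raise DataValidationError(f"unknown column(s) in {path}: {stray}")
    expected = {v.name for v in schema.raw_variables}
    absent = expected - set(raw.columns)
    if absent:
        raise DataValidationError(f"missing column(s) in {path}: {sorted(absent)}")

    values = pd.DataFrame(index=raw.index)
    structural = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    errors: list[str] = []
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_struct = cells == sentinel
        is_missing = cells == ""
        blank = is_struct | is_missing
        numeric = pd.to_numeric(cells.where(~blank), errors="coerce")
        bad = numeric.isna() & ~blank
        for i in raw.index[bad]:
            errors.append(f"non-numeric cell {cells[i]!r} at row {i}, column {col!r}")
        if not bad.any():
            # to_numeric can be a ulp off; astype(float) parses exactly
            numeric = cells.where(~blank).astype(float)
        spec = schema[col] if col in schema else None
        if spec is not None and spec.mtype in ("binary", "ordinal", "nominal"):
            lo, hi = (0, 1) if spec.mtype == "binary" else (1, spec.n_levels or np.inf)
            observed = numeric.dropna()
            out_of_range = observed[(observed < lo) | (observed > hi)]
            for i, v in out_of_range.items():
                errors.append(
                    f"value {v:g} out of range [{lo}, {hi}] at row {i}, column {col!r}"
                )
        values[col] = numeric
        structural[col] = is_struct
    if errors:
        raise DataValidationError("; ".join(errors))
    return Dataset(values, structural)


def _format_frame(data: Dataset, sentinel: str) -> pd.DataFrame:
    out = data.values.astype(object).copy()
    out = out.where(data.values.notna(), "")
    out = out.mask(data.structural, sentinel)
    return out


def write_dataset(data: Dataset, path, sentinel: str = STRUCTURAL_SENTINEL) -> None:
    _format_frame(data, sentinel).to_csv(path, index=False)


def write_sidecar(path, config: Mapping) -> Path:
    """Write ``<path>.json`` holding the run configuration and seed."""
    side = Path(str(path) + ".json")

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    side.write_text(json.dumps(dict(config), indent=2, default=default))
    return side


def write_stacked_imputations(
    completed: CompletedDatasets, path, sentinel: str = STRUCTURAL_SENTINEL
) -> Path:
    """Write the original plus M completed datasets as one stacked CSV.

    An ``_imp`` column indexes the block (0 = original, with its missing
    cells left empty; 1..M = completed copies) and ``_row`` the respondent.
    A JSON sidecar records config and provenance.
    """
    blocks = []
    for m, ds in enumerate([completed.original, *completed.datasets]):
        f = _format_frame(ds, sentinel)
        f.insert(0, "_row", np.arange(len(f)))
        f.insert(0, "_imp", m)
        blocks.append(f)
    pd.concat(blocks, ignore_index=True).to_csv(path, index=False)
    meta = dict(completed.provenance)
    if completed.config is not None:
        meta["config"] = vars(completed.config) if not hasattr(
            completed.config, "__dataclass_fields__"
        ) else {k: getattr(completed.config, k) for k in completed.config.__dataclass_fields__}
    write_sidecar(path, meta)
    return Path(path)


def read_stacked_imputations(path, sentinel: str = STRUCTURAL_SENTINEL):
    """Read a stacked CSV back into (original frame, list of completed frames)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    frames = []
    for m, block in raw.groupby("_imp", sort=True):
        body = block.drop(columns=["_imp", "_row"]).reset_index(drop=True)
        struct = body == sentinel
        vals = body.apply(lambda s: s.where(~(s == sentinel) & ~(s == "")).astype(float))
        frames.append(Dataset(vals, struct))
    return frames[0], frames[1:]


def diagnostic_compare(
    original: Dataset,
    completed: CompletedDatasets,
    variable: str,
    categorical: bool | None = None,
) -> pd.DataFrame:
    """Observed-versus-imputed comparison for one variable.

    Categorical variables: relative frequency of each level among observed
    cells versus imputed cells, per imputation and pooled.  Continuous:
    five-number summaries.  A fully observed variable yields the observed
    side only (there is nothing imputed to compare).  The table is plain
    data, ready for CSV export or plotting.
    """
    if variable not in original.values.columns:
        raise KeyError(variable)
    miss = original.missing_mask(variable)
    obs = original.values.loc[~miss & original.values[variable].notna(), variable]
    if categorical is None:
        categorical = obs.nunique() <= 10
    cols: dict[str, pd.Series] = {}
    if categorical:
        levels = sorted(obs.unique())

        def freq(s: pd.Series) -> pd.Series:
            c = s.value_counts(normalize=True)
            return pd.Series([c.get(lv, 0.0) for lv in levels], index=levels)

        cols["observed"] = freq(obs)
        if miss.any():
            pooled = []
            for m, ds in enumerate(completed, start=1):
                imp = ds.values.loc[miss, variable]
                cols[f"imp_{m}"] = freq(imp)
                pooled.append(imp)
            cols["imputed_pooled"] = freq(pd.concat(pooled))
        table = pd.DataFrame(cols)
        table.index.name = "level"
    else:
        def summary(s: pd.Series) -> pd.Series:
            q = s.quantile([0, 0.25, 0.5, 0.75, 1.0])
            q.index = ["min", "q1", "median", "q3", "max"]
            return q

        cols["observed"] = summary(obs)
        if miss.any():
            pooled = []
            for m, ds in enumerate(completed, start=1):
                imp = ds.values.loc[miss, variable]
                cols[f"imp_{m}"] = summary(imp)
                pooled.append(imp)
            cols["imputed_pooled"] = summary(pd.concat(pooled))
        table = pd.DataFrame(cols)
        table.index.name = "statistic"
    if not miss.any():
        import warnings

        warnings.warn(f"{variable!r} is fully observed; nothing imputed to compare",
                      stacklevel=2)
    return table
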