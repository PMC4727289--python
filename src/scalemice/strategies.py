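"""The six ways of handling item-level missingness in multi-item scales.

All six take the same input — a dataset whose scale items are partially
missing while the outcome and demographics are complete — and produce
analysis-ready data:

1. complete-case: drop every respondent with any missing analysis value;
2. proration: rescale the observed-item sum by 1/(proportion observed)
   for partially observed scales, drop respondents with a fully missing
   scale (effectively single imputation by the within-scale mean);
3. set any partially or fully missing scale's sum to missing and multiply
   impute the sums from a multivariate normal model given the outcome and
   demographics (wasteful: discards partial responses);
4. prorate partial scales, multiply impute only the fully missing sums;
5. item-level chained equations with the scale-summary predictor scheme
   (each item regressed on the other items of its own scale, the other
   scales' totals, outcome and demographics; linear-regression draws);
6. multiply impute all items jointly from a multivariate normal model —
   the benchmark when it is computationally feasible.

Methods 1-2 return a single dataset; 3-6 return M completed datasets for
Rubin's-rules pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .dataset import Dataset
from .engine import CompletedDatasets, ImputationConfig, _draw_continuous, run_mice
from .schema import SurveySchema

__all__ = [
    "StrategyResult",
    "prorated_scale_score",
    "mvn_impute",
    "apply_strategy",
    "METHOD_LABELS",
]

METHOD_LABELS = {
    1: "complete case",
    2: "proration",
    3: "MI of scale sums (partial discarded)",
    4: "proration + MI of missing sums",
    5: "item-level MICE with scale summaries",
    6: "item-level joint MVN (benchmark)",
}


@dataclass
class StrategyResult:
    """Analysis-ready output of one strategy."""

    method: int
    data: Dataset | None = None  # methods 1, 2
    completed: CompletedDatasets | None = None  # methods 3-6
    notes: dict = field(default_factory=dict)

    @property
    def is_multiple(self) -> bool:
        return self.completed is not None

    def analysis_frames(self) -> list[pd.DataFrame]:
        if self.is_multiple:
            return [ds.values for ds in self.completed]
        return [self.data.values]


# ---------------------------------------------------------------------------
# proration
# ---------------------------------------------------------------------------

def prorated_scale_score(items: Sequence[float] | np.ndarray, k: int | None = None) -> float:
    """Observed-item sum rescaled by scale size / number observed.

    Returns NaN when no item is observed.  With all items observed this is
    the plain sum.
    """
    arr = np.asarray(items, dtype=float)
    if k is None:
        k = arr.size
    if k < 2:
        raise ValueError("scale size k must be >= 2")
    obs = ~np.isnan(arr)
    n_obs = int(obs.sum())
    if n_obs == 0:
        return float("nan")
    return float(arr[obs].sum() * k / n_obs)


def _prorated_totals(data: Dataset, schema: SurveySchema) -> pd.DataFrame:
    """Per-scale prorated totals for every respondent (NaN = fully missing)."""
    out = {}
    for sc in schema.scales:
        vals = data.values[list(sc.items)].to_numpy(dtype=float)
        k = len(sc.items)
        n_obs = (~np.isnan(vals)).sum(axis=1)
        s = np.nansum(vals, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sc.total_name] = np.where(n_obs > 0, s * k / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame(out, index=data.values.index)


# ---------------------------------------------------------------------------
# multivariate-normal imputation
# ---------------------------------------------------------------------------

def mvn_impute(
    data: Dataset,
    modelled: Sequence[str],
    covariates: Sequence[str],
    M: int = 10,
    seed: int | None = None,
    sweeps: int = 20,
) -> CompletedDatasets:
    """Multiply impute ``modelled`` columns from a joint normal given covariates.

    The joint model is sampled by iterated conditional Gaussian draws (a
    Gibbs sweep over the modelled variables, each regressed on the
    covariates and the other modelled variables, with full posterior draws
    of the regression parameters).  ``sweeps`` burn-in sweeps precede each
    saved imputation; the chain is initialised from regression draws on
    the covariates, and twenty sweeps were verified (against the exact
    conditional mean in a correctly specified Gaussian setting) to reach
    stationarity even when a 17-variable block is wholly missing for a
    third of the rows.  Covariates must be fully observed.
    """
    modelled = list(modelled)
    covariates = list(covariates)
    cov_arr = data.values[covariates].to_numpy(dtype=float)
    if np.isnan(cov_arr).any():
        raise ValueError("covariates must be fully observed")
    Y = data.values[modelled].to_numpy(dtype=float)
    miss = np.isnan(Y)
    children = SeedSequence(seed).spawn(M)
    out = []
    for m in range(M):
        rng = default_rng(children[m])
        Ym = _mvn_chain(Y, miss, cov_arr, sweeps, rng)
        ds = data.copy()
        ds.values[modelled] = Ym
        out.append(ds)
    prov = {"modelled": modelled, "covariates": covariates, "M": M, "seed": seed, "sweeps": sweeps}
    return CompletedDatasets(datasets=out, original=data.copy(), provenance=prov)


def _mvn_chain(
    Y: np.ndarray, miss: np.ndarray, cov_arr: np.ndarray, sweeps: int, rng: Generator
) -> np.ndarray:
    n, q = Y.shape
    Ym = Y.copy()
    ones = np.ones((n, 1))
    Xc = np.concatenate([ones, cov_arr], axis=1)
    # initial fill: regression draw on the covariates alone.  Under
    # covariate-dependent missingness a marginal fill starts the chain a
    # long way from its stationary mean, and the one-coordinate sweep over
    # many correlated items mixes too slowly to recover within a short
    # burn-in; conditioning the start on the covariates removes that.
    for j in range(q):
        mj = miss[:, j]
        if mj.any():
            if (~mj).sum() == 0:
                raise ValueError("a modelled column has no observed values")
            Ym[mj, j] = _draw_continuous(Ym[~mj, j], Xc[~mj], Xc[mj], rng)
    incomplete = [j for j in range(q) if miss[:, j].any()]
    for _ in range(sweeps):
        for j in incomplete:
            others = [k for k in range(q) if k != j]
            X = np.concatenate([ones, cov_arr, Ym[:, others]], axis=1)
            mj = miss[:, j]
            fit_rows = ~mj
            Ym[mj, j] = _draw_continuous(Ym[fit_rows, j], X[fit_rows], X[mj], rng)
    return Ym


# ---------------------------------------------------------------------------
# strategy dispatcher
# ---------------------------------------------------------------------------

def apply_strategy(
    method: int,
    data: Dataset,
    schema: SurveySchema,
    M: int = 10,
    seed: int | None = None,
    cycles: int = 10,
) -> StrategyResult:
    """Run one of the six strategies on item-level missing data.

    Covariates for the MVN-based methods (3, 4, 6) are the outcome and all
    complete non-scale variables (in the simulation setting: Morisky score
    and age).
    """
    if method not in METHOD_LABELS:
        raise ValueError(f"unknown method {method}; expected 1..6")
    base = data.with_totals(schema)
    item_cols = [it for sc in schema.scales for it in sc.items]
    nonscale = [
        v.name
        for v in schema.raw_variables
        if schema.scale_of(v.name) is None and v.name in data.values.columns
    ]
    analysis_cols = nonscale + item_cols

    if method == 1:
        complete = base.values[analysis_cols].notna().all(axis=1)
        if not complete.any():
            raise ValueError("complete-case analysis leaves zero rows")
        ds = base.subset_rows(complete.to_numpy()).with_totals(schema)
        return StrategyResult(method=1, data=ds, notes={"n_dropped": int((~complete).sum())})

    if method == 2:
        pro = _prorated_totals(base, schema)
        keep = pro.notna().all(axis=1) & base.values[nonscale].notna().all(axis=1)
        ds = base.copy()
        ds.values[pro.columns] = pro
        ds = ds.subset_rows(keep.to_numpy())
        return StrategyResult(
            method=2,
            data=ds,
            notes={"n_dropped": int((~keep).sum()), "prorated": True},
        )

    totals = [sc.total_name for sc in schema.scales]
    covariates = nonscale

    if method in (3, 4):
        ds = base.copy()
        if method == 3:
            # any missing item voids the sum; partial responses discarded
            pass  # base.with_totals already leaves such sums NaN
        else:
            pro = _prorated_totals(base, schema)
            ds.values[totals] = pro  # partial scales prorated; only fully
            # missing scales remain NaN for imputation
        completed = mvn_impute(ds, totals, covariates, M=M, seed=seed)
        return StrategyResult(method=method, completed=completed, notes={"modelled": totals})

    if method == 5:
        config = ImputationConfig(
            M=M, cycles=cycles, scheme="proposed", seed=seed, force_continuous=True
        )
        completed = run_mice(data, schema, config)
        return StrategyResult(method=5, completed=completed, notes={"scheme": "proposed"})

    # method 6: joint MVN over all items
    completed = mvn_impute(base, item_cols, covariates, M=M, seed=seed)
    completed = CompletedDatasets(
        datasets=[ds.with_totals(schema) for ds in completed],
        original=completed.original,
        provenance=completed.provenance,
    )
    return StrategyResult(method=6, completed=completed, notes={"modelled": item_cols})
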