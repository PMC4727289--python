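"""Chained-equations multiple imputation (MICE / fully conditional specification).

Each incomplete variable gets its own conditional imputation model, chosen by
measurement type:

==============  =======================================================
continuous      Bayesian normal linear regression: residual variance
                drawn from its scaled inverse-chi-square posterior,
                coefficients from their conditional normal, imputations
                = linear predictor + Gaussian noise
binary          logistic regression
ordinal         proportional-odds (ordered logit)
nominal         baseline-category (multinomial) logit
==============  =======================================================

All categorical draws are *proper*: the coefficient vector is drawn from the
asymptotic normal of the fit before category probabilities are formed, so
parameter uncertainty propagates into the imputations as Rubin's rules
require.

Sweeps visit variables in ascending order of missingness; derived scale
totals are passively recomputed from their items before every draw that
could read a stale total, and gated (conditional) variables are imputed
only on rows whose current gate value satisfies the gate.

Sparse categorical fits that fail outright are retried with a weak ridge
penalty, then with collapsed categories; only then is the failure raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import optimize
from scipy.special import expit

from .dataset import Dataset
from .schema import (
    PredictorSet,
    SurveySchema,
    collapse_categories,
    derive_predictor_sets,
    validate_schema,
)

__all__ = [
    "ImputationConfig",
    "CompletedDatasets",
    "ImputationError",
    "order_by_missingness",
    "initial_fill",
    "draw_imputation",
    "passive_update",
    "run_mice",
]


class ImputationError(RuntimeError):
    """A conditional model could not be fit even after fallbacks."""


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for one chained-equations run.

    M is the number of completed datasets; ``cycles`` the number of sweeps
    per dataset (ten is the conventional default for stabilisation).
    ``ridge`` is the prior precision used by the sparse-fit fallback;
    ``collapse_min_share`` feeds the category-collapsing fallback.
    ``force_continuous`` imputes every variable with the linear model
    regardless of declared type (used by the strategy that imputes Likert
    items with linear regressions).
    """

    M: int = 25
    cycles: int = 10
    scheme: str = "proposed"
    seed: int | None = None
    ridge: float = 0.1
    collapse_min_share: float = 0.05
    force_continuous: bool = False

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2 for multiple imputation")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


@dataclass
class CompletedDatasets:
    """The M imputation-completed copies of one input dataset."""

    datasets: list[Dataset]
    original: Dataset
    config: ImputationConfig | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, m: int) -> Dataset:
        return self.datasets[m]

    @property
    def M(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# ordering and initial fill
# ---------------------------------------------------------------------------

def order_by_missingness(data: Dataset, schema: SurveySchema) -> list[str]:
    """Raw variables in ascending order of missing fraction.

    Structural cells count in neither numerator nor denominator.  Ties keep
    schema declaration order.  Gated variables are additionally deferred
    until after their gate (conditional imputation needs a current gate
    value), overriding pure missingness order when necessary.
    """
    raw = [v.name for v in schema.raw_variables if v.name in data.values.columns]
    order = {n: i for i, n in enumerate(schema.names)}
    ranked = sorted(raw, key=lambda n: (data.missing_fraction(n), order[n]))
    # stable gate-after-gate pass: move each gated variable after its gate
    for _ in range(len(ranked)):
        moved = False
        for v in list(ranked):
            spec = schema[v]
            if spec.gate is None:
                continue
            gname = spec.gate[0]
            if gname in ranked and ranked.index(gname) > ranked.index(v):
                ranked.remove(v)
                ranked.insert(ranked.index(gname) + 1, v)
                moved = True
        if not moved:
            break
    return ranked


def initial_fill(
    data: Dataset,
    rng: Generator | int | None = None,
    columns: Sequence[str] | None = None,
) -> Dataset:
    """Replace every missing cell by a uniform draw from its column's observed values."""
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    out = data.copy()
    for col in (out.columns if columns is None else columns):
        miss = out.missing_mask(col)
        if not miss.any():
            continue
        obs = out.observed_values(col)
        if obs.size == 0:
            raise ImputationError(f"variable {col!r} has no observed values to draw from")
        out.values.loc[miss, col] = rng.choice(obs, size=int(miss.sum()), replace=True)
    return out


def passive_update(data: Dataset, schema: SurveySchema) -> Dataset:
    """Recompute every scale-total column as the row-wise sum of its items."""
    return data.with_totals(schema)


def _passive_inplace(work: Dataset, schema: SurveySchema, scale: str | None = None) -> None:
    """In-place total recomputation (one scale, or all) for the sweep hot loop."""
    for sc in schema.scales:
        if scale is not None and sc.name != scale:
            continue
        items = [it for it in sc.items if it in work.values.columns]
        work.values[sc.total_name] = work.values[items].sum(axis=1, min_count=len(items))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _design_matrix(
    data: Dataset, predictors: Sequence[str], schema: SurveySchema, intercept: bool = True
) -> np.ndarray:
    """Numeric design matrix for the given predictor names.

    Nominal predictors expand to reference-coded dummies over their observed
    levels; binary/ordinal/continuous (and derived totals) enter as single
    numeric columns.  Structural holes in a gated predictor are filled with
    zero: the predictor then acts as a (response x willingness) term, which
    is well defined for every row.
    """
    cols: list[np.ndarray] = []
    if intercept:
        cols.append(np.ones(data.n))
    for name in predictors:
        x = data.values[name].to_numpy(dtype=float)
        x = np.where(np.isnan(x), 0.0, x)  # structural holes only, post-fill
        mtype = schema[name].mtype if name in schema else "continuous"
        if mtype == "nominal":
            levels = np.unique(data.values[name].dropna())
            for lv in levels[1:]:
                cols.append((x == lv).astype(float))
        else:
            cols.append(x)
    return np.column_stack(cols) if cols else np.empty((data.n, 0))


# ---------------------------------------------------------------------------
# proper draws per model family
# ---------------------------------------------------------------------------

def _draw_continuous(y: np.ndarray, X: np.ndarray, Xmis: np.ndarray, rng: Generator) -> np.ndarray:
    """Posterior-predictive draw under the normal linear model, Jeffreys prior."""
    n, p = X.shape
    XtX = X.T @ X
    # tiny jitter keeps the factorisation alive under collinearity
    XtX = XtX + np.eye(p) * 1e-10 * max(1.0, np.trace(XtX) / max(p, 1))
    Xty = X.T @ y
    L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    df = max(n - p, 1)
    sigma2 = rss / rng.chisquare(df) if rss > 0 else 0.0
    z = rng.standard_normal(p)
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return Xmis @ beta + np.sqrt(sigma2) * rng.standard_normal(len(Xmis))


def _penalized_fit(model, ridge: float):
    """Ridge-penalised ML via BFGS on the model's own likelihood.

    Returns (params, cov) with cov = inverse of the penalised observed
    information.  Generic over statsmodels likelihood models (logit,
    ordered, multinomial).
    """
    start = _start_params(model)
    k = start.size

    def neg_ll(b):
        return -model.loglike(b) + 0.5 * ridge * float(b @ b)

    def neg_grad(b):
        return -np.asarray(model.score(b)).ravel() + ridge * b

    res = optimize.minimize(
        neg_ll, start, jac=neg_grad, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    params = res.x
    H = -np.asarray(model.hessian(params)).reshape(k, k) + ridge * np.eye(k)
    cov = np.linalg.pinv(H)
    return params, cov


def _start_params(model) -> np.ndarray:
    sp = getattr(model, "start_params", None)
    if sp is not None:
        return np.asarray(sp, dtype=float).ravel(order="F")
    if hasattr(model, "J"):  # multinomial: K coefficients per non-base category
        return np.zeros(model.K * (model.J - 1))
    return np.zeros(model.exog.shape[1])


def _fit_with_fallback(make_model: Callable, ridge: float, **fit_kwargs):
    """Plain ML fit; on failure or non-finite output, ridge-penalised refit.

    Parameter vectors are flattened in column-major order, matching the
    internal layout of the multinomial likelihood.
    """
    model = make_model()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200, **fit_kwargs)
            params = np.asarray(res.params, dtype=float).ravel(order="F")
            cov = np.asarray(res.cov_params(), dtype=float)
            k = params.size
            cov = cov.reshape(k, k)
            converged = getattr(res, "mle_retvals", {}).get("converged", True)
            if np.isfinite(params).all() and np.isfinite(cov).all() and converged:
                return params, cov
        except Exception:
            pass
        return _penalized_fit(model, ridge)


def _draw_params(params: np.ndarray, cov: np.ndarray, rng: Generator) -> np.ndarray:
    """One draw from the asymptotic normal of a fit, via eigen square root."""
    cov = (cov + cov.T) / 2.0
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return params + (V * np.sqrt(w)) @ rng.standard_normal(len(params))


def _draw_binary(y, X, Xmis, rng, ridge):
    import statsmodels.api as sm

    levels = np.unique(y)
    if levels.size == 1:  # degenerate: only one category observed
        return np.full(len(Xmis), levels[0])
    y01 = (y == levels[1]).astype(float)
    params, cov = _fit_with_fallback(lambda: sm.Logit(y01, X), ridge)
    beta = _draw_params(params, cov, rng)
    p1 = expit(Xmis @ beta)
    return np.where(rng.random(len(Xmis)) < p1, levels[1], levels[0])


class _FastLogistic:
    """Vectorised standard-logistic cdf/pdf/ppf.

    Drop-in for the scipy frozen distribution inside the ordered model:
    the generic ``rv_continuous`` dispatch dominates fit time otherwise.
    """

    name = "logit"

    @staticmethod
    def cdf(x):
        return expit(x)

    @staticmethod
    def pdf(x):
        p = expit(x)
        return p * (1.0 - p)

    @staticmethod
    def ppf(q):
        from scipy.special import logit as _logit

        return _logit(q)


def _draw_ordinal(y, X, Xmis, rng, ridge, collapse_min_share):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    levels = np.unique(y)
    if levels.size == 1:
        return np.full(len(Xmis), levels[0])
    if levels.size == 2:
        return _draw_binary(y, np.column_stack([np.ones(len(X)), X]),
                            np.column_stack([np.ones(len(Xmis)), Xmis]), rng, ridge)

    def fit_draw(yv, lv):
        codes = np.searchsorted(lv, yv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, X, distr=_FastLogistic())
        params, cov = _fit_with_fallback(lambda: model, ridge, method="bfgs")
        # draw in the model's unconstrained parameterisation (beta, cutpoint
        # increments), where the asymptotic normal applies
        beta = _draw_params(params, cov, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probs = np.asarray(model.predict(beta, exog=Xmis))
        return probs

    try:
        probs = fit_draw(y, levels)
    except Exception:
        recode, recoded = collapse_categories(pd.Series(y), collapse_min_share, "adjacent_ordinal")
        y2 = recoded.to_numpy(dtype=float)
        levels = np.unique(y2)
        if levels.size == 2:
            return _draw_binary(y2, np.column_stack([np.ones(len(X)), X]),
                                np.column_stack([np.ones(len(Xmis)), Xmis]), rng, ridge)
        probs = fit_draw(y2, levels)
    return _sample_categories(probs, levels, rng)


def _draw_nominal(y, X, Xmis, rng, ridge, collapse_min_share):
    import statsmodels.api as sm

    levels = np.unique(y)
    if levels.size == 1:
        return np.full(len(Xmis), levels[0])
    if levels.size == 2:
        return _draw_binary(y, X, Xmis, rng, ridge)

    def fit_draw(yv, lv):
        codes = np.searchsorted(lv, yv)
        model = sm.MNLogit(codes, X)
        params, cov = _fit_with_fallback(lambda: model, ridge)
        beta = _draw_params(params, cov, rng)
        bmat = beta.reshape(model.K, model.J - 1, order="F")
        eta = np.column_stack([np.zeros(len(Xmis)), Xmis @ bmat])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    try:
        probs = fit_draw(y, levels)
    except Exception:
        recode, recoded = collapse_categories(pd.Series(y), collapse_min_share, "rarest_nominal")
        y2 = recoded.to_numpy(dtype=float)
        levels = np.unique(y2)
        if levels.size == 2:
            return _draw_binary(y2, X, Xmis, rng, ridge)
        probs = fit_draw(y2, levels)
    return _sample_categories(probs, levels, rng)


def _sample_categories(probs: np.ndarray, levels: np.ndarray, rng: Generator) -> np.ndarray:
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))[:, None]
    idx = (u > cum).sum(axis=1)
    return levels[np.clip(idx, 0, len(levels) - 1)]


def draw_imputation(
    target: str,
    predictor_set: PredictorSet | Sequence[str],
    data: Dataset,
    schema: SurveySchema,
    rng: Generator | int | None = None,
    *,
    missing: pd.Series | None = None,
    exclude_from_fit: pd.Series | None = None,
    ridge: float = 0.1,
    collapse_min_share: float = 0.05,
    force_continuous: bool = False,
) -> np.ndarray:
    """Proper imputation draw for the missing cells of ``target``.

    The conditional model is fit on rows where the target is genuinely
    observed — rows flagged by ``missing`` or ``exclude_from_fit`` (cells
    holding provisional fills mid-sweep) never enter the fit.  Predictors
    must be currently complete apart from structural holes.  Returns drawn
    values for the rows flagged by ``missing`` (default: the dataset's
    current missing mask for the target).
    """
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    predictors = (
        list(predictor_set.predictors)
        if isinstance(predictor_set, PredictorSet)
        else list(predictor_set)
    )
    if missing is None:
        missing = data.missing_mask(target)
    missing = missing.astype(bool)
    mis_rows = missing.to_numpy()
    obs_rows = data.values[target].notna().to_numpy() & ~mis_rows
    if exclude_from_fit is not None:
        obs_rows &= ~exclude_from_fit.astype(bool).to_numpy()
    if not mis_rows.any():
        return np.empty(0)
    if not obs_rows.any():
        raise ImputationError(f"no observed values of {target!r} to fit on")

    mtype = "continuous" if force_continuous else schema[target].mtype
    with_const = mtype != "ordinal"  # ordered model carries its own cutpoints
    Xall = _design_matrix(data, predictors, schema, intercept=with_const)
    X, Xmis = Xall[obs_rows], Xall[mis_rows]
    y = data.values[target].to_numpy(dtype=float)[obs_rows]

    # a predictor constant on the fit rows (e.g. a gate that is always
    # satisfied where the target is observed) carries no information and
    # breaks intercept-free fits; drop such columns
    start = 1 if with_const else 0
    keep = np.ones(X.shape[1], dtype=bool)
    keep[start:] = X[:, start:].std(axis=0) > 0
    X, Xmis = X[:, keep], Xmis[:, keep]
    if mtype == "ordinal" and X.shape[1] == 0:
        # no informative predictors: draw from the observed marginal
        return rng.choice(y, size=len(Xmis), replace=True)

    try:
        if mtype == "continuous":
            return _draw_continuous(y, X, Xmis, rng)
        if mtype == "binary":
            return _draw_binary(y, X, Xmis, rng, ridge)
        if mtype == "ordinal":
            return _draw_ordinal(y, X, Xmis, rng, ridge, collapse_min_share)
        if mtype == "nominal":
            return _draw_nominal(y, X, Xmis, rng, ridge, collapse_min_share)
    except ImputationError:
        raise
    except Exception as exc:  # pragma: no cover - fallback chain exhausted
        raise ImputationError(f"imputation model for {target!r} ({mtype}) failed: {exc}") from exc
    raise ValueError(f"unknown measurement type {mtype!r}")


# ---------------------------------------------------------------------------
# the chained-equations loop
# ---------------------------------------------------------------------------

def _gate_eligible(data: Dataset, schema: SurveySchema, name: str) -> np.ndarray:
    """Rows where the variable exists by design, under *current* gate values."""
    spec = schema[name]
    ok = ~data.structural[name].to_numpy()
    if spec.gate is not None:
        gname, gval = spec.gate
        ok = data.values[gname].to_numpy() == gval
    return ok


def _single_imputation(
    data: Dataset,
    schema: SurveySchema,
    psets: dict[str, PredictorSet],
    config: ImputationConfig,
    rng: Generator,
) -> Dataset:
    orig_missing = {v: data.missing_mask(v) for v in psets}
    work = initial_fill(data, rng, columns=list(psets))
    work = passive_update(work, schema)
    visit = order_by_missingness(data, schema)
    scale_of = {v: (schema.scale_of(v).name if schema.scale_of(v) else None) for v in visit}

    for _ in range(config.cycles):
        stale: str | None = None  # scale whose items changed since last update
        for var in visit:
            miss = orig_missing[var]
            if not miss.any():
                continue
            eligible = _gate_eligible(work, schema, var)
            target_rows = miss & eligible
            # gate currently unsatisfied: response is structurally missing
            off_rows = miss & ~eligible
            if off_rows.any():
                work.values.loc[off_rows, var] = np.nan
                work.structural.loc[off_rows, var] = True
            # rows whose gate switched back on need a value again
            work.structural.loc[target_rows, var] = False
            if not target_rows.any():
                continue
            if stale is not None and stale != scale_of[var]:
                # a total this draw may read is out of date; own-scale
                # siblings are read as items, so the own total can wait
                _passive_inplace(work, schema, stale)
                stale = None
            drawn = draw_imputation(
                var,
                psets[var],
                work,
                schema,
                rng,
                missing=target_rows,
                exclude_from_fit=miss,
                ridge=config.ridge,
                collapse_min_share=config.collapse_min_share,
                force_continuous=config.force_continuous,
            )
            work.values.loc[target_rows, var] = drawn
            if scale_of[var] is not None:
                stale = scale_of[var]
        _passive_inplace(work, schema)
    return work


def run_mice(
    data: Dataset, schema: SurveySchema, config: ImputationConfig
) -> CompletedDatasets:
    """Produce M completed copies of ``data`` by chained-equations imputation.

    Deterministic given ``config.seed``; per-imputation substreams are
    spawned from the master seed, so the M imputations are mutually
    independent and insensitive to execution order.
    """
    problems = validate_schema(schema)
    if problems:
        raise ValueError(f"invalid schema: {problems}")
    psets = {
        ps.target: ps
        for ps in derive_predictor_sets(schema, config.scheme)
        if ps.target in data.values.columns
    }
    base = data.with_totals(schema)
    children = SeedSequence(config.seed).spawn(config.M)
    completed = [
        _single_imputation(base, schema, psets, config, default_rng(children[m]))
        for m in range(config.M)
    ]
    prov = {
        "M": config.M,
        "cycles": config.cycles,
        "scheme": config.scheme,
        "seed": config.seed,
        "sub_seeds": [list(map(int, c.generate_state(1))) for c in children],
        "n_missing_cells": int(base.n_missing()),
    }
    return CompletedDatasets(datasets=completed, original=base, config=config, provenance=prov)
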