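"""Combining analyses across multiply imputed datasets.

Each completed dataset is analysed separately; per-imputation estimates are
pooled with Rubin's rules.  For M imputations with estimates theta_m and
squared standard errors U_m:

    theta_bar = mean(theta_m)
    W         = mean(U_m)                      (within-imputation variance)
    B         = var(theta_m)                   (between, divisor M - 1)
    T         = W + (1 + 1/M) B                (total variance)
    df        = (M - 1) (1 + W / ((1 + 1/M) B))^2

With B = 0 the reference distribution degenerates to the complete-data one
(df infinite, T = W).  Wald intervals use Student's t on df.

Also provided: a pooled univariate logistic screen (the variable-selection
step that flags candidate predictors of a binary outcome) and the Pearson
chi-square / percent-agreement summary of a 2x2 include-exclude decision
table comparing two selection approaches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset

__all__ = [
    "RubinPooled",
    "pool_rubin",
    "univariate_screen",
    "chi_square_agreement",
]


@dataclass(frozen=True)
class RubinPooled:
    """Rubin's-rules pooled estimate with its variance decomposition."""

    theta_bar: float
    W: float
    B: float
    T_total: float
    df: float
    M: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T_total))

    @property
    def ci95(self) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.975, self.df) if np.isfinite(self.df) else stats.norm.ppf(0.975)
        return (self.theta_bar - tcrit * self.se, self.theta_bar + tcrit * self.se)

    def pvalue(self, null: float = 0.0) -> float:
        """Two-sided Wald p-value on t(df)."""
        if self.T_total == 0:
            return 0.0 if self.theta_bar != null else 1.0
        tstat = (self.theta_bar - null) / self.se
        if np.isfinite(self.df):
            return float(2 * stats.t.sf(abs(tstat), self.df))
        return float(2 * stats.norm.sf(abs(tstat)))


def pool_rubin(estimates: Iterable[float], variances: Iterable[float]) -> RubinPooled:
    """Pool per-imputation point estimates and squared standard errors."""
    est = np.asarray(list(estimates), dtype=float)
    var = np.asarray(list(variances), dtype=float)
    if est.size != var.size:
        raise ValueError(f"{est.size} estimates but {var.size} variances")
    M = est.size
    if M < 2:
        raise ValueError("Rubin's rules need M >= 2 imputations")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    theta_bar = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / M) * B
    if B == 0:
        df = np.inf
    else:
        df = (M - 1) * (1 + W / ((1 + 1 / M) * B)) ** 2
    return RubinPooled(theta_bar=theta_bar, W=W, B=B, T_total=float(T), df=float(df), M=M)


# ---------------------------------------------------------------------------
# pooled univariate screening
# ---------------------------------------------------------------------------

def _univariate_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("univariate logistic fit did not converge")
    return float(res.params[1]), float(res.bse[1] ** 2)


def univariate_screen(
    completed: "Sequence[Dataset] | Iterable[Dataset]",
    outcome: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled univariate logistic screen of each candidate against the outcome.

    For every candidate, a logistic regression of the (binary) outcome on
    that single variable is fit in each completed dataset; coefficients are
    pooled by Rubin's rules and a two-sided Wald test on t(df) decides
    inclusion at level ``alpha``.  Non-convergent candidates are reported
    with ``error`` filled rather than aborting the screen.
    """
    datasets = list(completed)
    rows = []
    for cand in candidates:
        ests, variances, err = [], [], None
        for ds in datasets:
            frame = ds.values if isinstance(ds, Dataset) else ds
            y = frame[outcome].to_numpy(dtype=float)
            x = frame[cand].to_numpy(dtype=float)
            keep = ~(np.isnan(y) | np.isnan(x))
            try:
                b, v = _univariate_logit(y[keep], x[keep])
                ests.append(b)
                variances.append(v)
            except Exception as exc:
                err = str(exc)
                break
        if err is not None:
            rows.append({"candidate": cand, "error": err, "include": False})
            continue
        pooled = pool_rubin(ests, variances)
        p = pooled.pvalue()
        rows.append(
            {
                "candidate": cand,
                "coef": pooled.theta_bar,
                "se": pooled.se,
                "df": pooled.df,
                "p": p,
                "include": bool(p < alpha),
                "error": None,
            }
        )
    return pd.DataFrame(rows).set_index("candidate")


# ---------------------------------------------------------------------------
# 2x2 selection agreement
# ---------------------------------------------------------------------------

def chi_square_agreement(table: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and percent agreement.

    ``table`` holds the 2x2 cross-tabulation of include/exclude decisions
    under two selection approaches; agreement is the main-diagonal share.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("empty table")
    rowsum = t.sum(axis=1)
    colsum = t.sum(axis=0)
    if (rowsum == 0).any() or (colsum == 0).any():
        raise ValueError("zero marginal total: chi-square undefined")
    expected = np.outer(rowsum, colsum) / total
    chi2 = float(((t - expected) ** 2 / expected).sum())
    agreement = float(np.trace(t) / total)
    return chi2, agreement
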