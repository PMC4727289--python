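# scalemice

Multiple imputation by chained equations (MICE) for survey data that
contains **multiple multi-item scales** — the setting where imputing
every Likert item with every other item as a predictor makes the
conditional models so large they fail to converge, while imputing only
scale totals throws away partially answered scales.

`scalemice` imputes at item level but keeps prediction equations small
by representing every *other* scale by its summed score. With outcome
*p*, demographics *d₁…dₙ*, a 7-item scale *S* and a 17-item scale *T*
(summed scores *s*, *t*), the imputation models are

```
d₁ | p, d₂…dₙ, s, t
s₁ | p, d₁…dₙ, s₂…s₇, t
t₁ | p, d₁…dₙ, s, t₂…t₁₇
```

with totals recomputed passively after each draw. On a survey of 135
analysis variables this shrinks conditional models from 134 predictors
to at most the largest scale's size plus the non-scale variables —
the difference between chained equations failing and running.

The package provides:

* **`scalemice.schema`** — declarative survey schemas (variable roles
  and types, scale membership, conditional "gate" structure), predictor
  sets under the `full` / `totals_only` / `proposed` schemes, model-size
  reports, sparse-category collapsing, opt-out question splitting;
* **`scalemice.engine`** — the chained-equations engine: proper draws
  per measurement type (Bayesian linear, logistic, proportional-odds,
  multinomial), passive scale totals, conditional imputation of gated
  questions, ridge/collapse fallbacks for sparse categorical fits;
* **`scalemice.pooling`** — Rubin's rules, a pooled univariate logistic
  screen, and the Pearson χ²/percent-agreement summary of 2×2 variable
  selection decisions;
* **`scalemice.strategies`** — six comparable missing-data strategies,
  from complete-case analysis and proration to item-level joint-MVN
  imputation;
* **`scalemice.simulation`** — a simulation laboratory (323 respondents,
  binary adherence outcome, age, a 7-item and a 17-item scale, three
  calibrated missing-at-random scenarios) that scores the strategies by
  percent bias, coverage, and relative empirical SE with Monte-Carlo
  intervals;
* a **CLI**: `scalemice schema|impute|strategy|pool|agreement|simulate|diagnose`.

## Worked example

```python
import numpy as np, pandas as pd
import scalemice as sm
from scalemice.fixtures import toy_schema

schema = toy_schema()                    # p, d1..d3, S (7 items), T (17 items)
rng = np.random.default_rng(0)
n = 150
cols = {"p": rng.integers(0, 2, n).astype(float)}
for d in ("d1", "d2", "d3"):
    cols[d] = rng.normal(size=n)
for it in [f"s{i}" for i in range(1, 8)] + [f"t{i}" for i in range(1, 18)]:
    cols[it] = rng.integers(1, 6, n).astype(float)
df = pd.DataFrame(cols)
for c in df.columns[2:]:                 # 20 % nonresponse in items
    df.loc[rng.random(n) < 0.2, c] = np.nan

# 3 cycles keeps this demo quick; production runs use the default 10
completed = sm.run_mice(sm.Dataset(df), schema,
                        sm.ImputationConfig(M=5, cycles=3, scheme="proposed", seed=7))
ests, variances = [], []
import statsmodels.api as sm_api
for ds in completed:                     # logistic slope of p on the S total
    fit = sm_api.Logit(ds.values["p"], sm_api.add_constant(ds.values["s"])).fit(disp=0)
    ests.append(fit.params.iloc[1]); variances.append(fit.bse.iloc[1] ** 2)
pooled = sm.pool_rubin(ests, variances)
print(f"pooled slope {pooled.theta_bar:.3f}  se {pooled.se:.3f}  df {pooled.df:.1f}")
```

This prints (seed 7, ≈30 s: every item gets a proportional-odds model):

```
pooled slope 0.028  se 0.050  df 383.0
```

a pooled log-odds slope near zero — as it should be, since the toy data
draw outcome and items independently — with the total variance combining
within-imputation sampling error and between-imputation uncertainty, and
Rubin's reference degrees of freedom for the Wald interval.

Model sizes under the three schemes for the same schema:

```python
print(sm.model_size_report(schema))
#              n_models  min  median  max
# full               28   27    27.0   27
# totals_only        28    5     5.0    5
# proposed           28    5    21.0   21
```

Under `proposed` the largest model belongs to items of the 17-item
scale: outcome + 3 demographics + the other scale's total + 16 sibling
items = 21 predictors, versus 27 under `full`.

The selection-agreement statistic for a 2×2 include/exclude table
(counts 86, 3 / 25, 259):

```sh
$ scalemice agreement --counts 86,3,25,259
chi2 = 250.1, agreement = 92.5%
```

## The simulation laboratory

```sh
scalemice simulate --scenario base --reps 200 --methods 1,2,6 --m 10 \
    --seed 11 --out metrics.csv
```

compares complete-case analysis (1), proration (2) and the joint-MVN
benchmark (6) under the base missing-at-random scenario (35 % of
respondents lose a whole scale, 8 % lose one or two items, with
missingness driven by the outcome and age). Typical output at these
settings: complete case and proration biased low on the 17-item scale
mean by about −1.4 % and −1.3 % while the benchmark stays within ±0.2 %,
benchmark coverage compatible with the nominal 95 %, and multiple
imputation clearly more efficient (empirical SE ratios ≈ 0.6–0.8).
Scenarios `more_partial` (18 %/25 %) and `fewer_complete` (55 %/15 %)
and methods 3–5 are available the same way.

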