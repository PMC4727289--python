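"""Survey structure: variables, multi-item scales, conditional (gated) questions.

A :class:`SurveySchema` declares what each column of a survey dataset is —
its role (outcome, demographic, single item, scale item, derived scale
total), its measurement type, which scale it belongs to, and whether it is
asked conditionally on an earlier "gate" question.  The schema drives the
construction of per-variable imputation predictor sets under three schemes:

``full``
    every other raw variable predicts the target (the conventional
    chained-equations model);
``totals_only``
    each multi-item scale is represented by its summed total, and the
    target's own scale is dropped entirely (its total would leak the
    target);
``proposed``
    like ``totals_only``, except the target's own scale contributes its
    sibling items instead of a total — item-level imputation with
    summary-score predictors for all *other* scales.

The ``proposed`` scheme is the scale-summary adaptation this package is
built around: it keeps item-level imputation feasible when a survey holds
many multi-item instruments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "ScaleSpec",
    "SurveySchema",
    "PredictorSet",
    "SchemaError",
    "validate_schema",
    "derive_predictor_sets",
    "model_size_report",
    "collapse_categories",
    "split_optout_variable",
    "merge_optout_variable",
]

ROLES = frozenset({"outcome", "demographic", "single_item", "scale_item", "scale_total"})
MTYPES = frozenset({"continuous", "binary", "ordinal", "nominal"})
SCHEMES = ("full", "totals_only", "proposed")


class SchemaError(ValueError):
    """A schema violates its structural invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """One survey variable.

    Parameters
    ----------
    name : str
        Unique identifier, also the dataset column name.
    role : str
        One of ``outcome``, ``demographic``, ``single_item``, ``scale_item``,
        ``scale_total``.
    mtype : str
        Measurement type: ``continuous``, ``binary``, ``ordinal`` or
        ``nominal``.  Ordinal/nominal variables carry ``n_levels`` >= 2.
    scale : str, optional
        Owning scale; required iff role is ``scale_item`` or ``scale_total``.
    gate : tuple, optional
        ``(gate_variable, required_value)`` — the variable is only asked of
        respondents whose gate variable equals the required value.
    applicable : bool
        False marks a question not fielded in this dataset (e.g. an item
        dropped in one country); it is excluded from models and reports.
    n_levels : int, optional
        Number of categories for ordinal/nominal variables.
    """

    name: str
    role: str
    mtype: str
    scale: str | None = None
    gate: tuple[str, float] | None = None
    applicable: bool = True
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.mtype not in MTYPES:
            raise SchemaError(f"unknown mtype {self.mtype!r} for variable {self.name!r}")
        if self.mtype in ("ordinal", "nominal"):
            if self.n_levels is not None and self.n_levels < 2:
                raise SchemaError(f"{self.name}: ordinal/nominal need >= 2 levels")
        if self.role in ("scale_item", "scale_total") and not self.scale:
            raise SchemaError(f"{self.name}: role {self.role} requires a scale name")

    @property
    def derived(self) -> bool:
        """Derived variables (scale totals) are computed, never raw inputs."""
        return self.role == "scale_total"


@dataclass(frozen=True)
class ScaleSpec:
    """A multi-item scale whose analysis variable is the unweighted item sum."""

    name: str
    items: tuple[str, ...]
    total: str | None = None  # name of the derived total column; default "<name>_total"

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise SchemaError(f"scale {self.name!r} needs >= 2 items")
        if len(set(self.items)) != len(self.items):
            raise SchemaError(f"scale {self.name!r} lists a duplicate item")

    @property
    def total_name(self) -> str:
        return self.total if self.total is not None else f"{self.name}_total"


@dataclass
class SurveySchema:
    """Declarative survey description: variables, scales, analysis order."""

    variables: list[VariableSpec]
    scales: list[ScaleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {v.name: v for v in self.variables}

    # -- lookups ---------------------------------------------------------
    def __getitem__(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        """Canonical (declaration) order of all variables."""
        return [v.name for v in self.variables]

    def scale_of(self, name: str) -> ScaleSpec | None:
        for sc in self.scales:
            if name in sc.items or name == sc.total_name:
                return sc
        return None

    @property
    def raw_variables(self) -> list[VariableSpec]:
        """Non-derived, applicable variables — candidates for imputation."""
        return [v for v in self.variables if not v.derived and v.applicable]

    @property
    def outcome(self) -> VariableSpec:
        out = [v for v in self.variables if v.role == "outcome"]
        if len(out) != 1:
            raise SchemaError(f"schema declares {len(out)} outcomes, expected exactly 1")
        return out[0]

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    k: v
                    for k, v in {
                        "name": s.name,
                        "role": s.role,
                        "mtype": s.mtype,
                        "scale": s.scale,
                        "gate": list(s.gate) if s.gate else None,
                        "applicable": s.applicable,
                        "n_levels": s.n_levels,
                    }.items()
                    if v is not None
                }
                for s in self.variables
            ],
            "scales": [
                {"name": s.name, "items": list(s.items), "total": s.total_name}
                for s in self.scales
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SurveySchema":
        variables = []
        for v in doc["variables"]:
            gate = v.get("gate")
            variables.append(
                VariableSpec(
                    name=v["name"],
                    role=v["role"],
                    mtype=v["mtype"],
                    scale=v.get("scale"),
                    gate=(gate[0], gate[1]) if gate else None,
                    applicable=v.get("applicable", True),
                    n_levels=v.get("n_levels"),
                )
            )
        scales = [
            ScaleSpec(name=s["name"], items=tuple(s["items"]), total=s.get("total"))
            for s in doc.get("scales", [])
        ]
        return cls(variables=variables, scales=scales)

    @classmethod
    def from_json(cls, path) -> "SurveySchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class PredictorSet:
    """Predictors used to impute one target variable under one scheme."""

    target: str
    predictors: tuple[str, ...]
    scheme: str

    def __len__(self) -> int:
        return len(self.predictors)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_schema(schema: SurveySchema) -> list[str]:
    """Check structural invariants; return a list of violations (empty = pass).

    Fatal conditions (duplicate names, gate cycles) raise :class:`SchemaError`
    immediately since no later operation could interpret such a schema.
    """
    violations: list[str] = []
    names = [v.name for v in schema.variables]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise SchemaError(f"duplicate variable names: {sorted(dupes)}")

    n_outcomes = sum(v.role == "outcome" for v in schema.variables)
    if n_outcomes != 1:
        violations.append(f"exactly one outcome required, found {n_outcomes}")

    # scale membership
    item_owner: dict[str, str] = {}
    for sc in schema.scales:
        for it in sc.items:
            if it in item_owner:
                violations.append(f"item {it!r} in two scales ({item_owner[it]!r}, {sc.name!r})")
            item_owner[it] = sc.name
            if it not in schema:
                violations.append(f"scale {sc.name!r} references unknown item {it!r}")
            elif schema[it].role != "scale_item":
                violations.append(f"{it!r} listed in scale {sc.name!r} but role is {schema[it].role}")
    for v in schema.variables:
        if v.role == "scale_item" and v.name not in item_owner:
            violations.append(f"orphan scale item {v.name!r} (no scale lists it)")
        if v.role == "scale_total":
            totals = {sc.total_name for sc in schema.scales}
            if v.name not in totals:
                violations.append(f"scale_total {v.name!r} matches no declared scale")

    # gates: must exist, be binary, and be acyclic
    for v in schema.variables:
        if v.gate is None:
            continue
        gname, _ = v.gate
        if gname not in schema:
            violations.append(f"{v.name!r} gated on unknown variable {gname!r}")
            continue
        if schema[gname].mtype != "binary":
            violations.append(f"gate variable {gname!r} of {v.name!r} is not binary")
        # walk the gate chain looking for a cycle
        seen = {v.name}
        cur = gname
        while cur is not None:
            if cur in seen:
                raise SchemaError(f"cyclic gate chain through {v.name!r}")
            seen.add(cur)
            nxt = schema[cur].gate if cur in schema else None
            cur = nxt[0] if nxt else None
    return violations


# ---------------------------------------------------------------------------
# predictor sets
# ---------------------------------------------------------------------------

def derive_predictor_sets(
    schema: SurveySchema, scheme: str, targets: Iterable[str] | None = None
) -> list[PredictorSet]:
    """Build one :class:`PredictorSet` per raw (non-derived) variable.

    A categorical variable counts as one predictor regardless of its dummy
    expansion: the counting convention is questions, not design-matrix
    columns.

    Parameters
    ----------
    scheme : {"full", "totals_only", "proposed"}
    targets : iterable of str, optional
        Restrict to these targets (default: every raw variable).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    raw = [v.name for v in schema.raw_variables]
    if targets is None:
        targets = raw
    out = []
    for target in targets:
        preds = _predictors_for(schema, target, scheme, raw)
        out.append(PredictorSet(target=target, predictors=tuple(preds), scheme=scheme))
    return out


def _predictors_for(schema: SurveySchema, target: str, scheme: str, raw: Sequence[str]) -> list[str]:
    own = schema.scale_of(target)
    own_name = own.name if own is not None and target in own.items else None
    if scheme == "full":
        return [n for n in raw if n != target]
    preds: list[str] = []
    for n in raw:
        if n == target:
            continue
        sc = schema.scale_of(n)
        if sc is None or n not in sc.items:
            preds.append(n)  # non-scale variable: always in, as itself
        elif sc.name == own_name:
            if scheme == "proposed":
                preds.append(n)  # sibling item of the target's own scale
            # totals_only: own scale omitted entirely (its total leaks target)
        # other scales: represented once by their total, added below
    for sc in schema.scales:
        if not _scale_applicable(schema, sc):
            continue
        if sc.name == own_name:
            continue  # never the own total: it would contain the target
        preds.append(sc.total_name)
    return preds


def _scale_applicable(schema: SurveySchema, sc: ScaleSpec) -> bool:
    return any(it in schema and schema[it].applicable for it in sc.items)


def model_size_report(schema: SurveySchema) -> pd.DataFrame:
    """Predictor-count summary per scheme: min / median / max model size."""
    rows = []
    for scheme in SCHEMES:
        sizes = np.array([len(ps) for ps in derive_predictor_sets(schema, scheme)])
        rows.append(
            {
                "scheme": scheme,
                "n_models": sizes.size,
                "min": int(sizes.min()),
                "median": float(np.median(sizes)),
                "max": int(sizes.max()),
            }
        )
    return pd.DataFrame(rows).set_index("scheme")


# ---------------------------------------------------------------------------
# category collapsing
# ---------------------------------------------------------------------------

def collapse_categories(
    values: pd.Series | np.ndarray,
    min_share: float = 0.05,
    policy: str = "adjacent_ordinal",
) -> tuple[dict, pd.Series]:
    """Merge sparse categories until every observed share >= ``min_share``.

    Repeatedly takes the category with the smallest observed share and merges
    it into its neighbour: for ``adjacent_ordinal``, the adjacent category
    (in level order) with the smaller share; for ``rarest_nominal``, the
    next-rarest category.  Stops at two categories regardless.  Returns the
    recode map (old level -> new level) together with the recoded column so
    the identical collapsing can be reapplied at analysis time.
    """
    if policy not in ("adjacent_ordinal", "rarest_nominal"):
        raise ValueError(f"unknown policy {policy!r}")
    s = pd.Series(values)
    observed = s.dropna()
    levels = sorted(observed.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 observed categories to collapse")
    counts = {lv: int((observed == lv).sum()) for lv in levels}
    total = observed.size

    # union-find over levels; each merge unions two groups
    parent = {lv: lv for lv in levels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    groups = {lv: {lv} for lv in levels}
    while len(groups) > 2:
        shares = {g: sum(counts[m] for m in mem) / total for g, mem in groups.items()}
        gmin = min(shares, key=lambda g: (shares[g], levels.index(g)))
        if shares[gmin] >= min_share:
            break
        if policy == "adjacent_ordinal":
            ordered = sorted(groups, key=lambda g: min(levels.index(m) for m in groups[g]))
            i = ordered.index(gmin)
            nbrs = [ordered[j] for j in (i - 1, i + 1) if 0 <= j < len(ordered)]
            tgt = min(nbrs, key=lambda g: shares[g])
        else:
            others = sorted((g for g in groups if g != gmin), key=lambda g: shares[g])
            tgt = others[0]
        parent[find(gmin)] = find(tgt)
        groups[tgt] |= groups.pop(gmin)
    else:
        # loop exhausted by the len>2 guard: check whether sparsity remains
        shares = {g: sum(counts[m] for m in mem) / total for g, mem in groups.items()}
        if min(shares.values()) < min_share:
            warnings.warn(
                "category share below min_share but already at 2 categories; not collapsing",
                stacklevel=2,
            )

    # representative of each group: its lowest level (keeps ordinal order)
    recode = {}
    for lv in levels:
        root = find(lv)
        rep = min(groups[root], key=levels.index)
        recode[lv] = rep
    recoded = s.map(lambda x: recode.get(x, x))
    return recode, recoded


# ---------------------------------------------------------------------------
# opt-out splitting
# ---------------------------------------------------------------------------

def split_optout_variable(
    values: pd.Series | np.ndarray, optout_code: float
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Split an ordered-categorical column with an opt-out code in two.

    Returns ``(willingness, response, structural_mask)``:

    * ``willingness`` — 1 where a substantive response was given, 0 where the
      respondent opted out, NaN where the original is missing;
    * ``response`` — the ordinal value where willing, NaN otherwise;
    * ``structural_mask`` — True exactly where the response is structurally
      undefined (respondent opted out), distinguishing design-missing from
      nonresponse.

    ``merge_optout_variable`` reverses the split exactly.
    """
    s = pd.Series(values, dtype=float)
    substantive = s.notna() & (s != optout_code)
    if np.isfinite(optout_code) and (s[substantive] == optout_code).any():  # pragma: no cover
        raise ValueError("opt-out code collides with a substantive level")
    willingness = pd.Series(np.where(s.isna(), np.nan, np.where(s == optout_code, 0.0, 1.0)), index=s.index)
    response = s.where(substantive, np.nan)
    structural = (s == optout_code).fillna(False).astype(bool)
    return willingness, response, structural


def merge_optout_variable(
    willingness: pd.Series, response: pd.Series, optout_code: float
) -> pd.Series:
    """Inverse of :func:`split_optout_variable`."""
    w = pd.Series(willingness, dtype=float)
    r = pd.Series(response, dtype=float)
    out = r.copy()
    out[w == 0.0] = optout_code
    out[w.isna()] = np.nan
    return out
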