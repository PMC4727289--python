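"""Packaged example schemas.

``toy_schema`` is the didactic setting used throughout the docs: a binary
primary outcome ``p``, three demographics, a 7-item scale ``S`` and a
17-item scale ``T``.  ``survey_schema_2016`` encodes a real multinational
adherence survey (42 analysis variables, 14 multi-item subscales, opt-out
income questions, one country-specific item).  The published description
of that survey leaves some encoding choices open — most notably how the
income opt-out split and per-country applicability enter the variable
count — so this fixture documents its own encoding and model-size reports
are made against it as encoded, not against externally quoted counts.
"""

from __future__ import annotations

from .schema import ScaleSpec, SurveySchema, VariableSpec

__all__ = ["toy_schema", "survey_schema_2016"]


def toy_schema(n_demographics: int = 3) -> SurveySchema:
    """Outcome ``p``, demographics ``d1..dn``, scales S (7 items), T (17)."""
    d = [f"d{i}" for i in range(1, n_demographics + 1)]
    s_items = tuple(f"s{i}" for i in range(1, 8))
    t_items = tuple(f"t{i}" for i in range(1, 18))
    variables = [
        VariableSpec("p", role="outcome", mtype="binary"),
        *[VariableSpec(n, role="demographic", mtype="continuous") for n in d],
        *[
            VariableSpec(n, role="scale_item", mtype="ordinal", scale="S", n_levels=5)
            for n in s_items
        ],
        *[
            VariableSpec(n, role="scale_item", mtype="ordinal", scale="T", n_levels=5)
            for n in t_items
        ],
        VariableSpec("s", role="scale_total", mtype="continuous", scale="S"),
        VariableSpec("t", role="scale_total", mtype="continuous", scale="T"),
    ]
    scales = [ScaleSpec("S", items=s_items, total="s"), ScaleSpec("T", items=t_items, total="t")]
    return SurveySchema(variables=variables, scales=scales)


def _items(prefix: str, k: int, scale: str, n_levels: int = 5) -> list[VariableSpec]:
    return [
        VariableSpec(f"{prefix}_{i}", role="scale_item", mtype="ordinal",
                     scale=scale, n_levels=n_levels)
        for i in range(1, k + 1)
    ]


def survey_schema_2016(wales: bool = False) -> SurveySchema:
    """Encoding of the multinational adherence survey structure.

    Encoding choices: the adherence outcome (complete by design) enters as
    one binary score; each income question splits into a binary
    willingness gate plus a gated ordinal response; illness-perception
    items are imputed as a scale though analysed individually; with
    ``wales=True`` the 15th treatment-barriers item is flagged not
    applicable (that country fields a 14-item version).
    """
    scales: list[ScaleSpec] = []
    variables: list[VariableSpec] = [
        VariableSpec("morisky", role="outcome", mtype="binary"),
        VariableSpec("gender", role="demographic", mtype="binary"),
        VariableSpec("age", role="demographic", mtype="continuous"),
        VariableSpec("education", role="demographic", mtype="nominal", n_levels=3),
        VariableSpec("marital_status", role="demographic", mtype="binary"),
        VariableSpec("employment", role="demographic", mtype="binary"),
        VariableSpec("n_conditions", role="demographic", mtype="continuous"),
        VariableSpec("n_medicines", role="demographic", mtype="continuous"),
        VariableSpec("n_tablets", role="demographic", mtype="continuous"),
        VariableSpec("n_items_prescribed", role="demographic", mtype="continuous"),
        VariableSpec("dosage_frequency", role="single_item", mtype="ordinal", n_levels=4),
        VariableSpec("prescription_payment", role="single_item", mtype="nominal", n_levels=3),
        VariableSpec("affordability_problem", role="single_item", mtype="binary"),
        VariableSpec("income_source", role="single_item", mtype="nominal", n_levels=5),
        VariableSpec("health_status", role="single_item", mtype="ordinal", n_levels=5),
        VariableSpec("practitioner_type", role="single_item", mtype="nominal", n_levels=3),
        VariableSpec("practitioner_gender", role="single_item", mtype="binary"),
        VariableSpec("barriers_tpb", role="single_item", mtype="ordinal", n_levels=5),
    ]
    # opt-out income questions: willingness gate + gated ordinal response
    for stem in ("income_perception", "income_borrowing", "income_total"):
        variables.append(VariableSpec(f"{stem}_willing", role="single_item", mtype="binary"))
        variables.append(
            VariableSpec(stem, role="single_item", mtype="ordinal", n_levels=5,
                         gate=(f"{stem}_willing", 1.0))
        )
    # single-item batteries imputed item-by-item
    for i in range(1, 7):
        variables.append(
            VariableSpec(f"cost_coping_{i}", role="single_item", mtype="ordinal", n_levels=5)
        )
    for i in range(1, 5):
        variables.append(
            VariableSpec(f"time_pref_{i}", role="single_item", mtype="ordinal", n_levels=5)
        )
    # the 14 multi-item subscales
    for name, k in (
        ("mars", 5),
        ("satisfaction_practitioner", 17),
        ("satisfaction_practice", 16),
        ("optimism", 6),
        ("illness_perception", 8),
        ("necessities", 5),
        ("concerns", 6),
        ("attitude", 7),
        ("facilitators", 3),
        ("intention", 2),
        ("self_efficacy", 2),
        ("normative_beliefs", 3),
        ("barriers", 15),
        ("social_support", 17),
    ):
        items = _items(name, k, name)
        if name == "barriers" and wales:
            items[-1] = VariableSpec(
                items[-1].name, role="scale_item", mtype="ordinal", scale=name,
                n_levels=5, applicable=False,
            )
        variables.extend(items)
        scales.append(ScaleSpec(name, items=tuple(v.name for v in items)))
        variables.append(
            VariableSpec(f"{name}_total", role="scale_total", mtype="continuous", scale=name)
        )
    return SurveySchema(variables=variables, scales=scales)
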