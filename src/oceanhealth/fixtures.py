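"""Packaged reference tables: species list, risk weights, price-model
coefficients, and the 2013 per-goal assessment used as the worked example.

The 2013 assessment CSV is a verbatim transcription.  Its printed "Iconic
Places & Species" goal row is arithmetically the Iconic Species (ICO)
subgoal (its score is the mean of its own printed status and future), while
the printed "SP" row equals the mean of the two subgoal scores and is the
Sense of Place goal-level value; :func:`assessment_layers` applies that
interpretation.  The species fixture's COSEWIC statuses and range weights
are placeholders (per-species assessments are inputs, not packaged facts):
only the roster — 19 species, 4 from the original global list, 4 added on a
generic salmon reference — is load-bearing.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .iconic import SpeciesRecord
from .needs import RegressionCoefficients

#: Canonical goal ids, in reporting order.
GOALS = ("FP", "AN", "NP", "CS", "CP", "CL", "TR", "SOP", "CW", "BD")

GOAL_NAMES = {
    "FP": "Food Provision",
    "AN": "Aboriginal Needs",
    "NP": "Natural Products",
    "CS": "Carbon Storage",
    "CP": "Coastal Protection",
    "CL": "Coastal Livelihoods",
    "TR": "Tourism & Recreation",
    "SOP": "Sense of Place",
    "CW": "Clean Waters",
    "BD": "Biodiversity",
}

#: Subgoal composition of the multi-subgoal goals.
GOAL_STRUCTURE = {
    "FP": ("FIS", "MAR"),
    "CL": ("LIV", "ECO"),
    "SOP": ("LSP", "ICO"),
    "BD": ("HAB", "SPP"),
}

_NAME_TO_ID = {name: gid for gid, name in GOAL_NAMES.items()}
_NAME_TO_ID["Iconic Places & Species"] = "SOP"

__all__ = [
    "GOALS",
    "GOAL_NAMES",
    "GOAL_STRUCTURE",
    "species_table",
    "species_records",
    "risk_table",
    "regression_coefficients",
    "assessment_reported",
    "assessment_layers",
    "reported_goal_values",
    "reported_subgoal_values",
    "fp_yield_weights",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("oceanhealth").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def species_table() -> pd.DataFrame:
    """The 19-species roster with original-list and salmon-reference flags."""
    return _read("species.csv")


def species_records() -> list[SpeciesRecord]:
    return [
        SpeciesRecord(
            common_name=row.common_name,
            scientific_name=row.scientific_name,
            cosewic_status=row.cosewic_status,
            range_weight=float(row.range_weight),
            in_original_ohi=bool(row.in_original_ohi),
        )
        for row in species_table().itertuples()
    ]


@lru_cache(maxsize=None)
def risk_table() -> dict[str, float]:
    """COSEWIC status -> risk weight."""
    df = _read("risk_weights.csv")
    return dict(zip(df["cosewic_status"], df["risk_weight"].astype(float)))


@lru_cache(maxsize=None)
def regression_coefficients(group: str) -> RegressionCoefficients:
    """Packaged food-basket price-model coefficients for one group."""
    df = _read("price_model_coefficients.csv")
    df = df[df["group"] == group]
    if df.empty:
        raise ValueError(f"no packaged coefficients for group {group!r}")
    est = dict(zip(df["term"], df["estimate"].astype(float)))
    se = {
        t: float(s)
        for t, s in zip(df["term"], df["std_error"])
        if pd.notna(s)
    }
    return RegressionCoefficients(
        group=group,
        intercept=est["intercept"],
        b_rnfb=est.get("rnfb"),
        b_rnfb_dist=est.get("rnfb_dist"),
        b_iccpi=est["iccpi"],
        b_iccpi_dist=est["iccpi_dist"],
        b_pop=est["population"],
        std_errors=se,
        adj_r2=est.get("adj_r2"),
        f_stat=est.get("f_statistic"),
    )


@lru_cache(maxsize=None)
def assessment_reported() -> pd.DataFrame:
    """Verbatim 2013 assessment table (goal, subgoal, score .. resilience)."""
    df = _read("assessment_2013.csv")
    df["subgoal"] = df["subgoal"].fillna("")
    return df


def assessment_layers() -> pd.DataFrame:
    """Engine-ready layers: goal, subgoal, status, trend, pressure, resilience.

    Applies the Sense of Place interpretation: the printed goal row becomes
    the ICO subgoal; the printed LSP row stays; the printed "SP" row (a
    derived goal-level mean) is dropped.
    """
    rep = assessment_reported()
    rows = []
    for row in rep.itertuples():
        if row.goal == "OVERALL" or pd.isna(row.status):
            continue
        gid = _NAME_TO_ID[row.goal]
        if gid == "SOP":
            if row.subgoal == "SP":
                continue
            subgoal = "ICO" if row.subgoal == "" else row.subgoal
        else:
            subgoal = row.subgoal
        if gid in GOAL_STRUCTURE and subgoal == "":
            continue  # printed goal-level aggregate of subgoal rows
        if pd.isna(row.pressure) or pd.isna(row.resilience):
            continue
        rows.append(
            {
                "goal": gid,
                "subgoal": subgoal,
                "status": float(row.status),
                "trend": float(row.trend),
                "pressure": float(row.pressure),
                "resilience": float(row.resilience),
            }
        )
    return pd.DataFrame(rows)


def reported_subgoal_values(dimension: str) -> dict[tuple[str, str], float]:
    """Printed (goal, subgoal) -> value for one dimension, SOP-interpreted."""
    rep = assessment_reported()
    out: dict[tuple[str, str], float] = {}
    for row in rep.itertuples():
        if row.goal == "OVERALL":
            continue
        gid = _NAME_TO_ID[row.goal]
        value = getattr(row, dimension)
        if pd.isna(value):
            continue
        subgoal = row.subgoal
        if gid == "SOP":
            if subgoal == "SP":
                continue
            subgoal = "ICO" if subgoal == "" else subgoal
        out[(gid, subgoal)] = float(value)
    return out


def reported_goal_values(dimension: str) -> dict[str, float]:
    """Printed goal-level values for one dimension.

    Sense of Place has no printed goal-level row under the adopted
    interpretation, so its value is the equal-weight mean of its two subgoal
    values (e.g. score = mean(33.89, 84.91) = 59.40).
    """
    sub = reported_subgoal_values(dimension)
    out: dict[str, float] = {}
    for gid in GOALS:
        if gid == "SOP":
            out[gid] = (sub[("SOP", "LSP")] + sub[("SOP", "ICO")]) / 2.0
        elif (gid, "") in sub:
            out[gid] = sub[(gid, "")]
    return out


def fp_yield_weights() -> dict[str, float]:
    """Food Provision subgoal yield weights solved from the printed statuses.

    The printed goal status is a weighted mean of the two subgoal statuses;
    with s_FIS = 54.00, s_MAR = 85.77 and goal status 58.66 the wild-capture
    weight is (85.77 - 58.66) / (85.77 - 54.00) ~= 0.8533.  Cross-checks on
    the printed scores: 0.8533*59.36 + 0.1467*92.88 = 64.28.
    """
    sub = reported_subgoal_values("status")
    fis, mar = sub[("FP", "FIS")], sub[("FP", "MAR")]
    goal = reported_goal_values("status")["FP"]
    w_fis = (mar - goal) / (mar - fis)
    return {"FIS": w_fis, "MAR": 1.0 - w_fis}
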