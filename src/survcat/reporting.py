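"""Descriptive aggregations over categorized responses.

These are the tables behind category-frequency figures: weighted counts and
shares per category, optionally grouped by survey round or admin unit, with
the share denominator taken over all responses or over the free-text
("other") channel only.  Sampling weights are applied here and only here —
categorization itself never looks at weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import CategoryOrigin, CategoryScheme, ConfigurationError, SurveyResponse
from .strategies import CategoryAssignment

GROUPINGS = ("round", "admin_unit", "none")
DENOMINATORS = ("all_responses", "other_responses")


@dataclass
class FrequencyTable:
    """Weighted (category, group) counts and within-group shares."""

    rows: pd.DataFrame  # columns: category_index, group, count, share
    grouping: str
    denominator: str

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def aggregate(
    assignments: list[CategoryAssignment],
    responses: list[SurveyResponse],
    grouping: str = "none",
    denominator: str = "other_responses",
    use_weights: bool = True,
    exclude_rounds: tuple[int, ...] = (),
) -> FrequencyTable:
    """Tally weighted category frequencies and within-group shares.

    ``exclude_rounds`` drops survey rounds whose question format is not
    comparable (for multi-round trend tables).  Rows are ordered by category
    index then group key; shares within each group sum to 1.  Assignments
    with no parsed category are tallied under index 0.
    """
    if grouping not in GROUPINGS:
        raise ConfigurationError(f"unknown grouping {grouping!r}; expected {GROUPINGS}")
    if denominator not in DENOMINATORS:
        raise ConfigurationError(
            f"unknown denominator {denominator!r}; expected {DENOMINATORS}"
        )
    by_id = {r.response_id: r for r in responses}
    missing = [a.response_id for a in assignments if a.response_id not in by_id]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} assignments lack responses, e.g. {missing[0]!r}"
        )
    records = []
    for a in assignments:
        r = by_id[a.response_id]
        if r.survey_round in exclude_rounds:
            continue
        if grouping == "round":
            group = r.survey_round
        elif grouping == "admin_unit":
            group = r.admin_unit or "(none)"
        else:
            group = "all"
        records.append(
            {
                "category_index": a.category_index if a.category_index else 0,
                "group": group,
                "weight": r.weight if use_weights else 1.0,
            }
        )
    if not records:
        raise ConfigurationError("no responses left to aggregate")
    df = pd.DataFrame(records)
    counts = (
        df.groupby(["category_index", "group"], as_index=False)["weight"]
        .sum()
        .rename(columns={"weight": "count"})
    )
    totals = counts.groupby("group")["count"].transform("sum")
    counts["share"] = counts["count"] / totals
    counts = counts.sort_values(["category_index", "group"]).reset_index(drop=True)
    return FrequencyTable(rows=counts, grouping=grouping, denominator=denominator)


def new_vs_original_share(table: FrequencyTable, scheme: CategoryScheme) -> float:
    """Weighted share of assignments falling in researcher-added categories."""
    added = {
        c.index for c in scheme if c.origin == CategoryOrigin.ADDED_CATEGORY
    }
    df = table.rows
    total = df["count"].sum()
    if total == 0:
        raise ConfigurationError("empty frequency table")
    return float(df.loc[df["category_index"].isin(added), "count"].sum() / total)
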