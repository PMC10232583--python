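"""Coverage and overlap analytics over a variable x cohort presence matrix.

These are the data-discovery measures used to quantify harmonisation
potential: how many schema variables each cohort can supply per theme, how
variables overlap across cohorts, how the applied harmonisation strategies
split, and how closely the harmonised schema corresponds to cohort-native
data models.

Percentages are reported round-half-up to integer percent.
"""
from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mapping import CohortRuleSet
from .schema import Schema, strategy_tally

#: the variables harmonised through the interpretive transformations
#: (simplified scales / local-currency quantiles / presence-absence
#: reduction) rather than complete-or-close correspondence
INTERPRETIVE_VARIABLES = frozenset({
    "smoking_status", "ethnicity", "educational_level", "cohabitation",
    "accommodation_type", "income", "vigorous_exercise", "moderate_exercise",
    "walking",
})


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, round half up."""
    if denominator == 0:
        raise ValidationError("percentage with zero denominator")
    return int(math.floor(100 * numerator / denominator + 0.5))


@dataclass
class PresenceMatrix:
    """Binary variable x cohort availability grid.

    ``data`` is indexed by variable_id with one 0/1 integer column per
    cohort.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValidationError("duplicate cohort ids in presence matrix")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("presence cells must be strictly binary")
        self.data = self.data.astype(int)

    @property
    def variables(self) -> list[str]:
        return list(self.data.index)

    @property
    def cohorts(self) -> list[str]:
        return list(self.data.columns)

    def n_cohorts_per_variable(self) -> pd.Series:
        return self.data.sum(axis=1)

    def represented(self) -> list[str]:
        """Variables present in at least one cohort."""
        mask = self.data.sum(axis=1) > 0
        return list(self.data.index[mask])

    def present_in(self, cohort_id: str) -> list[str]:
        return list(self.data.index[self.data[cohort_id] == 1])


def load_presence_fixture() -> PresenceMatrix:
    """The packaged 124 x 4 presence matrix.

    Per-variable presence is not published directly; this matrix is one
    assignment consistent with every printed aggregate (theme-by-cohort
    counts, per-cohort totals, the overlap distribution, the four named
    absences and the ELSA/Memento unique-variable counts).
    """
    path = Path(importlib.resources.files("csurv") / "data"
                / "presence_matrix.csv")
    data = pd.read_csv(path, index_col="variable_id")
    return PresenceMatrix(data)


def build_presence(rule_sets: Mapping[str, CohortRuleSet],
                   raw_tables: Mapping[str, pd.DataFrame],
                   schema: Schema) -> PresenceMatrix:
    """Presence from rule sets plus raw tables.

    A variable counts as present for a cohort when the cohort has a
    data-producing rule for it and every source field the rule reads exists
    in the raw table.  ``not_collected`` annotations do not count.
    """
    cohorts = list(rule_sets)
    if len(set(cohorts)) != len(cohorts):
        raise ValidationError("duplicate cohort ids")
    grid = pd.DataFrame(0, index=pd.Index(schema.variable_ids,
                                          name="variable_id"),
                        columns=cohorts, dtype=int)
    for cohort, ruleset in rule_sets.items():
        raw = raw_tables[cohort]
        for vid, rule in ruleset.data_rules().items():
            if all(s in raw.columns for s in rule.sources):
                grid.loc[vid, cohort] = 1
    return PresenceMatrix(grid)


def theme_coverage(matrix: PresenceMatrix, schema: Schema) -> pd.DataFrame:
    """Variables per theme per cohort, with per-theme and per-cohort totals.

    Rows are the themes represented in the schema (core-list order) plus a
    ``Totals`` row; columns are ``variables_included`` plus one column per
    cohort.
    """
    unknown = [v for v in matrix.variables if v not in schema]
    if unknown:
        raise ValidationError(
            f"presence matrix contains variables unknown to schema: "
            f"{unknown[:5]}")
    theme_of = {v.variable_id: v.theme for v in schema}
    order: list[int] = []
    for spec in schema:
        if spec.theme.number not in order:
            order.append(spec.theme.number)
    rows = []
    for tno in order:
        vids = [v for v in matrix.variables if theme_of[v].number == tno]
        row = {"theme": schema.themes[tno].name,
               "variables_included": len(vids)}
        for c in matrix.cohorts:
            row[c] = int(matrix.data.loc[vids, c].sum())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("theme")
    totals = out.sum(axis=0)
    # conservation: per-cohort total equals the sum of its theme counts
    for c in matrix.cohorts:
        assert totals[c] == int(matrix.data[c].sum())
    out.loc["Totals"] = totals
    return out


def overlap_distribution(matrix: PresenceMatrix) -> dict[int, int]:
    """Histogram: number of cohorts a variable is present in -> variable count.

    Keys run 0..n_cohorts inclusive (the 0 bin reports variables found in no
    cohort); values sum to the number of variables.
    """
    counts = matrix.n_cohorts_per_variable().value_counts()
    hist = {k: int(counts.get(k, 0))
            for k in range(len(matrix.cohorts) + 1)}
    assert sum(hist.values()) == len(matrix.variables)
    return hist


def unique_counts(matrix: PresenceMatrix) -> dict[str, int]:
    """Variables present in exactly one cohort, per cohort."""
    single = matrix.data[matrix.n_cohorts_per_variable() == 1]
    return {c: int(single[c].sum()) for c in matrix.cohorts}


def correspondence_summary(matrix: PresenceMatrix,
                           interpretive_ids: Iterable[str] = INTERPRETIVE_VARIABLES
                           ) -> dict:
    """Split represented variables into complete-or-close vs interpretive.

    ``interpretive_ids`` must all be represented; percentages use the
    represented count as denominator.
    """
    represented = set(matrix.represented())
    interpretive = set(interpretive_ids)
    missing = sorted(interpretive - represented)
    if missing:
        raise ValidationError(
            f"interpretive variables not represented: {missing}")
    n_rep = len(represented)
    n_int = len(interpretive)
    n_close = n_rep - n_int
    return {
        "represented": n_rep,
        "complete_or_close": n_close,
        "complete_or_close_pct": percent(n_close, n_rep),
        "interpretive": n_int,
        "interpretive_pct": percent(n_int, n_rep),
    }


@dataclass
class CoverageReport:
    """All coverage analytics for one presence matrix + schema."""

    theme_counts: pd.DataFrame
    overlap: dict[int, int]
    strategy_tally: dict[str, int]
    correspondence: dict
    unique_counts: dict[str, int]
    n_variables: int
    n_represented: int

    @property
    def represented_pct(self) -> int:
        return percent(self.n_represented, self.n_variables)

    def to_dict(self) -> dict:
        return {
            "n_variables": self.n_variables,
            "n_represented": self.n_represented,
            "represented_pct": self.represented_pct,
            "theme_counts": {
                theme: {k: int(v) for k, v in row.items()}
                for theme, row in self.theme_counts.iterrows()},
            "overlap_distribution": {str(k): v for k, v in self.overlap.items()},
            "unique_counts": self.unique_counts,
            "strategy_tally": self.strategy_tally,
            "correspondence": self.correspondence,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 1),
                          **kwargs)


def coverage_report(matrix: PresenceMatrix, schema: Schema) -> CoverageReport:
    """Assemble the full harmonisation-potential report."""
    represented = matrix.represented()
    return CoverageReport(
        theme_counts=theme_coverage(matrix, schema),
        overlap=overlap_distribution(matrix),
        strategy_tally=strategy_tally(schema, restrict_to=set(represented)),
        correspondence=correspondence_summary(matrix),
        unique_counts=unique_counts(matrix),
        n_variables=len(matrix.variables),
        n_represented=len(represented),
    )
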