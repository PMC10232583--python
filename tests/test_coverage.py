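"""Coverage, overlap and correspondence analytics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csurv import (
    PresenceMatrix,
    build_presence,
    correspondence_summary,
    coverage_report,
    overlap_distribution,
    theme_coverage,
    unique_counts,
)
from csurv.coverage import percent
from csurv.errors import ValidationError


class TestPresenceFixture:
    def test_shape_and_represented_count(self, presence_fixture):
        assert presence_fixture.data.shape == (124, 4)
        assert len(presence_fixture.represented()) == 120

    def test_absent_variables_are_the_named_four(self, presence_fixture):
        absent = set(presence_fixture.variables) - set(
            presence_fixture.represented())
        assert absent == {"pollution_grime", "loneliness_scale_score",
                          "mci_diagnosis", "adas_cog_total_score"}

    def test_non_binary_cells_rejected(self):
        data = pd.DataFrame({"a": [0, 2]}, index=["x", "y"])
        with pytest.raises(ValidationError, match="binary"):
            PresenceMatrix(data)

    def test_duplicate_cohorts_rejected(self):
        data = pd.DataFrame([[1, 0]], columns=["a", "a"], index=["x"])
        with pytest.raises(ValidationError, match="duplicate"):
            PresenceMatrix(data)


class TestThemeCoverage:
    def test_cohort_totals(self, presence_fixture, schema):
        table = theme_coverage(presence_fixture, schema)
        assert table.loc["Totals", "airwave"] == 47
        assert table.loc["Totals", "elsa"] == 73
        assert table.loc["Totals", "genscot"] == 60
        assert table.loc["Totals", "memento"] == 92

    def test_imaging_theme_row(self, presence_fixture, schema):
        row = theme_coverage(presence_fixture, schema).loc["Imaging"]
        assert list(row[["airwave", "elsa", "genscot", "memento"]]) == \
            [0, 0, 0, 6]

    def test_conservation(self, presence_fixture, schema):
        table = theme_coverage(presence_fixture, schema)
        themes = table.drop(index="Totals")
        assert (themes.sum(axis=0) == table.loc["Totals"]).all()
        assert table.loc["Totals", "variables_included"] == 124

    def test_all_absent_matrix_gives_zeros(self, presence_fixture, schema):
        empty = PresenceMatrix(presence_fixture.data * 0)
        table = theme_coverage(empty, schema)
        assert (table.drop(columns="variables_included") == 0).all().all()


def _brute_force_overlap(data: pd.DataFrame) -> dict:
    """Independent tabulation: count matrix rows per explicit row sum."""
    hist = {k: 0 for k in range(data.shape[1] + 1)}
    for _, row in data.iterrows():
        hist[int(sum(row))] += 1
    return hist


class TestOverlapDistribution:
    def test_fixture_histogram(self, presence_fixture):
        assert overlap_distribution(presence_fixture) == {
            4: 34, 3: 10, 2: 30, 1: 46, 0: 4}

    def test_identity_case(self):
        data = pd.DataFrame(1, index=[f"v{i}" for i in range(7)],
                            columns=["a", "b", "c"])
        assert overlap_distribution(PresenceMatrix(data)) == {3: 7, 2: 0,
                                                              1: 0, 0: 0}

    def test_random_matrix_equals_brute_force(self):
        rng = np.random.default_rng(123)
        data = pd.DataFrame(rng.integers(0, 2, (200, 4)),
                            index=[f"v{i}" for i in range(200)],
                            columns=list("abcd"))
        matrix = PresenceMatrix(data)
        assert overlap_distribution(matrix) == _brute_force_overlap(data)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_brute_force_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        data = pd.DataFrame(rng.integers(0, 2, (n, 4)),
                            index=[f"v{i}" for i in range(n)],
                            columns=list("abcd"))
        matrix = PresenceMatrix(data)
        hist = overlap_distribution(matrix)
        assert hist == _brute_force_overlap(data)
        assert sum(hist.values()) == n


class TestCorrespondence:
    def test_nine_interpretive_variables(self, presence_fixture):
        summary = correspondence_summary(presence_fixture)
        assert summary["complete_or_close"] == 111
        assert summary["complete_or_close_pct"] == 93
        assert summary["interpretive"] == 9

    def test_empty_interpretive_set(self, presence_fixture):
        summary = correspondence_summary(presence_fixture,
                                         interpretive_ids=set())
        assert summary["complete_or_close"] == 120

    def test_all_flagged_interpretive(self, presence_fixture):
        rep = presence_fixture.represented()
        summary = correspondence_summary(presence_fixture,
                                         interpretive_ids=rep)
        assert summary["complete_or_close"] == 0

    def test_unrepresented_flag_rejected(self, presence_fixture):
        with pytest.raises(ValidationError, match="mci_diagnosis"):
            correspondence_summary(presence_fixture,
                                   interpretive_ids={"mci_diagnosis"})


class TestPercent:
    @pytest.mark.parametrize("num,den,expected", [
        (120, 124, 97), (61, 120, 51), (53, 120, 44), (111, 120, 93),
        (1, 200, 1), (1, 2, 50), (3, 8, 38),  # round half up: 37.5 -> 38
    ])
    def test_round_half_up(self, num, den, expected):
        assert percent(num, den) == expected


class TestBuildPresence:
    def test_matches_fixture_from_synthetic_cohorts(self, schema, rulesets,
                                                    raw_tables,
                                                    presence_fixture):
        matrix = build_presence(rulesets, raw_tables, schema)
        pd.testing.assert_frame_equal(matrix.data, presence_fixture.data)

    def test_empty_cohort_gives_all_absent_column(self, schema, rulesets,
                                                  raw_tables):
        tables = dict(raw_tables)
        tables["memento"] = pd.DataFrame()  # no source fields at all
        matrix = build_presence(rulesets, tables, schema)
        assert matrix.data["memento"].sum() == 0

    def test_unique_counts(self, presence_fixture):
        counts = unique_counts(presence_fixture)
        assert counts["elsa"] == 13
        assert counts["memento"] == 26
        assert sum(counts.values()) == 46


class TestCoverageReport:
    def test_report_is_internally_consistent(self, presence_fixture, schema):
        report = coverage_report(presence_fixture, schema)
        assert report.n_represented == 120
        assert report.represented_pct == 97
        assert sum(report.overlap.values()) == report.n_variables
        assert sum(report.strategy_tally.values()) == report.n_represented
        assert (report.correspondence["complete_or_close"]
                + report.correspondence["interpretive"]
                == report.n_represented)

    def test_json_round_trip(self, presence_fixture, schema):
        import json

        report = coverage_report(presence_fixture, schema)
        doc = json.loads(report.to_json())
        assert doc["strategy_tally"] == {"SC": 61, "AT": 53, "S": 6}
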