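"""Per-cohort mapping rules and the value-level harmonisation operations."""
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csurv import (
    MappingRule,
    apply_recode,
    encode_apoe,
    income_quantiles,
    infer_binary,
    load_mappings,
    truncate_date,
)
from csurv.errors import (
    CodebookViolationError,
    DuplicateRuleError,
    UnknownVariableError,
)
from csurv.mapping import smoking_from_two_fields


class TestLoadMappings:
    def test_packaged_rule_counts_match_cohort_totals(self, rulesets):
        data_counts = {c: len(rs.data_rules()) for c, rs in rulesets.items()}
        assert data_counts == {"airwave": 47, "elsa": 73, "genscot": 60,
                               "memento": 92}

    def test_every_rule_targets_a_schema_variable(self, schema, rulesets):
        for rs in rulesets.values():
            assert set(rs.rules) <= set(schema.variable_ids)

    def test_unknown_variable_rejected(self, schema, tmp_path):
        doc = textwrap.dedent("""\
            cohort_id: airwave
            rules:
              nonexistent: {kind: identity, source: x}
            """)
        path = tmp_path / "m.yaml"
        path.write_text(doc)
        with pytest.raises(UnknownVariableError, match="nonexistent"):
            load_mappings(path, schema)

    def test_recode_target_outside_codebook_rejected(self, schema, tmp_path):
        doc = textwrap.dedent("""\
            cohort_id: genscot
            rules:
              educational_level:
                kind: recode
                source: qual
                map: {Highers: 9}
            """)
        path = tmp_path / "m.yaml"
        path.write_text(doc)
        with pytest.raises(CodebookViolationError):
            load_mappings(path, schema)

    def test_duplicate_rule_rejected(self, schema, tmp_path):
        doc = textwrap.dedent("""\
            cohort_id: airwave
            rules:
              gender: {kind: recode, source: sex, map: {male: 1, female: 2}}
              gender: {kind: recode, source: sex, map: {male: 1, female: 2}}
            """)
        path = tmp_path / "m.yaml"
        path.write_text(doc)
        with pytest.raises(DuplicateRuleError, match="gender"):
            load_mappings(path, schema)


class TestApplyRecode:
    def test_genscot_highers_codes_secondary(self, rulesets):
        rule = rulesets["genscot"].rules["educational_level"]
        assert apply_recode("Highers", rule) == 3

    @pytest.mark.parametrize("cohort", ["airwave", "elsa", "genscot",
                                        "memento"])
    def test_no_qualification_codes_junior_everywhere(self, rulesets, cohort):
        rule = rulesets[cohort].rules["educational_level"]
        assert apply_recode("No qualification", rule) == 4

    def test_unmapped_label_is_missing_not_error(self, rulesets):
        rule = rulesets["airwave"].rules["educational_level"]
        assert apply_recode("astronaut school", rule) is None

    def test_case_insensitive_fallback(self, rulesets):
        rule = rulesets["genscot"].rules["educational_level"]
        assert apply_recode("  highers ", rule) == 3

    def test_missing_value_stays_missing(self, rulesets):
        rule = rulesets["airwave"].rules["educational_level"]
        assert apply_recode("", rule) is None
        assert apply_recode(None, rule) is None


class TestInferBinary:
    def test_date_presence(self):
        rule = MappingRule("ad_diagnosis", "date_presence", source="dx_date")
        assert infer_binary({"dx_date": "2009-03-02"}, rule) == 1
        assert infer_binary({"dx_date": ""}, rule) == 0
        assert infer_binary({}, rule) == 0
        # present but unparseable: missing, not 0
        assert infer_binary({"dx_date": "sometime in 2009"}, rule) is None

    @pytest.mark.parametrize("direction,threshold",
                             [("ge", 4), ("ge", 16), ("le", 10)])
    def test_score_threshold_matches_brute_force_grid(self, direction,
                                                      threshold):
        """Exhaustive integer score grid 0-50 against a literal comparison."""
        rule = MappingRule("depression_diagnosis", "score_threshold",
                           source="score", threshold=threshold,
                           direction=direction)
        for score in range(51):
            expected = int(score >= threshold if direction == "ge"
                           else score <= threshold)
            assert infer_binary({"score": score}, rule) == expected

    def test_score_threshold_unparseable_is_missing(self):
        rule = MappingRule("x", "score_threshold", source="score",
                           threshold=4)
        assert infer_binary({"score": "high"}, rule) is None

    def test_proxy_condition(self):
        rule = MappingRule("angina_diagnosis", "proxy_condition",
                           source="heart_disease", trigger="Yes")
        assert infer_binary({"heart_disease": "Yes"}, rule) == 1
        assert infer_binary({"heart_disease": "No"}, rule) == 0
        assert infer_binary({"heart_disease": ""}, rule) is None


class TestSmokingTwoFields:
    @pytest.mark.parametrize("ever,current,expected", [
        ("No", None, 0),
        ("Yes", "Yes", 2),
        ("Yes", "No", 1),
        ("Yes", None, 1),       # no secondary field: past smoker
        (None, "No", None),
    ])
    def test_resolution(self, ever, current, expected):
        assert smoking_from_two_fields(ever, current) == expected


class TestTruncateDate:
    @pytest.mark.parametrize("value,dialect,expected", [
        ("2001-05-17T13:45:00", "iso", "2001-05-17"),
        ("2001-05-17 13:45:00", "iso", "2001-05-17"),
        ("2001-05-17", "iso", "2001-05-17"),
        ("17/05/2001", "uk", "2001-05-17"),
        ("2001", "iso", None),          # partial date: missing, not imputed
        ("2001-02-30", "iso", None),    # calendar-invalid
        ("17/05/2001", "iso", None),    # wrong dialect
        ("", "iso", None),
    ])
    def test_cases(self, value, dialect, expected):
        assert truncate_date(value, dialect) == expected


class TestEncodeApoe:
    @pytest.mark.parametrize("label,code", [
        ("2/2", 1), ("2/3", 2), ("2/4", 3), ("3/3", 4), ("3/4", 5),
        ("4/4", 6), ("4/3", 5), ("e4/e2", 3), ("E3/E3", 4),
    ])
    def test_codes(self, label, code):
        assert encode_apoe(label) == code

    @pytest.mark.parametrize("label", ["1/3", "5/5", "3", "3/4/4", ""])
    def test_invalid_alleles_are_missing(self, label):
        assert encode_apoe(label) is None


def _quantile_oracle(values):
    """Independent sort-and-split comparator (ties to lower quantile)."""
    import math

    x = np.asarray(values, dtype=float)
    xs = np.sort(x)
    n = len(xs)
    cuts = [xs[math.ceil(n / 4) - 1], xs[math.ceil(n / 2) - 1],
            xs[math.ceil(3 * n / 4) - 1]]
    out = []
    for v in x:
        code = 1
        for c in cuts:
            if v > c:
                code += 1
        out.append(code)
    return np.asarray(out)


class TestIncomeQuantiles:
    def test_uniform_distinct_input_splits_evenly(self):
        codes, warns = income_quantiles(list(range(1, 101)))
        assert not warns
        values, counts = np.unique(codes, return_counts=True)
        assert list(values) == [1, 2, 3, 4]
        assert list(counts) == [25, 25, 25, 25]

    def test_ties_go_to_lower_quantile(self):
        codes, warns = income_quantiles([7.0] * 20)
        assert not warns
        assert set(codes) == {1.0}

    def test_insufficient_data(self):
        codes, warns = income_quantiles([1, 2, None, ""])
        assert np.isnan(codes).all()
        assert warns == ["insufficient data for quantiles"]

    def test_against_sort_and_split_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.lognormal(10, 0.6, 1000)
        codes, _ = income_quantiles(values)
        np.testing.assert_array_equal(codes, _quantile_oracle(values))

    def test_banded_income_resolves_midpoints(self, rulesets):
        rule = rulesets["memento"].rules["income"]
        labels = list(rule.bands) * 3
        codes, warns = income_quantiles(labels, bands=rule.bands)
        assert not warns
        # band order is income order, so codes are monotone in band index
        mid = {lab: rule.bands[lab] for lab in rule.bands}
        by_income = sorted(zip(labels, codes), key=lambda t: mid[t[0]])
        assert list(c for _, c in by_income) == sorted(c for _, c in by_income)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6,
                              allow_nan=False), min_size=4, max_size=60))
    def test_monotone_property(self, values):
        codes, _ = income_quantiles(values)
        order = np.argsort(values, kind="stable")
        assert (np.diff(codes[order]) >= 0).all()
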