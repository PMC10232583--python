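"""End-to-end harmonisation of raw cohort tables with full provenance.

``harmonise_cohort`` turns one raw participant-level table into a
schema-conformant harmonised table: one column per variable that has a
data-producing rule for that cohort, one provenance entry per (cohort,
variable) processed, no rows lost or created anywhere.  Variables a cohort
does not collect are omitted rather than emitted as all-missing; a
``not_collected`` rule (e.g. ethnicity in the French cohort, which may not
legally be collected) yields a provenance entry recording 100% missingness
but no output column.

Missing data uses one convention everywhere: NA in memory, the empty field
in CSV.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .mapping import (
    KINDS_BY_STRATEGY,
    CohortRuleSet,
    MappingRule,
    _is_missing,
    _parse_number,
    apply_recode,
    encode_apoe,
    income_quantiles,
    infer_binary,
    lookup_text,
    truncate_date,
)
from .schema import Schema, VariableSpec
from .standardise import DEFAULT_SKEW_THRESHOLD, zscore_standardise
from .errors import StandardisationError

_CODE_DTYPE = "Int64"
_NUM_DTYPE = "Float64"


@dataclass(frozen=True)
class ProvenanceEntry:
    cohort_id: str
    variable_id: str
    rule_kind: str
    n_mapped: int
    n_missing: int
    warnings: tuple[str, ...] = ()
    transform: str | None = None


@dataclass
class ProvenanceLog:
    entries: list[ProvenanceEntry] = field(default_factory=list)

    def append(self, entry: ProvenanceEntry) -> None:
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def for_variable(self, variable_id: str) -> ProvenanceEntry:
        for e in self.entries:
            if e.variable_id == variable_id:
                return e
        raise KeyError(variable_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cohort_id": e.cohort_id, "variable_id": e.variable_id,
              "rule_kind": e.rule_kind, "n_mapped": e.n_mapped,
              "n_missing": e.n_missing, "transform": e.transform or "",
              "warnings": "; ".join(e.warnings)} for e in self.entries])


@dataclass
class HarmonisedTable:
    """Participant-level harmonised data for one cohort."""

    cohort_id: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def _column_dtype(spec: VariableSpec) -> str:
    if spec.is_categorical:
        return _CODE_DTYPE
    if spec.value_type in ("quantity", "count", "zscore"):
        return _NUM_DTYPE
    return "object"


def _finalise(values: list, spec: VariableSpec) -> pd.Series:
    dtype = _column_dtype(spec)
    if dtype == "object":
        cleaned = [None if _is_missing(v) else v for v in values]
        return pd.Series(cleaned, dtype="object", name=spec.variable_id)
    cleaned = [pd.NA if v is None or (isinstance(v, float) and np.isnan(v))
               else v for v in values]
    return pd.Series(cleaned, dtype=dtype, name=spec.variable_id)


def _summarise(reasons: Counter) -> tuple[str, ...]:
    return tuple(f"{reason} (n={k})" for reason, k in sorted(reasons.items()))


def harmonise_variable(raw: pd.DataFrame, spec: VariableSpec,
                       rule: MappingRule, cohort_id: str,
                       skew_threshold: float = DEFAULT_SKEW_THRESHOLD
                       ) -> tuple[pd.Series | None, ProvenanceEntry]:
    """Produce one harmonised column (or None for ``not_collected``).

    The rule kind must be consistent with the variable's applied strategy;
    a mismatch raises :class:`ConfigError` before any data is touched.
    A rule naming a source field absent from the raw table yields an
    all-missing column plus a warning — the pipeline never fails on one
    cohort's idiosyncrasy.
    """
    if rule.variable_id != spec.variable_id:
        raise ConfigError(
            f"rule targets {rule.variable_id!r}, spec is {spec.variable_id!r}")
    if rule.kind not in KINDS_BY_STRATEGY[spec.applied_strategy]:
        raise ConfigError(
            f"{spec.variable_id}: rule kind {rule.kind!r} inconsistent with "
            f"strategy {spec.applied_strategy}")
    n = len(raw)

    def entry(series: pd.Series | None, warnings: tuple[str, ...] = (),
              transform: str | None = None) -> tuple:
        n_missing = n if series is None else int(series.isna().sum())
        return series, ProvenanceEntry(
            cohort_id=cohort_id, variable_id=spec.variable_id,
            rule_kind=rule.kind, n_mapped=n - n_missing, n_missing=n_missing,
            warnings=warnings, transform=transform)

    if rule.kind == "not_collected":
        return entry(None, warnings=(rule.reason or "not collected",))

    missing_fields = [s for s in rule.sources if s not in raw.columns]
    if missing_fields:
        series = _finalise([None] * n, spec)
        return entry(series, warnings=(
            f"source field(s) {missing_fields} not in raw table",))

    reasons: Counter = Counter()
    values: list

    if rule.kind == "recode":
        col = raw[rule.source]
        values = []
        for v in col:
            code = apply_recode(v, rule)
            if code is None and not _is_missing(v):
                reasons["unmapped label"] += 1
            values.append(code)
    elif rule.kind in ("date_presence", "score_threshold", "proxy_condition",
                       "smoking_two_field"):
        values = []
        primary = rule.sources[0]
        for _, rec in raw.iterrows():
            out = infer_binary(rec, rule)
            if out is None and not _is_missing(rec.get(primary)):
                reasons["unparseable source value"] += 1
            values.append(out)
    elif rule.kind in ("quantile", "banded_quantile"):
        codes, warns = income_quantiles(
            raw[rule.source], bands=rule.bands)
        for w in warns:
            reasons[w] += max(1, int(np.isnan(codes).sum()))
        values = [None if np.isnan(c) else int(c) for c in codes]
    elif rule.kind == "standardise":
        numeric = np.asarray(
            [np.nan if (p := _parse_number(v)) is None else p
             for v in raw[rule.source]], dtype=float)
        try:
            result = zscore_standardise(numeric, skew_threshold=skew_threshold)
        except StandardisationError as exc:
            series = _finalise([None] * n, spec)
            return entry(series, warnings=(str(exc),))
        series = _finalise(list(result.z_values), spec)
        return entry(series, warnings=_summarise(reasons),
                     transform=result.transform_applied)
    elif rule.kind == "date_truncate":
        values = []
        for v in raw[rule.source]:
            out = truncate_date(v, rule.dialect)
            if out is None and not _is_missing(v):
                reasons["partial or invalid date"] += 1
            values.append(out)
    elif rule.kind == "text_lookup":
        values = []
        for v in raw[rule.source]:
            out = lookup_text(v, rule.lookup)
            if out is None and not _is_missing(v):
                reasons["no keyword match"] += 1
            values.append(out)
    elif rule.kind == "apoe":
        values = []
        for v in raw[rule.source]:
            out = encode_apoe(v)
            if out is None and not _is_missing(v):
                reasons["unrecognised genotype"] += 1
            values.append(out)
    elif rule.kind == "units_or_other":
        # numeric units per week where quantifiable, sentinel "other" where
        # consumption is present but not quantifiable
        values = []
        for v in raw[rule.source]:
            if _is_missing(v):
                values.append(None)
            elif (num := _parse_number(v)) is not None:
                values.append(num)
            elif str(v).strip().lower() == "other":
                values.append(None)
                reasons["present but not quantifiable (other)"] += 1
            else:
                values.append(None)
                reasons["unparseable quantity"] += 1
    elif rule.kind in ("identity", "unit_convert"):
        factor = rule.factor if rule.kind == "unit_convert" else 1.0
        offset = rule.offset if rule.kind == "unit_convert" else 0.0
        values = []
        if spec.is_categorical:
            codes = spec.codebook.codes
            for v in raw[rule.source]:
                num = _parse_number(v)
                if num is None:
                    if not _is_missing(v):
                        reasons["unparseable code"] += 1
                    values.append(None)
                elif int(num) in codes and num == int(num):
                    values.append(int(num))
                else:
                    reasons["code outside codebook"] += 1
                    values.append(None)
        elif spec.value_type == "text":
            values = [None if _is_missing(v) else str(v)
                      for v in raw[rule.source]]
        else:
            for v in raw[rule.source]:
                num = _parse_number(v)
                if num is None and not _is_missing(v):
                    reasons["unparseable number"] += 1
                values.append(None if num is None else num * factor + offset)
    else:
        raise ConfigError(f"{spec.variable_id}: unknown rule kind {rule.kind!r}")

    series = _finalise(values, spec)
    if spec.is_categorical:
        present = set(series.dropna().astype(int))
        bad = present - spec.codebook.codes
        if bad:  # codebook closure: must hold on every run
            raise ValidationError(
                f"{spec.variable_id}: harmonised codes {sorted(bad)} outside "
                "codebook")
    return entry(series, warnings=_summarise(reasons))


def harmonise_cohort(raw: pd.DataFrame, schema: Schema,
                     ruleset: CohortRuleSet,
                     skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
                     per_variable_thresholds: Mapping[str, float] | None = None
                     ) -> tuple[HarmonisedTable, ProvenanceLog]:
    """Harmonise one cohort's raw table under its rule set.

    Output columns follow schema order and cover exactly the variables with
    data-producing rules for this cohort.  Row count is preserved.
    """
    per_variable_thresholds = dict(per_variable_thresholds or {})
    log = ProvenanceLog()
    columns: dict[str, pd.Series] = {}
    for spec in schema:
        rule = ruleset.rules.get(spec.variable_id)
        if rule is None:
            continue
        thr = per_variable_thresholds.get(spec.variable_id, skew_threshold)
        series, entry = harmonise_variable(raw, spec, rule,
                                           ruleset.cohort_id,
                                           skew_threshold=thr)
        log.append(entry)
        if series is not None:
            columns[spec.variable_id] = series
    if columns:
        data = pd.DataFrame(columns)
    else:
        data = pd.DataFrame(index=range(len(raw)))
    if len(data) != len(raw):
        raise ValidationError("row count changed during harmonisation")
    return HarmonisedTable(cohort_id=ruleset.cohort_id, data=data), log


def sidecar_dictionary(table: HarmonisedTable, schema: Schema,
                       provenance: ProvenanceLog | None = None) -> dict:
    """JSON-ready data dictionary for a harmonised table."""
    transforms = {}
    if provenance is not None:
        transforms = {e.variable_id: e.transform for e in provenance
                      if e.transform}
    cols = []
    for vid in table.columns:
        spec = schema[vid]
        col: dict[str, Any] = {
            "variable_id": vid, "name": spec.display_name,
            "theme": spec.theme.number, "theme_name": spec.theme.name,
            "strategy": spec.applied_strategy,
            "value_type": spec.value_type,
        }
        if spec.codebook is not None:
            col["codebook"] = {str(c): lab
                               for c, lab in spec.codebook.entries}
        if spec.units is not None:
            col["units"] = spec.units
        if vid in transforms:
            col["transform"] = transforms[vid]
        cols.append(col)
    return {"cohort_id": table.cohort_id, "n_rows": len(table),
            "columns": cols}


def write_harmonised(table: HarmonisedTable, path: str | Path,
                     schema: Schema,
                     provenance: ProvenanceLog | None = None) -> Path:
    """Write the harmonised CSV plus a ``.dict.json`` sidecar dictionary.

    Missing cells are empty fields.  Returns the sidecar path.
    """
    path = Path(path)
    table.data.to_csv(path, index=False, na_rep="")
    sidecar = path.with_suffix(".dict.json")
    with open(sidecar, "w") as fh:
        json.dump(sidecar_dictionary(table, schema, provenance), fh, indent=1)
        fh.write("\n")
    return sidecar


def read_harmonised(path: str | Path, schema: Schema,
                    cohort_id: str | None = None) -> HarmonisedTable:
    """Read a harmonised CSV back with schema-driven dtypes."""
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns
    dtypes = {}
    for vid in header:
        if vid in schema:
            dtypes[vid] = _column_dtype(schema[vid])
    data = pd.read_csv(path, dtype=dtypes, keep_default_na=True)
    for vid in header:
        if vid in schema and _column_dtype(schema[vid]) == "object":
            col = data[vid]
            data[vid] = col.astype("object").where(col.notna(), None)
    if cohort_id is None:
        sidecar = path.with_suffix(".dict.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                cohort_id = json.load(fh).get("cohort_id", path.stem)
        else:
            cohort_id = path.stem
    return HarmonisedTable(cohort_id=cohort_id, data=data)
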