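"""Per-cohort mapping rules and the value-level harmonisation operations.

A mapping file holds one rule per harmonised variable available in a cohort.
Rule kinds fall into the three harmonisation strategies:

* simple calibration — ``identity``, ``unit_convert``, ``date_truncate``,
  ``text_lookup``, ``units_or_other``, ``apoe`` and 1:1 ``recode`` maps;
* algorithmic transformation — ``recode`` tables, binary inference
  (``date_presence``, ``score_threshold``, ``proxy_condition``,
  ``smoking_two_field``), ``quantile`` / ``banded_quantile`` income coding,
  and the ``not_collected`` annotation;
* standardisation — ``standardise`` (z-scores, handled by
  :mod:`csurv.standardise`).

Value-level operations never raise on malformed data values: unmapped labels,
partial dates or unparseable scores harmonise to missing, and the pipeline
records the reason in provenance.
"""
from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

from .errors import (
    CodebookViolationError,
    DuplicateRuleError,
    MappingError,
    UnknownVariableError,
    ValidationError,
)
from .schema import Schema, VariableSpec

COHORT_IDS = ("airwave", "elsa", "genscot", "memento")

#: rule kinds permitted under each applied strategy
KINDS_BY_STRATEGY = {
    "SC": {"identity", "unit_convert", "date_truncate", "text_lookup",
           "units_or_other", "apoe", "recode"},
    "AT": {"recode", "date_presence", "score_threshold", "proxy_condition",
           "smoking_two_field", "quantile", "banded_quantile",
           "not_collected"},
    "S": {"standardise"},
}

MISSING = None  # single in-memory missing marker; empty field in CSV


@dataclass(frozen=True)
class CohortProfile:
    cohort_id: str
    display_name: str
    currency: str
    notes: str = ""


@dataclass(frozen=True)
class MappingRule:
    """One instruction for producing one harmonised variable in one cohort.

    ``sources`` lists every raw field the rule reads (empty for
    ``not_collected``).
    """

    variable_id: str
    kind: str
    source: str | None = None
    map: Mapping[str, int] | None = None          # recode
    unmapped_policy: str = "missing"
    threshold: float | None = None                # score_threshold
    direction: str = "ge"
    trigger: str | None = None                    # proxy_condition
    factor: float | None = None                   # unit_convert
    offset: float = 0.0
    dialect: str = "iso"                          # date_truncate
    lookup: Mapping[str, int] | None = None       # text_lookup
    bands: Mapping[str, float] | None = None      # banded_quantile
    ever_source: str | None = None                # smoking_two_field
    current_source: str | None = None
    reason: str | None = None                     # not_collected

    @property
    def sources(self) -> tuple[str, ...]:
        if self.kind == "smoking_two_field":
            return (self.ever_source, self.current_source)
        if self.kind == "not_collected":
            return ()
        return (self.source,)

    def validate(self, spec: VariableSpec) -> None:
        if self.kind == "recode":
            if not self.map:
                raise MappingError(f"{self.variable_id}: empty recode map")
            labels = list(self.map)
            if len(set(labels)) != len(labels):
                raise MappingError(
                    f"{self.variable_id}: duplicate source labels")
            if spec.codebook is not None:
                bad = sorted(set(self.map.values()) - spec.codebook.codes)
                if bad:
                    raise CodebookViolationError(
                        f"{self.variable_id}: recode targets {bad} outside "
                        f"codebook codes {sorted(spec.codebook.codes)}")
        if self.kind == "unit_convert":
            if not self.factor or not math.isfinite(self.factor):
                raise MappingError(
                    f"{self.variable_id}: unit_convert factor must be finite "
                    "and nonzero")
        if self.kind == "score_threshold" and self.threshold is None:
            raise MappingError(f"{self.variable_id}: missing threshold")
        if self.kind == "score_threshold" and self.direction not in ("ge", "le"):
            raise MappingError(
                f"{self.variable_id}: direction must be 'ge' or 'le'")
        if self.kind == "proxy_condition" and self.trigger is None:
            raise MappingError(f"{self.variable_id}: missing trigger label")


@dataclass
class CohortRuleSet:
    profile: CohortProfile
    rules: dict[str, MappingRule] = field(default_factory=dict)

    @property
    def cohort_id(self) -> str:
        return self.profile.cohort_id

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules.values())

    def data_rules(self) -> dict[str, MappingRule]:
        """Rules that actually read raw data (drops ``not_collected``)."""
        return {vid: r for vid, r in self.rules.items()
                if r.kind != "not_collected"}


class _DupKeyLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys (duplicate rules)."""


def _construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise DuplicateRuleError(f"duplicate rule for {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_DupKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping)


def _rule_from_dict(variable_id: str, raw: Mapping[str, Any]) -> MappingRule:
    known = {"kind", "source", "map", "unmapped_policy", "threshold",
             "direction", "trigger", "factor", "offset", "dialect", "lookup",
             "bands", "ever_source", "current_source", "reason"}
    extra = set(raw) - known
    if extra:
        raise MappingError(f"{variable_id}: unknown rule fields {sorted(extra)}")
    return MappingRule(variable_id=variable_id, **raw)


def load_mappings(path: str | Path, schema: Schema) -> CohortRuleSet:
    """Load one cohort's mapping file and validate it against the schema.

    Raises :class:`UnknownVariableError` for rules naming ids absent from the
    schema, :class:`DuplicateRuleError` for repeated (cohort, variable)
    pairs, and :class:`CodebookViolationError` for recode targets outside the
    target codebook.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.load(fh, Loader=_DupKeyLoader)
    if not isinstance(doc, dict) or "cohort_id" not in doc:
        raise MappingError(f"{path}: not a cohort mapping document")
    profile = CohortProfile(
        cohort_id=str(doc["cohort_id"]),
        display_name=str(doc.get("display_name", doc["cohort_id"])),
        currency=str(doc.get("currency", "")),
        notes=str(doc.get("notes", "")),
    )
    ruleset = CohortRuleSet(profile)
    for vid, raw in (doc.get("rules") or {}).items():
        if vid not in schema:
            raise UnknownVariableError(
                f"{profile.cohort_id}: rule for unknown variable {vid!r}")
        rule = _rule_from_dict(vid, raw)
        rule.validate(schema[vid])
        ruleset.rules[vid] = rule
    return ruleset


def packaged_mapping_path(cohort_id: str) -> Path:
    if cohort_id not in COHORT_IDS:
        raise ValidationError(f"unknown cohort id {cohort_id!r}; "
                              f"packaged cohorts are {COHORT_IDS}")
    return Path(importlib.resources.files("csurv") / "data"
                / f"mappings_{cohort_id}.yaml")


def load_packaged_mappings(schema: Schema) -> dict[str, CohortRuleSet]:
    """Rule sets for the four packaged cohort profiles."""
    return {c: load_mappings(packaged_mapping_path(c), schema)
            for c in COHORT_IDS}


# ---------------------------------------------------------------------------
# value-level operations
# ---------------------------------------------------------------------------

def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def apply_recode(value: Any, rule: MappingRule) -> int | None:
    """Map one source label through a recode table.

    Unmapped labels follow ``unmapped_policy`` (default: missing) and never
    raise.  Matching is exact first, then case-insensitive on stripped text.
    """
    if _is_missing(value):
        return MISSING
    label = str(value).strip()
    if label in rule.map:
        return rule.map[label]
    low = label.lower()
    for k, code in rule.map.items():
        if k.strip().lower() == low:
            return code
    if rule.unmapped_policy == "missing":
        return MISSING
    raise MappingError(
        f"{rule.variable_id}: unsupported unmapped_policy "
        f"{rule.unmapped_policy!r}")


def _parse_number(value: Any) -> float | None:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def infer_binary(record: Mapping[str, Any], rule: MappingRule) -> int | None:
    """Infer a yes/no (1/0) code for one participant record.

    ``date_presence``: 1 iff the source field holds a parseable date
    (absence of any value codes 0 — the condition was never recorded).
    ``score_threshold``: compare a numeric symptom score against the cut-off
    in the stated direction; unparseable scores are missing.
    ``proxy_condition``: 1 iff the proxy field equals its trigger label
    (case-insensitive); 0 for any other recorded answer.
    """
    if rule.kind == "date_presence":
        value = record.get(rule.source)
        if _is_missing(value):
            return 0
        return 1 if truncate_date(value, rule.dialect) is not None else MISSING
    if rule.kind == "score_threshold":
        value = record.get(rule.source)
        if _is_missing(value):
            return MISSING
        score = _parse_number(value)
        if score is None:
            return MISSING
        if rule.direction == "ge":
            return int(score >= rule.threshold)
        return int(score <= rule.threshold)
    if rule.kind == "proxy_condition":
        value = record.get(rule.source)
        if _is_missing(value):
            return MISSING
        return int(str(value).strip().lower() == rule.trigger.strip().lower())
    if rule.kind == "smoking_two_field":
        return smoking_from_two_fields(record.get(rule.ever_source),
                                       record.get(rule.current_source))
    raise MappingError(f"{rule.variable_id}: {rule.kind} is not an "
                       "inference rule")


def smoking_from_two_fields(ever: Any, current: Any) -> int | None:
    """never/past/current (0/1/2) from 'ever smoked' + 'currently smoking'.

    When only 'ever smoked: yes' is known the participant codes as a past
    smoker unless the secondary current-smoking field says yes.
    """
    if _is_missing(ever):
        return MISSING
    ever_yes = str(ever).strip().lower() in ("yes", "y", "1", "true")
    if not ever_yes:
        return 0
    if _is_missing(current):
        return 1
    current_yes = str(current).strip().lower() in ("yes", "y", "1", "true")
    return 2 if current_yes else 1


_ISO_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})([T ].*)?$")
_UK_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})( .*)?$")


def truncate_date(value: Any, dialect: str = "iso") -> str | None:
    """Truncate a date or datetime to ISO ``yyyy-mm-dd``.

    ``dialect`` names the documented input convention: ``iso``
    (``yyyy-mm-dd``, optionally with a time part) or ``uk``
    (``dd/mm/yyyy``).  Partial (e.g. year-only) or calendar-invalid input
    harmonises to missing rather than being imputed.
    """
    if _is_missing(value):
        return MISSING
    text = str(value).strip()
    if dialect == "uk":
        m = _UK_RE.match(text)
        if m is None:
            return MISSING
        day, month, year = int(m.group(1)), int(m.group(2)), int(m.group(3))
    else:
        m = _ISO_RE.match(text)
        if m is None:
            return MISSING
        year, month, day = int(m.group(1)), int(m.group(2)), int(m.group(3))
    try:
        return datetime(year, month, day).strftime("%Y-%m-%d")
    except ValueError:
        return MISSING


_APOE_CODES = {("2", "2"): 1, ("2", "3"): 2, ("2", "4"): 3,
               ("3", "3"): 4, ("3", "4"): 5, ("4", "4"): 6}


def encode_apoe(genotype: Any) -> int | None:
    """Code an APOE genotype label 1-6 over unordered e2/e3/e4 allele pairs.

    Accepts e.g. ``"3/4"``, ``"e4/e3"``, ``"E2/E2"``; order-insensitive.
    Alleles outside {2, 3, 4} harmonise to missing.
    """
    if _is_missing(genotype):
        return MISSING
    text = str(genotype).strip().lower().replace("ε", "").replace("e", "")
    parts = [p.strip() for p in re.split(r"[/|,;]", text) if p.strip()]
    if len(parts) != 2:
        return MISSING
    pair = tuple(sorted(parts))
    return _APOE_CODES.get(pair, MISSING)


def resolve_bands(values: Iterable[Any],
                  bands: Mapping[str, float]) -> np.ndarray:
    """Resolve banded income labels to their numeric midpoints (NaN unmapped)."""
    out = []
    for v in values:
        if _is_missing(v):
            out.append(np.nan)
            continue
        label = str(v).strip()
        if label in bands:
            out.append(float(bands[label]))
        else:
            num = _parse_number(v)
            out.append(np.nan if num is None else num)
    return np.asarray(out, dtype=float)


def income_quantiles(values: Iterable[Any],
                     bands: Mapping[str, float] | None = None
                     ) -> tuple[np.ndarray, list[str]]:
    """Within-cohort four-quantile coding of income (codes 1-4).

    Banded incomes are first resolved to band midpoints.  Boundaries sit at
    the order statistics of ranks ``ceil(n/4)``, ``ceil(n/2)`` and
    ``ceil(3n/4)`` of the non-missing values, with ties assigned to the
    lower quantile, so the coding is monotone in income.

    Returns ``(codes, warnings)`` where codes is a float array with NaN for
    missing.  Fewer than 4 non-missing values yields all-missing plus a
    warning.
    """
    if bands is not None:
        x = resolve_bands(values, bands)
    else:
        x = np.asarray([_parse_number(v) if not _is_missing(v) else np.nan
                        for v in values], dtype=float)
    codes = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 4:
        return codes, ["insufficient data for quantiles"]
    xs = np.sort(x[ok])
    q1 = xs[math.ceil(n / 4) - 1]
    q2 = xs[math.ceil(n / 2) - 1]
    q3 = xs[math.ceil(3 * n / 4) - 1]
    v = x[ok]
    c = np.where(v <= q1, 1, np.where(v <= q2, 2, np.where(v <= q3, 3, 4)))
    codes[ok] = c
    return codes, []


def lookup_text(value: Any, lookup: Mapping[str, int]) -> int | None:
    """Keyword lookup stub for free-text fields (e.g. cause of death).

    Case-insensitive substring match, longest keyword first; no match is
    missing.
    """
    if _is_missing(value):
        return MISSING
    text = str(value).lower()
    for key in sorted(lookup, key=len, reverse=True):
        if key.lower() in text:
            return lookup[key]
    return MISSING
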