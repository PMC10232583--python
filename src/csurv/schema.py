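"""The C-Surv-structured target schema: themes, codebooks and variable specs.

The C-Surv data model organises cohort variables into 18 top-level *themes*
(Administration, Sociodemographic, ..., Molecular).  A harmonisation schema is
an ordered collection of :class:`VariableSpec` records, each carrying the
theme, the harmonisation strategy and — depending on the variable type —
either a :class:`Codebook` (categorical targets) or measurement units
(quantitative targets).

Two strategy tags are stored per variable.  ``declared_strategy`` is the tag
printed in the core variable list; ``applied_strategy`` is the classification
under which the rule was actually executed against cohort data (many yes/no
items declared as simple calibration are in practice inferred
algorithmically, and several questionnaire scale scores declared as
algorithmic transformations reduce to direct mapping).  Tallies can be taken
over either tag.
"""
from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .errors import (
    CodebookError,
    DuplicateVariableError,
    EmptySchemaError,
    SchemaParseError,
    UnknownStrategyError,
    UnknownThemeError,
    ValidationError,
)

STRATEGIES = ("SC", "AT", "S")

#: Variable types a spec may declare.
VALUE_TYPES = ("text", "date", "binary", "categorical", "quantity", "count",
               "zscore")

_PACKAGED_SCHEMA = "csurv_core_124.yaml"


@dataclass(frozen=True)
class CSurvTheme:
    """One of the 18 C-Surv level-1 data themes."""

    number: int
    name: str

    def __post_init__(self) -> None:
        if not 1 <= self.number <= 18:
            raise UnknownThemeError(
                f"theme number {self.number} outside 1-18")
        if not self.name:
            raise ValidationError("theme name must be non-empty")


@dataclass(frozen=True)
class Codebook:
    """Ordered (code, label) pairs for a categorical target variable."""

    entries: tuple[tuple[int, str], ...]
    missing_policy: str = "empty cell"

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise CodebookError(f"duplicate codes in codebook: {codes}")
        if any(not label for _, label in self.entries):
            raise CodebookError("codebook labels must be non-empty")

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(c for c, _ in self.entries)

    def label_for(self, code: int) -> str:
        for c, label in self.entries:
            if c == code:
                return label
        raise KeyError(code)

    def code_for(self, label: str) -> int | None:
        """Exact-then-case-insensitive label lookup; None when absent."""
        for c, lab in self.entries:
            if lab == label:
                return c
        low = label.strip().lower()
        for c, lab in self.entries:
            if lab.lower() == low:
                return c
        return None

    def as_dict(self) -> dict[int, str]:
        return dict(self.entries)


@dataclass(frozen=True)
class VariableSpec:
    """One row of the core variable list."""

    variable_id: str
    display_name: str
    row_number: int
    theme: CSurvTheme
    declared_strategy: str
    applied_strategy: str
    value_type: str
    rule_text: str
    codebook: Codebook | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        for tag in (self.declared_strategy, self.applied_strategy):
            if tag not in STRATEGIES:
                raise UnknownStrategyError(
                    f"{self.variable_id}: unknown strategy {tag!r} "
                    f"(expected one of {STRATEGIES})")
        if self.value_type not in VALUE_TYPES:
            raise ValidationError(
                f"{self.variable_id}: unknown value_type {self.value_type!r}")
        if not 1 <= self.row_number <= 124:
            raise ValidationError(
                f"{self.variable_id}: row number {self.row_number} "
                "outside 1-124")
        if self.value_type in ("binary", "categorical") and (
                self.codebook is None or not self.codebook.entries):
            raise ValidationError(
                f"{self.variable_id}: categorical variable without codebook")
        if self.value_type == "quantity" and not self.units:
            raise ValidationError(
                f"{self.variable_id}: quantitative variable without units")
        if self.value_type == "binary":
            if set(self.codebook.entries) != {(1, "yes"), (0, "no")}:
                raise CodebookError(
                    f"{self.variable_id}: binary codebook must be exactly "
                    "1 yes / 0 no")

    @property
    def strategy(self) -> str:
        """The strategy under which the variable is harmonised in practice."""
        return self.applied_strategy

    @property
    def is_categorical(self) -> bool:
        return self.value_type in ("binary", "categorical")


class Schema:
    """Ordered, validated collection of :class:`VariableSpec`.

    Iteration preserves core-list row order.  ``schema[variable_id]`` returns
    the spec; ``variable_id in schema`` tests membership.
    """

    def __init__(self, themes: Iterable[CSurvTheme],
                 variables: Iterable[VariableSpec],
                 name: str = "schema") -> None:
        self.name = name
        self.themes: dict[int, CSurvTheme] = {}
        for t in themes:
            if t.number in self.themes:
                raise ValidationError(f"duplicate theme number {t.number}")
            self.themes[t.number] = t
        self._specs: dict[str, VariableSpec] = {}
        for spec in variables:
            if spec.variable_id in self._specs:
                raise DuplicateVariableError(
                    f"duplicate variable_id {spec.variable_id!r}")
            if spec.theme.number not in self.themes:
                raise UnknownThemeError(
                    f"{spec.variable_id}: theme {spec.theme.number} not in "
                    "theme table")
            self._specs[spec.variable_id] = spec
        if not self._specs:
            raise EmptySchemaError("no variables defined")
        # S is reserved for the cognitive performance scores (rows 69-74)
        for spec in self._specs.values():
            if "S" in (spec.declared_strategy, spec.applied_strategy) \
                    and not 69 <= spec.row_number <= 74:
                raise UnknownStrategyError(
                    f"{spec.variable_id}: strategy S outside the cognitive "
                    "performance block (rows 69-74)")

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self._specs.values())

    def __contains__(self, variable_id: str) -> bool:
        return variable_id in self._specs

    def __getitem__(self, variable_id: str) -> VariableSpec:
        return self._specs[variable_id]

    @property
    def variable_ids(self) -> list[str]:
        return list(self._specs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Schema):
            return NotImplemented
        return (list(self.themes.items()) == list(other.themes.items())
                and list(self._specs.items()) == list(other._specs.items()))


def _parse_variable(raw: Mapping, themes: Mapping[int, CSurvTheme]) -> VariableSpec:
    try:
        theme_no = int(raw["theme"])
    except KeyError as exc:
        raise SchemaParseError(f"variable entry missing field {exc}") from exc
    theme = themes.get(theme_no)
    if theme is None:
        raise UnknownThemeError(
            f"{raw.get('id', '?')}: unknown theme number {theme_no}")
    codebook = None
    if "codebook" in raw:
        codebook = Codebook(tuple((int(c), str(lab))
                                  for c, lab in raw["codebook"].items()))
    try:
        return VariableSpec(
            variable_id=str(raw["id"]),
            display_name=str(raw["name"]),
            row_number=int(raw["row"]),
            theme=theme,
            declared_strategy=str(raw["declared_strategy"]),
            applied_strategy=str(raw.get("applied_strategy",
                                         raw["declared_strategy"])),
            value_type=str(raw["value_type"]),
            rule_text=str(raw.get("rule", "")),
            codebook=codebook,
            units=raw.get("units"),
        )
    except KeyError as exc:
        raise SchemaParseError(
            f"variable entry missing field {exc}") from exc


def load_schema(path: str | Path) -> Schema:
    """Load and validate a schema file (YAML or JSON).

    Raises a distinct error per failure mode: :class:`SchemaParseError`,
    :class:`EmptySchemaError`, :class:`DuplicateVariableError`,
    :class:`UnknownThemeError`, :class:`UnknownStrategyError`.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise SchemaParseError(f"cannot parse schema file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaParseError(f"{path}: schema document must be a mapping")
    themes = {}
    for t in doc.get("themes", []):
        themes[int(t["number"])] = CSurvTheme(int(t["number"]), str(t["name"]))
    raw_vars = doc.get("variables")
    if not raw_vars:
        raise EmptySchemaError("no variables defined")
    specs = [_parse_variable(raw, themes) for raw in raw_vars]
    return Schema(themes.values(), specs,
                  name=str(doc.get("schema_name", path.stem)))


def save_schema(schema: Schema, path: str | Path) -> None:
    """Write a schema back to YAML; ``load_schema`` round-trips it."""
    doc = {
        "schema_name": schema.name,
        "themes": [{"number": t.number, "name": t.name}
                   for t in schema.themes.values()],
        "variables": [],
    }
    for spec in schema:
        entry: dict = {
            "id": spec.variable_id, "name": spec.display_name,
            "row": spec.row_number, "theme": spec.theme.number,
            "declared_strategy": spec.declared_strategy,
            "applied_strategy": spec.applied_strategy,
            "value_type": spec.value_type, "rule": spec.rule_text,
        }
        if spec.codebook is not None:
            entry["codebook"] = spec.codebook.as_dict()
        if spec.units is not None:
            entry["units"] = spec.units
        doc["variables"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True, width=100)


def packaged_schema_path() -> Path:
    """Path of the packaged 124-variable core schema."""
    return Path(importlib.resources.files("csurv") / "data" / _PACKAGED_SCHEMA)


def load_packaged_schema() -> Schema:
    """The packaged 124-variable neurodegeneration core schema."""
    return load_schema(packaged_schema_path())


def themes_covered(specs: Iterable[VariableSpec]) -> set[int]:
    """Distinct theme numbers represented by ``specs`` (empty set for none)."""
    return {spec.theme.number for spec in specs}


def strategy_tally(specs: Iterable[VariableSpec],
                   restrict_to: set[str] | None = None,
                   which: str = "applied") -> dict[str, int]:
    """Count variables per harmonisation strategy.

    Parameters
    ----------
    specs:
        Variable specs to tally.
    restrict_to:
        Optional subset of variable ids (e.g. the ids represented in at
        least one cohort).  Unknown ids raise ``ValidationError``.
    which:
        ``"applied"`` (default) or ``"declared"`` — which strategy tag to
        count.

    Returns a dict with all three strategy keys; counts sum to the number of
    (restricted) specs.
    """
    specs = list(specs)
    if which not in ("applied", "declared"):
        raise ValueError(f"which must be 'applied' or 'declared', got {which!r}")
    if restrict_to is not None:
        known = {s.variable_id for s in specs}
        unknown = sorted(set(restrict_to) - known)
        if unknown:
            raise ValidationError(
                f"restrict_to contains unknown variable ids: {unknown}")
        specs = [s for s in specs if s.variable_id in restrict_to]
    attr = f"{which}_strategy"
    counts = Counter(getattr(s, attr) for s in specs)
    return {tag: counts.get(tag, 0) for tag in STRATEGIES}
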