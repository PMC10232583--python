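"""Synthetic raw cohorts with the native codings the mapping rules expect.

Four cohort-style tables are generated directly from the packaged mapping
files, so each table carries exactly the source fields, label vocabularies
and measurement quirks its rule set must handle: NVQ/Highers/Baccalauréat
education labels, monthly-euro income bands, two-field smoking questions,
diagnosis-date fields, a right-skewed choice-reaction-time distribution
(log-normal, so the log_e standardisation branch triggers), and a
structurally absent ethnicity field in the French cohort.

Categorical fields draw multinomially from the rule's own vocabulary;
quantitative fields are normal with plausible location/scale; 5% of values
are missing by default.  One seed drives everything through independent
per-cohort substreams keyed by cohort id, so adding a cohort never shifts
another cohort's draws.  Variables are emulated cross-sectionally (no
longitudinal waves) and independently of each other: no epidemiological
correlation structure is simulated.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mapping import (
    COHORT_IDS,
    CohortRuleSet,
    MappingRule,
    load_packaged_mappings,
)
from .schema import Schema, load_packaged_schema

DEFAULT_N = 500
DEFAULT_SEED = 7
DEFAULT_MISSING_RATE = 0.05

_ID_PREFIX = {"airwave": "AIR", "elsa": "ELS", "genscot": "GEN",
              "memento": "MEM"}

# location/scale (and optional lower clip, rounding decimals) for numeric
# source fields; anything not listed falls back to (50, 15)
_NUMERIC_PROFILES: dict[str, tuple] = {
    "age": (65, 8, 40, 0),
    "years_education": (13, 3, 5, 0),
    "height": (170, 10, 140, 1),
    "height_m": (1.70, 0.10, 1.40, 2),
    "weight": (76, 14, 40, 1),
    "bmi": (26.5, 4.2, 15, 1),
    "grip_strength": (32, 10, 5, 1),
    "gait_speed": (1.2, 0.25, 0.3, 2),
    "systolic_bp": (132, 17, 80, 0),
    "diastolic_bp": (80, 10, 45, 0),
    "sleep_hours": (7.1, 1.2, 3, 1),
    "medications": (3, 2, 0, 0),
    "ghq_score": (12, 5, 0, 0),
    "depression_score": (8, 4, 0, 0),
    "epq_neuroticism": (11, 5, 0, 0),
    "epq_extraversion": (13, 4, 0, 0),
    "life_satisfaction_score": (25, 6, 5, 0),
    "job_satisfaction_score": (15, 4, 3, 0),
    "quality_of_life_score": (38, 8, 0, 0),
    "mmse_score": (27, 2.5, 10, 0),
    "cdr_total_score": (0.5, 0.5, 0, 1),
    "adl_score": (5.3, 0.9, 0, 0),
    "iadl_score": (7.2, 1.1, 0, 0),
    "number_of_house_occupants": (2.4, 1.2, 1, 0),
    "number_of_rooms": (4.8, 1.6, 1, 0),
    "social_contacts_per_month": (10, 6, 0, 0),
    "social_media_sites_used": (1.5, 1.2, 0, 0),
    "social_media_use_daily": (1.0, 1.0, 0, 0),
    "white_matter_volume": (480000, 50000, 300000, 0),
    "grey_matter_volume": (620000, 55000, 400000, 0),
    "left_hippocampal_volume": (3700, 450, 2000, 0),
    "right_hippocampal_volume": (3800, 450, 2000, 0),
    "wm_hyperintensities": (4500, 2500, 0, 0),
    "amyloid_pib_suvr": (1.3, 0.3, 0.7, 2),
    "haemoglobin": (14.2, 1.3, 9, 1),
    "white_cell_count": (6.8, 1.8, 2, 1),
    "rbc_count": (4.7, 0.5, 3, 2),
    "total_cholesterol": (205, 38, 100, 0),
    "hdl_cholesterol": (55, 14, 20, 0),
    "creatinine": (0.9, 0.2, 0.4, 2),
    "glucose": (98, 18, 60, 0),
    "crp": (2.5, 2.0, 0, 2),
    "cortisol_decrease": (8.5, 3.0, 0, 2),
    "abeta_42_plasma": (38, 8, 10, 1),
    "abeta_40_plasma": (210, 40, 80, 1),
    "abeta_42_csf": (800, 250, 200, 0),
    "abeta_40_csf": (9500, 2500, 3000, 0),
    "total_tau": (320, 120, 80, 0),
    "p_tau": (45, 18, 10, 0),
    "annual_income_gbp": None,   # log-normal, handled specially
    "crt_msec": None,            # log-normal, handled specially
    "numeracy_score": (18, 5, 0, 0),
}

_APOE_FREQ = {"2": 0.08, "3": 0.77, "4": 0.15}


@dataclass(frozen=True)
class CohortGeneratorProfile:
    """Stated world for one synthetic cohort."""

    cohort_id: str
    n_participants: int = DEFAULT_N
    seed: int = DEFAULT_SEED
    missing_rate: float = DEFAULT_MISSING_RATE

    def __post_init__(self) -> None:
        if self.cohort_id not in COHORT_IDS:
            raise ValidationError(f"unknown cohort_id {self.cohort_id!r}")
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")


def _cohort_rng(seed: int, cohort_id: str) -> np.random.Generator:
    # independent substream per cohort: spawn key from a stable hash of the id
    key = zlib.crc32(cohort_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _dates(rng, n, start_year, end_year, dialect, with_time=False):
    years = rng.integers(start_year, end_year + 1, n)
    months = rng.integers(1, 13, n)
    days = rng.integers(1, 29, n)  # stay calendar-valid in every month
    out = []
    for y, m, d in zip(years, months, days):
        if dialect == "uk":
            out.append(f"{d:02d}/{m:02d}/{y}")
        elif with_time:
            out.append(f"{y}-{m:02d}-{d:02d}T12:00:00")
        else:
            out.append(f"{y}-{m:02d}-{d:02d}")
    return out


def _numeric(rng, n, source):
    prof = _NUMERIC_PROFILES.get(source, (50, 15, 0, 1))
    loc, scale, lo, dec = prof
    x = np.clip(rng.normal(loc, scale, n), lo, None)
    return np.round(x, dec) if dec else np.round(x).astype(int)


def _generate_source(rng, n, source: str, rule: MappingRule,
                     dialect: str, cohort_id: str,
                     proxy_vocab: Mapping[str, list[str]],
                     value_type: str = "quantity") -> list:
    kind = rule.kind
    if source == "cohort_id":
        return [f"{_ID_PREFIX[cohort_id]}-{i:05d}" for i in range(1, n + 1)]
    if kind == "recode":
        labels = list(rule.map)
        return list(rng.choice(labels, n))
    if kind == "smoking_two_field":
        ever = rng.choice(["Yes", "No"], n, p=[0.55, 0.45])
        if source == rule.ever_source:
            return list(ever)
        current = np.where((ever == "Yes") & (rng.random(n) < 0.4),
                           "Yes", "No")
        return list(current)
    if kind == "proxy_condition":
        vocab = proxy_vocab[source]
        probs = np.full(len(vocab), 0.75 / max(1, len(vocab) - 1))
        probs[-1] = 0.25  # last entry is a trigger; keep triggers plausible
        return list(rng.choice(vocab, n, p=probs / probs.sum()))
    if kind == "date_presence":
        has = rng.random(n) < 0.25
        dates = _dates(rng, n, 1995, 2015, dialect)
        return [d if h else "" for d, h in zip(dates, has)]
    if kind == "score_threshold":
        hi = max(7, int(2 * (rule.threshold or 1)))
        return list(rng.integers(0, hi + 1, n))
    if kind == "quantile":
        return list(np.round(np.exp(rng.normal(np.log(30000), 0.5, n))))
    if kind == "banded_quantile":
        return list(rng.choice(list(rule.bands), n))
    if kind == "standardise":
        if source == "crt_msec":
            # right-skewed reaction times: the log_e branch must trigger
            return list(np.round(np.exp(rng.normal(np.log(600), 0.6, n)), 1))
        return list(_numeric(rng, n, source))
    if kind == "units_or_other":
        units = np.round(np.abs(rng.normal(8, 6, n)), 1)
        other = rng.random(n) < 0.10
        return ["other" if o else u for u, o in zip(units, other)]
    if kind == "apoe":
        alleles = list(_APOE_FREQ)
        probs = list(_APOE_FREQ.values())
        a = rng.choice(alleles, n, p=probs)
        b = rng.choice(alleles, n, p=probs)
        flip = rng.random(n) < 0.5
        return [f"{y}/{x}" if f else f"{x}/{y}"
                for x, y, f in zip(a, b, flip)]
    if kind == "text_lookup":
        keys = list(rule.lookup)
        return [f"death due to {k}" for k in rng.choice(keys, n)]
    if kind == "date_truncate":
        if "birth" in source:
            return _dates(rng, n, 1935, 1965, dialect)
        if "death" in source:
            return _dates(rng, n, 2010, 2020, dialect)
        return _dates(rng, n, 2005, 2015, dialect,
                      with_time=True)  # exercises time-of-day truncation
    if kind in ("identity", "unit_convert"):
        if kind == "identity" and source == "sex":
            return list(rng.choice(["male", "female"], n))
        if value_type == "binary":  # source already coded 1/0
            return list(rng.choice([1, 0], n, p=[0.6, 0.4]))
        if value_type == "categorical":
            return list(rng.integers(1, 3, n))
        return list(_numeric(rng, n, source))
    raise ValidationError(f"cannot generate source for rule kind {kind!r}")


def generate_cohort(profile: CohortGeneratorProfile | str,
                    n: int | None = None,
                    seed: int | None = None,
                    schema: Schema | None = None,
                    ruleset: CohortRuleSet | None = None,
                    missing_rate: float | None = None) -> pd.DataFrame:
    """Generate one raw cohort-style table.

    Accepts either a :class:`CohortGeneratorProfile` or a cohort id plus
    keyword overrides.  Output is fully determined by (cohort_id, n, seed,
    missing_rate); the same profile always yields an identical table.
    """
    if isinstance(profile, str):
        profile = CohortGeneratorProfile(
            cohort_id=profile,
            n_participants=n if n is not None else DEFAULT_N,
            seed=seed if seed is not None else DEFAULT_SEED,
            missing_rate=(missing_rate if missing_rate is not None
                          else DEFAULT_MISSING_RATE))
    if schema is None:
        schema = load_packaged_schema()
    if ruleset is None:
        ruleset = load_packaged_mappings(schema)[profile.cohort_id]
    rng = _cohort_rng(profile.seed, profile.cohort_id)
    n_rows = profile.n_participants
    dialect = "uk" if profile.cohort_id == "elsa" else "iso"

    # proxy fields may be shared across rules (e.g. one clinical-diagnosis
    # label field feeding several condition flags): pool their vocabularies
    proxy_vocab: dict[str, list[str]] = {}
    for rule in ruleset.data_rules().values():
        if rule.kind == "proxy_condition":
            proxy_vocab.setdefault(rule.source, ["none"])
            vocab = proxy_vocab[rule.source]
            if rule.trigger not in vocab:
                vocab.append(rule.trigger)

    columns: dict[str, list] = {}
    # schema order makes column layout (and the rng draw order) deterministic
    for spec in schema:
        rule = ruleset.rules.get(spec.variable_id)
        if rule is None or rule.kind == "not_collected":
            continue
        for source in rule.sources:
            if source in columns:
                continue
            columns[source] = _generate_source(
                rng, n_rows, source, rule, dialect, profile.cohort_id,
                proxy_vocab, value_type=spec.value_type)

    table = pd.DataFrame(columns)
    # sprinkle missingness everywhere except the participant identifier
    for col in table.columns:
        if col == "cohort_id":
            continue
        mask = rng.random(n_rows) < profile.missing_rate
        if mask.any():
            table[col] = table[col].astype(object)
            table.loc[mask, col] = np.nan
    table.attrs["cohort_id"] = profile.cohort_id
    return table


def generate_all(seed: int = DEFAULT_SEED, n: int = DEFAULT_N,
                 schema: Schema | None = None,
                 missing_rate: float = DEFAULT_MISSING_RATE
                 ) -> dict[str, pd.DataFrame]:
    """Generate all four cohort tables from one seed.

    The presence pattern of the result equals the packaged presence matrix
    by construction (every rule's source fields are generated, none other).
    """
    if schema is None:
        schema = load_packaged_schema()
    rulesets = load_packaged_mappings(schema)
    return {
        cohort: generate_cohort(
            CohortGeneratorProfile(cohort, n_participants=n, seed=seed,
                                   missing_rate=missing_rate),
            schema=schema, ruleset=rulesets[cohort])
        for cohort in COHORT_IDS
    }
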