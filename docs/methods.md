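# Methods

## The problem

Cohort studies label and structure their data idiosyncratically, which makes
*data discovery* — finding out, before requesting access, which studies hold
variables relevant to a planned analysis — slow and error-prone.
Harmonisation for discovery needs only generic latent constructs and
relatively simple rules: the goal is an accurate inventory of what each
cohort can supply under a common target definition, not a pooled analysis
dataset.

This package implements such a harmonisation engine around a 124-variable
core schema optimised for neurodegeneration research, organised by the
C-Surv data model (18 level-1 data themes, from Administration through
Molecular), and evaluates it against four deliberately diverse cohort
profiles: an occupational cohort (Airwave), a social-science ageing cohort
(ELSA), a genetics cohort (Generation Scotland) and a neurodegeneration
cohort (Memento).

## Harmonisation strategies

Every target variable carries one of three strategies:

* **Simple calibration (SC)** — direct mapping of a source variable onto the
  target, possibly with unit conversion (declared factor/offset pairs only,
  e.g. m → cm), Gregorian date truncation to `yyyy-mm-dd`, or a keyword
  lookup stub for free text (cause of death → ICD-11 chapter). Alcohol
  consumption is numeric units/week where derivable, with a sentinel
  "other" provenance mark where drinking is reported but not quantifiable.
* **Algorithmic transformation (AT)** — rule-based recoding or inference:
  recode tables from native label vocabularies (education qualifications →
  a 4-level experience scale, ethnicity, cohabitation, housing type,
  smoking), binary inference (presence of a diagnosis date, a symptom-score
  cut-off, or a proxy answer such as self-reported heart disease standing in
  for angina/MI), two-field smoking resolution (ever × currently), and
  within-cohort income quantiles in local currency.
* **Standardisation (S)** — cognitive performance scores harmonised to
  z-scores within dataset (below).

Each variable also records both a *declared* and an *applied* strategy tag:
many yes/no items nominally calibratable end up inferred algorithmically in
practice, while several questionnaire scale scores reduce to direct mapping.
Tallies can be taken over either tag; the applied split over the 120
represented variables is 61 SC / 53 AT / 6 S.

## Skew-conditional z-scoring

Scores are standardised as `z = (x − x̄) / s` with the n−1 standard
deviation. When the raw sample is markedly skewed, a natural-log
normalisation precedes z-scoring: the sample is shifted so its minimum is at
least 1 (`shift = 1 − min` when `min < 1`, handling zero/negative scores),
then log-transformed. The trigger is the moment-based Fisher–Pearson
skewness `g1 = m3 / m2^{3/2}` with `|g1| ≥ skew_threshold`; the threshold
defaults to 1.0 and is configurable globally and per variable
(`standardisation: {skew_threshold, per_variable_overrides}`). The default
separates the typical cognitive-score skews seen in ageing cohorts (roughly
−0.5 … 0.3, which z-score directly) from strongly right-skewed reaction
times (skew above 1), which take the log branch. Neither the estimator nor
the exact threshold is canonical; both are design choices, flagged as such.
Rank-based inverse-normal transforms and cross-cohort pooled norming are
deliberately out of scope: standardisation is within dataset.

## Numerical and policy choices

* **Missingness** — one convention everywhere: NA in memory, the empty field
  in CSV. Unmapped categorical labels harmonise to missing, never silently
  to "other" (that would fabricate data); "other" is emitted only when the
  source says other. Partial dates (e.g. a bare year) go to missing rather
  than being imputed to mid-year. Value-level operations never raise on
  malformed data; the pipeline records per-variable counts and reasons in a
  provenance log (one entry per cohort × variable, with
  `n_mapped + n_missing = row count` guaranteed).
* **Income quantiles** — order-statistic split at ranks ⌈n/4⌉, ⌈n/2⌉,
  ⌈3n/4⌉ of the non-missing values, ties to the lower quantile (so constant
  incomes all code 1 and the coding is monotone). Banded sources resolve to
  band midpoints first; an open top band resolves to 1.5 × its lower bound.
  Fewer than 4 non-missing values yields all-missing plus a warning.
* **APOE** — genotype labels are normalised order-insensitively over
  unordered e2/e3/e4 pairs onto codes 1–6; alleles outside {2,3,4} are
  missing.
* **Smoking** — target codebook {0 never, 1 past, 2 current}. A cohort
  asking only "ever smoked?" resolves yes through a secondary "currently
  smoking?" field when present, else codes past.
* **Exercise** — measurement diversity across cohorts reduces vigorous /
  moderate / walking activity to presence/absence: any positive frequency
  codes 1, an explicit none codes 0.
* **Not-collected variables** — a `not_collected` rule (ethnicity in the
  French cohort, where collecting it is legally restricted) produces a
  provenance entry recording 100% missingness and its reason, but no output
  column; variables a cohort simply lacks are omitted entirely, matching the
  presence semantics of the coverage analytics.
* **Percentages** — round half up to integer percent.

## Coverage analytics

The presence matrix is the binary variable × cohort grid: a variable is
present for a cohort when the cohort has a data-producing rule whose source
fields all exist in its raw table. From it the package computes theme-level
coverage counts with per-cohort totals (conservation asserted on every
report), the overlap distribution (how many cohorts share each variable,
with the 0-cohort bin always explicit), per-cohort unique-variable counts,
the applied-strategy tally over represented variables, and the
correspondence summary (represented minus the nine interpretive variables =
complete-or-close).

Per-variable presence across the four cohort profiles is not itself a
published quantity; the packaged matrix is one assignment chosen to satisfy
all the aggregate constraints simultaneously (theme × cohort counts, totals
47/73/60/92, overlap histogram {4:34, 3:10, 2:30, 1:46, 0:4}, the four
variables found nowhere, and the ELSA/Memento unique counts 13/26), with
cohort-plausible placement (imaging and CSF biomarkers in the
neurodegeneration cohort, family disease history in the genetics cohort,
early-life and social-environment items in the social-science cohort).

## What the synthetic cohorts do and do not establish

The generator reads the packaged mapping files and emits, for each cohort,
exactly the raw source fields its rules consume, with the native label
vocabularies the rules expect (NVQ/Highers/Baccalauréat-style education
labels, monthly-euro income bands, two-field smoking questions,
diagnosis-date fields, dd/mm/yyyy dates for ELSA). Categorical fields draw
multinomially from the rule vocabulary; quantitative fields are normal with
plausible location/scale; choice reaction time is log-normal with σ = 0.6 so
the log_e branch triggers reliably at the default n = 500; 5% of values are
missing at random (the legally absent ethnicity field is not generated at
all). One seed drives everything through independent per-cohort substreams
keyed by a stable hash of the cohort id, so adding a cohort never shifts
another's draws, and identical profiles yield byte-identical tables.

Green tests on these cohorts establish that the engine is correct: every
rule executes, codebook closure and row conservation hold, presence built
from generated tables equals the packaged matrix by construction, and the
pipeline is deterministic. They do **not** establish anything about real
cohort data: variables are generated independently (no epidemiological
correlation structure), missingness is uniform at random, there are no
longitudinal waves, and the published cognitive-score skews describe real
data that the generator does not attempt to match.

## Known limitations

* Free-text interpretation is a keyword-lookup stub (ICD-11 chapter level);
  real cause-of-death or medication coding needs proper terminology tooling.
* Longitudinal/wave-level harmonisation, latent-variable modelling and
  multiple imputation are intentionally out of scope.
* The presence matrix is one constraint-satisfying assignment, not ground
  truth at the per-variable level; analytics that depend only on the stated
  aggregates are insensitive to this, per-variable queries are not.
* Currency is local per cohort; no cross-cohort currency conversion.
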