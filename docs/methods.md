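# Methods

This note documents the models, rules and numerical choices behind
`fedomop`, in the order the pipeline runs.

## Schema scanning and column classification

No CDM version layout is hard-coded.  The schema is read at run time
through a two-query dialect seam (list tables, list columns; SQLite is the
embedded dialect, others can be registered) and every column is classified
by naming pattern, in strict precedence:

1. `person_id` (exact, case-insensitive) → person link;
2. suffix `_concept_id` → vocabulary link;
3. suffix `_id` whose stem names a table → foreign key (the stem is the
   name minus `_id`, matched exactly and case-insensitively — no
   pluralization heuristics); `_id` columns with no matching table are
   classified `other` and preserved untouched;
4. suffix `_date` / `_datetime` → date;
5. anything else → value.

Foreign-key edges are derived solely from this classification: person links
point at `person`, concept links at `concept`, stem matches at their stem
table; a table's own primary key (`note_id` inside `note`) produces no
edge.  Join paths between tables are shortest paths over the undirected
edge set, with a lexicographic tie-break on intermediate table names so
resolution is deterministic.  The person anchor table is *not* treated as a
domain (event) table even though it carries concept columns: its person
link is its own primary key, not an event reference.

## Query pushdown

All filters (person set, concept set, column subset) compile into a single
parameterized `SELECT`; literals are always bound, never interpolated, and
every generated statement is read-only (connections are additionally opened
in read-only mode).  An *empty* id set means "match nothing" and compiles
to a contradiction predicate; an *absent* filter means unrestricted — the
two are deliberately distinct.  `IN` lists are split into batches of at
most 999 placeholders (the lowest common default among embedded engines)
and results re-sorted by the table's primary key, so batch size is
unobservable.  Row order is not part of the contract; all equivalence tests
compare multisets.

## Disclosure control

The subset rule: an exposed object representing `c` unique persons passes
iff `c == 0` (absence) or `c ≥ k`, where `k` is the site's subset threshold
(default 5 — conservative; deployments configure their own, and it is a
required knob, not a constant; equality passes because the rule blocks
counts strictly *below* the threshold).  The rule is enforced at three
levels, because OMOP data is relational and one person spans many rows:

* per concept, when catalogs are listed and when datasets are assembled
  (sub-threshold concepts are removed before reshaping);
* per extracted table, on the fetched rows *before* any reshaping — a
  2-person extract is disclosive as a whole even if every concept within it
  would be dropped anyway;
* per aggregate request, which is refused when the complete-case row count
  falls below `k` or the parameters/observations ratio exceeds the GLM
  ratio limit (default 0.33).

Refusal messages name the refused object only — never a count below
threshold, never person ids.  Per-site transcripts record every
client-visible message so opacity is testable.

## Reshaping

Concept translation replaces `*_concept_id` values with names from the
site's **own** `concept` table (vocabulary versions are a site property);
unknown ids degrade to `concept_<id>` rather than failing.  The wide pivot
produces one row per person with columns
`<sanitized concept>.<attribute>[.<k>]`: the occurrence index `k` is
1-based and chronological by the table's date column (default: first
`*_start_date`, else `*_date`, else `*_datetime` in schema order), ties
broken by primary-key order, and is only appended when a concept actually
recurs.  Distinct concept ids that sanitize to the same name get an
`_<concept_id>` suffix.  Every generated column carries provenance
`(concept_id, attribute, occurrence)`, which makes the pivot invertible and
lets tests assert event conservation.  Time-point completion pads each
person's series to the union of time points observed across the dataset,
inserting NA entries; it is idempotent by construction.  Merges are left
joins on person id — the left table is the cohort anchor, mirroring the
workflow where an existing cohort table restricts all subsequent queries
via a server-held person filter whose repr never exposes the ids.  The NA
sentinel is pandas' `NA` (distinct from `""` and `0`), serialized as an
empty CSV field.

## Federated GLM

Families: binomial/logit and gaussian/identity.  Per iteration each site
contributes `(XᵀWX, XᵀWz, deviance, n)` computed at the broadcast β; the
client sums in site order and solves.  Numerical choices:

* initialization β = 0; convergence when
  `|dev_t − dev_{t−1}| / (|dev_t| + 0.1) < tol`, default `tol = 1e-8`, at
  most 25 iterations (standard IRLS practice);
* fitted probabilities clamped to `[1e-10, 1 − 1e-10]` so working weights
  stay finite; the clamp is identical on every path, preserving the
  pooled ≡ federated identity;
* a singular summed information matrix raises an error naming the
  collinear columns (identified from the SVD null space);
* rows with NA in any model variable are dropped site-locally
  (complete-case) — wide pivots create NAs by construction, so this is
  decided here to keep the design matrix well defined;
* inference is Wald (`OR = e^β`, CI `e^{β±1.96·SE}`,
  `p = 2(1−Φ(|β/SE|))`), consistent with odds-ratio tables whose CIs are
  symmetric on the log scale; profile-likelihood intervals are not
  implemented.

The pooled fit runs the identical loop with a single local contribution,
so a one-site federation is bit-for-bit equal to pooling; the gaussian
family reaches the normal-equations solution after one β update and the
iteration counter reports exactly that.  The pooled path is itself
validated against statsmodels on random logistic instances (both driven to
full convergence, `tol = 1e-12`, when comparing MLEs at 1e-8).

## Synthetic data generator

The generator emulates the *structure* a production OMOP warehouse
presents — demographics, multi-record domain tables, a local vocabulary,
longitudinal measurements — with a fully known ground truth: independent
Bernoulli predictor indicators at stated prevalences and an outcome drawn
from the stated logistic model, so the generating log-ORs are exactly the
estimand of a correctly specified logistic regression (no confounding by
default; correlation between predictors is deliberately absent so recovery
tests are unambiguous).  The default `copd_demo` scenario: predictors
tobacco use (prevalence 0.25, observation domain), vitamin D deficiency
(0.10), history of asthma (0.08), history of rheumatoid arthritis (0.04,
all condition domain); generating odds ratios 6.43, 6.14, 20.02, 8.22;
baseline log-odds −4, giving an outcome prevalence near 5%.  Prevalences
are chosen once as field-realistic EHR frequencies.  Longitudinal
structure: haemoglobin on a fixed annual grid (3 points from 2016,
mid-January) with 20% missing-at-random dropout, plus a qualitative
SARS-COV2 antigen test whose positive result is vocabulary concept 9191
("Positive").  Event dates are uniform over 2015–2020 — arbitrary but
fixed for reproducibility.  Local concepts use ids ≥ 2,000,000,000, the
conventional site-defined range.  Site partitioning shuffles persons by
seed and deals round-robin, replicating the vocabulary to every site.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated or confounded risk factors,
measurement error and miscoding, informative missingness, visit/provider/
drug/cost tables, cross-site vocabulary drift, and realistic marginal
distributions of laboratory values.  Tests on it establish the *mechanics*
(exact federation, disclosure completeness, reshaping conservation) and
estimator calibration under a correctly specified model, not clinical
realism.

## Problem sizes used in validation

The federated-versus-pooled identity and parameter recovery run at
n = 20,000 persons over 3 sites (one fixed seed each); interval calibration
uses 200 replicate cohorts of n = 5,000 drawn directly from the generator's
cohort model; payload additivity uses 50 random partitions of an n = 2,000,
p = 5 logistic dataset; disclosure recounts and pushdown equivalence use
randomized databases of 60–400 persons.  These sizes give sampling noise
well below the tolerances being asserted while keeping the whole validation
suite runnable in well under a minute apiece.

## Known limitations

* One embedded SQL dialect (SQLite); the dialect seam is the documented
  extension point, but no server DBMS dialect ships.
* No unit harmonization of measurement values and no mapping between
  vocabulary versions across sites — cross-site concept comparability is
  assumed to have been handled during data harmonization.
* Additive GLM terms only: no interactions, offsets, weights, or families
  beyond binomial/logit and gaussian/identity.
* The federation is an in-process simulation: the payload contract is the
  method; transport security (TLS, tokens) is out of scope.
* Only the two disclosure safeguards described above are implemented; the
  broader family of aggregation checks in deployed federated stacks is not
  enumerated here.
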