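# Methods

This note documents the models, rules and numerical choices behind
`milescreen`, and what its synthetic components do and do not establish.

## The screening model

Screening content is a knowledge base (KB) over a closed range of age
months (completed calendar months, floor convention, 1-based). Each month
node lists 3–6 questions — the expert rule for an adequate per-visit
measure — drawn from four language domains with fixed per-domain quotas
(defaults 3 sensory reception / 32 language perception / 48 production /
25 pragmatics, totalling 108). Sensory-reception items probe hearing and
are restricted to months 1–12. A question may be linked to several
consecutive months, modelling milestones whose attainment window spans
more than one month; its *anchor* is the earliest month it is asked.
The KB validates structurally (month coverage, per-month counts,
resolvable and applicable question references, quota conservation,
first-year sensory restriction); validation findings are returned as data
so a caller can render them, and only the graph export refuses to operate
on an invalid KB.

The published description of the deployed system counts "106 milestones"
and "108 questions" without reconciling the two. Here the question is the
atomic screening unit (108 by default); an optional `milestone_groups`
mapping can record any coarser grouping as metadata without affecting
behaviour.

A session's form is the age-month's questions plus the questions answered
"no" in the child's most recent prior session that are still inside their
applicability window (deduplicated, month-node order first). Carrying
forward only the immediately previous session's failures is a deliberate
minimal reading of the observed re-asking behaviour; a full carry-forward
history is easy to add via `history` but is not the default.

### Decision rule

Given a completed session, any failed alarm-class question forces
`refer_early_intervention`. Otherwise the count *w* of failed
warning-class questions selects a repeat interval: 1 → 3 months,
2 → 2 months, ≥3 → 1 month; *w*=0 is typical development. The mapping
from failure count to interval is not fixed by the published account of
the deployed system — only the three intervals and their warning
semantics are — so it is a pluggable `DecisionPolicy` with this graded
default (more failures, sooner follow-up). "Don't know" answers never
count toward *w* by default (a missing observation must not escalate); a
session answered entirely with don't-know is flagged `low_information`
rather than escalated. `dk_counts_as_fail=True` flips this for
sensitivity analyses. Control data (gestation, birth complications,
family history, bilingual context) never modifies the decision in the
default policy; it is carried into reports and statistics only.

The rule is a pure function of (answers, severity classes, policy);
improving any answer from "no" to "yes" can never raise the suggestion's
severity. Both properties are tested, the latter against exhaustive
enumeration of all 3^k answer vectors for small forms.

## Synthetic data

### Knowledge-base generator

`gen_kb` places questions by (seeded) random assignment: first-year-only
sensory items are spread over months ≤ 12 first so they are never
stranded, then every month receives its minimum of home questions, then
the remainder is distributed where capacity remains (≤ 6 per month). A
configurable fraction of questions (default 0.25) extends to up to two
consecutive later months, respecting the per-month cap. Alarm typing is
Bernoulli per question (default fraction 0.15 — the published account
does not state how alarm items are distributed over months, so this is
exposed as a parameter rather than asserted). Identical configurations
and seeds produce byte-identical serialized KBs.

### Cohort generator

`gen_cohort` assigns demographics **exactly** (stratified assignment, not
sampling) from a centre × gender × age-band cross-tabulation; randomness
is confined to ages within bands, gestational weeks, which children carry
risk factors, and the latent impairment labels
(Bernoulli(`impairment_prevalence`)). The default composition is the
field study's: 218 children (134 nursery school / 84 psychopedagogical
centre; 99 girls / 119 boys; age bands 26 / 102 / 90), exactly 8 preterm
(< 37 gestational weeks), 13 with any birth complication, 2 with a family
history of neurodevelopmental disorder, and 10 bilingual children (7
girls, 3 boys), recorded only at the nursery school. Note the top age
band is 90, the sum of the published cross-tabulation's cells; the
published column header gives 84, which is inconsistent with the 218
total and the gender margins, so the cells are taken as authoritative.
`CohortConfig.with_size(n)` rescales the composition proportionally
(largest-remainder rounding) for simulation studies at other sizes.

### Answer model

Each child i has a latent ability θᵢ ~ N(0, 1); impaired children are
shifted down by δ. The probability of passing question q at age t is

    P(yes) = logistic(a · (t − m_q + b) + θᵢ − δ · impairedᵢ)

with m_q the question's anchor month, a the age slope (default 5 logits /
month), δ the impairment shift (default 10), b the attainment lag
(default 1 month: a typically developing child is expected to attain a
milestone about one month before the screen first probes it), and a small
`dk_rate` (default 0.02) replacing answers with don't-know. P(yes) is
strictly increasing in age.

The parameter geometry matters: healthy children must pass items anchored
at their own age (logit a·b + θ ≈ 5 + θ > 0) while impaired children fail
them (a·b − δ + θ ≈ −5 + θ < 0), which requires δ > a·b. Under the
defaults the flagged (warning + alarm) fraction of a simulated cohort is
a consistent estimator of the impairment prevalence (tested at n = 2000
within three binomial standard errors, three seeds). No per-question
response data exist to calibrate a, δ or b against reality; they are
exposed parameters defining a clean test-bed, not psychometric claims.
Passing simulator-based tests therefore shows internal consistency of the
pipeline, not field validity: real answer processes are not conditionally
independent given a scalar ability, don't-know is not missing at random,
and evaluators are not exchangeable.

### Study simulation

`simulate_study` screens every child once at the cohort reference date;
repeat suggestions trigger one follow-up at the suggested interval while
the child stays inside KB coverage, capped at 2 sessions per child —
echoing the observed mean of ~1.24 assessments per child without
modelling calendar constraints. An `accept_model` maps suggestion types
to evaluator decline probabilities (default: always accept).

## Packaged study tables and reconstruction

The field study's child-level data are not deposited; its printed
aggregates are packaged as CSV/JSON (cohort composition, final-suggestion
distribution, severity by gender, the alarm month × centre × gender
matrix, control-information outcomes, acceptance by suggestion type,
individual decline reasons, scalar constants), with SHA-256 checksums and
load-time cross-table consistency checks (e.g. final suggestions sum to
218, acceptance rows to 270 with 7 declines, gender alarms equal the
referral count).

`reconstruct_records` builds a 270-row record set reproducing every
encoded table exactly: alarm children take centre/gender/month straight
from the alarm matrix; per-gender warning totals are split across the
three repeat types by largest-remainder allocation; declined rows are
matched to the individual decline-reason entries (gender and month);
filler children pin the month-18 (9/11) and month-24 (4/10) evaluation
denominators; remaining children are allocated to centres and age bands
against the cohort cross-tabulation, with ages drawn inside bands
(avoiding the pinned months); the 52 non-final assessments are attached
to the most severely classified children first. Cells no table pins —
evaluation dates, intra-band ages, the per-question answers — are filled
deterministically under the seed and are synthetic. Infeasible table
combinations raise an error naming the conflict. The reconstruction is
deterministic and idempotent; any seed yields the same marginals.

Two published fragments are deliberately not encoded: a "23/40" month-15
proportion whose denominator matches no printed table, and per-grade
concordance percentages whose denominators were never printed.

## Statistics layer

All aggregates operate on a tidy record set (one row per session plus a
long answers table). Percentage conventions follow the tables they
mirror: stratified tables use the full record count as the base for every
cell, rounded to one decimal; concordance is reported to two decimals;
sample size is a ceiling. Raw counts and fractions are always emitted
alongside, because the published tables round inconsistently in places
(e.g. one proportion printed as both 30% and 29.7%, and two
typical-development percentage cells that disagree with their own
counts). Every stratified output conserves the grand total (asserted).
Age bands are fixed at ≤12 / 13–24 / 25–36 months, matching preschool
grades; the handful of children marginally older than 36 months fall into
the top band, consistent with the alarm matrix containing a month-37
column.

The sample-size calculator implements n₀ = z²p(1−p)/e² with the finite
population correction n = n₀/(1 + (n₀−1)/N), returning the ceiling; the
correction never increases n and vanishes as N → ∞.

## Problem sizes and determinism

Tests and the acceptance script use the study-scale fixture (270 rows),
generator-scale KBs (108 questions), and simulations of 120–2000 children
(the parameter-recovery check uses 2000 children × 3 seeds and runs in
under a second per seed). Every source of randomness flows through
explicit integer seeds via `numpy.random.default_rng`; property tests are
derandomized.

## Known limitations

- Synthetic KB content carries no clinical validity; only its shape is
  realistic.
- The answer model is a single-factor logistic; it cannot express
  domain-specific deficits (e.g. production-only delay) that the real
  study observed.
- The reconstruction yields *a* child-level data set consistent with the
  printed tables, not *the* study's data; analyses that depend on joints
  the tables do not pin (e.g. suggestion × age × centre beyond alarms)
  are synthetic artefacts of the allocator.
- The engine screens; it does not distinguish transient delay from
  persistent disorder, and is not a diagnostic tool.
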