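# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the choices made where the design was genuinely open.

## Record model and dates

Records follow the classic public registry XML dialect: one
`clinical_study` document per trial with identifiers, overall status,
partially specified dates, the free-text eligibility block
(`eligibility/criteria/textblock`), locations and contacts.  Coordinates are
required to be present on the record (city-level precision); the package
never calls a geocoding or registry service.

Registry dates come at year, month, or day precision ("2013", "June 2013",
"June 6, 2013").  All comparisons use the **latest-day interpretation**: a
month maps to its last calendar day, a year to December 31.  This is a
deliberate reconstruction, not a registry-documented rule: it is the
conservative reading under which a record is only "past" once the entire
stated period has elapsed, so imprecise dates can never create false
conflict flags.  Staleness (`days_since_update`) uses the same reading and
clamps at zero when the update month straddles the reference day; an update
strictly after the reference date raises an error, since it can only arise
from a corrupted corpus.

Each domain carries its own audit reference date (the day its set was
retrieved), stored on the corpus manifest.  Audits never consult the wall
clock, which keeps every run reproducible.

The record model carries a single completion date.  Registries distinguish
"primary completion" from "study completion"; which one a given export
exposes is a property of the export, so the manifest's provenance field is
the place to document the source, and the audit logic is agnostic to it.

## Status-conflict rule and recency statistics

A trial is *conflicting* iff its status is open ("Recruiting" or "Not yet
recruiting", matched case-insensitively; all unrecognized statuses map to
`unknown` and are treated as not open) **and** the latest day of its
completion date precedes the reference date.  Records without a completion
date are never conflicting.  Reported percentages are whole percents,
rounded half away from zero — the convention used for all tables in this
package.

Group staleness comparisons use a one-sided Mann–Whitney *U* test with the
first sample's U statistic (U₁ = R₁ − n₁(n₁+1)/2 from midranks):

- **exact**: full enumeration of all C(n₁+n₂, n₁) rank assignments, used
  when the data are untied and min(n₁, n₂) ≤ `exact_threshold` (default 8,
  with a hard cap on enumeration size so a tiny sample against a huge one
  falls back to the approximation);
- **normal approximation**: mean n₁n₂/2, variance n₁n₂/12·((N+1) −
  Σ(t³−t)/(N(N−1))) with the usual tie correction, and a 0.5 continuity
  correction.

Tests verify the exact path against scipy's exact method and the
approximation against both exhaustive enumeration (all untied samples with
n₁+n₂ ≤ 10, agreement within 0.05 absolute) and a 10⁵-draw permutation
oracle for tied samples.

## Eligibility formats and segmentation

Two macro-formats are recognized.  *Suggested*: a line matching "inclusion
criteria" (any case, optional numbering and trailing colon) occurring
before any "exclusion criteria" line, with at least one bullet after it.
The exclusion section may legitimately be absent, so order is only enforced
when both headings appear.  *Extended*: at least two of the three topic
headings ("disease characteristics", "patient characteristics", "prior
concurrent therapy"), each followed by a bulleted list — requiring all
three would under-detect and one alone is too weak a signal.

Segmentation emits one criterion per bullet (`-`, `*`, `•`, or `N.`
markers), joins continuation lines with a single space, takes the role from
the governing heading (all extended-format items are inclusion criteria,
flagged negated when they open with "No"), and derives indent depth from an
indent stack: each additional indent of at least two spaces opens one
nesting level, whatever its width; tabs expand to four spaces.  Relative
indentation is preserved through XML round-trips because it is semantic —
nested criteria signal sub-populations.

Blocks matching neither format cannot be segmented; format tables report
them in a separate column, and criterion counts exclude them.

## Barrier detectors and the rule pack

The four detectors are an explicitly rule-based reconstruction of a
manual annotation task.  All patterns live in a versioned YAML rule pack
(`data/rules.yaml`), loaded at run time and swappable; every output records
the pack version.  Unicode comparators are normalized to ASCII equivalents
through a length-preserving character map, so evidence offsets always index
the original criterion text.

- **temporal**: a quantity with a time unit (digits or number words +
  day/week/month/year/hour) co-occurring with a temporal anchor (since,
  within, prior, before, at least, no more than, </>/≤/≥, …).
- **labs and scores**: an analyte term (ANC, bilirubin, creatinine, …) or a
  named score (ECOG, Karnofsky, DAS28, …) with a quantitative context — a
  unit token (/µL, mg/dL, IU/L, …), a comparator+number, or a numeric
  range.  A score name with no numeric level does not fire; the definition
  asks what the criteria *require*, and a bare mention requires nothing
  quantitative.
- **sub-population**: a conditional marker (if/unless/only if/for patients
  with/in case of/only applies), or structurally, a criterion naming a
  condition subgroup ("patients with …") followed by deeper-indented child
  criteria.  The subgroup header is the evidence trigger.
- **patient behavior/abilities**: volition and ability phrases (willing to,
  able to, must agree to, capable of, compliance with, consent to).

Criteria about age or gender are excluded from temporal and lab detection:
registries carry age and gender as structured fields that need no text
interpretation.  A criterion may carry several categories at once (a
temporally constrained lab value); there is no mutual exclusion.  Trials
whose blocks cannot be segmented are annotated line-by-line in a declared
degraded mode, in which the structural sub-population rule is unavailable.

Logical-inference criteria ("limited disease that would not normally be
treated") are out of scope by design and simply remain unflagged — a known
limitation shared with any pattern-based approach.

## Follow-up sampling and outcomes

Per domain, follow-up candidates are open-status trials with at least one
United States location, ordered ascending by last update (latest-day
reading, trial id as tie-break).  The ordered list is cut into four
contiguous, as-equal-as-possible segments — remainders go to the earliest
segments, a deterministic convention chosen because the original
segment-boundary rule is unrecoverable — and up to ten trials per segment
are drawn without replacement by a seeded generator; shorter segments are
taken whole.

Contact plans take the three nearest locations that have any contact
information (haversine distance, Earth radius 6371.0 km, to Boston, MA at
42.3601° N, 71.0589° W), then the overall and backup contacts.  Location
order is a content-based total order (distance, then facility and city as
tie-breaks; coordinate-less locations last), so the chosen nearest-3 set is
invariant to input ordering.  The "3 calls + 1 email" budget is attempt
metadata, not wall-clock scheduling.

Responses are classified first-informative-wins: a confirmed-open or
confirmed-closed answer decides the outcome; a refusal with no later
informative answer is *don't know*; all-unreachable or an empty contact
plan is *no answer*.  Outcome tables report a `dropped` column for trials
removed between sampling and outreach (e.g. completed in the interim);
dropped trials are excluded from n and the percentages.

## Synthetic generator

The generator is the package's study-conditions definition: a pure function
of (spec, seed) producing a corpus plus planted ground truth.  The default
spec has four domains with 98/113/124/102 trials, reference dates in
June–July 2013, planted conflict prevalences 0.14/0.46/0.15/0.19,
format mixes with 79–98% suggested and 0–18% extended, per-domain barrier
prevalences matching a published four-domain audit (e.g. 0.42/0.70/0.78/0.61
for the first domain), and mean criteria per trial of 10.3–16.7 (negative
binomial with dispersion 4, minimum 1), pooling to ≈5,950 criteria over 437
trials.

Dates follow a two-regime log-normal lag model: trials that are conflicting
or truly closed draw their last-update lag around a 600-day median, all
others around 60 days (σ = 0.6).  This single coupling plants both
directional recency effects — conflicting records staler than clean ones,
and closed trials staler than open ones — at effect sizes the rank-sum test
detects with p ≪ 0.05 at the default corpus size.  A planted conflict is
realized physically, as an open status plus a month-precision completion
date at least 40 days back (whose month therefore lies entirely in the
past); non-conflicting trials get future or absent completion dates.  True
recruitment state (open/closed) is drawn independently at P(closed) = 0.3
per domain.

Criteria are rendered from a template bank shipped as data: one file per
category, plus subgroup-header/child templates for the structural rule and
distractor templates that match no detector.  Slots (drug, disease,
condition, numbers, units) are filled at random.  Templates are written
against the category definitions and the detectors against the rule pack;
their agreement (each template trips exactly its own detector, distractors
trip none) is asserted by a drift test rather than shared code, so the
recovery experiments are not tautological.  Planted barrier flags are
realized as one or two template criteria per true category; sub-population
flags render as a conditional criterion or, in segmentable formats, as a
subgroup header with an indented child.  "Neither"-format trials render
their criteria as plain prose lines, which exercises the degraded
annotation path end to end.

The simulated outreach draws, per trial, whether any attempt gets through
(default P = 0.69, i.e. a planted 31% per-trial no-answer rate), then a
refusal (P = 0.03) or an informative answer (P = 0.97) that reports the
trial's true status.  Records with no contact information anywhere become
*no answer* regardless, so the realized no-answer rate sits slightly above
the planted 31%.

What the generator does **not** emulate: real medical language (templates
are short, unambiguous English), annotator disagreement, registry
vocabulary drift, geocoding error, or any particular historical registry
snapshot.  Passing recovery tests therefore demonstrates that the pipeline
is correct and internally consistent — that detectors, segmenter and
statistics recover exactly what was planted — not that the rule pack would
reproduce human judgments on real registry prose.

## Numerical and testing conventions

- Percentages: whole percent, half away from zero.
- Exact rank-sum enumeration: threshold min(n₁,n₂) ≤ 8, capped at 2×10⁶
  subsets.
- Prevalence recovery is asserted against exact binomial intervals at the
  planted n.  Where many counts are checked simultaneously (20 planted
  prevalences across the default corpus), the per-comparison coverage is
  Bonferroni-adjusted so the joint false-alarm rate stays near 5%; targeted
  checks of single published rows use plain 95% intervals.
- Default problem sizes (437-trial corpus, ≈6,000 criteria, 10⁵-draw
  permutation oracle) keep the full suite under ten seconds while leaving
  every statistical check well-powered.

## Known limitations

- The rule pack is tuned for the template bank's vocabulary plus common
  clinical phrasings; real registry text will contain constructions it
  misses (precision on real prose is unmeasured by design).
- The status vocabulary models open vs. not-open only; "suspended" or
  "terminated" carry no special semantics.
- Fuzzy-date conventions (latest-day comparison, rounding rule) are
  documented reconstructions, not registry specifications.
- The XML dialect targets the classic export; the current JSON API is a
  non-goal.
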