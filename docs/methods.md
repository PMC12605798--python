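# Methods

This note documents the models and procedures implemented in `tnfiswitch`,
the defaults and their rationale, the synthetic-data model and what passing
tests do and do not establish about real data, and the numerical and design
choices made where the problem was genuinely open.

## Cohort model

The unit of analysis is the patient's timeline of TNFi **order encounters**:
one (patient, calendar date) with exactly one canonical TNFi after cleaning.
Six canonical categories are used — adalimumab, etanercept, certolizumab,
golimumab, infliximab-biooriginator, infliximab-biosimilar — with the
biosimilars deliberately kept distinct from the originator, so an
originator↔biosimilar transition is a switch like any other.

Cleaning runs in a fixed order, each stage appending `(in, removed, out)`
to an attrition log whose chaining (`out(k) == in(k+1)`) is validated:

1. **Name normalization.** Case-insensitive substring matching against a
   replaceable lexicon (CSV: `pattern,canonical,name_kind`), with hyphens
   folded to spaces so "infliximab-dyyb" and "infliximab dyyb" match alike.
   The longest matching pattern wins, which is what lets a biosimilar
   suffixed name beat the bare originator generic embedded inside it.
   Canonical category labels are implicit patterns of every lexicon, making
   normalization idempotent. Dose and route tokens are ignored implicitly
   by substring matching. Orders matching nothing are dropped (non-TNFi).
2. **Missing demographics.** Orders of patients absent from the
   demographics table are dropped.
3. **Deduplication** on (patient, date, canonical). Dosage and modality
   are outside the model, so two same-day orders of the same drug are one
   clinical fact. Rows are fully sorted before the first-of-group is kept,
   making the result invariant under input permutation.
4. **Note linkage.** Orders at encounters without any clinical note are
   dropped (their switch status cannot be audited); every surviving
   encounter is linked to its maximum-timestamp note, on the view that the
   last note version is the most complete. Timestamp ties break by
   lexicographically greatest note id — an arbitrary but deterministic rule.
5. **Multi-TNFi exclusion.** All orders at any (patient, date) carrying
   ≥ 2 distinct canonicals are removed; a same-day pair of different drugs
   is an ambiguity, never a switch.

**Switch detection** then emits one event per adjacent pair of order
encounters with different canonicals, with 1-based ordinals per patient and
the destination encounter's note attached. Intervening encounters without
TNFi orders are invisible to this definition.

**Follow-up classification** partitions patients exhaustively: a patient
with ≥ 1 switch is a *switcher* regardless of follow-up (switch status is
assigned before the follow-up exclusion); a non-switcher is *followed* if
any encounter falls ≥ 183 days after their last TNFi order, else *lost to
follow-up*. 183 days is the nearest whole-day count to half of 365.25; the
horizon is a parameter (`CohortConfig.horizon_days`). Anchoring the horizon
at the **last** order is a choice — "six months after the medication
order" is ambiguous between first and last order; the last order is the
conservative reading (a patient is only called a confirmed non-switcher if
they were observed after their final exposure). Follow-up years run from
first TNFi order to last encounter of any kind, divided by 365.25.

**Tabulation** (`tabulate_demographics`) summarises the followed cohort
(lost-to-follow-up excluded): mean (SD) for age and follow-up years;
count (%) per stratum for sex, race, first documented TNFi and primary
diagnosis; switch-count bands {0, 1, 2, >2} reported both as % of the
switcher stratum and % of the followed cohort. Diagnosis categories with
fewer than `min_cell = 10` switchers are merged into "Other", a standard
small-cell de-identification rule. Group comparisons use Pearson
chi-square without continuity correction (categorical) and Welch's
two-sided t-test (continuous); degenerate inputs report NaN rather than
raising.

## Extraction model

A backend is any callable `prompt -> raw text` with a `backend_id`. Four
prompt variants share one task body and four-key JSON schema and differ
only in which value lists they enumerate: none (`default`), the six drug
categories (`drugs_provided`), the seven reason categories
(`reasons_provided`), or both (`all_values_provided`). The note is placed
in a `Clinical note:` block ahead of the task body; optional
model-specific template tags wrap the prompt without altering it.

The parser is **total**: it locates the first balanced JSON object in the
response (string-aware brace scanning, code fences stripped), folds keys
case-insensitively, routes drug answers through the lexicon, and matches
reason answers against the taxonomy with punctuation/whitespace folding.
Anything unparseable degrades to a flagged record (`parse_ok = False`,
all fields NA). Unmatched free-text reasons are binned as *other* with the
text preserved — NA is reserved for "no reason documented", so an answer
that is a reason, just not a recognised one, must not masquerade as
absence. How a production model's malformed output should be normalized is
not externally specified; these rules are this package's own contract,
stated here so they can be disputed.

The **reference extractor** is co-designed with the note templates: switch
sentences always verbalize the stopped drug before the started one and
distractor sentences never mention a TNFi, so the order of first mention of
distinct canonicals identifies (stopped, started); reasons are detected by
exact phrase-bank lookup. It is exact on noise-free template notes by
construction — which is the point: it makes the evaluation harness testable
against a known-perfect backend, not a model of clinical language.

The **noisy backend** wraps the reference rules and, independently per
field with probability *e*, replaces the true value with a uniform draw
over the field's six substantive values (six drugs; six non-NA reasons).
The draw may coincide with the truth, so per-field accuracy is
1 − e + e/6 — a closed form the tests and the acceptance script check at
e = 0.3 (expectation 0.75). Per-note randomness derives from
(seed, note hash), so records are reproducible and independent of
processing order. Batch extraction caches raw responses keyed on
(backend id, prompt variant, note hash); a warm-cache rerun makes zero
backend calls and reproduces records bit-identically, and a backend
exception on one note yields a flagged record without stopping the run.

## Evaluation model

**Silver labels** are derived from structured orders: each switch's
destination note is labeled (last = source drug, new = destination drug).
No reason can be observed in structured data, so silver sets carry no
reason field at all — absent, not NA.

**Micro-F1** pools TP/FP/FN over the substantive classes. An NA prediction
makes no positive prediction; an NA label contributes no positive truth;
a note with both NA contributes nothing. Two null policies: `all_values`
scores every labeled note; `null_dropped` first removes notes whose record
itself reports reason = NA — self-filtering on the *evaluated* backend's
output, which mirrors evaluating only notes the model believes contain
medication-switch information. `null_dropped` is not guaranteed to score
higher; only `n_evaluated(null_dropped) ≤ n_evaluated(all_values)` is an
invariant. Zero evaluable notes report NaN with n = 0.

**Win rates**: for ordered pair (A, B), win = mean(A correct ∧ B wrong),
loss = the reverse, tie = remainder, so win + loss + tie = 1 exactly and
win(A, B) = loss(B, A). Correctness of a record means every truth-labeled
field matches (gold when available, silver drug fields otherwise; the
truth source is recorded in the report). Mean win rate averages over
opponents — "against all other models" — with a population SD across
opponents; win-minus-loss against a designated baseline summarises one
column of the matrix. **Concordance** is truth-free per-field agreement
between two backends (NA = NA counts), reported in percent with mean and
population SD across fields. Population (n-divisor) SDs are used in both
places because the opponents/fields are the whole population of interest,
not a sample.

The **validation/test split** is patient-level (all of a patient's notes
on one side) to prevent leakage; the published description does not state
the split unit, so the safer unit was chosen. Validation size is
`round(fraction × n_patients)` at the default fraction 0.05.

## Trajectory summaries

Sequences are first drug + destination drugs in ordinal order. The flow
table counts stage-wise transitions up to `max_depth = 3` (the banding
first / second / third-or-more), with a terminal "no further switch" node;
conservation (inflow of each node = its next-stage outflow) is validated
on construction. Reason-by-ordinal tables exclude NA-reason records from
denominators by default — shares are reported among notes with an
extractable reason, and the denominators are always reported explicitly
alongside the proportions.

## Synthetic-data model

Per patient: a status is drawn from {switcher 0.1825, lost-to-follow-up
0.206, followed non-switcher 0.6115}; a switcher's switch count comes from
band weights {1: 0.701, 2: 0.198, 3: 0.0497, 4: 0.0213} (renormalized —
the published band percentages sum to 97 %); the first drug from the
published first-TNFi shares (adalimumab 0.409, infliximab-biooriginator
0.263, etanercept 0.241, certolizumab 0.033, infliximab-biosimilar 0.031,
golimumab 0.023); each switch destination uniformly from the other five
drugs. Reasons follow the published extracted-reason shares
(lack of efficacy 0.569, adverse event 0.135, insurance/cost 0.108,
patient preference 0.082) with the two unreported categories splitting the
remainder (drug resistance 0.053, other 0.053); each switch note
verbalizes its reason with probability 0.41, matching the reported 59 %
of reason-free notes. Statuses are planted directly rather than emerging
from a per-encounter switch hazard: that makes the ground truth exact and
the analytic switcher-fraction expectation equal to the configured
probability, at the cost of not modelling switch-timing dynamics.

Timelines: k + 1 drug runs padded with Poisson(3) extra maintenance
encounters, inter-encounter gaps Gamma(2, 60) days clipped to [14, 365],
start dates uniform over six years. Followed patients get a follow-up
encounter 200–700 days after their last order; lost patients get at most
one within 150 days. Spellings are drawn from the lexicon's synonym pools
with random dose/route suffixes.

Corruption injections and their accounting: an extra duplicate order per
encounter with p = 0.27 (the published duplicate share of raw orders),
a second distinct TNFi on the same date with p = 0.034, a missing note
with p = 0.087. The latter two are restricted to encounters that are
neither the first of a drug run nor the patient's final encounter —
removing such an encounter provably cannot change run boundaries (so no
switch appears or disappears and no switch note is relinked) nor the
follow-up gap of a lost patient. This is what makes the end-to-end
recovery tests exact rather than statistical: deduplication removes
exactly the planted duplicate count, the multi-TNFi stage removes exactly
2 × the injected encounter count, and the rebuilt switch set equals the
planted one. A fraction p = 0.15 of encounters also receives an earlier
same-day draft note, exercising the last-note rule. Patients without
demographics (p = 0.001) are generated but excluded from ground truth,
since the pipeline drops them at stage 2.

All randomness flows from one root seed through `numpy` `SeedSequence`
spawning, one child stream per patient, so outputs are byte-identical for
a given config and unaffected by generation order.

**What passing tests show — and don't.** Exact recovery and micro-F1 = 1.0
on synthetic notes validate the *pipeline and metrics*: the attrition
accounting, switch detection, label derivation and scoring are correct.
They say nothing about extraction quality on real clinical prose — the
note generator deliberately produces templated text with a closed phrase
inventory, no negations, no historical medication narratives, no OCR noise
and no ambiguous attribution, all of which real notes have. Real-model
benchmarking requires plugging an actual LLM adapter into the backend
contract; its scores are then *measured*, not asserted, by this framework.

## Problem sizes and numerics

Default test and acceptance runs use 300–2000 synthetic patients and 2000
calibration notes — sizes at which every binomial 3-SE check has
comfortable power while the full suite runs in well under a minute of
compute for generation and evaluation combined. Stochastic assertions use
fixed seeds and 3-SE tolerances computed from the analytic expectation,
never tuned bands. Percentages are compared after rounding to the printed
precision; flow conservation and attrition chaining are integer-exact;
win/loss/tie identities hold to 1e-12. Ties are broken deterministically
everywhere (note ids lexicographically, lexicon patterns by length then
text, sorted group keys), so repeated runs are bit-identical.

## Known limitations

* Dose changes, discontinuations and switches to non-TNFi therapies are
  out of scope; a patient who simply stops therapy is indistinguishable
  from one whose orders moved elsewhere.
* The bundled lexicon is a reasonable US-market name list, not an
  authoritative registry export; it is a data file users should replace
  for other formularies or markets.
* "Consecutive encounters" means consecutive TNFi-*order* encounters;
  gaps of years between them still count as one transition.
* The published switch-band counts (1481 + 418 + 150 = 2049) do not sum to
  the published switcher total (2112); the tabulation helpers reproduce the
  published arithmetic when given the published denominators, but on actual
  data bands always sum to the stratum total by construction.
* Silver labels inherit every bias of order data (orders placed but never
  administered, administrations recorded elsewhere); the framework treats
  the silver/gold distinction as first-class rather than hiding it.
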