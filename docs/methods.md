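# Methods

This note documents the models, conventions and design choices behind
`attesa`, in the order the pipeline applies them, together with what the
synthetic corpora do and do not establish.

## Pre-processing

Six steps, in a fixed order chosen so each step simplifies the next one's
input:

1. **Lower-casing** — length-preserving (characters whose lowercase form
   would expand, e.g. `İ`, are left as-is so the offset map stays 1:1).
2. **Number words → digits** — a closed lexicon of Italian cardinals (1–60,
   plus tens to 90) and basic ordinals (`numbers.yaml`). Running this
   *before* pregnancy removal means "trentadue settimane di gravidanza" is
   caught by the gestational rule as "32 settimane …". Homographs of
   function words (*un*, *una*, *sei*) are converted only when a time unit
   follows, so "una visita" and "sei in cura" are untouched.
3. **Pregnancy-context removal** — a number followed by a week unit
   (settimana/sett/sg/w) within ±4 tokens of a pregnancy trigger
   (gravidanza, gestazione, amenorrea, s.g., …) is deleted together with the
   trigger and any glued preposition ("alla **32 settimana di gravidanza**").
   The window is **clause-bounded**: it never crosses `; . ! ? ,` — so in
   "gravidanza; controllo tra 2 settimane" the waiting time survives — and a
   number introduced by tra/fra/entro/dopo/ogni is never treated as
   gestational. The deletion runs to fixpoint, which keeps the whole
   pre-processor idempotent. The window width and the clause rule are this
   package's own reconstruction of a heuristic whose exact published form is
   not available; both are configurable in code.
4. **Punctuation pruning** — punctuation becomes a space, *except* `/ - .`
   with digits on both sides (date separators). Whitespace is collapsed.
5. **Unit lemmatization** — the default backend is a closed dictionary
   (mesi→mese, settimane→settimana, giorni→giorno, anni→anno). The hook
   accepts any `token -> lemma` callable; a full morphological backend
   (spaCy Italian) is attempted only on request and falls back to the
   dictionary with a logged warning when unavailable. A closed dictionary
   is deliberate: it can never rewrite a non-temporal token.
6. **Typo correction** — alphabetic tokens of length ≥ 4 that are not in the
   temporal lexicon and lie at edit distance ≤ 1 (edlib) from *exactly one*
   lexicon entry are replaced. Ambiguity ⇒ no correction; short tokens are
   exempt because clinical abbreviations ("ter", "qt", "gg") would otherwise
   be mangled. Correction is last so it operates on lemmatized text.

Every step is executed through an edit list that maintains a monotone map
from processed to raw character offsets; extracted spans are therefore
always reported on the raw text.

## The formal language

Five families built from shared named sub-patterns (grammar.yaml):

| family | example | priority |
|---|---|---|
| precise_date | "entro il 15/03/2022", "12.01.22" | 60 |
| range | "tra 3 e 6 mesi", "3-6 mesi" | 50 |
| month_year | "a ottobre 2022" | 40 |
| interval | "tra 3 mesi", "entro 30 gg", "per 2 settimane" | 30 |
| bare_duration | "controllo 6 mesi" | 20 |

The compiler substitutes `{{NAME}}` placeholders recursively, so a family is
readable as structure ("TRIGGER NUM UNIT") and sub-patterns are written
once. Overlaps are resolved by priority, then longest span, then leftmost —
a total order, so scanning is deterministic.

Context conditions — word boundaries at the span edges (which also keeps a
number from matching inside an ICD code like `01282`), and suppression of
spans followed by " fa" ("ago") — are **post-filters applied outside the
regexes**. This makes "matches" a property of the substring in its context,
identical for the left-to-right scanner and for the brute-force
all-substrings oracle used in the tests, rather than an artefact of scan
order.

Unit abbreviations accepted: gg/g (day), sett/set (week), aa (year). `mm`
is *not* accepted for month: it is ambiguous with millimetres, and the
design is precision-first — a missed indication costs one data point, a
false one corrupts the delay statistics. "oggi"/"domani" are likewise out
of grammar by default (not waiting times). Two-digit years resolve to
2000–2049; earlier resolutions become past dates and are deleted anyway.

## Normalization (NTI)

- Durations: day ×1, week ×7, month ×30, year ×365 (Italian NHS
  priority-class maxima are quoted in the same 30/60/120-day style). The
  generator uses the same convention, so exact-recovery tests are
  convention-independent checks of the machinery, not of the factor choice.
- Ranges take the **upper** bound (default): "within 3–6 months" is late
  only after the outer bound. `lower`/`midpoint` are available.
- Precise dates and month+year anchor to the **referral date** — the text
  was written then, not at booking. Month+year completes the day to the 1st.
- Deletion rules: target date ≤ referral date (past mention), impossible
  calendar dates, and any value outside (0, 730] days. The 730-day horizon
  is configurable; beyond two years is implausible for a monitored
  follow-up.
- When several expressions survive ("controllo tra 6 mesi; terapia per 2
  settimane"), the one nearest in tokens to a follow-up keyword (controllo,
  rivalutazione, visita, follow up, …) is selected; ties go leftmost.
  Associating *multiple* indications to multiple exams in one referral is
  out of scope.
- Bare numbers without a unit ("controllo a 6") are never matched: unit
  inference was judged too error-prone, matching the precision-first stance.

## Delay computation

`delay = (first_proposed − booking) − NTI`, positive meaning the booking
system offered the exam later than prescribed. The sign convention is fixed
by the substantive reading "negative average ⇒ timely". Postponement
(`max(0, accepted − first_proposed)`) is patient-attributable and kept out
of the delay; an accepted date earlier than the proposed one is a data
error, logged and treated as 0.

Cohort: screenings, ER visits, priority-U referrals and lab tests are
excluded; follow-ups are specialist records with a follow-up code plus
radiology records with the Z flag. Group summaries (by exam type, radiology
type, LHA, prescriber type) report only groups with more than `min_group`
(default 1000) records; delay statistics are computed over delayed records
only, with type-7 (linear-interpolation) quartiles and population SD (a
singleton group has SD 0). The `pct_with_indication` denominator is
records; unique-referral denominators can be obtained by deduplicating on
`referral_id` upstream.

## Evaluation

Positives are gold `followup_waiting_time` items only; a text whose only
temporal content is a past date or a gestational age is a *negative* for
this task (its correct prediction is null). NTI correctness compares
canonical days, so "90 giorni" and "3 mesi" agree. Three populations (all /
any temporal indication / follow-up indication) de-bias the accuracy from
the ~98% of easy negatives. Undefined ratios (empty population, tp+fp=0)
are reported as absent, never as 0 or 1. Report rounding is 3 decimals.

`counts_from_error_analysis` reconstructs a full confusion matrix from a
published error analysis (N, FP, FN, rounded recall) by integer search over
tp; all tp values consistent with the printed recall yield the same rounded
metrics, which the function verifies.

## Synthetic corpora

The generator emulates: ≈2% prevalence of waiting-time indications among
follow-up texts; phrasing drawn from the five families with abbreviation,
number-word and uppercase variation; diagnosis stubs as negatives; and a
distractor library (past month+year, gestational weeks, ICD codes,
"scan osseo 07 20"-style past exams, "N mesi fa") at a configurable rate.
Typos are single-character edits on temporal tokens of positive phrases.
Referral tables have coherent date chains; for indicated exams the
booking-to-proposed gap is NTI + delay, with a 16% delayed fraction and
delayed delays drawn lognormal(μ=1.79, σ=1.52) — median ≈ 6 days, mean ≈ 19
days; timely gaps are negative-exponential (mean 45 days below the NTI).
All sizes and rates are `GeneratorConfig` fields; generation is a pure
function of config + seed.

What passing tests show — and do not show. Perfect recovery on clean
synthetic corpora is a *consistency* result: the generator's template bank
is expressible in the grammar by construction (an optional `include_unseen`
subset deliberately is not, for recall studies). It demonstrates that the
machinery is lossless, not that the grammar covers all real-world phrasing;
real texts contain expression types no template bank anticipates, and real
performance must be established on annotated real data. Likewise the
degradation profile (precision stays ≈1, recall falls gently under 5%
typos) reflects the injected-typo model — single edits on long temporal
tokens — not the full variety of human misspelling.

Problem sizes used by the default suite and the acceptance script — 10 000
texts per corpus run, 20 000 records per cohort, 1000 texts for the
scanner/oracle equivalence sweep — were chosen to estimate each quantity
well inside its sampling tolerance.

## Known limitations

- The grammar is a reconstruction: recall on real referrals depends on
  coverage that only annotation rounds can drive (the intended
  semi-automatic loop: run, review FN/FP listings, extend the YAML).
- Month=30/year=365 makes "12 mesi" (360 d) ≠ "1 anno" (365 d); gold and
  prediction must share the convention.
- Only one NTI per text; multi-exam referrals share it.
- The O/Z flag is a proxy for follow-up status of instrumental exams and is
  known to include non-follow-up psychiatry/sports-medicine/dialysis
  referrals; the synthetic generator does not model that contamination.
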