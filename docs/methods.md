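# Methods

This note documents the modelling decisions behind `sigdose`: what the
parser assumes, what the defaults mean, what the synthetic corpus does and
does not emulate, and where behaviour was genuinely open to choice.

## The dosage model

A sig is modelled as a sequence of medication periods. Each period is fully
described by a per-administration dose (possibly a range), a rate of
administration (a frequency in administrations/day or an interval between
administrations), an optional per-administration strength, an optional
duration, and an optional PRN (as-needed) marker. The daily dosage is

    daily_low  = dose_low  × f_low
    daily_high = dose_high × f_high

where an interval of a–b hours inverts to f_low = 24/b, f_high = 24/a
(ordering is preserved because a ≤ b), intervals in days/weeks/months invert
to 1/(d), 1/(7d), 1/(30d) administrations per day, and PRN sets
daily_low = 0 (the patient may take nothing). When a strength is present the
alternate daily dose is strength × f under the same pairing. Range doses and
range frequencies pair low-with-low and high-with-high; the grammar has no
construct in which the conservative pairing would differ.

All quantities are decimals canonicalized to ≤ 3 decimal places
(`ROUND_HALF_UP`, trailing zeros stripped). Exact arithmetic (fractions)
is used internally and rounding happens once, on the final values, so the
parser and the independent gold oracle agree bit-for-bit whenever they agree
mathematically. Evaluation compares these canonical decimals exactly; there
is no floating-point tolerance anywhere in scoring.

### Decisions that were genuinely open

- **No implicit once-daily default.** A period with a dose but no frequency
  or interval yields nothing. Guessing "daily" would raise sensitivity at
  the cost of manufactured false positives, and the whole point of a
  deterministic parser in clinical use is a near-perfect PPV.
- **Parenthetical strength is the per-administration amount.** "take 1/2
  tablet (50 mg) every day" means the patient takes 50 mg per
  administration, i.e. 50 mg/day — reading "(50 mg)" as a per-tablet
  strength (giving 25 mg/day) halves the actual dose. Real-world sigs are
  ambiguous here; the convention is applied uniformly by parser and
  generator and is called out because it is the single most consequential
  interpretation rule in the package.
- **Inline strength with no form word** ("take 50 mg daily") is treated as a
  dose in strength units (50 mg/day in `daily_dose_*`, alternate fields
  empty), not duplicated into both field groups.
- **An inline strength after a form dose** is accepted only when directly
  adjacent ("1 tablet 50 mg daily"). A detached clause such as "max 90 mg"
  is deliberately left unconsumed so its numeral trips the uncertainty flag.
- **Interval beats frequency** when both match in one period (the interval
  is the more specific statement); both matched spans count as consumed.
- **Uncertain results carry no periods.** Whether tentative extractions
  should survive alongside the flag is arguable; emptying them guarantees
  that downstream consumers can never accidentally use a dose the parser
  itself does not trust.
- **A final open-ended period has an empty duration** (nothing is asserted
  about how long the maintenance dose continues).
- **PRN gold convention**: daily_low = 0, daily_high = the maximum the
  schedule allows. The generator uses the identical convention, so
  evaluation is self-consistent.

## Normalization

Stage order is fixed: lowercase/collapse → number words → synonyms → stop
phrases → collapse. Synonym keys are written against numeric forms
("2 times"), so numbers must be normalized first; stripping runs last and
its phrase list is validated digit-free at load, which yields the numeral-
conservation property the uncertainty flag depends on. The synonym table is
applied in a single simultaneous longest-key-first pass and is validated
idempotent at construction (no canonical form contains another key), which
makes the whole pipeline idempotent by construction.

The shipped synonym and stop-phrase tables (`sigdose/data/*.tsv`) are a
curated reconstruction of common English sig abbreviations (q-notation
frequencies, form words, route phrases). They are deliberately editable:
`--lexicon` swaps in site-specific tables without code changes.

Fraction literals convert only when not date-like: "1/2" converts, while
"01/02/2024" (second slash) and year-adjacent forms do not. The same
date exemption governs the uncertainty sweep (dd/dd, dd/dd/yyyy, four-digit
years 1900–2099, month-name-adjacent numbers).

## Evaluation

The unit of analysis is the sig; matching is all-or-nothing over the
daily-dosage variables of all periods (daily dose, alternate daily dose,
duration — low/high/units each). `optional_period`, `start_condition` and
`hold_condition` are ignored in scoring. `uncertain` counts as unparsed:
against non-empty gold it is a false negative, against empty gold a true
negative. Metrics with zero denominators are reported as undefined (`None`),
never as 0 — silent zeros would distort small subgroup tables.

The permutation test for comparing two parsers is a paired sign-flip design:
the statistic is the F1 difference computed from per-sig confusion cells;
under the null each sig's pair of cells is swapped with probability ½;
the two-sided p-value uses add-one smoothing, (1 + #{|T*| ≥ |T|})/(B + 1),
with B = 10,000 by default and a mandatory seed. Within permutation
replicates an undefined F1 is scored as 0.0 (the observed statistic uses the
same convention, keeping the comparison fair); with realistic cell vectors
the case does not arise. The Monte-Carlo p agrees with exhaustive
enumeration of all 2^n flip patterns for small n (property-tested at n = 8).

## The synthetic corpus

The generator emulates the *structure* of real HFrEF sig datasets: one to
five sequential periods (titrations joined by "then"/"increase to", each
non-final step carrying a duration), dose ranges, PRN clauses, parenthetical
strengths, duration clauses, hold-condition clauses containing numerals, and
sigs from which no daily dose is extractable. Gold period objects are
computed from the template parameters by a separate implementation of the
dosage contract above (fractions → one final rounding), not by calling the
extractor — parser-vs-gold agreement is therefore an oracle test.

Default generation probabilities (all exposed on `SynthConfig`): 30%
multi-period, 10% range dose, 10% PRN, 25% parenthetical strength, 30%
duration on single-period sigs, 10% no-dose, 5% hold-condition, noise level
0.5, six HFrEF drug-class labels plus a sex label for subgroup exercises.
No public distribution over sig patterns exists to calibrate against; these
values were chosen once as a realistic mix that exercises every grammar
path, and the proportions are measurable via `corpus_stats`.

Noise operators are restricted to the normalizer's inverse image —
number-to-word substitution, "0.5" → "1/2", form/time abbreviations
(tab/cap/wk/mo), frequency variants (bid, twice daily, qd...), route and
filler insertions, casing, politeness — so every non-adversarial rendering
is recoverable and any parse miss is a bug, not noise. Hold-condition
records are the deliberate exception: they are flagged `expect_uncertain`
and the parser is *required* to abstain on them.

What the corpus does **not** emulate: misspellings, truncated or non-English
sigs, free-order clause permutations, weight-based (mg/kg) dosing, taper
grammars beyond the period model, and the empirical pattern distribution of
any real health system. Perfect closure scores on synthetic data therefore
demonstrate internal consistency of grammar, arithmetic and evaluator — not
expected performance on real clinical text.

## Problem sizes and determinism

The shipped test suite and acceptance script run the generator at corpus
sizes of 300–2,000 sigs with fixed seeds — large enough that every template
family and noise operator occurs many times, while keeping the whole suite
fast. Generation uses Python's Mersenne-Twister `random.Random(seed)`;
the permutation test uses NumPy's PCG64. Equal seeds give byte-identical
corpora and identical p-values; the parser itself is seed-free and fully
deterministic.

## Known limitations

- The synonym/stop lexicons cover common abbreviations, not any site's full
  vocabulary; unknown abbreviations containing digits will (correctly) push
  sigs to `uncertain`, lowering sensitivity rather than PPV.
- `start_condition` and `hold_condition` are carried as raw text only; no
  semantic extraction is attempted.
- Interval units of weeks/months invert through a 30-day month; calendar
  precision is out of scope.
- The CSV round trip represents absent-vs-empty gold with an explicit
  `gold_annotated` column; files produced by other tools must follow this
  convention to preserve the distinction.
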