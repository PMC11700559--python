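# sigdose

Deterministic extraction of **daily dosage** from free-text prescription
signatures (*sigs*), with an exact-match evaluation harness and a synthetic
gold-annotated sig generator.

## The problem

When a medication is ordered, the sig tells the patient how to take it —
"take one tablet twice daily". Clinicians often skip the structured entry
fields and write the sig as free text, which makes it hard to check
automatically whether a patient is on the recommended daily dose. This
matters acutely for guideline-directed therapy in heart failure with reduced
ejection fraction (HFrEF), where drugs such as beta blockers and ARNIs are
titrated stepwise to target daily doses.

`sigdose` implements a rule-based parser for this task. Rule-based extraction
is attractive in the clinical setting because it is fast, free, fully
deterministic, and — crucially — *abstains* when it is not sure, rather than
hallucinating a dose. High positive predictive value (PPV) is the operative
metric: an extracted daily dose that is wrong can mislead a clinician,
whereas an explicit "uncertain" flag invites manual review.

## The method

Each sig is converted to an ordered list of **period objects**, one per
medication period, carrying:

- `Daily_Dose_Low/High/Units` — total per-day intake in form units
  (tablet, capsule, ...),
- `AltDaily_Dose_Low/High/Units` — the same quantity in mass/volume units
  (mg, mcg, mL) when a strength is stated,
- `Duration_Low/High/Units` — how long the period lasts (day/week/month),

plus `Optional_Period`, `Start_Condition` and `Hold_Condition` carried as
free text. The pipeline:

1. **Normalize** — lowercase; spell numbers numerically ("one" → 1,
   "1/2" → 0.5, dates exempt); expand synonyms on word boundaries
   ("wk" → "week", "bid" → "2 times daily"); strip text irrelevant to dosing
   ("by mouth", "with food"). Stop phrases are digit-free by construction, so
   no numeral is ever lost.
2. **Split periods** on the titration keywords *then* and *increase to*.
3. **Extract clauses** per period: dose (`0.5 tablet`, `1-2 capsule`, with
   optional parenthetical strength `(50 mg)`), frequency (`2 times daily`,
   `every other day`, `weekly`), interval q-notation via the regex

       ((^q)|( q))([\s]?)([\d]+)((-)([\d]+))?([\s]?)((hr$)|(h$)|(hr)|(h)|(month)|(week)|(day)|($)|(prn))

   so `q4hr` is every 4 hours and `q2-3hr` every 2 to 3 hours, and duration
   (`for 1 week`, `for 7 to 10 day`).
4. **Compute the daily dose**: daily = dose × administrations/day. Intervals
   invert — `q a–b hr` gives frequency 24/b to 24/a per day. PRN (as-needed)
   zeroes the lower bound. A parenthetical strength is the
   *per-administration* amount, so "take 1/2 tablet (50 mg) every day" is
   50 mg/day — not 25.
5. **Flag uncertainty**: if any non-date numeral is left unconsumed (a hold
   threshold, a maximum), the whole sig is tagged `uncertain`, its periods
   are withheld, and it counts as unparsed downstream.

Evaluation is all-or-nothing at the sig level: a sig is a true positive only
if every period matches the gold standard exactly on the daily-dosage
variables. PPV = TP/(TP+FP), sensitivity = TP/(TP+FN),
F1 = 2·PPV·sens/(PPV+sens), with subgroup tables and a paired sign-flip
permutation test for comparing two parsers on the same sigs.

Because real clinical sigs cannot ship with the package, `sigdose.synth`
generates gold-annotated corpora with the same structural variety —
titrations up to 5 periods, dose ranges, PRN, parenthetical strengths,
durations, hold-condition clauses, no-dose sigs — where the gold arithmetic
is implemented independently of the extractor, so parser-vs-gold tests are a
genuine oracle comparison.

## Worked example

```python
from sigdose import SigRecord, parse_sig

res = parse_sig(SigRecord(
    sig_id="rx1",
    text="Take 1/2 tablet (50 mg) by mouth daily for 1 week, "
         "then increase to one tablet (100 mg) daily",
))
print(res.status.value)
print(res.normalized_text)
for i, p in enumerate(res.periods):
    print(f"period {i}: daily {p.daily_dose_low}-{p.daily_dose_high} "
          f"{p.daily_dose_units}, alt {p.alt_daily_dose_low}-"
          f"{p.alt_daily_dose_high} {p.alt_daily_dose_units}, "
          f"duration {p.duration_low}-{p.duration_high} {p.duration_units}")
```

prints

```
parsed
take 0.5 tablet (50 mg) daily for 1 week then increase to 1 tablet (100 mg) daily
period 0: daily 0.5-0.5 tablet, alt 50-50 mg, duration 1-1 week
period 1: daily 1-1 tablet, alt 100-100 mg, duration None-None None
```

— a two-period titration: half a tablet (50 mg/day) for the first week, then
one tablet (100 mg/day) indefinitely (an open-ended final period has no
duration). Appending a clause like `"hold if sbp less than 90"` flips the
status to `uncertain` with residual token `90`: the parser refuses to assert
a dose when an unexplained numeral remains.

## Command line

```console
sigdose synth --n 1000 --seed 7 --out corpus.jsonl        # gold-annotated corpus + stats sidecar
sigdose parse --in corpus.jsonl --out parsed.jsonl        # [--lexicon dir] to override tables
sigdose eval  --pred parsed.jsonl --gold corpus.jsonl --out report.json \
              [--group-by drug_class] \
              [--permute-against other.jsonl --n-perm 10000 --seed 3]
```

## Layout

- `sigdose.model` — `SigRecord`, `PeriodObject`, `ParseResult` (pydantic,
  exact-decimal dosage fields)
- `sigdose.io` — lossless JSONL/CSV corpus and result round trips
- `sigdose.normalize` — number words, synonym table, stop phrases
  (default tables in `sigdose/data/*.tsv`)
- `sigdose.extract` — period splitter, clause grammars, dosage arithmetic,
  uncertainty flag
- `sigdose.evaluate` — confusion semantics, metrics, subgroups, permutation
  test
- `sigdose.synth` — synthetic corpus generator with independent gold oracle
- `sigdose.cli` — `sigdose parse | eval | synth`

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
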