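"""Period splitting, clause extraction, daily-dose arithmetic and the
uncertainty flag.

A normalized sig is split into medication periods on the titration keywords
``then`` and ``increase to``.  Within each period span, four clause grammars
run independently:

* interval — q-notation (``q4hr``, ``q2-3hr``) via :data:`INTERVAL_PATTERN`
  plus the spelled-out form ``every N [to M] hour/day/week/month``;
* frequency — administrations per day from phrases like ``2 times daily``,
  ``every day``, ``every other day``, ``weekly``;
* dose — per-administration quantity and form unit (``0.5 tablet``,
  ``1-2 capsule``), with an optional strength: a parenthetical ``(50 mg)``
  immediately after the dose expression, or an inline ``50 mg``.  The
  parenthetical strength is interpreted as the *per-administration* amount,
  not a per-unit strength;
* duration — ``for N [to M] day/week/month`` or ``x N unit``.

Daily dosage is dose × administrations-per-day.  An interval of ``a-b`` hours
inverts to a frequency range of ``24/b`` to ``24/a`` per day.  PRN (as-needed)
dosing zeroes the daily-dose lower bound.  After extraction, any numeral left
unconsumed in the sig that is not date-like flips the whole result to
``uncertain`` — the safety valve that keeps precision high: a number the
grammar did not understand (a hold threshold, a maximum) may change the
meaning of the numbers it did.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Optional

from .model import ParseResult, ParseStatus, PeriodObject, SigRecord, canon3
from .normalize import SynonymTable, normalize

__all__ = [
    "INTERVAL_PATTERN",
    "PeriodSpan",
    "ExtractedClauses",
    "InvalidClauseError",
    "split_periods",
    "extract_interval",
    "extract_frequency",
    "extract_dose",
    "extract_duration",
    "extract_clauses",
    "compute_period",
    "detect_uncertainty",
    "parse_sig",
]

# Interval (q-notation) pattern.  Matches "q4hr" capturing 4 and "q2-3hr"
# capturing 2 and 3; the empty suffix alternative means a bare "qN" defaults
# to hours, and "prn" may ride along as the suffix.
INTERVAL_PATTERN = re.compile(
    r"((^q)|( q))([\s]?)([\d]+)((-)([\d]+))?([\s]?)"
    r"((hr$)|(h$)|(hr)|(h)|(month)|(week)|(day)|($)|(prn))"
)

# Spelled-out interval, the target form of q-notation ("every 4 hour").
_EVERY_N_RE = re.compile(
    r"\bevery (\d+)(?:\s*(?:-|to)\s*(\d+))? (hour|hr|h|day|week|month)s?\b"
)

_G_LOW, _G_HIGH, _G_SUFFIX = 5, 8, 10

_NUM = r"\d+(?:\.\d+)?"
_RANGE = rf"({_NUM})(?:\s*(?:-|to)\s*({_NUM}))?"

_FORM_UNITS = "tablet|capsule|pill|puff|drop|ml|spray|patch"
_STRENGTH_UNITS = "mg|mcg|g|ml"

_DOSE_RE = re.compile(rf"\b{_RANGE}\s*({_FORM_UNITS})s?\b")
_PAREN_STRENGTH_RE = re.compile(rf"\s*\(\s*{_RANGE}\s*({_STRENGTH_UNITS})\s*\)")
_INLINE_STRENGTH_RE = re.compile(rf"\b{_RANGE}\s*({_STRENGTH_UNITS})\b")
# Strength stated right after the form dose ("1 tablet 50 mg"); anchored so an
# unrelated clause like "max 90 mg" is NOT consumed and trips the uncertainty flag.
_ADJACENT_STRENGTH_RE = re.compile(rf"\s+{_RANGE}\s*({_STRENGTH_UNITS})\b")

_FREQ_N_TIMES_RE = re.compile(rf"\b{_RANGE}\s*times?\s+daily\b")
_FREQ_N_WEEKLY_RE = re.compile(r"\b(\d+)\s*times?\s+weekly\b")
_FREQ_EOD_RE = re.compile(r"\bevery other day\b")
_FREQ_DAILY_RE = re.compile(
    r"\b(?:every day|daily|nightly|every morning|every evening|every afternoon)\b"
)
_FREQ_WEEKLY_RE = re.compile(r"\b(?:weekly|every week)\b")

_DURATION_RE = re.compile(rf"\bfor {_RANGE}(?: more)? (day|week|month)s?\b")
_DURATION_X_RE = re.compile(rf"\bx\s?({_NUM}) (day|week|month)s?\b")

_PRN_RE = re.compile(r"\bprn\b")

_SPLIT_RE = re.compile(r"\bthen\b|\bincrease to\b")

Span = tuple[int, int]


class InvalidClauseError(ValueError):
    """A clause is syntactically matched but semantically invalid (e.g. q0h)."""


@dataclass(frozen=True)
class PeriodSpan:
    """One medication-period slice of the normalized sig."""

    index: int
    text: str
    start: int  # offset of `text` within the normalized sig
    start_condition_text: str = ""


@dataclass
class IntervalMatch:
    low: int
    high: int
    unit: str  # hour | day | week | month
    prn: bool
    spans: list[Span]


@dataclass
class FrequencyMatch:
    low: Fraction
    high: Fraction
    spans: list[Span]


@dataclass
class DoseMatch:
    dose_low: Decimal
    dose_high: Decimal
    dose_unit: str
    strength_low: Optional[Decimal]
    strength_high: Optional[Decimal]
    strength_unit: Optional[str]
    spans: list[Span]


@dataclass
class DurationMatch:
    low: Decimal
    high: Decimal
    unit: str
    spans: list[Span]


@dataclass
class ExtractedClauses:
    """All clause matches for one period span, after reconciliation.

    At most one of (frequency, interval) survives reconciliation: when both
    match, the interval wins (it is the more specific statement) but both
    matched spans count as consumed.
    """

    dose: Optional[DoseMatch] = None
    frequency: Optional[FrequencyMatch] = None
    interval: Optional[IntervalMatch] = None
    duration: Optional[DurationMatch] = None
    prn: bool = False
    consumed_spans: list[Span] = field(default_factory=list)


def split_periods(normalized_text: str) -> list[PeriodSpan]:
    """Split on the titration keywords "then" and "increase to".

    Returns spans in textual order with their offsets into the normalized sig;
    empty slices (e.g. a trailing "then") are dropped.
    """
    spans: list[PeriodSpan] = []
    pos = 0
    pieces: list[tuple[int, str]] = []
    for m in _SPLIT_RE.finditer(normalized_text):
        pieces.append((pos, normalized_text[pos:m.start()]))
        pos = m.end()
    pieces.append((pos, normalized_text[pos:]))
    idx = 0
    for start, piece in pieces:
        stripped = piece.strip()
        if not stripped:
            continue
        offset = start + piece.index(stripped[0])
        spans.append(PeriodSpan(index=idx, text=stripped, start=offset))
        idx += 1
    return spans


def extract_interval(span_text: str) -> Optional[IntervalMatch]:
    """Parse q-notation or an "every N [to M] unit" clause into an interval.

    A single value yields low == high; a bare "qN" with no unit suffix means
    hours; a "prn" suffix marks as-needed dosing.
    """
    m = INTERVAL_PATTERN.search(span_text)
    if m is not None:
        low = int(m.group(_G_LOW))
        high = int(m.group(_G_HIGH)) if m.group(_G_HIGH) else low
        suffix = m.group(_G_SUFFIX) or ""
        prn = suffix == "prn"
        unit = {"hr": "hour", "h": "hour", "": "hour", "prn": "hour"}.get(suffix, suffix)
        rest = span_text[m.end():].lstrip()
        if rest.startswith("prn"):
            prn = True
        return IntervalMatch(low=low, high=high, unit=unit, prn=prn, spans=[m.span()])
    m = _EVERY_N_RE.search(span_text)
    if m is not None:
        low = int(m.group(1))
        high = int(m.group(2)) if m.group(2) else low
        unit = {"hr": "hour", "h": "hour"}.get(m.group(3), m.group(3))
        prn = bool(_PRN_RE.search(span_text[m.end():]))
        return IntervalMatch(low=low, high=high, unit=unit, prn=prn, spans=[m.span()])
    return None


def extract_frequency(span_text: str) -> Optional[FrequencyMatch]:
    """Map a frequency phrase to administrations per day.

    "N times daily" → N; "every day"/"daily"/"nightly"/"every morning" → 1;
    "every other day" → 1/2; "weekly" → 1/7; ranges map to (low, high).
    """
    m = _FREQ_N_TIMES_RE.search(span_text)
    if m is not None:
        low = Fraction(Decimal(m.group(1)))
        high = Fraction(Decimal(m.group(2))) if m.group(2) else low
        return FrequencyMatch(low=low, high=high, spans=[m.span()])
    m = _FREQ_N_WEEKLY_RE.search(span_text)
    if m is not None:
        f = Fraction(int(m.group(1)), 7)
        return FrequencyMatch(low=f, high=f, spans=[m.span()])
    m = _FREQ_EOD_RE.search(span_text)
    if m is not None:
        return FrequencyMatch(low=Fraction(1, 2), high=Fraction(1, 2), spans=[m.span()])
    m = _FREQ_DAILY_RE.search(span_text)
    if m is not None:
        return FrequencyMatch(low=Fraction(1), high=Fraction(1), spans=[m.span()])
    m = _FREQ_WEEKLY_RE.search(span_text)
    if m is not None:
        return FrequencyMatch(low=Fraction(1, 7), high=Fraction(1, 7), spans=[m.span()])
    return None


def extract_dose(span_text: str) -> Optional[DoseMatch]:
    """Extract per-administration quantity, form unit, and optional strength.

    A parenthetical "(X mg)" directly after the dose expression is the
    per-administration strength.  An inline "X mg" with no form word means the
    dose itself is stated in strength units.
    """
    m = _DOSE_RE.search(span_text)
    if m is not None:
        dose_low = canon3(m.group(1))
        dose_high = canon3(m.group(2)) if m.group(2) else dose_low
        unit = m.group(3)
        spans = [m.span()]
        s_low = s_high = None
        s_unit = None
        pm = _PAREN_STRENGTH_RE.match(span_text, m.end())
        if pm is not None:
            s_low = canon3(pm.group(1))
            s_high = canon3(pm.group(2)) if pm.group(2) else s_low
            s_unit = pm.group(3)
            spans.append(pm.span())
        else:
            im = _ADJACENT_STRENGTH_RE.match(span_text, m.end())
            if im is not None:
                s_low = canon3(im.group(1))
                s_high = canon3(im.group(2)) if im.group(2) else s_low
                s_unit = im.group(3)
                spans.append(im.span())
        return DoseMatch(dose_low, dose_high, unit, s_low, s_high, s_unit, spans)
    m = _INLINE_STRENGTH_RE.search(span_text)
    if m is not None:
        dose_low = canon3(m.group(1))
        dose_high = canon3(m.group(2)) if m.group(2) else dose_low
        return DoseMatch(dose_low, dose_high, m.group(3), None, None, None, [m.span()])
    return None


def extract_duration(span_text: str) -> Optional[DurationMatch]:
    """Extract "for N [to M] day/week/month" or "x N unit"."""
    m = _DURATION_RE.search(span_text)
    if m is not None:
        low = canon3(m.group(1))
        high = canon3(m.group(2)) if m.group(2) else low
        return DurationMatch(low=low, high=high, unit=m.group(3), spans=[m.span()])
    m = _DURATION_X_RE.search(span_text)
    if m is not None:
        v = canon3(m.group(1))
        return DurationMatch(low=v, high=v, unit=m.group(2), spans=[m.span()])
    return None


def _overlaps(span: Span, spans: list[Span]) -> bool:
    return any(span[0] < e and s < span[1] for s, e in spans)


def extract_clauses(span_text: str) -> ExtractedClauses:
    """Run all clause grammars on one period span and reconcile overlaps."""
    clauses = ExtractedClauses()
    clauses.interval = extract_interval(span_text)
    if clauses.interval is not None:
        clauses.consumed_spans.extend(clauses.interval.spans)
    # Frequency still runs when an interval matched (its span counts as
    # consumed) but the interval wins the reconciliation.
    freq = extract_frequency(span_text)
    if freq is not None:
        clauses.consumed_spans.extend(freq.spans)
        if clauses.interval is None:
            clauses.frequency = freq
    dose = extract_dose(span_text)
    if dose is not None and not any(
        _overlaps(s, clauses.consumed_spans) for s in dose.spans
    ):
        clauses.dose = dose
        clauses.consumed_spans.extend(dose.spans)
    duration = extract_duration(span_text)
    if duration is not None and not any(
        _overlaps(s, clauses.consumed_spans) for s in duration.spans
    ):
        clauses.duration = duration
        clauses.consumed_spans.extend(duration.spans)
    clauses.prn = bool(_PRN_RE.search(span_text)) or (
        clauses.interval.prn if clauses.interval else False
    )
    return clauses


_DAYS_PER = {"day": 1, "week": 7, "month": 30}


def _interval_to_frequency(iv: IntervalMatch) -> tuple[Fraction, Fraction]:
    """Invert an interval to administrations/day: q a-b hr → (24/b, 24/a)."""
    if iv.low <= 0 or iv.high <= 0:
        raise InvalidClauseError(f"non-positive interval {iv.low}-{iv.high}")
    if iv.unit == "hour":
        return Fraction(24, iv.high), Fraction(24, iv.low)
    days = _DAYS_PER[iv.unit]
    return Fraction(1, iv.high * days), Fraction(1, iv.low * days)


def _round3(f: Fraction) -> Decimal:
    return canon3(Decimal(f.numerator) / Decimal(f.denominator))


def compute_period(clauses: ExtractedClauses) -> Optional[PeriodObject]:
    """Combine clauses into a period object, or None when no daily dose follows.

    daily = dose × frequency (low×low, high×high); alt daily = strength ×
    frequency; PRN zeroes the lower bounds.  A period with no dose, or with
    neither a frequency nor an interval, yields no daily dose — there is no
    implicit once-daily default, by design: guessing manufactures false
    positives, and the method's clinical value is its precision.
    """
    if clauses.dose is None:
        return None
    if clauses.interval is not None:
        f_low, f_high = _interval_to_frequency(clauses.interval)
    elif clauses.frequency is not None:
        f_low, f_high = clauses.frequency.low, clauses.frequency.high
    else:
        return None
    d = clauses.dose
    daily_low = _round3(Fraction(d.dose_low) * f_low)
    daily_high = _round3(Fraction(d.dose_high) * f_high)
    alt_low = alt_high = None
    if d.strength_low is not None:
        alt_low = _round3(Fraction(d.strength_low) * f_low)
        alt_high = _round3(Fraction(d.strength_high) * f_high)
    if clauses.prn:
        daily_low = Decimal(0)
        if alt_low is not None:
            alt_low = Decimal(0)
    kwargs = dict(
        daily_dose_low=daily_low,
        daily_dose_high=daily_high,
        daily_dose_units=d.dose_unit,
        alt_daily_dose_low=alt_low,
        alt_daily_dose_high=alt_high,
        alt_daily_dose_units=d.strength_unit if alt_low is not None else None,
    )
    if clauses.duration is not None:
        kwargs.update(
            duration_low=clauses.duration.low,
            duration_high=clauses.duration.high,
            duration_units=clauses.duration.unit,
        )
    return PeriodObject(**kwargs)


# Numeric tokens for the uncertainty sweep: runs of digits possibly joined by
# "." or "/" so a date like 01/02/2024 is one token.
_NUM_TOKEN_RE = re.compile(r"\d+(?:[./]\d+)*")
_DATE_SLASH_RE = re.compile(r"^\d{1,2}/\d{1,2}(?:/\d{2,4})?$")
_YEAR_RE = re.compile(r"^(?:19|20)\d{2}$")
_MONTH_NAMES = (
    "january february march april may june july august september october "
    "november december jan feb mar apr jun jul aug sep sept oct nov dec"
).split()


def _is_date_like(token: str, text: str, start: int, end: int) -> bool:
    if _DATE_SLASH_RE.match(token) or _YEAR_RE.match(token):
        return True
    before = text[:start].rstrip().split()
    after = text[end:].lstrip().split()
    neighbors = ([before[-1]] if before else []) + ([after[0]] if after else [])
    return any(n in _MONTH_NAMES for n in neighbors)


def _merge(spans: list[Span]) -> list[Span]:
    merged: list[Span] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_uncertainty(
    normalized_text: str, all_consumed_spans: list[Span]
) -> tuple[bool, list[str]]:
    """Flag numerals the grammars did not consume.

    Returns (uncertain, residual_tokens).  Date-like tokens (dd/dd,
    dd/dd/yyyy, four-digit years, month-name-adjacent numbers) are exempt.
    """
    consumed = _merge(all_consumed_spans)
    residual = []
    for m in _NUM_TOKEN_RE.finditer(normalized_text):
        covered = any(s <= m.start() and m.end() <= e for s, e in consumed)
        if covered:
            continue
        if _is_date_like(m.group(0), normalized_text, m.start(), m.end()):
            continue
        residual.append(m.group(0))
    return bool(residual), residual


def parse_sig(
    record: SigRecord,
    synonyms: Optional[SynonymTable] = None,
    stop_phrases=None,
) -> ParseResult:
    """Full pipeline: normalize → split periods → extract → flag uncertainty.

    ``status`` is ``parsed`` only when at least one period produced a daily
    dose *and* no non-date numeral was left unexplained; ``uncertain`` results
    carry no periods (downstream they count as unparsed).
    """
    if not record.text.strip():
        raise ValueError(f"sig {record.sig_id!r}: empty text")
    norm = normalize(record.text, synonyms=synonyms, stop_phrases=stop_phrases)
    spans = split_periods(norm)
    periods: list[PeriodObject] = []
    consumed: list[Span] = []
    for span in spans:
        clauses = extract_clauses(span.text)
        consumed.extend((s + span.start, e + span.start) for s, e in clauses.consumed_spans)
        period = compute_period(clauses)
        if period is not None:
            periods.append(period)
    uncertain, residual = detect_uncertainty(norm, consumed)
    if uncertain:
        return ParseResult(
            sig_id=record.sig_id,
            status=ParseStatus.UNCERTAIN,
            periods=[],
            residual_tokens=residual,
            normalized_text=norm,
        )
    if periods:
        return ParseResult(
            sig_id=record.sig_id,
            status=ParseStatus.PARSED,
            periods=periods,
            normalized_text=norm,
        )
    return ParseResult(sig_id=record.sig_id, status=ParseStatus.NO_DOSE, normalized_text=norm)
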