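"""Clause grammars, daily-dose arithmetic and the uncertainty flag."""

from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigdose.extract import (
    INTERVAL_PATTERN,
    ExtractedClauses,
    InvalidClauseError,
    IntervalMatch,
    compute_period,
    detect_uncertainty,
    extract_clauses,
    extract_dose,
    extract_duration,
    extract_frequency,
    extract_interval,
    parse_sig,
    split_periods,
)
from sigdose.model import ParseStatus, SigRecord


class TestSplitPeriods:
    def test_then_splits_two_spans(self):
        spans = split_periods("take 1 tablet daily for 1 week then 2 tablet daily")
        assert [s.text for s in spans] == [
            "take 1 tablet daily for 1 week",
            "2 tablet daily",
        ]

    def test_no_keyword_single_span(self):
        spans = split_periods("take 1 tablet daily")
        assert len(spans) == 1

    def test_increase_to_keeps_object_in_next_span(self):
        spans = split_periods("1 tablet daily increase to 2 tablet daily after 2 week")
        assert [s.text for s in spans] == [
            "1 tablet daily",
            "2 tablet daily after 2 week",
        ]

    def test_offsets_index_into_normalized_text(self):
        text = "1 tablet daily then 2 tablet daily"
        for span in split_periods(text):
            assert text[span.start : span.start + len(span.text)] == span.text


class TestInterval:
    def test_regex_q4hr(self):
        m = INTERVAL_PATTERN.search("q4hr")
        assert m is not None and m.group(5) == "4"

    def test_regex_q2_3hr_range(self):
        m = INTERVAL_PATTERN.search("q2-3hr")
        assert (m.group(5), m.group(8)) == ("2", "3")

    @pytest.mark.parametrize(
        "text, low, high, unit, prn",
        [
            ("q4hr", 4, 4, "hour", False),
            ("q2-3hr", 2, 3, "hour", False),
            ("q6h prn", 6, 6, "hour", True),
            ("take 1 tablet q12h", 12, 12, "hour", False),
            ("q8", 8, 8, "hour", False),  # bare qN defaults to hours
            ("q2day", 2, 2, "day", False),
            ("every 8 hour", 8, 8, "hour", False),
            ("every 4 to 6 hour", 4, 6, "hour", False),
        ],
    )
    def test_extract_interval(self, text, low, high, unit, prn):
        iv = extract_interval(text)
        assert (iv.low, iv.high, iv.unit, iv.prn) == (low, high, unit, prn)

    def test_no_interval_returns_none(self):
        assert extract_interval("take 1 tablet daily") is None


class TestFrequency:
    @pytest.mark.parametrize(
        "text, low, high",
        [
            ("take 1 tablet 2 times daily", 2, 2),
            ("1 tablet every other day", Fraction(1, 2), Fraction(1, 2)),
            ("1 tablet every day", 1, 1),
            ("1 tablet daily", 1, 1),
            ("1 tablet nightly", 1, 1),
            ("2 to 3 times daily", 2, 3),
            ("1 tablet weekly", Fraction(1, 7), Fraction(1, 7)),
            ("1 time daily", 1, 1),
        ],
    )
    def test_extract_frequency(self, text, low, high):
        f = extract_frequency(text)
        assert (f.low, f.high) == (Fraction(low), Fraction(high))

    def test_no_frequency_words(self):
        assert extract_frequency("no frequency words here") is None


class TestDose:
    def test_dose_with_parenthetical_strength(self):
        d = extract_dose("take 0.5 tablet (50 mg) every day")
        assert (d.dose_low, d.dose_high, d.dose_unit) == (Decimal("0.5"), Decimal("0.5"), "tablet")
        assert (d.strength_low, d.strength_high, d.strength_unit) == (
            Decimal(50), Decimal(50), "mg",
        )

    def test_range_dose_no_strength(self):
        d = extract_dose("take 1-2 tablet")
        assert (d.dose_low, d.dose_high, d.dose_unit) == (Decimal(1), Decimal(2), "tablet")
        assert d.strength_low is None

    def test_no_quantity(self):
        assert extract_dose("use as directed") is None

    def test_inline_mg_without_form_word_is_dose_in_strength_units(self):
        d = extract_dose("take 50 mg daily")
        assert (d.dose_low, d.dose_unit) == (Decimal(50), "mg")
        assert d.strength_low is None

    def test_detached_mg_clause_not_swallowed_as_strength(self):
        d = extract_dose("2 tablet daily max 90 mg")
        assert d.strength_low is None


class TestDuration:
    @pytest.mark.parametrize(
        "text, low, high, unit",
        [
            ("take 1 tablet daily for 1 week", 1, 1, "week"),
            ("for 7 to 10 day", 7, 10, "day"),
            ("x 2 month", 2, 2, "month"),
        ],
    )
    def test_extract_duration(self, text, low, high, unit):
        d = extract_duration(text)
        assert (d.low, d.high, d.unit) == (Decimal(low), Decimal(high), unit)

    def test_no_duration(self):
        assert extract_duration("take 1 tablet daily") is None


class TestComputePeriod:
    def test_strength_times_frequency_gives_alt_daily(self):
        clauses = extract_clauses("take 0.5 tablet (50 mg) every day")
        p = compute_period(clauses)
        assert (p.daily_dose_low, p.daily_dose_high) == (Decimal("0.5"), Decimal("0.5"))
        assert (p.alt_daily_dose_low, p.alt_daily_dose_high) == (Decimal(50), Decimal(50))
        assert p.alt_daily_dose_units == "mg"

    def test_dose_times_frequency(self):
        p = compute_period(extract_clauses("1 tablet 2 times daily"))
        assert (p.daily_dose_low, p.daily_dose_high) == (Decimal(2), Decimal(2))

    def test_interval_range_inversion(self):
        # q2-3hr: f = (24/3, 24/2) = (8, 12); dose 1-2 -> daily 8-24
        p = compute_period(extract_clauses("1-2 tablet q2-3hr"))
        assert (p.daily_dose_low, p.daily_dose_high) == (Decimal(8), Decimal(24))

    def test_prn_zeroes_lower_bounds(self):
        p = compute_period(extract_clauses("1 tablet (25 mg) 2 times daily prn"))
        assert p.daily_dose_low == 0
        assert p.daily_dose_high == Decimal(2)
        assert p.alt_daily_dose_low == 0
        assert p.alt_daily_dose_high == Decimal(50)

    def test_no_frequency_and_no_interval_yields_nothing(self):
        # no implicit once-daily default
        assert compute_period(extract_clauses("take 1 tablet")) is None

    def test_zero_interval_is_invalid(self):
        iv = IntervalMatch(low=0, high=0, unit="hour", prn=False, spans=[(0, 3)])
        clauses = extract_clauses("1 tablet")
        clauses.interval = iv
        with pytest.raises(InvalidClauseError):
            compute_period(clauses)

    @given(
        st.integers(1, 24),
        st.integers(0, 23),
        st.decimals(min_value="0.25", max_value=4, places=2),
        st.decimals(min_value=0, max_value=4, places=2),
    )
    def test_interval_inversion_preserves_ordering(self, a, extra, dose, dose_extra):
        b = a + extra
        clauses = extract_clauses(f"{dose}-{dose + dose_extra} tablet q{a}-{b}h")
        p = compute_period(clauses)
        assert p.daily_dose_low <= p.daily_dose_high


class TestUncertainty:
    def test_unconsumed_threshold_numeral_flags_uncertain(self):
        rec = SigRecord(sig_id="s", text="take 1 tablet daily hold if sbp less than 90")
        res = parse_sig(rec)
        assert res.status == ParseStatus.UNCERTAIN
        assert res.residual_tokens == ["90"]
        assert res.periods == []

    def test_dates_are_exempt(self):
        rec = SigRecord(sig_id="s", text="take 1 tablet daily starting 01/02/2024")
        assert parse_sig(rec).status == ParseStatus.PARSED

    def test_month_name_dates_are_exempt(self):
        rec = SigRecord(sig_id="s", text="take 1 tablet daily starting january 5")
        assert parse_sig(rec).status == ParseStatus.PARSED

    def test_all_consumed_not_uncertain(self):
        uncertain, residual = detect_uncertainty("1 tablet daily", [(0, 13)])
        assert not uncertain and residual == []


class TestParseSig:
    def test_introduction_example(self):
        res = parse_sig(SigRecord(sig_id="s", text="take one tablet twice daily"))
        assert res.status == ParseStatus.PARSED
        [p] = res.periods
        assert (p.daily_dose_low, p.daily_dose_high, p.daily_dose_units) == (
            Decimal(2), Decimal(2), "tablet",
        )

    def test_unparseable_is_no_dose(self):
        res = parse_sig(SigRecord(sig_id="s", text="use as directed"))
        assert res.status == ParseStatus.NO_DOSE

    def test_uncertain_empties_periods(self):
        res = parse_sig(
            SigRecord(sig_id="s", text="take 1 tablet daily then 2 tablets daily, max 90 mg")
        )
        assert res.status == ParseStatus.UNCERTAIN
        assert res.periods == []
        assert "90" in res.residual_tokens

    def test_empty_text_is_an_error(self):
        rec = SigRecord.model_construct(sig_id="s", text="  ")
        with pytest.raises(ValueError):
            parse_sig(rec)

    def test_titration_yields_two_periods(self):
        res = parse_sig(
            SigRecord(sig_id="s", text="take 1 tablet daily for 1 week then 2 tablets daily")
        )
        assert res.status == ParseStatus.PARSED
        assert len(res.periods) == 2
        assert res.periods[0].duration_units == "week"
        assert res.periods[1].duration_units is None

    def test_appending_hold_clause_flips_to_uncertain_without_changing_dose(self):
        base = parse_sig(SigRecord(sig_id="s", text="take 1 tablet daily"))
        held = parse_sig(SigRecord(sig_id="s", text="take 1 tablet daily hold if hr below 55"))
        assert base.status == ParseStatus.PARSED
        assert held.status == ParseStatus.UNCERTAIN
        assert held.periods == []  # never silently altered, simply withheld

    def test_determinism(self):
        rec = SigRecord(sig_id="s", text="Take 1-2 Tabs PO q4-6h PRN for 7 days")
        assert parse_sig(rec) == parse_sig(rec)

    def test_parsed_periods_satisfy_ordering_invariants(self):
        for text in [
            "take 1-2 tablet q2-3hr",
            "0.5-1 tablet (25 mg) 2 to 3 times daily for 7 to 10 day",
            "take 1 tablet every other day",
        ]:
            res = parse_sig(SigRecord(sig_id="s", text=text))
            for p in res.periods:
                assert p.daily_dose_low <= p.daily_dose_high
                if p.alt_daily_dose_low is not None:
                    assert p.alt_daily_dose_low <= p.alt_daily_dose_high
                if p.duration_low is not None:
                    assert p.duration_low <= p.duration_high
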