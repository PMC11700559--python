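"""Core domain types for sig parsing.

A *sig* (prescription signature) is the free-text instruction on a medication
order, e.g. ``"take one tablet twice daily"``.  The structured target is a list
of *period objects*: one per contiguous medication period, each carrying the
daily dose range, an optional alternate (mass/volume) daily dose, and an
optional duration.  Titration sigs ("1 tablet daily for 1 week then 2 tablets
daily") chain several periods.

Dose and duration quantities are held as :class:`~decimal.Decimal` canonicalized
to at most three decimal places, so equality comparisons and serialization are
exact — no binary-float drift across a write/read round trip.
"""

from __future__ import annotations

import enum
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_serializer, field_validator, model_validator

__all__ = [
    "canon3",
    "PeriodObject",
    "SigRecord",
    "ParseStatus",
    "ParseResult",
]

_Q3 = Decimal("0.001")


def canon3(value: Decimal | int | float | str) -> Decimal:
    """Canonicalize a quantity to at most 3 decimal places, trailing zeros stripped.

    This is the single rounding contract shared by every producer of dose
    numbers in the package; two quantities are "equal" iff their canonical
    forms are equal.
    """
    d = Decimal(str(value)) if not isinstance(value, Decimal) else value
    d = d.quantize(_Q3, rounding=ROUND_HALF_UP)
    if d == d.to_integral_value():
        return d.quantize(Decimal(1))
    return d.normalize()


class PeriodObject(BaseModel):
    """One medication period's structured dosage.

    ``daily_dose_*`` is the total per-day intake in form units (tablet,
    capsule, ...); ``alt_daily_dose_*`` is the same quantity in mass/volume
    units (mg, mcg, mL) when the sig states a strength; ``duration_*`` bounds
    how long the period lasts.  PRN (as-needed) periods have
    ``daily_dose_low`` (and alt low) of 0.
    """

    model_config = ConfigDict(frozen=True)

    optional_period: bool = False
    start_condition: str = ""
    daily_dose_low: Decimal
    daily_dose_high: Decimal
    daily_dose_units: str
    alt_daily_dose_low: Optional[Decimal] = None
    alt_daily_dose_high: Optional[Decimal] = None
    alt_daily_dose_units: Optional[str] = None
    duration_low: Optional[Decimal] = None
    duration_high: Optional[Decimal] = None
    duration_units: Optional[str] = None
    hold_condition: str = ""

    @field_validator(
        "daily_dose_low",
        "daily_dose_high",
        "alt_daily_dose_low",
        "alt_daily_dose_high",
        "duration_low",
        "duration_high",
        mode="before",
    )
    @classmethod
    def _canonize(cls, v):
        if v is None or (isinstance(v, str) and v == ""):
            return None
        d = canon3(v)
        if d < 0:
            raise ValueError("dose/duration quantities must be non-negative")
        return d

    @field_validator("alt_daily_dose_units", "duration_units", mode="before")
    @classmethod
    def _empty_to_none(cls, v):
        if isinstance(v, str) and v == "":
            return None
        return v

    @model_validator(mode="after")
    def _check_invariants(self) -> "PeriodObject":
        if self.daily_dose_low > self.daily_dose_high:
            raise ValueError("daily_dose_low > daily_dose_high")
        alt = (self.alt_daily_dose_low, self.alt_daily_dose_high, self.alt_daily_dose_units)
        if any(v is not None for v in alt) and not all(v is not None for v in alt):
            raise ValueError("alt daily dose fields must be jointly present or jointly empty")
        if self.alt_daily_dose_low is not None and self.alt_daily_dose_low > self.alt_daily_dose_high:
            raise ValueError("alt_daily_dose_low > alt_daily_dose_high")
        if (self.duration_low is not None or self.duration_high is not None) and self.duration_units is None:
            raise ValueError("duration bounds present without duration_units")
        if self.duration_units is not None and self.duration_units not in ("day", "week", "month"):
            raise ValueError(f"duration_units must be day/week/month, got {self.duration_units!r}")
        if (
            self.duration_low is not None
            and self.duration_high is not None
            and self.duration_low > self.duration_high
        ):
            raise ValueError("duration_low > duration_high")
        return self

    @field_serializer(
        "daily_dose_low",
        "daily_dose_high",
        "alt_daily_dose_low",
        "alt_daily_dose_high",
        "duration_low",
        "duration_high",
    )
    def _ser_decimal(self, v: Optional[Decimal], _info):
        return None if v is None else str(v)


class SigRecord(BaseModel):
    """One free-text sig, optionally with gold annotations and group labels.

    ``gold`` distinguishes absent from empty: ``None`` means the sig is
    unannotated; an empty list means the annotator judged that no daily dose
    is extractable from this sig.
    """

    model_config = ConfigDict(frozen=True)

    sig_id: str
    text: str
    groups: dict[str, str] = {}
    gold: Optional[list[PeriodObject]] = None

    @field_validator("text")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("sig text must be non-empty after trimming")
        return v


class ParseStatus(str, enum.Enum):
    PARSED = "parsed"
    NO_DOSE = "no_dose"
    UNCERTAIN = "uncertain"


class ParseResult(BaseModel):
    """Outcome of parsing one sig.

    ``uncertain`` is the safety status: numerals that are not dates remained in
    the sig after extraction, so any tentative periods are discarded and the
    offending numeric tokens are listed in ``residual_tokens`` for audit.
    """

    model_config = ConfigDict(frozen=True)

    sig_id: str
    status: ParseStatus
    periods: list[PeriodObject] = []
    residual_tokens: list[str] = []
    normalized_text: str = ""

    @model_validator(mode="after")
    def _check_invariants(self) -> "ParseResult":
        if self.status == ParseStatus.PARSED and not self.periods:
            raise ValueError("status=parsed requires at least one period")
        if self.status == ParseStatus.UNCERTAIN and not self.residual_tokens:
            raise ValueError("status=uncertain requires residual_tokens")
        if self.status != ParseStatus.PARSED and self.periods:
            raise ValueError("periods must be empty unless status=parsed")
        return self

    @field_serializer("status")
    def _ser_status(self, v: ParseStatus, _info):
        return v.value
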