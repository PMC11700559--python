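"""Synthetic gold-annotated sig generator.

Emulates the structural variety of real HFrEF prescription sigs: single- and
multi-period titrations (up to 5 periods joined by "then"/"increase to"),
range doses, PRN clauses, parenthetical strengths, duration clauses,
hold-condition clauses containing numerals, and sigs with no extractable
daily dose.  Every record carries gold period objects computed from the
template parameters by the daily-dosage arithmetic contract
(daily = dose × administrations/day, interval inversion, PRN low = 0) —
implemented here *independently* of the extractor so parser-vs-gold tests are
an oracle comparison, not a tautology.

Noise operators perturb the rendered text only within the normalizer's
inverse image (abbreviations, number words, fraction literals, route/filler
insertions, casing), so the parser is expected to recover the gold exactly on
every non-adversarial record.  Hold-condition records are the deliberate
exception: they carry an ``expect_uncertain`` flag because their trailing
numeral must trip the parser's uncertainty flag.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .model import PeriodObject, SigRecord

__all__ = ["SynthConfig", "SynthRecord", "generate", "corpus_stats"]

DRUG_CLASSES = (
    "ACE inhibitor",
    "beta blocker",
    "ARB",
    "ARNI",
    "SGLT-2 inhibitor",
    "MRA",
)


class SynthConfig(BaseModel):
    """Distributional knobs for the generator; defaults are the study conditions."""

    model_config = ConfigDict(frozen=True)

    n_sigs: int = Field(ge=0)
    seed: int
    max_periods: int = Field(default=5, ge=1, le=5)
    p_multi_period: float = Field(default=0.3, ge=0, le=1)
    p_range_dose: float = Field(default=0.1, ge=0, le=1)
    p_prn: float = Field(default=0.1, ge=0, le=1)
    p_strength_paren: float = Field(default=0.25, ge=0, le=1)
    p_duration: float = Field(default=0.3, ge=0, le=1)
    p_no_dose: float = Field(default=0.1, ge=0, le=1)
    p_hold_condition: float = Field(default=0.05, ge=0, le=1)
    noise_level: float = Field(default=0.5, ge=0, le=1)
    drug_classes: tuple[str, ...] = DRUG_CLASSES


@dataclass(frozen=True)
class SynthRecord:
    """A generated sig with provenance: which template, which noise operators."""

    record: SigRecord
    template_id: str
    noise_applied: tuple[str, ...] = ()
    expect_uncertain: bool = False


# ---------------------------------------------------------------------------
# Independent gold arithmetic (the oracle side of the shared dosage contract)

_Q3 = Decimal("0.001")


def _dec3(fr: Fraction) -> Decimal:
    d = (Decimal(fr.numerator) / Decimal(fr.denominator)).quantize(_Q3, ROUND_HALF_UP)
    return d.quantize(Decimal(1)) if d == d.to_integral_value() else d.normalize()


def _gold_daily(
    dose_low: Decimal,
    dose_high: Decimal,
    f_low: Fraction,
    f_high: Fraction,
    prn: bool,
) -> tuple[Decimal, Decimal]:
    low = Fraction(dose_low) * f_low
    high = Fraction(dose_high) * f_high
    if prn:
        low = Fraction(0)
    return _dec3(low), _dec3(high)


# ---------------------------------------------------------------------------
# Template menus.  Each frequency entry is (canonical phrase, f_low, f_high)
# with f in administrations per day; interval-style entries carry the already
# inverted frequency so the gold side never calls extractor code.

_FREQ_MENU: list[tuple[str, Fraction, Fraction]] = [
    ("every day", Fraction(1), Fraction(1)),
    ("daily", Fraction(1), Fraction(1)),
    ("2 times daily", Fraction(2), Fraction(2)),
    ("3 times daily", Fraction(3), Fraction(3)),
    ("4 times daily", Fraction(4), Fraction(4)),
    ("every other day", Fraction(1, 2), Fraction(1, 2)),
    ("every morning", Fraction(1), Fraction(1)),
    ("nightly", Fraction(1), Fraction(1)),
    ("q12h", Fraction(24, 12), Fraction(24, 12)),
    ("q8h", Fraction(24, 8), Fraction(24, 8)),
    ("q6h", Fraction(24, 6), Fraction(24, 6)),
    ("q4-6h", Fraction(24, 6), Fraction(24, 4)),
    ("every 8 hour", Fraction(24, 8), Fraction(24, 8)),
    ("weekly", Fraction(1, 7), Fraction(1, 7)),
]

# Simple daily-only frequencies used for titration chains (interval notation
# mid-titration is unrealistic).
_TITRATION_FREQS = [e for e in _FREQ_MENU if e[0] in ("every day", "daily", "2 times daily")]

_DOSE_MENU: dict[str, list[str]] = {
    "tablet": ["0.5", "1", "1.5", "2", "3"],
    "capsule": ["1", "2", "3"],
    "pill": ["1", "2"],
}
_UNIT_WEIGHTS = [("tablet", 0.7), ("capsule", 0.2), ("pill", 0.1)]

_STRENGTH_MENU = ["12.5", "25", "50", "100"]

_DURATION_MENU = [
    ("for 1 week", "1", "1", "week"),
    ("for 2 week", "2", "2", "week"),
    ("for 7 day", "7", "7", "day"),
    ("for 7 to 10 day", "7", "10", "day"),
    ("for 1 month", "1", "1", "month"),
]

_NO_DOSE_TEMPLATES = [
    "use as directed",
    "take as directed",
    "take as directed by your provider",
    "use per package instructions",
]

_HOLD_CLAUSES = [
    "hold if sbp less than 90",
    "hold if sbp greater than 180",
    "hold if heart rate below 55",
    "hold if blood sugar less than 70",
]

_WORDS = {
    "1": "one", "2": "two", "3": "three", "4": "four", "5": "five",
    "6": "six", "7": "seven", "8": "eight", "9": "nine", "10": "ten",
}

_FREQ_VARIANTS: dict[str, list[str]] = {
    "2 times daily": ["twice daily", "bid", "2 times a day"],
    "3 times daily": ["tid", "thrice daily", "3 times per day"],
    "4 times daily": ["qid"],
    "every day": ["qd", "qday", "once daily", "each day"],
    "daily": ["every day", "qdaily"],
    "every other day": ["qod"],
    "nightly": ["qhs", "at bedtime", "every night"],
    "every morning": ["qam"],
}


# ---------------------------------------------------------------------------
# Noise operators: each is the inverse image of a normalizer rule, so the
# parser recovers the canonical form.  An operator returns None when it does
# not apply to the given text.


def _noise_word_number(text: str, rng: random.Random) -> Optional[str]:
    # letter-adjacency excluded so q-notation tokens like "q4-6h" stay intact
    m = re.search(r"(?<![\w.])([1-9]|10)(?![\w.])", text)
    if m is None:
        return None
    return text[: m.start()] + _WORDS[m.group(1)] + text[m.end():]


def _noise_half_fraction(text: str, rng: random.Random) -> Optional[str]:
    if re.search(r"(?<!\d)0\.5(?!\d)", text) is None:
        return None
    return re.sub(r"(?<!\d)0\.5(?!\d)", "1/2", text, count=1)


def _noise_abbrev_form(text: str, rng: random.Random) -> Optional[str]:
    for canonical, shorts in (("tablet", ["tab", "tabs"]), ("capsule", ["cap", "caps"])):
        if re.search(rf"\b{canonical}\b", text):
            return re.sub(rf"\b{canonical}\b", rng.choice(shorts), text)
    return None


def _noise_abbrev_time(text: str, rng: random.Random) -> Optional[str]:
    for canonical, short in (("week", "wk"), ("month", "mo")):
        if re.search(rf"\b{canonical}\b", text):
            return re.sub(rf"\b{canonical}\b", short, text)
    return None


def _noise_prn_phrase(text: str, rng: random.Random) -> Optional[str]:
    if re.search(r"\bprn\b", text) is None:
        return None
    return re.sub(r"\bprn\b", "as needed", text)


def _noise_route(text: str, rng: random.Random) -> Optional[str]:
    m = re.search(r"\b(tablet|capsule|pill)\b", text)
    if m is None:
        return None
    route = rng.choice(["by mouth", "po", "orally"])
    return text[: m.end()] + " " + route + text[m.end():]


def _noise_filler(text: str, rng: random.Random) -> Optional[str]:
    return text + " " + rng.choice(["with food", "with water", "with meals"])


def _noise_casing(text: str, rng: random.Random) -> Optional[str]:
    return text.upper() if rng.random() < 0.5 else text.capitalize()


def _noise_politeness(text: str, rng: random.Random) -> Optional[str]:
    return "please " + text


_NOISE_OPS = [
    ("word_number", _noise_word_number),
    ("half_fraction", _noise_half_fraction),
    ("abbrev_form", _noise_abbrev_form),
    ("abbrev_time", _noise_abbrev_time),
    ("prn_phrase", _noise_prn_phrase),
    ("route", _noise_route),
    ("filler", _noise_filler),
    ("politeness", _noise_politeness),
    ("casing", _noise_casing),
]


def _noise_freq_variant(text: str, freq_phrase: str, rng: random.Random) -> Optional[str]:
    variants = _FREQ_VARIANTS.get(freq_phrase)
    if not variants or freq_phrase not in text:
        return None
    return text.replace(freq_phrase, rng.choice(variants))


# ---------------------------------------------------------------------------


def _weighted_choice(rng: random.Random, pairs: list[tuple[str, float]]) -> str:
    r = rng.random()
    acc = 0.0
    for value, w in pairs:
        acc += w
        if r < acc:
            return value
    return pairs[-1][0]


def _gen_period(
    rng: random.Random,
    config: SynthConfig,
    unit: str,
    freq: tuple[str, Fraction, Fraction],
    with_duration: bool,
    prn: bool,
    strength: Optional[str],
) -> tuple[str, PeriodObject]:
    """Render one period's text and its independently computed gold object."""
    phrase, f_low, f_high = freq
    dose_low_s = rng.choice(_DOSE_MENU[unit])
    dose_low = Decimal(dose_low_s)
    if rng.random() < config.p_range_dose:
        dose_high = dose_low + Decimal(1)
        dose_text = f"{dose_low_s}-{dose_high}"
    else:
        dose_high = dose_low
        dose_text = dose_low_s
    parts = [f"take {dose_text} {unit}"]
    alt_low = alt_high = None
    alt_units = None
    if strength is not None:
        parts.append(f"({strength} mg)")
        s = Decimal(strength)
        alt_low = _dec3(Fraction(s) * f_low)
        alt_high = _dec3(Fraction(s) * f_high)
        if prn:
            alt_low = Decimal(0)
        alt_units = "mg"
    parts.append(phrase)
    dur_low = dur_high = None
    dur_units = None
    if with_duration:
        dur_text, lo, hi, dur_units = rng.choice(_DURATION_MENU)
        parts.append(dur_text)
        dur_low, dur_high = Decimal(lo), Decimal(hi)
    if prn:
        parts.append("prn")
    daily_low, daily_high = _gold_daily(dose_low, dose_high, f_low, f_high, prn)
    gold = PeriodObject(
        daily_dose_low=daily_low,
        daily_dose_high=daily_high,
        daily_dose_units=unit,
        alt_daily_dose_low=alt_low,
        alt_daily_dose_high=alt_high,
        alt_daily_dose_units=alt_units,
        duration_low=dur_low,
        duration_high=dur_high,
        duration_units=dur_units,
    )
    return " ".join(parts), gold


def _gen_record(rng: random.Random, config: SynthConfig, index: int) -> SynthRecord:
    sig_id = f"synth-{index:05d}"
    groups = {
        "drug_class": rng.choice(list(config.drug_classes)),
        "sex": rng.choice(["F", "M"]),
    }
    if rng.random() < config.p_no_dose:
        text = rng.choice(_NO_DOSE_TEMPLATES)
        text, applied = _apply_noise(text, None, rng, config.noise_level)
        return SynthRecord(
            record=SigRecord(sig_id=sig_id, text=text, groups=groups, gold=[]),
            template_id="no_dose",
            noise_applied=applied,
        )

    multi = config.max_periods > 1 and rng.random() < config.p_multi_period
    unit = _weighted_choice(rng, _UNIT_WEIGHTS)
    strength = rng.choice(_STRENGTH_MENU) if (
        unit in ("tablet", "capsule") and rng.random() < config.p_strength_paren
    ) else None

    if multi:
        k = rng.randint(2, config.max_periods)
        freq = rng.choice(_TITRATION_FREQS)
        pieces: list[str] = []
        gold: list[PeriodObject] = []
        for j in range(k):
            final = j == k - 1
            piece, g = _gen_period(
                rng, config, unit, freq,
                with_duration=not final,
                prn=False,
                strength=strength,
            )
            pieces.append(piece)
            gold.append(g)
        joined = pieces[0]
        for piece in pieces[1:]:
            joiner = rng.choice(["then", "increase to"])
            body = piece[len("take "):] if joiner == "increase to" else piece
            joined = f"{joined} {joiner} {body}"
        text, applied = _apply_noise(joined, freq[0], rng, config.noise_level)
        return SynthRecord(
            record=SigRecord(sig_id=sig_id, text=text, groups=groups, gold=gold),
            template_id=f"multi{k}",
            noise_applied=applied,
        )

    freq = rng.choice(_FREQ_MENU)
    prn = rng.random() < config.p_prn
    with_duration = rng.random() < config.p_duration
    text, g = _gen_period(rng, config, unit, freq, with_duration, prn, strength)
    hold = rng.random() < config.p_hold_condition
    template_id = "single_prn" if prn else "single"
    if hold:
        clause = rng.choice(_HOLD_CLAUSES)
        text = f"{text} {clause}"
        g = g.model_copy(update={"hold_condition": clause})
        template_id += "_hold"
    text, applied = _apply_noise(text, freq[0], rng, config.noise_level)
    return SynthRecord(
        record=SigRecord(sig_id=sig_id, text=text, groups=groups, gold=[g]),
        template_id=template_id,
        noise_applied=applied,
        expect_uncertain=hold,
    )


def _apply_noise(
    text: str, freq_phrase: Optional[str], rng: random.Random, noise_level: float
) -> tuple[str, tuple[str, ...]]:
    applied: list[str] = []
    if freq_phrase is not None and rng.random() < noise_level:
        out = _noise_freq_variant(text, freq_phrase, rng)
        if out is not None:
            text = out
            applied.append("freq_variant")
    for name, op in _NOISE_OPS:
        if rng.random() < noise_level:
            out = op(text, rng)
            if out is not None and out != text:
                text = out
                applied.append(name)
    return text, tuple(applied)


def generate(config: SynthConfig) -> list[SynthRecord]:
    """Generate a gold-annotated corpus; byte-identical for equal (seed, config)."""
    rng = random.Random(config.seed)
    return [_gen_record(rng, config, i) for i in range(config.n_sigs)]


def corpus_stats(records: list[SynthRecord]) -> dict:
    """Realized corpus proportions, for comparison against the config knobs."""
    if not records:
        raise ValueError("corpus_stats requires a non-empty corpus")
    n = len(records)
    no_dose = sum(r.record.gold == [] for r in records)
    multi = sum(r.record.gold is not None and len(r.record.gold) > 1 for r in records)
    prn = sum(r.template_id.startswith("single_prn") for r in records)
    uncertain = sum(r.expect_uncertain for r in records)
    texts = {r.record.text for r in records}
    return {
        "n": n,
        "no_dose_fraction": no_dose / n,
        "multi_period_fraction": multi / n,
        "prn_fraction": prn / n,
        "expect_uncertain_fraction": uncertain / n,
        "unique_text_ratio": len(texts) / n,
    }
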