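"""Deterministic lexical normalization of sig text.

The pipeline rewrites a raw sig into a canonical form the extraction grammars
are written against:

1. lowercase and collapse whitespace;
2. :func:`words_to_numbers` — spelled-out quantities ("one", "half",
   "two and a half") and fraction literals ("1/2") become decimal numerals;
3. :func:`apply_synonyms` — abbreviations and variant phrasings are expanded
   ("wk" → "week", "bid" → "2 times daily", "twice" → "2 times");
4. :func:`strip_irrelevant` — route phrases, filler and punctuation noise are
   removed; this stage can never remove a numeral.

The stage order matters: synonym keys are written against numeric forms
("2 times"), and stripping runs last so no numeral is eaten before extraction.
``normalize`` is idempotent and fully deterministic.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .model import canon3

__all__ = [
    "SynonymTable",
    "words_to_numbers",
    "apply_synonyms",
    "strip_irrelevant",
    "normalize",
    "load_stop_phrases",
    "default_stop_phrases",
]

_WORD_NUMBERS = {
    "zero": "0", "one": "1", "two": "2", "three": "3", "four": "4",
    "five": "5", "six": "6", "seven": "7", "eight": "8", "nine": "9",
    "ten": "10", "eleven": "11", "twelve": "12", "thirteen": "13",
    "fourteen": "14", "fifteen": "15", "sixteen": "16", "seventeen": "17",
    "eighteen": "18", "nineteen": "19", "twenty": "20",
}
_WORD_NUMBER_RE = re.compile(r"\b(" + "|".join(_WORD_NUMBERS) + r")\b")

# "1/2" but not a date component: 1-2 digit numerator/denominator with no
# adjacent digit or slash (excludes 01/02/2024 and year-adjacent forms).
_FRACTION_RE = re.compile(r"(?<![\d/.])(\d{1,2})/(\d{1,2})(?![\d/])")
_ONE_HALF_RE = re.compile(r"\bone[- ]half\b")
_N_AND_HALF_RE = re.compile(r"\b(\d+(?:\.\d+)?) and (?:a half|an half|0\.5)\b")
_HALF_A_RE = re.compile(r"\bhalf (?:a |an )?")
_HALF_RE = re.compile(r"\bhalf\b")


def words_to_numbers(text: str) -> str:
    """Rewrite spelled-out quantities and fraction literals as decimal numerals.

    Handles cardinal words up to twenty, "half"/"one-half", "N and a half",
    and fraction literals like "1/2" (date-like tokens such as 01/02/2024 are
    exempt).  Non-matching text passes through untouched.
    """
    def _frac(m: re.Match) -> str:
        denominator = int(m.group(2))
        if denominator == 0:
            return m.group(0)
        return str(canon3(int(m.group(1)) / denominator))

    t = _FRACTION_RE.sub(_frac, text)
    t = _ONE_HALF_RE.sub("0.5", t)
    t = _WORD_NUMBER_RE.sub(lambda m: _WORD_NUMBERS[m.group(1)], t)
    t = _N_AND_HALF_RE.sub(lambda m: str(canon3(float(m.group(1)) + 0.5)), t)
    t = _HALF_A_RE.sub("0.5 ", t)
    t = _HALF_RE.sub("0.5", t)
    return t


class SynonymTable:
    """Ordered surface→canonical rewrite table.

    Keys are matched case-insensitively on word boundaries, longest key first,
    in a single simultaneous pass (so a replacement's output is never itself
    rewritten).  The table is validated to be idempotent at construction: no
    canonical form may contain another key.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries = sorted(entries, key=lambda kv: -len(kv[0]))
        if not self.entries:
            self._pattern = None
            return
        self._map = {k.lower(): v for k, v in self.entries}
        alternation = "|".join(re.escape(k) for k, _ in self.entries)
        self._pattern = re.compile(r"\b(?:" + alternation + r")\b", re.IGNORECASE)
        for _, canonical in self.entries:
            if self.apply(canonical) != canonical:
                raise ValueError(
                    f"synonym table not idempotent: canonical form {canonical!r} "
                    "contains another key"
                )

    def apply(self, text: str) -> str:
        if self._pattern is None:
            return text
        return self._pattern.sub(lambda m: self._map[m.group(0).lower()], text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        entries = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            surface, _, canonical = line.partition("\t")
            if not _:
                raise ValueError(f"bad synonym line (no tab): {line!r}")
            entries.append((surface.strip(), canonical.strip()))
        return cls(entries)

    @classmethod
    def default(cls) -> "SynonymTable":
        with resources.as_file(resources.files("sigdose.data") / "synonyms.tsv") as p:
            return cls.from_tsv(p)


def apply_synonyms(text: str, table: Optional[SynonymTable] = None) -> str:
    """Replace every table key with its canonical form, word-boundary safe."""
    if table is None:
        table = _default_synonyms()
    return table.apply(text)


def load_stop_phrases(path: str | Path) -> list[str]:
    phrases = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if any(c.isdigit() for c in line):
            raise ValueError(f"stop phrase may not contain digits: {line!r}")
        phrases.append(line)
    return phrases


def default_stop_phrases() -> list[str]:
    with resources.as_file(resources.files("sigdose.data") / "stop_phrases.tsv") as p:
        return load_stop_phrases(p)


_SYNONYMS_CACHE: Optional[SynonymTable] = None
_STOP_CACHE: Optional[list[str]] = None


def _default_synonyms() -> SynonymTable:
    global _SYNONYMS_CACHE
    if _SYNONYMS_CACHE is None:
        _SYNONYMS_CACHE = SynonymTable.default()
    return _SYNONYMS_CACHE


def _default_stop() -> list[str]:
    global _STOP_CACHE
    if _STOP_CACHE is None:
        _STOP_CACHE = default_stop_phrases()
    return _STOP_CACHE


# Punctuation noise: periods not inside a decimal number, plus clause
# punctuation.  Parentheses, hyphens and slashes are meaningful and kept.
_PUNCT_RE = re.compile(r"[;:!?\"]|,|(?<!\d)\.|\.(?!\d)")


def strip_irrelevant(text: str, stop_phrases: Optional[Iterable[str]] = None) -> str:
    """Remove stop phrases (routes, filler) and punctuation noise.

    Stop phrases are guaranteed digit-free at load time, so this stage can
    never remove a numeral.
    """
    phrases = list(stop_phrases) if stop_phrases is not None else _default_stop()
    t = text
    if phrases:
        alternation = "|".join(re.escape(p) for p in sorted(phrases, key=len, reverse=True))
        t = re.sub(r"\b(?:" + alternation + r")\b", " ", t, flags=re.IGNORECASE)
    t = _PUNCT_RE.sub(" ", t)
    return t


def normalize(
    text: str,
    synonyms: Optional[SynonymTable] = None,
    stop_phrases: Optional[Iterable[str]] = None,
) -> str:
    """Full normalization pipeline; idempotent and deterministic."""
    t = " ".join(text.lower().split())
    t = words_to_numbers(t)
    t = apply_synonyms(t, synonyms)
    t = strip_irrelevant(t, stop_phrases)
    return " ".join(t.split())
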