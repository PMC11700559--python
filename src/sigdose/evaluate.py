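"""Exact-match evaluation of parse results against gold annotations.

The unit of analysis is the whole sig.  A sig counts as correctly extracted
only when every medication period matches the gold standard exactly on the
daily-dosage variables (daily dose low/high/units, alternate daily dose
low/high/units, duration low/high/units); ``optional_period``,
``start_condition`` and ``hold_condition`` are outside the scope of daily
dosage and are ignored.  Confusion semantics:

* TP — a daily dose was extracted and is correct;
* FP — a daily dose was extracted but is incorrect (including extraction from
  a sig whose gold says nothing was extractable);
* TN — nothing extracted, and the gold agrees nothing was extractable;
* FN — nothing extracted (including ``uncertain`` results, which count as
  unparsed) although the gold has a daily dose.

PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 = 2·PPV·sens/(PPV+sens).
A zero denominator leaves the metric *undefined* (``None``), never 0 — silent
zeros distort subgroup tables on small groups.

The paired permutation test compares two parsers on the same sigs: the
statistic is the difference in F1 computed from per-sig confusion cells, the
null swaps each sig's paired cells with probability ½, and the two-sided
p-value uses add-one smoothing: (1 + #{|stat*| ≥ |stat|})/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .model import ParseResult, ParseStatus, PeriodObject, SigRecord, canon3

__all__ = [
    "Cell",
    "ConfusionCounts",
    "Metrics",
    "PermutationResult",
    "match_periods",
    "classify_sig",
    "count_cells",
    "compute_metrics",
    "f1_score",
    "subgroup_metrics",
    "permutation_test",
    "evaluate",
]

Cell = Literal["TP", "FP", "TN", "FN"]

# Canonical spellings for unit tokens so "tab" and "tablet" compare equal even
# if a gold file was written with abbreviated units.
_UNIT_CANON = {
    "tab": "tablet", "tabs": "tablet", "tablets": "tablet",
    "cap": "capsule", "caps": "capsule", "capsules": "capsule",
    "pills": "pill",
    "milliliter": "ml", "milliliters": "ml", "cc": "ml",
    "milligram": "mg", "milligrams": "mg",
    "microgram": "mcg", "micrograms": "mcg", "ug": "mcg",
    "days": "day", "weeks": "week", "months": "month",
}


def _canon_unit(u: Optional[str]) -> Optional[str]:
    if u is None:
        return None
    u = u.lower()
    return _UNIT_CANON.get(u, u)


def _num_eq(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return canon3(a) == canon3(b)


def match_periods(predicted: Sequence[PeriodObject], gold: Sequence[PeriodObject]) -> bool:
    """True iff both lists agree position-wise on every daily-dosage variable."""
    if len(predicted) != len(gold):
        return False
    for p, g in zip(predicted, gold):
        if not (
            _num_eq(p.daily_dose_low, g.daily_dose_low)
            and _num_eq(p.daily_dose_high, g.daily_dose_high)
            and _canon_unit(p.daily_dose_units) == _canon_unit(g.daily_dose_units)
            and _num_eq(p.alt_daily_dose_low, g.alt_daily_dose_low)
            and _num_eq(p.alt_daily_dose_high, g.alt_daily_dose_high)
            and _canon_unit(p.alt_daily_dose_units) == _canon_unit(g.alt_daily_dose_units)
            and _num_eq(p.duration_low, g.duration_low)
            and _num_eq(p.duration_high, g.duration_high)
            and _canon_unit(p.duration_units) == _canon_unit(g.duration_units)
        ):
            return False
    return True


def classify_sig(result: ParseResult, gold: Optional[Sequence[PeriodObject]]) -> Cell:
    """Assign one confusion cell; ``uncertain`` counts as not extracted."""
    if gold is None:
        raise ValueError(f"sig {result.sig_id!r} is unannotated; cannot score")
    extracted = result.status == ParseStatus.PARSED
    if extracted:
        return "TP" if match_periods(result.periods, gold) else "FP"
    return "TN" if len(gold) == 0 else "FN"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def count_cells(cells: Sequence[Cell]) -> ConfusionCounts:
    return ConfusionCounts(
        tp=sum(c == "TP" for c in cells),
        fp=sum(c == "FP" for c in cells),
        tn=sum(c == "TN" for c in cells),
        fn=sum(c == "FN" for c in cells),
    )


@dataclass(frozen=True)
class Metrics:
    ppv: Optional[float]
    sensitivity: Optional[float]
    f1: Optional[float]


def f1_score(ppv: Optional[float], sensitivity: Optional[float]) -> Optional[float]:
    """Harmonic mean of PPV and sensitivity; None when undefined."""
    if ppv is None or sensitivity is None or (ppv + sensitivity) == 0:
        return None
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    ppv = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else None
    sens = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else None
    return Metrics(ppv=ppv, sensitivity=sens, f1=f1_score(ppv, sens))


def _gold_map(records: Sequence[SigRecord]) -> dict[str, Optional[list[PeriodObject]]]:
    return {r.sig_id: r.gold for r in records}


def subgroup_metrics(
    results: Sequence[ParseResult],
    records: Sequence[SigRecord],
    group_label: str,
) -> dict[str, Metrics]:
    """Metrics within each value of a group label (e.g. drug_class).

    Sigs missing the label are excluded, mirroring the exclusion of patients
    without a recorded attribute.
    """
    rec_by_id = {r.sig_id: r for r in records}
    values = {r.groups[group_label] for r in records if group_label in r.groups}
    if not values:
        raise ValueError(f"no sig carries group label {group_label!r}")
    out: dict[str, Metrics] = {}
    for value in sorted(values):
        cells = [
            classify_sig(res, rec_by_id[res.sig_id].gold)
            for res in results
            if res.sig_id in rec_by_id
            and rec_by_id[res.sig_id].groups.get(group_label) == value
        ]
        out[value] = compute_metrics(count_cells(cells))
    return out


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int


_CELL_CODES: Mapping[str, int] = {"TP": 0, "FP": 1, "TN": 2, "FN": 3}


def _f1_from_code_counts(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    # Inside the permutation null an undefined F1 is scored as 0.0; the
    # observed statistic uses the same convention so the comparison is fair.
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
        f1 = 2 * ppv * sens / (ppv + sens)
    return np.nan_to_num(f1, nan=0.0)


def permutation_test(
    outcomes_a: Sequence[Cell],
    outcomes_b: Sequence[Cell],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Paired sign-flip permutation test on the F1 difference of two parsers.

    ``outcomes_a``/``outcomes_b`` are per-sig confusion cells paired by
    position (same sigs, same order).  Two-sided p with add-one smoothing.
    """
    if len(outcomes_a) != len(outcomes_b):
        raise ValueError(
            f"paired outcome vectors differ in length: {len(outcomes_a)} vs {len(outcomes_b)}"
        )
    a = np.array([_CELL_CODES[c] for c in outcomes_a], dtype=np.int8)
    b = np.array([_CELL_CODES[c] for c in outcomes_b], dtype=np.int8)
    n = len(a)

    def f1_of(codes: np.ndarray) -> float:
        tp = float((codes == 0).sum())
        fp = float((codes == 1).sum())
        fn = float((codes == 3).sum())
        return float(_f1_from_code_counts(np.array(tp), np.array(fp), np.array(fn)))

    stat = f1_of(a) - f1_of(b)
    rng = np.random.default_rng(seed)
    flips = rng.random((n_perm, n)) < 0.5
    pa = np.where(flips, b, a)  # (n_perm, n)
    pb = np.where(flips, a, b)
    tp_a = (pa == 0).sum(axis=1).astype(float)
    fp_a = (pa == 1).sum(axis=1).astype(float)
    fn_a = (pa == 3).sum(axis=1).astype(float)
    tp_b = (pb == 0).sum(axis=1).astype(float)
    fp_b = (pb == 1).sum(axis=1).astype(float)
    fn_b = (pb == 3).sum(axis=1).astype(float)
    null = _f1_from_code_counts(tp_a, fp_a, fn_a) - _f1_from_code_counts(tp_b, fp_b, fn_b)
    extreme = int((np.abs(null) >= abs(stat) - 1e-12).sum())
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(statistic=stat, p_value=p, n_perm=n_perm, seed=seed)


def evaluate(
    results: Sequence[ParseResult],
    records: Sequence[SigRecord],
    group_label: Optional[str] = None,
) -> dict:
    """Score results against the records' gold; returns a JSON-ready report."""
    gold = _gold_map(records)
    missing = [r.sig_id for r in results if r.sig_id not in gold]
    if missing:
        raise ValueError(f"results with no matching gold record: {missing[:5]}")
    cells = [classify_sig(r, gold[r.sig_id]) for r in results]
    counts = count_cells(cells)
    metrics = compute_metrics(counts)
    report = {
        "n": counts.total,
        "counts": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "metrics": {"ppv": metrics.ppv, "sensitivity": metrics.sensitivity, "f1": metrics.f1},
    }
    if group_label is not None:
        report["subgroups"] = {
            label: {"ppv": m.ppv, "sensitivity": m.sensitivity, "f1": m.f1}
            for label, m in subgroup_metrics(results, records, group_label).items()
        }
    return report
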