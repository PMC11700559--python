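"""Readers and writers for sig corpora and parse results.

Two interchangeable formats:

* JSONL — one JSON object per line.  A :class:`~sigdose.model.SigRecord` line is
  ``{"sig_id", "text", "groups"?, "gold"?: [period...]}``; the ``gold`` key is
  *omitted* for unannotated sigs and present-but-empty (``[]``) for sigs
  annotated as having no extractable daily dose.  A
  :class:`~sigdose.model.ParseResult` line mirrors the model fields.
* CSV — UTF-8, comma delimiter, mandatory header, one row per (sig, period)
  with a ``period_index`` (or ``gold_period_index``) column; sig-level fields
  repeat on every row.  The ``gold_annotated`` column (1/0) carries the
  absent-vs-empty gold distinction that JSONL expresses by key presence.

Both directions are lossless: ``read(write(x)) == x`` and a second write is
byte-identical to the first.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .model import ParseResult, ParseStatus, PeriodObject, SigRecord

__all__ = [
    "read_sigs",
    "write_sigs",
    "read_parse_results",
    "write_parse_results",
]

Format = Literal["jsonl", "csv"]

PERIOD_FIELDS = [
    "optional_period",
    "start_condition",
    "daily_dose_low",
    "daily_dose_high",
    "daily_dose_units",
    "alt_daily_dose_low",
    "alt_daily_dose_high",
    "alt_daily_dose_units",
    "duration_low",
    "duration_high",
    "duration_units",
    "hold_condition",
]


class SigFileError(ValueError):
    """Malformed sig/result file; message names the offending line."""


def _infer_format(path: Path, format: Optional[str]) -> Format:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown format {format!r}")
        return format  # type: ignore[return-value]
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix in (".csv",):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            raise SigFileError(f"duplicate sig_id {sid!r}")
        seen.add(sid)


# ---------------------------------------------------------------------------
# SigRecord I/O


def read_sigs(path: str | Path, format: Optional[Format] = None) -> list[SigRecord]:
    """Read a sig corpus; one :class:`SigRecord` per JSONL line / CSV sig group."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = _read_sigs_jsonl(path) if fmt == "jsonl" else _read_sigs_csv(path)
    _check_unique_ids([r.sig_id for r in records])
    return records


def _read_sigs_jsonl(path: Path) -> list[SigRecord]:
    records: list[SigRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                records.append(SigRecord.model_validate(obj))
            except Exception as exc:
                raise SigFileError(f"{path.name}:{lineno}: {exc}") from exc
    return records


def _period_to_row(p: PeriodObject) -> dict[str, str]:
    d = p.model_dump(mode="json")
    row = {}
    for f in PERIOD_FIELDS:
        v = d[f]
        if v is None:
            row[f] = ""
        elif isinstance(v, bool):
            row[f] = "1" if v else "0"
        else:
            row[f] = str(v)
    return row


def _period_from_row(row: dict[str, str], prefix: str) -> PeriodObject:
    kwargs = {}
    for f in PERIOD_FIELDS:
        v = row.get(prefix + f, "")
        if f == "optional_period":
            kwargs[f] = v == "1"
        else:
            kwargs[f] = v if v != "" else ("" if f in ("start_condition", "hold_condition") else None)
    return PeriodObject.model_validate(kwargs)


def _read_sigs_csv(path: Path) -> list[SigRecord]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        order: list[str] = []
        by_id: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = row["sig_id"]
                if sid not in by_id:
                    groups = {
                        k[len("group_"):]: v
                        for k, v in row.items()
                        if k.startswith("group_") and v != ""
                    }
                    annotated = row.get("gold_annotated", "0") == "1"
                    by_id[sid] = {
                        "sig_id": sid,
                        "text": row["text"],
                        "groups": groups,
                        "gold": [] if annotated else None,
                    }
                    order.append(sid)
                if row.get("gold_period_index", "") != "":
                    by_id[sid]["gold"].append(_period_from_row(row, "gold_"))
            except Exception as exc:
                raise SigFileError(f"{path.name}:{lineno}: {exc}") from exc
    try:
        return [SigRecord.model_validate(by_id[sid]) for sid in order]
    except Exception as exc:
        raise SigFileError(f"{path.name}: {exc}") from exc


def write_sigs(records: Iterable[SigRecord], path: str | Path, format: Optional[Format] = None) -> None:
    """Write a sig corpus losslessly (see module docstring for the schema)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = list(records)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                obj = {"sig_id": r.sig_id, "text": r.text}
                if r.groups:
                    obj["groups"] = r.groups
                if r.gold is not None:
                    obj["gold"] = [p.model_dump(mode="json") for p in r.gold]
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
        return
    group_labels = sorted({k for r in records for k in r.groups})
    header = (
        ["sig_id", "text"]
        + [f"group_{g}" for g in group_labels]
        + ["gold_annotated", "gold_period_index"]
        + [f"gold_{f}" for f in PERIOD_FIELDS]
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, lineterminator="\n")
        writer.writeheader()
        for r in records:
            base = {"sig_id": r.sig_id, "text": r.text}
            for g in group_labels:
                base[f"group_{g}"] = r.groups.get(g, "")
            base["gold_annotated"] = "0" if r.gold is None else "1"
            if r.gold:
                for i, p in enumerate(r.gold):
                    row = dict(base, gold_period_index=str(i))
                    row.update({f"gold_{k}": v for k, v in _period_to_row(p).items()})
                    writer.writerow(row)
            else:
                writer.writerow(dict(base, gold_period_index=""))


# ---------------------------------------------------------------------------
# ParseResult I/O


def write_parse_results(
    results: Iterable[ParseResult], path: str | Path, format: Optional[Format] = None
) -> None:
    """Serialize parse results; ``read_parse_results`` inverts this exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    results = list(results)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in results:
                fh.write(r.model_dump_json() + "\n")
        return
    header = (
        ["sig_id", "status", "normalized_text", "residual_tokens", "period_index"]
        + [f"p_{f}" for f in PERIOD_FIELDS]
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, lineterminator="\n")
        writer.writeheader()
        for r in results:
            base = {
                "sig_id": r.sig_id,
                "status": r.status.value,
                "normalized_text": r.normalized_text,
                "residual_tokens": "|".join(r.residual_tokens),
            }
            if r.periods:
                for i, p in enumerate(r.periods):
                    row = dict(base, period_index=str(i))
                    row.update({f"p_{k}": v for k, v in _period_to_row(p).items()})
                    writer.writerow(row)
            else:
                writer.writerow(dict(base, period_index=""))


def read_parse_results(path: str | Path, format: Optional[Format] = None) -> list[ParseResult]:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        results = []
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    results.append(ParseResult.model_validate(json.loads(line)))
                except Exception as exc:
                    raise SigFileError(f"{path.name}:{lineno}: {exc}") from exc
        _check_unique_ids([r.sig_id for r in results])
        return results
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        order: list[str] = []
        by_id: dict[str, dict] = {}
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = row["sig_id"]
                if sid not in by_id:
                    by_id[sid] = {
                        "sig_id": sid,
                        "status": ParseStatus(row["status"]),
                        "normalized_text": row["normalized_text"],
                        "residual_tokens": row["residual_tokens"].split("|") if row["residual_tokens"] else [],
                        "periods": [],
                    }
                    order.append(sid)
                if row.get("period_index", "") != "":
                    by_id[sid]["periods"].append(_period_from_row(row, "p_"))
            except Exception as exc:
                raise SigFileError(f"{path.name}:{lineno}: {exc}") from exc
    try:
        results = [ParseResult.model_validate(by_id[sid]) for sid in order]
    except Exception as exc:
        raise SigFileError(f"{path.name}: {exc}") from exc
    _check_unique_ids([r.sig_id for r in results])
    return results
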