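"""On-disk contracts: referral tables (CSV/TSV), gold annotations and
extraction outputs (JSONL).

A referral can encompass up to eight examinations; each row of a referral
table is one prescribed examination carrying both referral-level fields
(doctor, dates, ATS) and exam-level fields (type, flag, text).  Column names
vary across regional exports, so the mapping from canonical field names to
column headers is configuration, not code.

Dates are serialized ISO-8601 internally whatever the input dialect; spans
are 0-based half-open on the raw text.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, datetime
from pathlib import Path
from typing import Iterator, Optional

from .nti_normalizer import NTI

logger = logging.getLogger(__name__)

EXAM_CATEGORIES = ("specialist", "radiology", "lab", "other")
PRIORITY_CLASSES = ("U", "B", "D", "P")
GOLD_UNITS = ("day", "week", "month", "year", "date")
INDICATION_KINDS = ("none", "other_temporal", "followup_waiting_time")


class ReferralIOError(ValueError):
    """Fatal configuration or format error in an input file."""


@dataclass
class ReferralRecord:
    """One prescribed examination with its referral- and exam-level fields."""

    doctor_id: str
    referral_id: str
    exam_index: int
    referral_date: Optional[date]
    booking_date: Optional[date]
    first_proposed_date: Optional[date]
    accepted_date: Optional[date]
    exam_type_code: str
    exam_category: str
    is_followup_code: bool
    oz_flag: Optional[str]
    priority_class: Optional[str]
    is_screening: bool
    is_er: bool
    facility_id: str
    ats_id: str
    prescriber_type: str
    clinical_question: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.referral_id, self.exam_index)


@dataclass
class GoldAnnotation:
    """Gold label for one text: presence, kind, and normalized value."""

    text_id: str
    has_indication: bool
    indication_kind: str
    gold_value: Optional[float] = None
    gold_unit: Optional[str] = None
    gold_days: Optional[int] = None

    def validate(self) -> None:
        if self.indication_kind not in INDICATION_KINDS:
            raise ValueError(f"unknown indication_kind: {self.indication_kind!r}")
        if (self.gold_value is None) != (self.gold_unit is None):
            raise ValueError("gold_value and gold_unit must be present together")
        if self.gold_days is not None and self.gold_value is None:
            raise ValueError("gold_days requires gold_value and gold_unit")
        if self.gold_value is not None and self.gold_days is None:
            raise ValueError("gold_value present without resolved gold_days")
        if self.gold_unit is not None and self.gold_unit not in GOLD_UNITS:
            raise ValueError(f"unknown gold_unit: {self.gold_unit!r}")
        if self.gold_value is not None and self.gold_value <= 0:
            raise ValueError("gold_value must be positive")
        if self.has_indication and self.indication_kind == "followup_waiting_time" \
                and self.gold_days is None:
            raise ValueError("followup_waiting_time annotation lacks gold_days")


@dataclass
class TableDialect:
    """How a referral export is laid out: delimiter, encoding, date format,
    and the mapping canonical-field -> column header."""

    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "auto"  # auto | iso | dmy
    columns: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            delimiter=cfg.get("delimiter", ","),
            encoding=cfg.get("encoding", "utf-8"),
            date_format=cfg.get("date_format", "auto"),
            columns=cfg.get("columns", {}),
        )

    def column(self, field_name: str) -> str:
        return self.columns.get(field_name, field_name)


_FIELD_NAMES = [f.name for f in dc_fields(ReferralRecord)]
_MANDATORY = ("referral_id", "exam_index", "referral_date", "exam_type_code",
              "exam_category", "clinical_question")
_DATE_FIELDS = ("referral_date", "booking_date", "first_proposed_date", "accepted_date")
_BOOL_FIELDS = ("is_followup_code", "is_screening", "is_er")


def parse_date(cell: str, date_format: str = "auto") -> Optional[date]:
    """Parse ISO-8601 or dd/mm/yyyy; empty cell -> None; invalid -> ValueError."""
    cell = (cell or "").strip()
    if not cell:
        return None
    formats = {"iso": ["%Y-%m-%d"], "dmy": ["%d/%m/%Y"],
               "auto": ["%Y-%m-%d", "%d/%m/%Y"]}[date_format]
    for fmt in formats:
        try:
            return datetime.strptime(cell, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {cell!r}")


def _parse_bool(cell: str) -> bool:
    return (cell or "").strip().lower() in ("1", "true", "t", "yes", "y", "si", "sì")


def read_referrals(
    path: str | Path,
    dialect: Optional[TableDialect] = None,
    errors: Optional[list[tuple[int, str]]] = None,
) -> Iterator[ReferralRecord]:
    """Stream records from a referral table; bad rows are skipped and logged.

    ``errors``, if given, collects (row_number, message) for every skipped row.
    A mandatory column missing from the header is fatal.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with open(path, "r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for name in _MANDATORY:
            if dialect.column(name) not in header:
                raise ReferralIOError(
                    f"{path}: mandatory column {dialect.column(name)!r} "
                    f"(field {name!r}) missing from header"
                )
        for rownum, row in enumerate(reader, start=2):
            try:
                yield _row_to_record(row, dialect)
            except ValueError as exc:
                msg = f"row {rownum}: {exc}"
                logger.warning("%s: %s (row skipped)", path, msg)
                if errors is not None:
                    errors.append((rownum, str(exc)))


def _row_to_record(row: dict[str, str], dialect: TableDialect) -> ReferralRecord:
    def cell(name: str) -> str:
        return row.get(dialect.column(name)) or ""

    values: dict[str, object] = {}
    for name in _FIELD_NAMES:
        raw = cell(name)
        if name in _DATE_FIELDS:
            values[name] = parse_date(raw, dialect.date_format)
        elif name in _BOOL_FIELDS:
            values[name] = _parse_bool(raw)
        elif name == "exam_index":
            values[name] = int(raw) if raw.strip() else 1
        elif name in ("oz_flag", "priority_class"):
            values[name] = raw.strip() or None
        else:
            values[name] = raw

    record = ReferralRecord(**values)  # type: ignore[arg-type]
    if record.exam_category not in EXAM_CATEGORIES:
        raise ValueError(f"unknown exam_category: {record.exam_category!r}")
    if record.oz_flag not in (None, "O", "Z"):
        raise ValueError(f"invalid O/Z flag: {record.oz_flag!r}")
    if record.priority_class not in (None,) + PRIORITY_CLASSES:
        raise ValueError(f"invalid priority class: {record.priority_class!r}")
    if not (1 <= record.exam_index <= 8):
        raise ValueError(f"exam_index out of range 1-8: {record.exam_index}")
    if record.referral_date and record.booking_date \
            and record.booking_date < record.referral_date:
        raise ValueError("booking date precedes referral date")
    return record


def write_referrals(records: list[ReferralRecord], path: str | Path,
                    dialect: Optional[TableDialect] = None) -> None:
    """Write a referral table (dates ISO-8601, booleans 1/0)."""
    dialect = dialect or TableDialect()
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow([dialect.column(n) for n in _FIELD_NAMES])
        for r in records:
            row = []
            for name in _FIELD_NAMES:
                v = getattr(r, name)
                if v is None:
                    row.append("")
                elif name in _DATE_FIELDS:
                    row.append(v.isoformat())
                elif name in _BOOL_FIELDS:
                    row.append("1" if v else "0")
                else:
                    row.append(str(v))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# gold annotations (JSONL)
# ---------------------------------------------------------------------------

def read_gold(path: str | Path) -> list[GoldAnnotation]:
    """Read gold annotations; an invariant violation is fatal with line number."""
    out: list[GoldAnnotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                ann = GoldAnnotation(
                    text_id=str(obj["text_id"]),
                    has_indication=bool(obj["has_indication"]),
                    indication_kind=str(obj["indication_kind"]),
                    gold_value=obj.get("gold_value"),
                    gold_unit=obj.get("gold_unit"),
                    gold_days=obj.get("gold_days"),
                )
                ann.validate()
            except (KeyError, ValueError, TypeError) as exc:
                raise ReferralIOError(f"{path}: line {lineno}: {exc}") from exc
            out.append(ann)
    return out


def write_gold(annotations: list[GoldAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            obj: dict[str, object] = {
                "text_id": a.text_id,
                "has_indication": a.has_indication,
                "indication_kind": a.indication_kind,
            }
            if a.gold_value is not None:
                obj["gold_value"] = a.gold_value
                obj["gold_unit"] = a.gold_unit
                obj["gold_days"] = a.gold_days
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# extraction outputs (JSONL)
# ---------------------------------------------------------------------------

def write_extractions(
    results: list[tuple[str, Optional[NTI]]],
    path: str | Path,
) -> None:
    """Write extraction results; a null NTI is written explicitly so that
    downstream counts of absence are exact."""
    with open(path, "w", encoding="utf-8") as fh:
        for text_id, nti in results:
            obj: dict[str, object] = {"text_id": text_id}
            if nti is None:
                obj["nti"] = None
            else:
                obj["nti"] = {
                    "days": nti.days,
                    "value": nti.value,
                    "unit": nti.unit,
                    "kind": nti.kind,
                    "span": list(nti.source_span),
                }
                if nti.anchor_date is not None:
                    obj["nti"]["anchor_date"] = nti.anchor_date.isoformat()
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_extractions(path: str | Path) -> list[tuple[str, Optional[NTI]]]:
    out: list[tuple[str, Optional[NTI]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                text_id = str(obj["text_id"])
                n = obj["nti"]
                nti = None
                if n is not None:
                    anchor = n.get("anchor_date")
                    nti = NTI(
                        days=int(n["days"]),
                        value=float(n["value"]),
                        unit=str(n["unit"]),
                        kind=str(n["kind"]),
                        source_span=(int(n["span"][0]), int(n["span"][1])),
                        anchor_date=date.fromisoformat(anchor) if anchor else None,
                    )
            except (KeyError, ValueError, TypeError) as exc:
                raise ReferralIOError(f"{path}: line {lineno}: {exc}") from exc
            out.append((text_id, nti))
    return out
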