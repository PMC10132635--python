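"""Photo-identification sighting records.

Each record is one photo-confirmed observation of one individually
identified turtle (facial scale pattern = permanent mark) on one date at
one reef site.  Records missing any of the required fields (identity,
species, date, site) are rejected rather than imputed.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO

SPECIES = ("hawksbill", "green")
JUVENILE_MAX_CM = 60.0  # carapace length at or below which a turtle is a juvenile

#: default CSV column mapping (field name -> header name)
DEFAULT_SCHEMA = {
    "turtle_id": "turtle_id",
    "species": "species",
    "date": "date",
    "site": "site",
    "atoll": "atoll",
    "carapace_length": "carapace_length_cm",
    "tail_long": "tail_long",
    "sex": "sex",
}

CSV_HEADER = [
    "turtle_id", "species", "date", "site", "atoll",
    "carapace_length_cm", "tail_long", "sex",
]


@dataclass(frozen=True)
class SightingRecord:
    turtle_id: str
    species: str
    date: _dt.date
    site: str
    atoll: str = ""
    carapace_length: Optional[float] = None  # straight carapace length, cm
    tail_long: Optional[bool] = None
    sex: str = "unknown"
    life_stage: str = "unknown"

    def __post_init__(self):
        for f in ("turtle_id", "species", "site"):
            if not getattr(self, f):
                raise ValueError(f"{f} is required")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if not isinstance(self.date, _dt.date):
            raise ValueError("date must be a datetime.date")
        if self.carapace_length is not None and self.carapace_length <= 0:
            raise ValueError("carapace_length must be positive when present")


@dataclass
class Rejection:
    row: int       # 1-based data-row number (excluding header)
    reason: str
    raw: dict

    def __str__(self):
        return f"row {self.row}: {self.reason}"


_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _parse_bool(text: str) -> Optional[bool]:
    t = text.strip().lower()
    if not t:
        return None
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def parse_sightings(
    source: TextIO | str | Iterable[str],
    schema: dict[str, str] | None = None,
) -> tuple[list[SightingRecord], list[Rejection]]:
    """Parse sighting records from delimited text.

    Rows missing a required field (turtle_id, species, date, site), with an
    unparseable date, an unknown species, or a non-positive size estimate
    are rejected with a reason; parsing never fails on a bad row.  An
    unreadable source or a header missing a required mapped column is fatal.

    Returns
    -------
    (records, rejections)
        Valid records (classified into life stage / sex) and the rejection
        log.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return [], []
    for field in ("turtle_id", "species", "date", "site"):
        col = schema.get(field)
        if col is None or col not in reader.fieldnames:
            raise ValueError(f"required column {col!r} ({field}) absent from header")

    records: list[SightingRecord] = []
    rejections: list[Rejection] = []
    for i, row in enumerate(reader, start=1):
        def _get(field):
            col = schema.get(field)
            v = row.get(col) if col else None
            return (v or "").strip()

        reason = None
        for field in ("turtle_id", "species", "date", "site"):
            if not _get(field):
                reason = f"missing {field if field != 'turtle_id' else 'identification'}"
                break
        if reason is None:
            species = _get("species").lower()
            if species not in SPECIES:
                reason = f"unknown species {_get('species')!r}"
        if reason is None:
            try:
                date = _dt.date.fromisoformat(_get("date"))
            except ValueError:
                reason = f"malformed date {_get('date')!r}"
        if reason is None:
            length = None
            raw_len = _get("carapace_length")
            if raw_len:
                try:
                    length = float(raw_len)
                    if length <= 0:
                        reason = f"non-positive carapace length {raw_len!r}"
                except ValueError:
                    reason = f"malformed carapace length {raw_len!r}"
        if reason is None:
            try:
                tail = _parse_bool(_get("tail_long"))
            except ValueError:
                reason = f"malformed tail_long {_get('tail_long')!r}"
        if reason is not None:
            rejections.append(Rejection(i, reason, dict(row)))
            continue

        sex = _get("sex").lower() or "unknown"
        if sex not in ("male", "female", "unknown"):
            rejections.append(Rejection(i, f"unknown sex {_get('sex')!r}", dict(row)))
            continue
        rec = SightingRecord(
            turtle_id=_get("turtle_id"), species=species, date=date,
            site=_get("site"), atoll=_get("atoll"),
            carapace_length=length, tail_long=tail, sex=sex,
        )
        records.append(classify_record(rec))
    return records, rejections


def classify_record(record: SightingRecord,
                    conflict_log: list | None = None) -> SightingRecord:
    """Resolve life stage and sex from size and tail morphology.

    Turtles at or below 60 cm carapace length are juveniles; larger turtles
    are adults, and an adult with an elongated tail is a male.  Without a
    size estimate the life stage is unknown.  The length rule takes
    precedence over tail morphology: a <=60 cm turtle flagged tail_long is
    classified juvenile and the conflict is logged.
    """
    length = record.carapace_length
    if length is None:
        return replace(record, life_stage="unknown")
    if length <= JUVENILE_MAX_CM:
        if record.tail_long and conflict_log is not None:
            conflict_log.append(
                f"{record.turtle_id} on {record.date}: long tail reported at "
                f"{length:g} cm; length rule wins, classified juvenile"
            )
        return replace(record, life_stage="juvenile")
    if record.tail_long:
        return replace(record, life_stage="adult", sex="male")
    return replace(record, life_stage="adult",
                   sex=record.sex if record.sex == "female" else "unknown")


def write_sightings(records: Iterable[SightingRecord], stream: TextIO) -> None:
    """Write records as CSV in the canonical ingest schema."""
    w = csv.writer(stream)
    w.writerow(CSV_HEADER)
    for r in records:
        w.writerow([
            r.turtle_id, r.species, r.date.isoformat(), r.site, r.atoll,
            "" if r.carapace_length is None else f"{r.carapace_length:g}",
            "" if r.tail_long is None else str(r.tail_long).lower(),
            "" if r.sex == "unknown" else r.sex,
        ])
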