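"""Domain types and delimited-text I/O for ambulatory claims records.

The data model mirrors the structure of Taiwanese National Health Insurance
ambulatory claims as used in pharmacoepidemiological studies of traditional
Chinese medicine: each visit carries up to three ordered ICD-9 diagnosis
codes (first position = main reason for the visit), a set of TCM modalities
(Chinese herbal medicine, acupuncture, massage), and — for CHM visits — a
prescription of one or more reimbursed herbal products, each either a fixed
herbal formula (HF) or a single-herb concentrate (SH) with a daily dose in
grams, a duration in days, and an administrations-per-day frequency.

On-disk format is plain CSV (UTF-8, header row, ISO-8601 dates):

``visits.csv``
    visit_id,patient_id,visit_date,dx1,dx2,dx3,modality
    (modality is a semicolon-joined set, e.g. ``CHM;ACUPUNCTURE``)
``items.csv``
    visit_id,chm_id,chm_name,chm_type,dose_g_per_day,duration_days,admin_per_day

ICD-9 codes are accepted with or without the decimal point (``6254`` and
``625.4`` are the same code) and stored canonically *with* the point.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CHM",
    "ACUPUNCTURE",
    "MASSAGE",
    "MODALITIES",
    "ClaimsError",
    "SchemaError",
    "ReferentialError",
    "ParseError",
    "PrescriptionItem",
    "VisitRecord",
    "ClaimsDataset",
    "normalize_icd9",
    "round_half_up",
    "read_claims",
    "write_claims",
    "write_table",
]

CHM = "CHM"
ACUPUNCTURE = "ACUPUNCTURE"
MASSAGE = "MASSAGE"
MODALITIES = frozenset({CHM, ACUPUNCTURE, MASSAGE})

CHM_TYPES = frozenset({"HF", "SH"})

VISIT_COLUMNS = ["visit_id", "patient_id", "visit_date", "dx1", "dx2", "dx3", "modality"]
ITEM_COLUMNS = [
    "visit_id",
    "chm_id",
    "chm_name",
    "chm_type",
    "dose_g_per_day",
    "duration_days",
    "admin_per_day",
]


class ClaimsError(Exception):
    """Base class for claims-data errors."""


class SchemaError(ClaimsError):
    """A file or record set does not match the documented schema."""


class ReferentialError(ClaimsError):
    """A row references an entity that does not exist."""


class ParseError(ClaimsError):
    """A field value could not be parsed; message carries file and line."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed claims tables).

    Python's builtin ``round`` is banker's rounding; prevalence tables in this
    literature round 0.05 up, so percentages use this helper throughout.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_icd9(code: str) -> str:
    """Canonicalize an ICD-9 code to dotted form (``6254`` -> ``625.4``).

    Numeric codes have a three-character category, E-codes a four-character
    one; V-codes behave like numeric codes. Already-dotted codes pass through
    unchanged (idempotent). Empty input is rejected.
    """
    c = code.strip().upper()
    if not c:
        raise ParseError("empty diagnosis code")
    if "." in c:
        head, _, tail = c.partition(".")
        return head if not tail else f"{head}.{tail}"
    prefix = 4 if c.startswith("E") else 3
    if len(c) <= prefix:
        return c
    return f"{c[:prefix]}.{c[prefix:]}"


@dataclass(frozen=True)
class PrescriptionItem:
    """One reimbursed CHM product on a prescription.

    ``chm_type`` distinguishes multi-herb formulas (HF) from single-herb
    concentrates (SH); the dose is grams of concentrated powder per day.
    """

    chm_id: str
    chm_name: str
    chm_type: str
    dose_g_per_day: float
    duration_days: int
    admin_per_day: int

    def __post_init__(self) -> None:
        if self.chm_type not in CHM_TYPES:
            raise SchemaError(f"chm_type must be one of {sorted(CHM_TYPES)}, got {self.chm_type!r}")
        if self.dose_g_per_day < 0:
            raise SchemaError(f"dose_g_per_day must be >= 0, got {self.dose_g_per_day}")
        if self.duration_days < 1:
            raise SchemaError(f"duration_days must be >= 1, got {self.duration_days}")
        if self.admin_per_day < 1:
            raise SchemaError(f"admin_per_day must be >= 1, got {self.admin_per_day}")


@dataclass(frozen=True)
class VisitRecord:
    """One ambulatory visit: ordered diagnoses, modalities, prescription items.

    Diagnoses hold 1-3 ICD-9 codes; position one is the main reason for the
    visit. ``items`` is nonempty exactly when CHM is among the modalities.
    """

    visit_id: str
    patient_id: str
    visit_date: _dt.date
    diagnoses: tuple[str, ...]
    modality: frozenset[str]
    items: tuple[PrescriptionItem, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.diagnoses) <= 3:
            raise SchemaError(
                f"visit {self.visit_id}: need 1-3 diagnoses, got {len(self.diagnoses)}"
            )
        bad = set(self.modality) - MODALITIES
        if bad:
            raise SchemaError(f"visit {self.visit_id}: unknown modality {sorted(bad)}")
        has_chm = CHM in self.modality
        if has_chm != bool(self.items):
            raise SchemaError(
                f"visit {self.visit_id}: items nonempty iff CHM modality present "
                f"(CHM={has_chm}, {len(self.items)} items)"
            )
        ids = [it.chm_id for it in self.items]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"visit {self.visit_id}: duplicate chm_id {dupes}")

    @property
    def item_set(self) -> frozenset[str]:
        return frozenset(it.chm_id for it in self.items)


@dataclass
class ClaimsDataset:
    """A collection of visits plus the catalog of CHM products they reference."""

    visits: list[VisitRecord]
    item_catalog: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for v in self.visits:
            if v.visit_id in seen:
                raise SchemaError(f"duplicate visit_id {v.visit_id!r}")
            seen.add(v.visit_id)
            for it in v.items:
                if it.chm_id not in self.item_catalog:
                    raise SchemaError(
                        f"visit {v.visit_id}: chm_id {it.chm_id!r} missing from catalog"
                    )

    @classmethod
    def from_visits(cls, visits: Iterable[VisitRecord]) -> "ClaimsDataset":
        """Build a dataset, deriving the catalog from the items themselves."""
        visits = list(visits)
        catalog: dict[str, tuple[str, str]] = {}
        for v in visits:
            for it in v.items:
                entry = (it.chm_name, it.chm_type)
                prior = catalog.setdefault(it.chm_id, entry)
                if prior != entry:
                    raise SchemaError(
                        f"chm_id {it.chm_id!r} has conflicting catalog entries {prior} vs {entry}"
                    )
        return cls(visits=visits, item_catalog=catalog)


def _check_header(found: Sequence[str] | None, expected: Sequence[str], path: str) -> None:
    found = list(found or [])
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise SchemaError(f"{path}: {'; '.join(parts)}")


def read_claims(visits_path: str | Path, items_path: str | Path) -> ClaimsDataset:
    """Read a visits/items CSV pair into a typed :class:`ClaimsDataset`.

    Diagnosis codes are normalized to dotted ICD-9 form; row order is
    preserved. Raises :class:`SchemaError` on header mismatch,
    :class:`ReferentialError` when an item row names an unknown visit, and
    :class:`ParseError` (with file and line number) on malformed values.
    """
    visits_path, items_path = Path(visits_path), Path(items_path)

    items_by_visit: dict[str, list[PrescriptionItem]] = {}
    catalog: dict[str, tuple[str, str]] = {}
    with open(items_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ITEM_COLUMNS, str(items_path))
        for lineno, row in enumerate(reader, start=2):
            try:
                item = PrescriptionItem(
                    chm_id=row["chm_id"],
                    chm_name=row["chm_name"],
                    chm_type=row["chm_type"],
                    dose_g_per_day=float(row["dose_g_per_day"]),
                    duration_days=int(row["duration_days"]),
                    admin_per_day=int(row["admin_per_day"]),
                )
            except (ValueError, SchemaError) as exc:
                raise ParseError(f"{items_path}:{lineno}: {exc}") from exc
            items_by_visit.setdefault(row["visit_id"], []).append(item)
            entry = (item.chm_name, item.chm_type)
            prior = catalog.setdefault(item.chm_id, entry)
            if prior != entry:
                raise SchemaError(
                    f"{items_path}:{lineno}: chm_id {item.chm_id!r} conflicts with "
                    f"earlier catalog entry {prior}"
                )

    visits: list[VisitRecord] = []
    seen_visit_ids: set[str] = set()
    with open(visits_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, VISIT_COLUMNS, str(visits_path))
        for lineno, row in enumerate(reader, start=2):
            try:
                date = _dt.date.fromisoformat(row["visit_date"])
            except ValueError as exc:
                raise ParseError(f"{visits_path}:{lineno}: bad date {row['visit_date']!r}") from exc
            dx = tuple(
                normalize_icd9(row[c]) for c in ("dx1", "dx2", "dx3") if row[c].strip()
            )
            modality = frozenset(m for m in row["modality"].split(";") if m)
            try:
                visit = VisitRecord(
                    visit_id=row["visit_id"],
                    patient_id=row["patient_id"],
                    visit_date=date,
                    diagnoses=dx,
                    modality=modality,
                    items=tuple(items_by_visit.pop(row["visit_id"], [])),
                )
            except SchemaError as exc:
                raise ParseError(f"{visits_path}:{lineno}: {exc}") from exc
            seen_visit_ids.add(visit.visit_id)
            visits.append(visit)

    if items_by_visit:
        orphan = sorted(items_by_visit)[0]
        raise ReferentialError(
            f"{items_path}: {sum(map(len, items_by_visit.values()))} item row(s) reference "
            f"unknown visit_id(s), e.g. {orphan!r}"
        )
    return ClaimsDataset(visits=visits, item_catalog=catalog)


def write_claims(
    data: ClaimsDataset, visits_path: str | Path, items_path: str | Path
) -> None:
    """Write a dataset back to the visits/items CSV pair (inverse of read)."""
    with open(visits_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(VISIT_COLUMNS)
        for v in data.visits:
            dx = list(v.diagnoses) + [""] * (3 - len(v.diagnoses))
            w.writerow(
                [v.visit_id, v.patient_id, v.visit_date.isoformat(), *dx,
                 ";".join(sorted(v.modality))]
            )
    with open(items_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ITEM_COLUMNS)
        for v in data.visits:
            for it in v.items:
                w.writerow(
                    [v.visit_id, it.chm_id, it.chm_name, it.chm_type,
                     repr(it.dose_g_per_day), it.duration_days, it.admin_per_day]
                )


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write uniform records as CSV with a fixed column order.

    All rows must share one key set; column order is ``columns`` if given,
    else the first row's key order. Values in columns whose name ends in
    ``_pct`` are rendered to one decimal with half-up rounding, matching
    printed prevalence tables. An empty row list yields a header-only file
    (``columns`` required in that case).
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise SchemaError("cannot infer columns from an empty row list")
        columns = list(rows[0].keys())
    columns = list(columns)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for row in rows:
            if set(row.keys()) != set(columns):
                raise SchemaError(
                    f"heterogeneous rows: expected columns {columns}, got {sorted(row)}"
                )
            out = []
            for c in columns:
                v = row[c]
                if c.endswith("_pct") and v is not None:
                    v = f"{round_half_up(float(v), 1):.1f}"
                out.append(v)
            w.writerow(out)
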