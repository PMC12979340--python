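"""Delimited-text readers and writers.

All files are UTF-8, comma-delimited CSV with a header row and ISO-8601
dates.  Readers convert calendar dates to integer day indices and compute
the derived dispensation fields; rows that cannot be parsed are rejected
with row-numbered diagnostics rather than aborting the whole file, while
a missing column is a schema error.

The drug catalog is an external CSV (``din,drug_class,form``) so that
jurisdiction-specific product codes stay configuration, not code.
Unknown product codes are rejected, not silently dropped.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    DRUG_CLASSES,
    Dispensation,
    DoseSegment,
    Episode,
    HospitalStay,
    Interval,
    day_index,
    day_to_date,
)

__all__ = [
    "SchemaError",
    "RowIssue",
    "example_catalog",
    "read_catalog",
    "write_catalog",
    "read_dispensations",
    "write_dispensations",
    "read_hospitalizations",
    "write_episodes",
    "read_episodes",
    "write_relations",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


@dataclass(frozen=True)
class RowIssue:
    """A row-level diagnostic: 1-based data-row number plus a message."""

    row: int
    message: str


_DISP_COLUMNS = ("person_id", "din", "date_of_service", "days_supply", "quantity", "strength")


def example_catalog(codes_per_class: int = 16) -> dict[str, str]:
    """A synthetic drug catalog mapping made-up product codes to OAT classes.

    Codes are of the form ``MET001`` .. ``IOA016``; they are placeholders
    for jurisdiction-specific DIN/PINs, useful for testing and simulation.
    """
    prefix = {"methadone": "MET", "bup_nal": "BUP", "srom": "SRO", "ioat": "IOA"}
    return {
        f"{prefix[cls]}{i:03d}": cls
        for cls in DRUG_CLASSES
        for i in range(1, codes_per_class + 1)
    }


def read_catalog(path) -> dict[str, str]:
    """Read a drug catalog CSV (``din,drug_class[,form]``) into a din -> class map."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for c in ("din", "drug_class"):
            if c not in cols:
                raise SchemaError(f"catalog is missing required column {c!r}")
        catalog: dict[str, str] = {}
        for i, row in enumerate(reader, start=1):
            din = row["din"].strip()
            cls = row["drug_class"].strip()
            if din in catalog and catalog[din] != cls:
                raise ValueError(
                    f"catalog row {i}: din {din!r} mapped to both "
                    f"{catalog[din]!r} and {cls!r}; codes must be disjoint"
                )
            catalog[din] = cls
    return catalog


def write_catalog(catalog: dict[str, str], path) -> None:
    pd.DataFrame(
        [(din, cls, "") for din, cls in sorted(catalog.items())],
        columns=["din", "drug_class", "form"],
    ).to_csv(path, index=False)


def read_dispensations(
    path, catalog: dict[str, str]
) -> tuple[list[Dispensation], list[RowIssue]]:
    """Parse a dispensations CSV, resolving product codes through ``catalog``.

    Returns the parsed records plus row-numbered diagnostics for rejected
    rows (unresolvable din, unparseable date, non-positive days supply /
    quantity / strength).
    """
    disps: list[Dispensation] = []
    issues: list[RowIssue] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in _DISP_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"dispensations file is missing columns: {missing}")
        for i, row in enumerate(reader, start=1):
            din = row["din"].strip()
            drug = catalog.get(din)
            if drug is None:
                issues.append(RowIssue(i, f"unresolvable din {din!r}"))
                continue
            try:
                date = _dt.date.fromisoformat(row["date_of_service"].strip())
            except ValueError:
                issues.append(
                    RowIssue(i, f"unparseable date_of_service {row['date_of_service']!r}")
                )
                continue
            try:
                days_supply = int(row["days_supply"])
                quantity = float(row["quantity"])
                strength = float(row["strength"])
                disp = Dispensation(
                    person_id=row["person_id"].strip(),
                    drug=drug,
                    service_day=day_index(date),
                    days_supply=days_supply,
                    quantity=quantity,
                    strength=strength,
                    din=din,
                )
            except ValueError as exc:
                issues.append(RowIssue(i, str(exc)))
                continue
            disps.append(disp)
    return disps, issues


def write_dispensations(disps: Iterable[Dispensation], path) -> None:
    rows = [
        (
            d.person_id,
            d.din,
            day_to_date(d.service_day).isoformat(),
            d.days_supply,
            d.quantity,
            d.strength,
        )
        for d in disps
    ]
    pd.DataFrame(rows, columns=list(_DISP_COLUMNS)).to_csv(path, index=False)


def read_hospitalizations(path) -> tuple[list[HospitalStay], list[RowIssue]]:
    """Parse a hospitalization CSV (``person_id,admit_date,discharge_date``)."""
    stays: list[HospitalStay] = []
    issues: list[RowIssue] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in ("person_id", "admit_date", "discharge_date") if c not in cols]
        if missing:
            raise SchemaError(f"hospitalizations file is missing columns: {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                admit = day_index(_dt.date.fromisoformat(row["admit_date"].strip()))
                discharge = day_index(_dt.date.fromisoformat(row["discharge_date"].strip()))
                stays.append(HospitalStay(row["person_id"].strip(), admit, discharge))
            except ValueError as exc:
                issues.append(RowIssue(i, str(exc)))
    return stays, issues


_EPISODE_COLUMNS = (
    "person_id",
    "episode_id",
    "start_date",
    "end_date",
    "type",
    "drug_sequence",
    "n_dispensations",
    "duration_days",
    "max_co_dispensation_days",
    "n_switches",
    "bridged_hospital_days",
    "dose_segments",
)


def _segments_to_str(segments: Sequence[DoseSegment]) -> str:
    return "|".join(
        f"{day_to_date(s.interval.start).isoformat()}..{day_to_date(s.interval.end).isoformat()}"
        f"@{s.drug}:{s.mg_per_day!r}"
        for s in segments
    )


def _segments_from_str(text: str) -> tuple[DoseSegment, ...]:
    if not text:
        return ()
    out = []
    for piece in text.split("|"):
        span, _, rest = piece.partition("@")
        drug, _, dose = rest.rpartition(":")
        a, _, b = span.partition("..")
        out.append(
            DoseSegment(
                Interval(
                    day_index(_dt.date.fromisoformat(a)),
                    day_index(_dt.date.fromisoformat(b)),
                ),
                drug,
                float(dose),
            )
        )
    return tuple(out)


def write_episodes(episodes: Sequence[Episode], path) -> None:
    """Write episodes to CSV, one row per episode; round-trips via :func:`read_episodes`.

    Raises if one person's episodes overlap (an integrity violation the
    builder should never produce).
    """
    by_person: dict[str, list[Episode]] = {}
    for e in episodes:
        by_person.setdefault(e.person_id, []).append(e)
    for pid, eps in by_person.items():
        eps = sorted(eps, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping episodes for person {pid!r}: "
                    f"{a.episode_id} ends day {a.end}, {b.episode_id} starts day {b.start}"
                )
    rows = [
        (
            e.person_id,
            e.episode_id,
            day_to_date(e.start).isoformat(),
            day_to_date(e.end).isoformat(),
            e.type,
            ";".join(e.drug_sequence),
            e.n_dispensations,
            e.duration_days,
            e.max_co_dispensation_days,
            e.n_switches,
            e.bridged_hospital_days,
            _segments_to_str(e.dose_segments),
        )
        for e in episodes
    ]
    pd.DataFrame(rows, columns=list(_EPISODE_COLUMNS)).to_csv(path, index=False)


def read_episodes(path) -> list[Episode]:
    out: list[Episode] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in _EPISODE_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"episodes file is missing columns: {missing}")
        for row in reader:
            out.append(
                Episode(
                    person_id=row["person_id"],
                    episode_id=row["episode_id"],
                    start=day_index(_dt.date.fromisoformat(row["start_date"])),
                    end=day_index(_dt.date.fromisoformat(row["end_date"])),
                    type=row["type"],
                    drug_sequence=tuple(
                        d for d in row["drug_sequence"].split(";") if d
                    ),
                    n_dispensations=int(row["n_dispensations"]),
                    max_co_dispensation_days=int(row["max_co_dispensation_days"]),
                    n_switches=int(row["n_switches"]),
                    dose_segments=_segments_from_str(row["dose_segments"]),
                    bridged_hospital_days=int(row["bridged_hospital_days"]),
                )
            )
    return out


def write_relations(annotated, path) -> None:
    """Write annotated per-record relations (person, drug, index, label, gap, overlap)."""
    rows = []
    idx: dict[str, int] = {}
    for d, rel in annotated:
        k = d.person_id
        idx[k] = idx.get(k, -1) + 1
        rows.append(
            (
                d.person_id,
                d.drug,
                idx[k],
                rel.label,
                "" if rel.gap_days is None else rel.gap_days,
                "" if rel.overlap_days is None else rel.overlap_days,
            )
        )
    pd.DataFrame(
        rows, columns=["person_id", "drug", "index", "label", "gap_days", "overlap_days"]
    ).to_csv(path, index=False)
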