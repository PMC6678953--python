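"""Parsing and coding of MCOD-like record tables.

The pipeline consumes delimited text (CSV/TSV) with a YAML column schema
rather than the fixed-width NCHS public-use layout. Condition codes are
carried either in a single delimited field or in 20 positional columns;
the schema decides. Parsing is streaming and fault-tolerant: malformed
rows are skipped and counted, never fatal, which is the only workable
policy at tens of millions of records.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .records import (
    DEFAULT_AGE_CUTS,
    CategoryMap,
    CodedRecord,
    RawDeathRecord,
    age_band,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSchema",
    "ParseReport",
    "parse_mcod",
    "map_code_to_category",
    "code_record",
    "filter_usable",
    "build_indicator_matrix",
]

_REQUIRED_FIELDS = (
    "record_id",
    "data_year",
    "age_years",
    "sex",
    "race",
    "education",
    "marital",
    "resident_status",
    "place_of_death",
    "manner",
    "underlying_cause",
)


@dataclass(frozen=True)
class ColumnSchema:
    """Maps the record fields onto the columns of a delimited file.

    ``columns`` maps each logical field name to the file's column name.
    ``conditions_style`` is ``"delimited"`` (one field holding all entity
    codes, split on ``conditions_delimiter``) or ``"positional"`` (columns
    ``<prefix>1`` .. ``<prefix>20``).
    """

    columns: dict[str, str]
    conditions_style: str = "delimited"
    conditions_column: str = "conditions"
    conditions_delimiter: str = " "
    conditions_prefix: str = "cond"
    delimiter: str = ","
    missing_tokens: tuple[str, ...] = ("", "NA", ".")

    def __post_init__(self) -> None:
        missing = [f for f in _REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(f"column schema missing required fields: {missing}")
        if self.conditions_style not in ("delimited", "positional"):
            raise ValueError(f"unknown conditions_style {self.conditions_style!r}")

    @classmethod
    def default(cls) -> "ColumnSchema":
        """Identity schema: file columns named exactly like the fields."""
        return cls(columns={f: f for f in _REQUIRED_FIELDS})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cond = cfg.get("conditions", {})
        return cls(
            columns=dict(cfg["columns"]),
            conditions_style=cond.get("style", "delimited"),
            conditions_column=cond.get("column", "conditions"),
            conditions_delimiter=cond.get("delimiter", " "),
            conditions_prefix=cond.get("prefix", "cond"),
            delimiter=cfg.get("delimiter", ","),
            missing_tokens=tuple(cfg.get("missing_tokens", ("", "NA", "."))),
        )


@dataclass
class ParseReport:
    """Row bookkeeping accumulated while streaming a file."""

    n_parsed: int = 0
    n_malformed: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)


def _clean(value: str | None, missing: tuple[str, ...]) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return None if value in missing else value


def parse_mcod(
    path: str | Path,
    schema: ColumnSchema | None = None,
    report: ParseReport | None = None,
) -> Iterator[RawDeathRecord]:
    """Stream :class:`RawDeathRecord` objects from a delimited file.

    Rows that fail validation (malformed ICD codes, out-of-range age,
    unknown categorical level) are skipped; their row numbers and reasons
    accumulate on *report*.
    """
    schema = schema or ColumnSchema.default()
    report = report if report is not None else ParseReport()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=schema.delimiter)
        if reader.fieldnames is None:
            return  # empty file
        needed = {schema.columns[f] for f in _REQUIRED_FIELDS}
        if schema.conditions_style == "delimited":
            needed.add(schema.conditions_column)
        absent = sorted(needed - set(reader.fieldnames))
        if absent:
            raise ValueError(f"input file lacks required columns: {absent}")
        for rownum, row in enumerate(reader, start=2):  # 1 = header line
            try:
                yield _parse_row(row, schema)
                report.n_parsed += 1
            except (ValueError, KeyError) as exc:
                report.n_malformed += 1
                report.errors.append((rownum, str(exc)))
    if report.n_malformed:
        logger.warning("skipped %d malformed rows", report.n_malformed)


def _parse_row(row: dict[str, str], schema: ColumnSchema) -> RawDeathRecord:
    miss = schema.missing_tokens
    get = lambda f: _clean(row.get(schema.columns[f]), miss)

    if schema.conditions_style == "delimited":
        raw_codes = row.get(schema.conditions_column) or ""
        codes = [c for c in raw_codes.split(schema.conditions_delimiter) if c.strip()]
    else:
        codes = []
        for i in range(1, 21):
            c = _clean(row.get(f"{schema.conditions_prefix}{i}"), miss)
            if c:
                codes.append(c)

    age = get("age_years")
    return RawDeathRecord(
        record_id=get("record_id") or "",
        data_year=int(get("data_year") or 0),
        age_years=int(age) if age is not None else None,
        sex=get("sex") or "",
        race=get("race") or "",
        education=get("education"),
        marital=get("marital"),
        resident_status=get("resident_status") or "",
        place_of_death=get("place_of_death"),
        manner=get("manner"),
        underlying_cause=get("underlying_cause") or "",
        entity_conditions=tuple(codes),
    )


def map_code_to_category(code: str, category_map: CategoryMap) -> str:
    """Aggregate one ICD-10 code to its disease category (longest prefix wins)."""
    return category_map.lookup(code)


def code_record(
    raw: RawDeathRecord,
    category_map: CategoryMap,
    age_cuts: Sequence[int] = DEFAULT_AGE_CUTS,
) -> CodedRecord:
    """Aggregate a record's codes to categories and derive its indicators.

    Categories are deduplicated across the entity-axis codes; the
    multimorbidity flag is 1 when two or more *different* categories
    remain. The underlying cause is mapped separately and not force-added
    to the condition set.
    """
    categories = frozenset(category_map.lookup(c) for c in raw.entity_conditions)
    return CodedRecord(
        raw=raw,
        categories=categories,
        underlying_category=category_map.lookup(raw.underlying_cause),
        multimorbid=int(len(categories) >= 2),
        age_group=age_band(raw.age_years, age_cuts),
    )


def filter_usable(records: Iterable[CodedRecord]) -> tuple[list[CodedRecord], int]:
    """Drop records with no health condition, as the study filter does.

    Returns the usable records and the count omitted; both are logged so
    the run manifest can mirror the parsed/omitted/usable bookkeeping.
    """
    usable: list[CodedRecord] = []
    omitted = 0
    for rec in records:
        if rec.usable:
            usable.append(rec)
        else:
            omitted += 1
    logger.info("filter_usable: %d usable, %d omitted", len(usable), omitted)
    return usable, omitted


_CODED_FIELDS = list(_REQUIRED_FIELDS) + [
    "conditions",
    "categories",
    "underlying_category",
    "multimorbid",
    "age_group",
]


def write_coded_csv(records: Iterable[CodedRecord], path: str | Path) -> None:
    """Persist coded records (stage artifact consumed by later stages)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CODED_FIELDS)
        for rec in records:
            r = rec.raw
            w.writerow(
                [
                    r.record_id,
                    r.data_year,
                    "" if r.age_years is None else r.age_years,
                    r.sex,
                    r.race,
                    r.education or "",
                    r.marital or "",
                    r.resident_status,
                    r.place_of_death or "",
                    r.manner or "",
                    r.underlying_cause,
                    " ".join(r.entity_conditions),
                    "|".join(sorted(rec.categories)),
                    rec.underlying_category,
                    rec.multimorbid,
                    rec.age_group or "",
                ]
            )


def read_coded_csv(path: str | Path) -> list[CodedRecord]:
    """Load a coded-records artifact written by :func:`write_coded_csv`."""
    out: list[CodedRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            age = row["age_years"]
            raw = RawDeathRecord(
                record_id=row["record_id"],
                data_year=int(row["data_year"]),
                age_years=int(age) if age else None,
                sex=row["sex"],
                race=row["race"],
                education=row["education"] or None,
                marital=row["marital"] or None,
                resident_status=row["resident_status"],
                place_of_death=row["place_of_death"] or None,
                manner=row["manner"] or None,
                underlying_cause=row["underlying_cause"],
                entity_conditions=tuple(c for c in row["conditions"].split() if c),
            )
            cats = frozenset(c for c in row["categories"].split("|") if c)
            out.append(
                CodedRecord(
                    raw=raw,
                    categories=cats,
                    underlying_category=row["underlying_category"],
                    multimorbid=int(row["multimorbid"]),
                    age_group=row["age_group"] or None,
                )
            )
    return out


def build_indicator_matrix(
    records: Sequence[CodedRecord],
    vocab: Sequence[str],
) -> np.ndarray:
    """Binary record x category matrix over *vocab* (row sum = number of
    different conditions on the record)."""
    index = {label: j for j, label in enumerate(vocab)}
    out = np.zeros((len(records), len(vocab)), dtype=np.float64)
    for i, rec in enumerate(records):
        for cat in rec.categories:
            j = index.get(cat)
            if j is None:
                raise ValueError(
                    f"record {rec.record_id!r} carries category {cat!r} "
                    "absent from the vocabulary"
                )
            out[i, j] = 1.0
    return out
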