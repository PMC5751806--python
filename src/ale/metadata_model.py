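"""Data model and I/O for GEO sample metadata.

A GEO sample (GSM) carries free-text annotation fields supplied by the
submitting investigator: a title, a description, per-channel "source name"
and "characteristics" strings, plus organism/molecule and the accessions
linking it to its series (experiment, GSE) and platform (GPL).  The
characteristics field is a loosely structured block of ``key: value`` pairs
("Age: 25 days; Tissue: Pancreas; ...") and is the single most informative
field for label extraction, so it is parsed eagerly into ordered pairs.

Readers accept a GEOmetadb-style SQLite table, TSV, or JSON-lines; column
names follow either the GEOmetadb dialect (``gsm``, ``characteristics_ch1``)
or generic names (``sample_id``, ``characteristics``) via an alias map.
Unknown columns are never dropped — they are routed to ``extra_fields`` and
remain searchable.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import MetadataError

logger = logging.getLogger(__name__)

#: Pair separators accepted inside a characteristics block.  GEOmetadb
#: concatenates pairs with semicolons; raw SOFT exports use newlines or tabs.
DEFAULT_SEPARATORS: tuple[str, ...] = (";", "\t", "\n")


def parse_characteristics(
    raw: str, separators: Sequence[str] = DEFAULT_SEPARATORS
) -> list[tuple[str, str]]:
    """Split a raw characteristics block into ordered ``(key, value)`` pairs.

    Segments are delimited by any of *separators*; each segment is split on
    its FIRST colon only, so values may themselves contain colons
    ("tissue: liver: left lobe" -> ("tissue", "liver: left lobe")).  Keys and
    values are whitespace-trimmed.  A segment without a colon becomes a pair
    with an empty key.  Total function: empty input yields an empty list.
    """
    if raw is None or not raw.strip():
        return []
    sep_re = "|".join(re.escape(s) for s in separators)
    pairs: list[tuple[str, str]] = []
    for segment in re.split(sep_re, raw):
        segment = segment.strip()
        if not segment:
            continue
        if ":" in segment:
            key, value = segment.split(":", 1)
            pairs.append((key.strip(), value.strip()))
        else:
            pairs.append(("", segment))
    return pairs


def serialize_characteristics(pairs: Iterable[tuple[str, str]], sep: str = "; ") -> str:
    """Inverse of :func:`parse_characteristics` for colon-free keys."""
    return sep.join(f"{k}: {v}" if k else v for k, v in pairs)


@dataclass
class SampleMetadata:
    """Textual annotation of one GEO sample.

    ``source_name``, ``characteristics_raw`` and ``characteristics`` are
    keyed by microarray channel number (1 for one-color arrays, 1 and 2 for
    two-color arrays).  ``characteristics`` is always derivable from
    ``characteristics_raw`` via :func:`parse_characteristics`.
    """

    sample_id: str
    series_id: str = ""
    platform_id: str = ""
    organism: str = ""
    molecule: str = ""
    title: str = ""
    description: str = ""
    source_name: dict[int, str] = field(default_factory=dict)
    characteristics_raw: dict[int, str] = field(default_factory=dict)
    characteristics: dict[int, list[tuple[str, str]]] = field(default_factory=dict)
    extra_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise MetadataError("sample_id must be nonempty")
        for ch in (*self.source_name, *self.characteristics_raw):
            if not (isinstance(ch, int) and ch >= 1):
                raise MetadataError(f"channel numbers must be positive ints, got {ch!r}")
        if not self.characteristics:
            self.characteristics = {
                ch: parse_characteristics(raw)
                for ch, raw in self.characteristics_raw.items()
            }


@dataclass(frozen=True)
class FieldOrder:
    """Order in which annotation fields are searched for a label.

    The parsed characteristics pairs come first because they are attributes
    the experimenter explicitly labeled; if a label is found there the search
    terminates.  Otherwise the remaining free-text fields are tried in order.
    """

    fields: tuple[str, ...] = (
        "characteristics",
        "description",
        "source_name",
        "title",
        "extra",
    )

    _KNOWN = frozenset({"characteristics", "description", "source_name", "title", "extra"})

    def __post_init__(self) -> None:
        unknown = set(self.fields) - self._KNOWN
        if unknown:
            raise MetadataError(f"unknown field classes: {sorted(unknown)}")


DEFAULT_FIELD_ORDER = FieldOrder()


def field_units(
    meta: SampleMetadata,
    field_class: str,
    priority_key_re: str | re.Pattern[str] | None = None,
) -> list[tuple[str, str | None, str]]:
    """Enumerate the searchable text units of one field class.

    Returns ``(field_label, key, text)`` triples.  For ``characteristics``
    one triple is produced per parsed pair (channel 1 before channel 2);
    pairs whose key matches *priority_key_re* are moved to the front, which
    lets an extractor inspect e.g. the explicit "sex:" pair before the rest.
    For the free-text classes ``key`` is None and ``text`` is the whole field.
    """
    if field_class == "characteristics":
        prio = re.compile(priority_key_re, re.IGNORECASE) if priority_key_re else None
        first: list[tuple[str, str | None, str]] = []
        rest: list[tuple[str, str | None, str]] = []
        for ch in sorted(meta.characteristics):
            for key, value in meta.characteristics[ch]:
                unit = (f"characteristics_ch{ch}", key, value)
                if prio is not None and prio.search(key):
                    first.append(unit)
                else:
                    rest.append(unit)
        return first + rest
    if field_class == "description":
        return [("description", None, meta.description)] if meta.description else []
    if field_class == "source_name":
        return [
            (f"source_name_ch{ch}", None, meta.source_name[ch])
            for ch in sorted(meta.source_name)
            if meta.source_name[ch]
        ]
    if field_class == "title":
        return [("title", None, meta.title)] if meta.title else []
    if field_class == "extra":
        return [(name, None, text) for name, text in meta.extra_fields.items() if text]
    raise MetadataError(f"unknown field class {field_class!r}")


# ---------------------------------------------------------------------------
# column-name dialects

_SIMPLE_ALIASES = {
    "gsm": "sample_id",
    "sample_id": "sample_id",
    "geo_accession": "sample_id",
    "series_id": "series_id",
    "gse": "series_id",
    "gpl": "platform_id",
    "platform_id": "platform_id",
    "title": "title",
    "description": "description",
}

_CHANNEL_RE = re.compile(r"^(characteristics|source_name|organism|molecule)(?:_ch(\d+))?$")


def metadata_from_row(row: dict[str, object]) -> SampleMetadata:
    """Build a :class:`SampleMetadata` from one flat column->text mapping.

    Accepts both GEOmetadb and generic column names; NULL/None values become
    empty strings; unrecognized columns land in ``extra_fields``.
    """
    fields: dict[str, object] = {
        "source_name": {},
        "characteristics_raw": {},
        "extra_fields": {},
    }
    for col, value in row.items():
        text = "" if value is None else str(value)
        name = col.strip().lower()
        if name in _SIMPLE_ALIASES:
            fields[_SIMPLE_ALIASES[name]] = text
            continue
        m = _CHANNEL_RE.match(name)
        if m:
            base, ch_str = m.group(1), m.group(2)
            ch = int(ch_str) if ch_str else 1
            if base == "characteristics":
                fields["characteristics_raw"][ch] = text
            elif base == "source_name":
                fields["source_name"][ch] = text
            elif ch == 1:  # organism/molecule are single strings; ch1 wins
                fields[base] = text
            else:
                fields["extra_fields"][col] = text
            continue
        fields["extra_fields"][col] = text
    if "sample_id" not in fields:
        raise MetadataError(f"row lacks a sample id column: {sorted(row)}")
    return SampleMetadata(**fields)  # type: ignore[arg-type]


def read_metadata_sqlite(
    path: str | Path, table: str = "gsm", query: str | None = None
) -> list[SampleMetadata]:
    """Read sample metadata from a GEOmetadb-style SQLite database.

    *query* overrides the default ``SELECT * FROM {table}``.  The table must
    carry a sample-id column (``gsm`` or ``sample_id``); any other subset of
    the known columns is accepted, missing ones become empty fields.
    """
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such SQLite file: {path}")
    try:
        con = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
        try:
            con.row_factory = sqlite3.Row
            rows = con.execute(query or f"SELECT * FROM {table}").fetchall()
        finally:
            con.close()
    except sqlite3.Error as exc:
        raise MetadataError(f"cannot read {path}: {exc}") from exc
    return [metadata_from_row(dict(r)) for r in rows]


def _flatten(meta: SampleMetadata) -> dict[str, str]:
    out = {
        "sample_id": meta.sample_id,
        "series_id": meta.series_id,
        "platform_id": meta.platform_id,
        "organism": meta.organism,
        "molecule": meta.molecule,
        "title": meta.title,
        "description": meta.description,
    }
    for ch in sorted(meta.source_name):
        out[f"source_name_ch{ch}"] = meta.source_name[ch]
    for ch in sorted(meta.characteristics_raw):
        out[f"characteristics_ch{ch}"] = meta.characteristics_raw[ch]
    out.update(meta.extra_fields)
    return out


def read_metadata_tabular(path: str | Path) -> list[SampleMetadata]:
    """Read metadata from TSV (``.tsv``) or JSON-lines (``.jsonl``/``.json``)."""
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such metadata file: {path}")
    if path.suffix in {".jsonl", ".json"}:
        records = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    records.append(metadata_from_row(json.loads(line)))
        return records
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        return [metadata_from_row(row) for row in reader]


def write_metadata_tabular(path: str | Path, records: Iterable[SampleMetadata]) -> None:
    """Write metadata as TSV (or JSON-lines if the path ends in .jsonl)."""
    path = Path(path)
    rows = [_flatten(m) for m in records]
    if path.suffix == ".jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
        return
    columns: list[str] = []
    for row in rows:
        for col in row:
            if col not in columns:
                columns.append(col)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# label records (the pipeline's common output currency)

LABEL_COLUMNS = (
    "sample_id",
    "label_type",
    "value",
    "unit",
    "source",
    "confidence",
    "matched_field",
    "matched_text",
)


@dataclass(frozen=True)
class LabelRecord:
    """One extracted or predicted label, with full provenance."""

    sample_id: str
    label_type: str  # sex | age | tissue
    value: str  # sex category, age in years, or ontology term id
    unit: str = ""  # raw age unit as written ("days"), else empty
    source: str = "text"  # text | ml
    confidence: float = 1.0
    matched_field: str = ""
    matched_text: str = ""


def write_labels(path: str | Path, labels: Iterable[LabelRecord]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LABEL_COLUMNS)
        for lab in labels:
            writer.writerow(
                [
                    lab.sample_id,
                    lab.label_type,
                    lab.value,
                    lab.unit,
                    lab.source,
                    repr(lab.confidence),
                    lab.matched_field,
                    lab.matched_text,
                ]
            )


def read_labels(path: str | Path) -> list[LabelRecord]:
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such label file: {path}")
    out: list[LabelRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                LabelRecord(
                    sample_id=row["sample_id"],
                    label_type=row["label_type"],
                    value=row["value"],
                    unit=row.get("unit", ""),
                    source=row.get("source", "text"),
                    confidence=float(row.get("confidence", 1.0)),
                    matched_field=row.get("matched_field", ""),
                    matched_text=row.get("matched_text", ""),
                )
            )
    return out
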