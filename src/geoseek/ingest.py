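"""Reading, writing, and filtering series-level repository metadata.

A *series* is one submitted study record (GEO-style ``GSE...`` accession)
carrying free-text fields (title, summary, overall design) plus the
attributes used for inclusion filtering (organisms, experiment types,
platform vendor, retired/subseries flags).

Three dialects are supported:

* ``soft`` — the key-value ``!Series_<field> = value`` lines of GEO's SOFT
  family of formats.  Only series-level lines are read; sample- and
  platform-level lines are ignored.  SOFT carries platform accessions, not
  vendors, so a platform->vendor mapping may be supplied.
* ``json`` — the canonical dialect: a UTF-8 array of objects whose field
  names match :class:`SeriesRecord`.
* ``tsv`` — a header row plus one series per row; set-valued fields are
  semicolon-joined and a ``has_overall_design`` column distinguishes an
  absent overall design from an empty one.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

__all__ = [
    "SeriesRecord",
    "FilterCriteria",
    "DEFAULT_CRITERIA",
    "MetadataParseError",
    "parse_series_metadata",
    "filter_series",
    "records_to_json",
    "records_to_tsv",
]


class MetadataParseError(ValueError):
    """Malformed metadata input (missing accession, duplicate accession, ...)."""


@dataclass(frozen=True)
class SeriesRecord:
    """One data series and the metadata fields the pipeline consumes.

    ``overall_design`` is ``None`` when the submitter provided none; this is
    distinct from an empty string.
    """

    accession: str
    title: str
    summary: str = ""
    overall_design: str | None = None
    organisms: frozenset[str] = field(default_factory=frozenset)
    experiment_types: frozenset[str] = field(default_factory=frozenset)
    platform_vendor: str | None = None
    is_retired: bool = False
    is_subseries: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.title:
            raise ValueError(f"{self.accession}: title must be non-empty")
        object.__setattr__(self, "organisms", frozenset(self.organisms))
        object.__setattr__(self, "experiment_types", frozenset(self.experiment_types))


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria applied by :func:`filter_series`.

    ``allowed_combinations`` is a set of (experiment type, platform vendor)
    pairs; a record passes if at least one of its experiment types, combined
    with its vendor, matches a pair (case-insensitively).
    """

    required_organism: str = "Homo sapiens"
    allowed_combinations: frozenset[tuple[str, str]] = frozenset()
    exclude_retired: bool = True
    exclude_subseries: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_combinations:
            raise ValueError("allowed_combinations must be non-empty")
        object.__setattr__(
            self,
            "allowed_combinations",
            frozenset((e.lower(), v.lower()) for e, v in self.allowed_combinations),
        )


#: Inclusion rules for human transcriptomic series: not retired, homo sapiens,
#: array profiling on Affymetrix/Illumina/Agilent or high-throughput
#: sequencing profiling on Illumina, and not a subseries of a superseries.
DEFAULT_CRITERIA = FilterCriteria(
    required_organism="Homo sapiens",
    allowed_combinations=frozenset(
        [
            ("expression profiling by array", "Affymetrix"),
            ("expression profiling by array", "Illumina"),
            ("expression profiling by array", "Agilent"),
            ("expression profiling by high throughput sequencing", "Illumina"),
        ]
    ),
)


def filter_series(
    records: Iterable[SeriesRecord], criteria: FilterCriteria = DEFAULT_CRITERIA
) -> list[SeriesRecord]:
    """Return the records satisfying *all* criteria, in input order.

    A record missing a criterion-relevant field (no organisms, no vendor)
    fails that criterion.
    """
    organism = criteria.required_organism.lower()
    kept = []
    for rec in records:
        if criteria.exclude_retired and rec.is_retired:
            continue
        if criteria.exclude_subseries and rec.is_subseries:
            continue
        if organism not in {o.lower() for o in rec.organisms}:
            continue
        vendor = (rec.platform_vendor or "").lower()
        pairs = {(e.lower(), vendor) for e in rec.experiment_types}
        if not pairs & criteria.allowed_combinations:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Parsing


def parse_series_metadata(
    stream: TextIO | str,
    dialect: str = "soft",
    platform_vendors: Mapping[str, str] | None = None,
) -> list[SeriesRecord]:
    """Parse series metadata from *stream* in the given dialect.

    Parameters
    ----------
    stream
        An open text stream or a string of file content.
    dialect
        One of ``soft``, ``json``, ``tsv``.
    platform_vendors
        Platform-accession -> vendor mapping, used only by the SOFT dialect
        (SOFT series blocks name platforms such as ``GPL570``, not vendors).

    Raises
    ------
    MetadataParseError
        If a block/row lacks an accession (the error names the line) or an
        accession occurs twice.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if dialect == "soft":
        records = _parse_soft(stream, platform_vendors or {})
    elif dialect == "json":
        records = _parse_json(stream)
    elif dialect == "tsv":
        records = _parse_tsv(stream)
    else:
        raise ValueError(f"unsupported dialect: {dialect!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise MetadataParseError(f"duplicate accession: {rec.accession}")
        seen.add(rec.accession)
    return records


def _parse_soft(stream: TextIO, platform_vendors: Mapping[str, str]) -> list[SeriesRecord]:
    blocks: list[tuple[int, dict[str, list[str]]]] = []
    current: dict[str, list[str]] | None = None
    start_line = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("^SERIES"):
            current = {}
            start_line = lineno
            blocks.append((start_line, current))
            continue
        if not line.startswith("!Series_"):
            continue  # sample/platform-level or comment lines
        if current is None:
            current = {}
            start_line = lineno
            blocks.append((start_line, current))
        key, _, value = line[len("!Series_") :].partition("=")
        current.setdefault(key.strip().lower(), []).append(value.strip())

    records = []
    for lineno, block in blocks:
        acc_values = block.get("geo_accession")
        if not acc_values or not acc_values[0]:
            raise MetadataParseError(
                f"series block starting at line {lineno} has no !Series_geo_accession"
            )
        platforms = block.get("platform_id", [])
        vendors = {platform_vendors[p] for p in platforms if p in platform_vendors}
        relations = block.get("relation", [])
        status = " ".join(block.get("status", [])).lower()
        records.append(
            SeriesRecord(
                accession=acc_values[0],
                title=" ".join(block.get("title", [])),
                summary=" ".join(block.get("summary", [])),
                overall_design=(
                    " ".join(block["overall_design"]) if "overall_design" in block else None
                ),
                organisms=frozenset(block.get("organism", []))
                | frozenset(block.get("sample_organism", [])),
                experiment_types=frozenset(block.get("type", [])),
                platform_vendor=sorted(vendors)[0] if vendors else None,
                is_retired="retired" in status,
                is_subseries=any(r.lower().startswith("subseries of") for r in relations),
            )
        )
    return records


_JSON_FIELDS = (
    "accession",
    "title",
    "summary",
    "overall_design",
    "organisms",
    "experiment_types",
    "platform_vendor",
    "is_retired",
    "is_subseries",
)


def _record_from_mapping(obj: Mapping, where: str) -> SeriesRecord:
    if not obj.get("accession"):
        raise MetadataParseError(f"{where}: missing accession")
    return SeriesRecord(
        accession=obj["accession"],
        title=obj.get("title", ""),
        summary=obj.get("summary", ""),
        overall_design=obj.get("overall_design"),
        organisms=frozenset(obj.get("organisms", ())),
        experiment_types=frozenset(obj.get("experiment_types", ())),
        platform_vendor=obj.get("platform_vendor"),
        is_retired=bool(obj.get("is_retired", False)),
        is_subseries=bool(obj.get("is_subseries", False)),
    )


def _parse_json(stream: TextIO) -> list[SeriesRecord]:
    try:
        data = json.load(stream)
    except json.JSONDecodeError as exc:
        raise MetadataParseError(f"invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, list):
        raise MetadataParseError("canonical JSON dialect requires a top-level array")
    return [_record_from_mapping(obj, f"object {i}") for i, obj in enumerate(data)]


def _parse_tsv(stream: TextIO) -> list[SeriesRecord]:
    reader = csv.DictReader(stream, delimiter="\t")
    records = []
    for i, row in enumerate(reader, start=2):  # line 1 is the header
        if not row.get("accession"):
            raise MetadataParseError(f"line {i}: missing accession")
        has_design = row.get("has_overall_design", "").strip().lower() in {"1", "true", "yes"}
        records.append(
            SeriesRecord(
                accession=row["accession"],
                title=row.get("title", ""),
                summary=row.get("summary", ""),
                overall_design=row.get("overall_design", "") if has_design else None,
                organisms=frozenset(_split_multi(row.get("organisms", ""))),
                experiment_types=frozenset(_split_multi(row.get("experiment_types", ""))),
                platform_vendor=row.get("platform_vendor") or None,
                is_retired=row.get("is_retired", "").strip().lower() in {"1", "true", "yes"},
                is_subseries=row.get("is_subseries", "").strip().lower() in {"1", "true", "yes"},
            )
        )
    return records


def _split_multi(value: str) -> list[str]:
    return [part for part in (p.strip() for p in value.split(";")) if part]


# ---------------------------------------------------------------------------
# Writers (both emit UTF-8 text; callers handle files)


def records_to_json(records: Iterable[SeriesRecord]) -> str:
    """Serialize records to the canonical JSON dialect (deterministic bytes)."""
    objs = []
    for rec in records:
        obj = {
            "accession": rec.accession,
            "title": rec.title,
            "summary": rec.summary,
            "overall_design": rec.overall_design,
            "organisms": sorted(rec.organisms),
            "experiment_types": sorted(rec.experiment_types),
            "platform_vendor": rec.platform_vendor,
            "is_retired": rec.is_retired,
            "is_subseries": rec.is_subseries,
        }
        objs.append(obj)
    return json.dumps(objs, ensure_ascii=False, sort_keys=True, indent=1) + "\n"


def records_to_tsv(records: Iterable[SeriesRecord]) -> str:
    """Serialize records to the TSV dialect."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(
        [
            "accession",
            "title",
            "summary",
            "overall_design",
            "has_overall_design",
            "organisms",
            "experiment_types",
            "platform_vendor",
            "is_retired",
            "is_subseries",
        ]
    )
    for rec in records:
        writer.writerow(
            [
                rec.accession,
                rec.title,
                rec.summary,
                rec.overall_design or "",
                "true" if rec.overall_design is not None else "false",
                ";".join(sorted(rec.organisms)),
                ";".join(sorted(rec.experiment_types)),
                rec.platform_vendor or "",
                "true" if rec.is_retired else "false",
                "true" if rec.is_subseries else "false",
            ]
        )
    return buf.getvalue()
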