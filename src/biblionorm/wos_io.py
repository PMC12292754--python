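"""Reading, filtering, and writing Web of Science-style tab-delimited exports.

The supported dialect is the WoS Core Collection "Tab-delimited (UTF-8)"
export: one header row of two-letter field tags (AU, TI, SO, DE, ID, C1,
DT, LA, PY, TC, UT, ...), one data row per record, and multi-valued
fields joined with ``"; "``.  The line-tagged "plain text" dialect is
intentionally unsupported.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "PublicationRecord",
    "Corpus",
    "FilterCriteria",
    "FilterReport",
    "WosFormatError",
    "CorpusIntegrityError",
    "parse_wos_export",
    "write_wos_export",
    "apply_inclusion_filters",
    "extract_countries",
    "read_country_mapping",
    "DEFAULT_COUNTRY_MAPPING",
    "UK_CONSTITUENTS",
]


class WosFormatError(ValueError):
    """The input stream is not a parseable tab-delimited WoS export."""


class CorpusIntegrityError(ValueError):
    """A corpus-level invariant (e.g. unique record ids) is violated."""


#: Field tags the parser requires in the header row.
REQUIRED_TAGS = ("DT", "LA", "PY", "TC")

#: WoS spells some countries in more than one way; this default table maps
#: the known variant spellings to one canonical label.
DEFAULT_COUNTRY_MAPPING: dict[str, str] = {
    "Turkiye": "Turkey",
    "Peoples R China": "China",
    "U Arab Emirates": "United Arab Emirates",
    "Czechia": "Czech Republic",
}

#: Constituent countries that WoS lists instead of "United Kingdom".
UK_CONSTITUENTS = ("England", "Scotland", "Wales", "North Ireland", "Northern Ireland")

#: Frequent country labels that need no normalization; anything outside this
#: set and the mapping table is passed through verbatim but logged as unknown.
_COMMON_COUNTRIES = frozenset(
    {
        "USA", "China", "United Kingdom", "Italy", "Germany", "Canada",
        "France", "India", "Australia", "Japan", "Spain", "Netherlands",
        "Switzerland", "Sweden", "Denmark", "Brazil", "South Korea",
        "Saudi Arabia", "Turkey", "Egypt", "Iran", "Singapore", "Belgium",
        "Austria", "Norway", "Finland", "Poland", "Portugal", "Greece",
        "Ireland", "Israel", "Mexico", "Argentina", "South Africa",
        "New Zealand", "Pakistan", "Thailand", "Malaysia", "Taiwan",
    }
)


@dataclass
class PublicationRecord:
    """One bibliographic record from a WoS-style export."""

    record_id: str
    document_type: str
    language: str
    title: str = ""
    source_title: str = ""
    author_keywords: list[str] = field(default_factory=list)
    keywords_plus: list[str] = field(default_factory=list)
    countries: list[str] = field(default_factory=list)
    publication_year: int | None = None
    times_cited: int = 0

    def __post_init__(self) -> None:
        if self.times_cited < 0:
            raise ValueError(f"times_cited must be >= 0, got {self.times_cited}")
        if self.publication_year is not None and not (1900 <= self.publication_year <= 2100):
            raise ValueError(f"implausible publication year {self.publication_year}")
        self.author_keywords = [k for k in self.author_keywords if k.strip()]
        self.keywords_plus = [k for k in self.keywords_plus if k.strip()]

    def document_type_components(self) -> list[str]:
        """Semicolon-split components of a possibly compound document type.

        WoS emits compound types like ``"Article; Early Access"``; filtering
        tests membership on the components, so that record counts as Article.
        """
        return [part.strip() for part in self.document_type.split(";") if part.strip()]


@dataclass
class Corpus:
    """An ordered collection of publication records with parse provenance."""

    records: list[PublicationRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise CorpusIntegrityError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria for corpus refinement.

    A record is retained iff any component of its document type is in
    ``allowed_types``, its language is in ``allowed_languages``, and its
    year falls inside ``year_range`` (both ends inclusive; ``None`` leaves
    the corresponding end unbounded).
    """

    allowed_types: frozenset[str] = frozenset({"Article", "Review"})
    allowed_languages: frozenset[str] = frozenset({"English"})
    year_range: tuple[int | None, int | None] = (None, None)

    def __post_init__(self) -> None:
        if not self.allowed_types or not self.allowed_languages:
            raise ValueError("allowed_types and allowed_languages must be non-empty")


@dataclass
class FilterReport:
    """Accounting of one filtering pass: every removal attributed to a rule."""

    n_input: int
    n_retained: int
    n_removed_by_rule: dict[str, int]

    @property
    def percent_reduction(self) -> float:
        """Percentage of input records removed; 0 for an empty input."""
        if self.n_input == 0:
            return 0.0
        return 100.0 * (self.n_input - self.n_retained) / self.n_input

    def validate(self) -> None:
        if self.n_retained + sum(self.n_removed_by_rule.values()) != self.n_input:
            raise CorpusIntegrityError("filter report does not conserve record count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_removed_by_rule": self.n_removed_by_rule,
                "percent_reduction": self.percent_reduction,
            },
            indent=2,
        )


def _split_multi(value: str) -> list[str]:
    return [part.strip() for part in value.split(";") if part.strip()]


def extract_countries(
    affiliation_field: str,
    mapping_table: Mapping[str, str] | None = None,
    merge_uk: bool = True,
    unknown_log: list[str] | None = None,
) -> list[str]:
    """Extract a deduplicated list of country labels from a C1-style field.

    Addresses are ``"; "``-separated with the country as the last
    comma-separated token of each address.  An optional ``[Author; ...]``
    prefix (WoS address grammar) is ignored.  Variant spellings are
    normalized through ``mapping_table``; with ``merge_uk`` the UK
    constituent countries collapse to "United Kingdom".  Unmapped labels
    pass through verbatim (and are appended to ``unknown_log`` if given).
    """
    if not affiliation_field or not affiliation_field.strip():
        return []
    mapping = dict(DEFAULT_COUNTRY_MAPPING)
    if mapping_table:
        mapping.update(mapping_table)

    text = affiliation_field
    # Strip bracketed author lists so their internal semicolons do not split addresses.
    out: list[str] = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(depth - 1, 0)
        elif depth == 0:
            out.append(ch)
    text = "".join(out)

    countries: list[str] = []
    for address in text.split(";"):
        address = address.strip()
        if not address:
            continue
        token = address.rsplit(",", 1)[-1].strip().rstrip(".").strip()
        if not token:
            continue
        # "90210 USA" style zip+country tails
        if token.upper().endswith("USA"):
            token = "USA"
        label = mapping.get(token, token)
        if merge_uk and label in UK_CONSTITUENTS:
            label = "United Kingdom"
        if (
            unknown_log is not None
            and token not in mapping
            and token not in UK_CONSTITUENTS
            and token not in _COMMON_COUNTRIES
        ):
            unknown_log.append(token)
        if label not in countries:
            countries.append(label)
    return countries


def read_country_mapping(stream: io.TextIOBase | Iterable[str]) -> dict[str, str]:
    """Read a two-column tab-separated variant -> canonical country table."""
    mapping: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise WosFormatError(f"country mapping rows need 2 columns, got: {line!r}")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def parse_wos_export(
    stream: io.TextIOBase | Iterable[str],
    country_mapping: Mapping[str, str] | None = None,
    merge_uk_countries: bool = True,
    source_name: str = "<stream>",
) -> Corpus:
    """Parse a tab-delimited WoS export into a :class:`Corpus`.

    Rows missing a required field are kept (with logged defaults: missing
    citations -> 0, missing year -> None) and reported in the corpus
    provenance under ``"warnings"`` rather than silently dropped.

    Raises
    ------
    WosFormatError
        If the stream is empty or the header lacks a required tag.
    CorpusIntegrityError
        If two rows share a record id.
    """
    reader = csv.reader(iter(stream), delimiter="\t", quoting=csv.QUOTE_NONE)
    try:
        header = next(reader)
    except StopIteration:
        raise WosFormatError("empty stream: expected a header row of WoS field tags") from None
    header = [tag.strip().lstrip("﻿") for tag in header]
    missing = [tag for tag in REQUIRED_TAGS if tag not in header]
    if missing:
        raise WosFormatError(
            f"header is missing required field tags {missing}; expected at least {list(REQUIRED_TAGS)}"
        )
    col = {tag: i for i, tag in enumerate(header)}

    def get(row: Sequence[str], tag: str) -> str:
        i = col.get(tag)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    warnings: list[str] = []
    records: list[PublicationRecord] = []
    for lineno, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        record_id = get(row, "UT") or f"ROW-{lineno}"
        tc_raw = get(row, "TC")
        if tc_raw:
            times_cited = int(float(tc_raw))
        else:
            times_cited = 0
            warnings.append(f"{record_id}: missing TC, defaulting to 0")
        py_raw = get(row, "PY")
        year: int | None
        if py_raw:
            year = int(float(py_raw))
        else:
            year = None
            warnings.append(f"{record_id}: missing PY, excluded from year-based metrics")
        if not get(row, "DT"):
            warnings.append(f"{record_id}: missing DT")
        if not get(row, "LA"):
            warnings.append(f"{record_id}: missing LA")
        records.append(
            PublicationRecord(
                record_id=record_id,
                document_type=get(row, "DT"),
                language=get(row, "LA"),
                title=get(row, "TI"),
                source_title=get(row, "SO"),
                author_keywords=_split_multi(get(row, "DE")),
                keywords_plus=_split_multi(get(row, "ID")),
                countries=extract_countries(
                    get(row, "C1") or get(row, "RP"),
                    country_mapping,
                    merge_uk=merge_uk_countries,
                ),
                publication_year=year,
                times_cited=times_cited,
            )
        )
    return Corpus(records, provenance={"source": source_name, "warnings": warnings})


_WRITE_TAGS = ("UT", "DT", "LA", "TI", "SO", "DE", "ID", "C1", "PY", "TC")


def write_wos_export(corpus: Corpus, stream: io.TextIOBase) -> None:
    """Serialize a corpus back to the tab-delimited dialect.

    Countries are written as one synthetic address per country so that
    ``parse_wos_export(write_wos_export(c))`` round-trips field-by-field
    (assuming country labels are already canonical).
    """
    writer = csv.writer(stream, delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None, lineterminator="\n")
    writer.writerow(_WRITE_TAGS)
    for rec in corpus:
        c1 = "; ".join(f"Institution, City, {country}" for country in rec.countries)
        writer.writerow(
            [
                rec.record_id,
                rec.document_type,
                rec.language,
                rec.title,
                rec.source_title,
                "; ".join(rec.author_keywords),
                "; ".join(rec.keywords_plus),
                c1,
                "" if rec.publication_year is None else str(rec.publication_year),
                str(rec.times_cited),
            ]
        )


def apply_inclusion_filters(
    corpus: Corpus, criteria: FilterCriteria
) -> tuple[Corpus, FilterReport]:
    """Apply document-type / language / year inclusion criteria.

    Each removed record is attributed to the first rule it fails, in the
    order document_type, language, year.  The report conserves counts:
    retained + removals == input.
    """
    retained: list[PublicationRecord] = []
    removed = {"document_type": 0, "language": 0, "year": 0}
    lo, hi = criteria.year_range
    for rec in corpus:
        if not set(rec.document_type_components()) & criteria.allowed_types:
            removed["document_type"] += 1
            continue
        if rec.language not in criteria.allowed_languages:
            removed["language"] += 1
            continue
        year_ok = True
        if lo is not None or hi is not None:
            if rec.publication_year is None:
                year_ok = False
            else:
                if lo is not None and rec.publication_year < lo:
                    year_ok = False
                if hi is not None and rec.publication_year > hi:
                    year_ok = False
        if not year_ok:
            removed["year"] += 1
            continue
        retained.append(rec)
    report = FilterReport(
        n_input=len(corpus), n_retained=len(retained), n_removed_by_rule=removed
    )
    report.validate()
    filtered = Corpus(retained, provenance=dict(corpus.provenance, filtered=True))
    return filtered, report
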