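"""Citation and productivity indicators for bibliometric tables.

All year arithmetic uses the inclusive active-years convention: a source
publishing since 1977 evaluated at reference year 2025 has been active
``2025 - 1977 + 1 = 49`` years.  This is the convention under which the
standard indicator tables (h/g/m-index per source, TC/Year per document)
are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .wos_io import Corpus

__all__ = [
    "MetricsConfig",
    "h_index",
    "g_index",
    "m_index",
    "tc_per_year",
    "mean_tc_per_year",
    "normalized_tc",
    "avg_citations_per_doc",
    "percent_change",
    "annual_increments",
    "trend_topic_stats",
    "round_half_up",
    "source_table",
    "country_table",
    "annual_citation_profile",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Reference year for age-based rates; never inferred from the clock."""

    reference_year: int = 2025


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding, the convention of printed indicator tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def h_index(citation_counts: Iterable[int]) -> int:
    """Largest h such that at least h items have >= h citations each."""
    counts = sorted((int(c) for c in citation_counts), reverse=True)
    h = 0
    for i, c in enumerate(counts, start=1):
        if c >= i:
            h = i
        else:
            break
    return h


def g_index(citation_counts: Iterable[int]) -> int:
    """Largest g <= N whose top-g items jointly have >= g^2 citations.

    The index is capped at the number of items (no zero-padding), so a
    single 100-cited paper has g = 1.
    """
    counts = sorted((int(c) for c in citation_counts), reverse=True)
    cumulative = 0
    g = 0
    for i, c in enumerate(counts, start=1):
        cumulative += c
        if cumulative >= i * i:
            g = i
    return g


def m_index(h: int, first_year: int, reference_year: int) -> float:
    """m-quotient: h-index per inclusive active year."""
    if first_year > reference_year:
        raise ValueError("first_year must not exceed reference_year")
    return h / (reference_year - first_year + 1)


def tc_per_year(times_cited: int, publication_year: int, reference_year: int) -> float:
    """Citations per inclusive year of document age."""
    if publication_year > reference_year:
        raise ValueError("publication_year must not exceed reference_year")
    return times_cited / (reference_year - publication_year + 1)


def mean_tc_per_year(corpus: Corpus, year: int, reference_year: int) -> float:
    """Mean TC/Year over the documents published in ``year``."""
    rates = [
        tc_per_year(rec.times_cited, year, reference_year)
        for rec in corpus
        if rec.publication_year == year
    ]
    if not rates:
        raise ValueError(f"no documents published in {year}")
    return float(np.mean(rates))


def normalized_tc(
    times_cited: int, cohort_citations: Sequence[int]
) -> float:
    """Document citations relative to its same-year cohort mean."""
    if not cohort_citations:
        raise ValueError("empty publication-year cohort")
    mean = float(np.mean(cohort_citations))
    if mean == 0:
        raise ValueError("cohort mean citations is zero; normalized TC undefined")
    return times_cited / mean


def avg_citations_per_doc(citations: int, documents: int) -> float:
    if documents < 1:
        raise ValueError("documents must be >= 1")
    return citations / documents


def percent_change(a: float, b: float) -> float:
    """Relative change from a to b, in percent."""
    if a == 0:
        raise ValueError("percent change from zero is undefined")
    return 100.0 * (b - a) / a


def annual_increments(cumulative_series: Mapping[int, int] | pd.Series) -> pd.Series:
    """Convert a cumulative per-year series to annual increments.

    The first year's increment equals its cumulative value; a decreasing
    cumulative series is a data error.
    """
    series = pd.Series(dict(cumulative_series)).sort_index()
    if (series.diff().dropna() < 0).any():
        raise ValueError("cumulative series must be non-decreasing")
    increments = series.diff()
    if len(series):
        increments.iloc[0] = series.iloc[0]
    return increments.astype(series.dtype)


def _nearest_rank(sorted_values: Sequence[int], p: float) -> int:
    """Nearest-rank quantile (ceil(p*n), lower-median convention)."""
    n = len(sorted_values)
    rank = max(1, int(np.ceil(p * n)))
    return sorted_values[rank - 1]


def trend_topic_stats(
    corpus: Corpus,
    keyword: str,
    min_freq: int = 1,
    field_selector: str = "both",
) -> tuple[int, int, int, int] | None:
    """Occurrence count and year quartiles for one (normalized) keyword.

    A document contributes its publication year once if the keyword occurs
    in the selected field(s).  Keywords below ``min_freq`` return None.
    Quartiles use the nearest-rank (lower-median) convention.
    """
    years = []
    for rec in corpus:
        fields: list[str] = []
        if field_selector in {"author_keywords", "both"}:
            fields += rec.author_keywords
        if field_selector in {"keywords_plus", "both"}:
            fields += rec.keywords_plus
        if keyword in fields and rec.publication_year is not None:
            years.append(rec.publication_year)
    if len(years) < min_freq:
        return None
    years.sort()
    return (
        len(years),
        _nearest_rank(years, 0.25),
        _nearest_rank(years, 0.50),
        _nearest_rank(years, 0.75),
    )


def source_table(corpus: Corpus, config: MetricsConfig | None = None) -> pd.DataFrame:
    """Per-source indicator table: h/g/m-index, total citations, volume, start year."""
    config = config or MetricsConfig()
    rows = []
    frame = pd.DataFrame(
        {
            "source": [r.source_title for r in corpus],
            "year": [r.publication_year for r in corpus],
            "tc": [r.times_cited for r in corpus],
        }
    )
    frame = frame[frame["source"] != ""]
    for source, docs in frame.groupby("source"):
        years = docs["year"].dropna()
        first_year = int(years.min()) if len(years) else None
        h = h_index(docs["tc"])
        rows.append(
            {
                "source": source,
                "h_index": h,
                "g_index": g_index(docs["tc"]),
                "m_index": (
                    round_half_up(m_index(h, first_year, config.reference_year), 3)
                    if first_year is not None
                    else float("nan")
                ),
                "total_citations": int(docs["tc"].sum()),
                "publications": len(docs),
                "publication_start": first_year,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["h_index", "total_citations"], ascending=False
        ).reset_index(drop=True)
    return table


def country_table(corpus: Corpus) -> pd.DataFrame:
    """Per-country documents, citations, and average citations/document."""
    agg: dict[str, dict[str, int]] = {}
    for rec in corpus:
        for country in rec.countries:
            entry = agg.setdefault(country, {"documents": 0, "citations": 0})
            entry["documents"] += 1
            entry["citations"] += rec.times_cited
    rows = [
        {
            "country": country,
            "documents": entry["documents"],
            "citations": entry["citations"],
            "avg_citations_per_doc": round_half_up(
                avg_citations_per_doc(entry["citations"], entry["documents"]), 2
            ),
        }
        for country, entry in agg.items()
    ]
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("documents", ascending=False).reset_index(drop=True)
    return table


def annual_citation_profile(corpus: Corpus, config: MetricsConfig | None = None) -> pd.DataFrame:
    """Per publication year: document count and mean TC/Year."""
    config = config or MetricsConfig()
    years = sorted({r.publication_year for r in corpus if r.publication_year is not None})
    rows = [
        {
            "year": year,
            "documents": sum(1 for r in corpus if r.publication_year == year),
            "mean_tc_per_year": mean_tc_per_year(corpus, year, config.reference_year),
        }
        for year in years
    ]
    return pd.DataFrame(rows)
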