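"""Three-tier synonym detection and thesaurus construction.

The normalization cascade takes a raw keyword vocabulary and produces a
VOSviewer-compatible thesaurus in five stages:

1. term cleaning (punctuation/whitespace/case normalization);
2. pharmaceutical component extraction (dosage forms, concentrations),
   yielding a core name per term;
3. three parallel synonym-pair detectors —
   * **exact**: equal signatures after removing hyphens and spaces,
   * **semantic**: DBSCAN on ``1 - cosine`` distances between term
     embeddings, emitting within-cluster pairs that individually meet the
     cosine threshold,
   * **fuzzy**: normalized string similarity of core names, gated so that
     conflicting concentrations or dosage forms block the pair;
4. graph-based merging of the pair evidence into connected-component
   synonym groups with a deterministic canonical-term rule
   (frequency, then brevity, then lexicographic order);
5. emission of an acyclic, idempotent variant -> canonical thesaurus.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field, replace
from difflib import SequenceMatcher
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .embeddings import CharNgramTfidfProvider, EmbeddingProvider, validate_embeddings
from .wos_io import Corpus, PublicationRecord

__all__ = [
    "NormalizationConfig",
    "TermComponents",
    "MatchEvidence",
    "SynonymGroup",
    "Thesaurus",
    "TermCleaningError",
    "ThesaurusIntegrityError",
    "clean_term",
    "extract_components",
    "exact_variation_pairs",
    "semantic_clusters",
    "fuzzy_match_pairs",
    "detect_synonym_pairs",
    "merge_groups",
    "select_canonical",
    "build_thesaurus",
    "write_thesaurus",
    "read_thesaurus",
    "apply_thesaurus",
    "extract_term_frequencies",
    "normalize_vocabulary",
]


class TermCleaningError(ValueError):
    """A term is unusable after cleaning (e.g. all punctuation)."""


class ThesaurusIntegrityError(ValueError):
    """Thesaurus invariants (single mapping, acyclicity) are violated."""


DEFAULT_DOSAGE_FORMS = frozenset(
    {"tablet", "capsule", "injection", "solution", "cream", "patch", "suspension"}
)
#: Concentration units; compound units (mg/ml, iu/ml) must sort before their
#: prefixes when building the recognizer regex.
DEFAULT_UNITS = frozenset({"mg", "g", "µg", "ug", "ml", "%", "mg/ml", "iu", "iu/ml"})


@dataclass(frozen=True)
class NormalizationConfig:
    """Tunable thresholds of the synonym cascade.

    cosine_threshold
        Minimum pairwise cosine similarity for the semantic tier; DBSCAN's
        eps is derived as ``1 - cosine_threshold``.
    fuzzy_ratio_threshold
        Minimum fuzzy similarity, as a percentage (the common fuzzy-ratio
        convention), between core names.
    min_group_size
        Smallest synonym group that is kept after merging.
    """

    cosine_threshold: float = 0.85
    dbscan_min_samples: int = 2
    fuzzy_ratio_threshold: float = 90.0
    min_group_size: int = 2
    dosage_form_lexicon: frozenset[str] = DEFAULT_DOSAGE_FORMS
    unit_lexicon: frozenset[str] = DEFAULT_UNITS
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cosine_threshold < 1.0):
            raise ValueError("cosine_threshold must be in (0, 1)")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if not (0.0 < self.fuzzy_ratio_threshold <= 100.0):
            raise ValueError("fuzzy_ratio_threshold is a percentage in (0, 100]")


@dataclass(frozen=True)
class TermComponents:
    """Pharmaceutical components split out of a cleaned term."""

    core_name: str
    dosage_form: str | None = None
    concentration: tuple[float, str] | None = None
    qualifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class MatchEvidence:
    """One detected synonym pair with its tier and similarity score."""

    term_a: str
    term_b: str
    tier: str  # exact | semantic | fuzzy
    score: float

    def __post_init__(self) -> None:
        if self.term_a == self.term_b:
            raise ValueError("evidence pair must link two distinct terms")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        a, b = sorted((self.term_a, self.term_b))
        return a, b


@dataclass
class SynonymGroup:
    canonical: str
    variants: set[str]
    evidence: list[MatchEvidence] = field(default_factory=list)

    @property
    def members(self) -> set[str]:
        return self.variants | {self.canonical}


class Thesaurus:
    """A variant -> canonical mapping, chain-free and idempotent.

    No canonical term may itself appear as a variant key, which makes a
    single application of the mapping a fixed point.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self.mapping: dict[str, str] = dict(mapping or {})
        self.validate()

    def validate(self) -> None:
        canonicals = set(self.mapping.values())
        chained = sorted(canonicals & self.mapping.keys())
        if chained:
            raise ThesaurusIntegrityError(
                f"canonical terms also appear as variants (chains): {chained}"
            )
        for variant, canonical in self.mapping.items():
            if variant == canonical:
                raise ThesaurusIntegrityError(f"self-mapping for {variant!r}")

    def apply(self, term: str) -> str:
        return self.mapping.get(term, term)

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Thesaurus) and self.mapping == other.mapping


_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")
_QUOTES = {0x2018: "'", 0x2019: "'", 0x201C: '"', 0x201D: '"', 0x00B4: "'", 0x0060: "'"}
_EDGE_PUNCT = "\"'`.,;:!?()[]{}<>/\\|-_*+=~^&%$#@"


def clean_term(text: str) -> str:
    """Normalize one raw keyword string.

    Lowercases, maps Unicode dashes to ``-`` and curly quotes to straight
    ones, collapses whitespace runs to single spaces, and strips leading
    and trailing punctuation.  Raises :class:`TermCleaningError` when
    nothing but punctuation remains.
    """
    if not text or not text.strip():
        raise TermCleaningError(f"empty term: {text!r}")
    s = unicodedata.normalize("NFKC", text)
    s = s.translate(_DASHES).translate(_QUOTES)
    s = s.lower()
    s = re.sub(r"\s+", " ", s).strip()
    s = s.strip(_EDGE_PUNCT + " ")
    if not s:
        raise TermCleaningError(f"term is all punctuation: {text!r}")
    return s


def _unit_pattern(units: Iterable[str]) -> re.Pattern[str]:
    alts = sorted(units, key=len, reverse=True)
    body = "|".join(re.escape(u) for u in alts)
    return re.compile(rf"(?<![\w.])(\d+(?:\.\d+)?)\s*({body})(?![a-z/])")


def extract_components(cleaned_term: str, config: NormalizationConfig | None = None) -> TermComponents:
    """Split a cleaned term into core name, dosage form, and concentration.

    Concentrations are ``number + unit`` with the unit from the configured
    lexicon; dosage forms are whole-word lexicon hits.  Recognized spans
    are removed from the core name; a term that is nothing but components
    keeps the full cleaned string as its core.
    """
    config = config or NormalizationConfig()
    term = cleaned_term
    concentration: tuple[float, str] | None = None
    dosage_form: str | None = None
    qualifiers: list[str] = []

    for match in re.finditer(r"\(([^)]*)\)", term):
        qualifiers.append(match.group(1).strip())
    term_wo_qual = re.sub(r"\([^)]*\)", " ", term)

    m = _unit_pattern(config.unit_lexicon).search(term_wo_qual)
    residual = term_wo_qual
    if m:
        concentration = (float(m.group(1)), m.group(2))
        residual = residual[: m.start()] + " " + residual[m.end() :]

    words = []
    for word in residual.split():
        if dosage_form is None and word in config.dosage_form_lexicon:
            dosage_form = word
            continue
        words.append(word)
    core = " ".join(words).strip(" -")
    if not core:
        core = cleaned_term
    return TermComponents(
        core_name=core,
        dosage_form=dosage_form,
        concentration=concentration,
        qualifiers=tuple(q for q in qualifiers if q),
    )


def exact_variation_pairs(terms: Sequence[str]) -> list[MatchEvidence]:
    """Exact-tier pairs: equal signatures after dropping hyphens and spaces."""
    by_signature: dict[str, list[str]] = {}
    for term in dict.fromkeys(terms):
        signature = term.replace("-", "").replace(" ", "")
        by_signature.setdefault(signature, []).append(term)
    evidence = []
    for members in by_signature.values():
        for a, b in combinations(sorted(members), 2):
            evidence.append(MatchEvidence(a, b, tier="exact", score=1.0))
    return evidence


def semantic_clusters(
    terms: Sequence[str],
    provider: EmbeddingProvider | None = None,
    config: NormalizationConfig | None = None,
) -> list[MatchEvidence]:
    """Semantic-tier pairs via DBSCAN on cosine distances.

    DBSCAN runs with ``eps = 1 - cosine_threshold`` on the full pairwise
    ``1 - cosine`` distance matrix.  Within each non-noise cluster, a pair
    is emitted only if its own cosine similarity also meets the threshold;
    this prevents density chaining from linking sub-threshold pairs.
    """
    config = config or NormalizationConfig()
    provider = provider or CharNgramTfidfProvider()
    terms = list(dict.fromkeys(terms))
    if len(terms) < 2:
        return []
    vectors = validate_embeddings(provider.embed(terms), len(terms))
    sim = np.clip(vectors @ vectors.T, -1.0, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    labels = DBSCAN(
        eps=1.0 - config.cosine_threshold,
        min_samples=config.dbscan_min_samples,
        metric="precomputed",
    ).fit_predict(dist)

    evidence = []
    for label in sorted(set(labels)):
        if label == -1:
            continue
        idx = np.flatnonzero(labels == label)
        for i, j in combinations(idx, 2):
            if sim[i, j] >= config.cosine_threshold:
                evidence.append(
                    MatchEvidence(terms[i], terms[j], tier="semantic", score=float(sim[i, j]))
                )
    return evidence


def _fuzzy_similarity(a: str, b: str) -> float:
    return SequenceMatcher(a=a, b=b, autojunk=False).ratio()


def fuzzy_match_pairs(
    terms: Sequence[str],
    components_map: Mapping[str, TermComponents] | None = None,
    config: NormalizationConfig | None = None,
) -> list[MatchEvidence]:
    """Fuzzy-tier pairs: core-name string similarity with component gating.

    A candidate pair is blocked outright when both terms carry a
    concentration and the concentrations differ, or both carry a dosage
    form and the forms differ — "amoxicillin 250 mg" never matches
    "amoxicillin 500 mg" however similar the strings are.
    """
    config = config or NormalizationConfig()
    terms = list(dict.fromkeys(terms))
    if components_map is None:
        components_map = {t: extract_components(t, config) for t in terms}
    evidence = []
    for a, b in combinations(sorted(terms), 2):
        ca, cb = components_map[a], components_map[b]
        if (
            ca.concentration is not None
            and cb.concentration is not None
            and ca.concentration != cb.concentration
        ):
            continue
        if (
            ca.dosage_form is not None
            and cb.dosage_form is not None
            and ca.dosage_form != cb.dosage_form
        ):
            continue
        score = _fuzzy_similarity(ca.core_name, cb.core_name)
        if score * 100.0 >= config.fuzzy_ratio_threshold:
            evidence.append(MatchEvidence(a, b, tier="fuzzy", score=score))
    return evidence


def detect_synonym_pairs(
    terms: Sequence[str],
    provider: EmbeddingProvider | None = None,
    config: NormalizationConfig | None = None,
) -> list[MatchEvidence]:
    """Run the three detection tiers in parallel over a cleaned vocabulary."""
    config = config or NormalizationConfig()
    terms = list(dict.fromkeys(terms))
    components = {t: extract_components(t, config) for t in terms}
    evidence = exact_variation_pairs(terms)
    evidence += semantic_clusters(terms, provider, config)
    evidence += fuzzy_match_pairs(terms, components, config)
    return evidence


def merge_groups(
    evidence: Iterable[MatchEvidence],
    frequencies: Mapping[str, int],
    config: NormalizationConfig | None = None,
) -> list[SynonymGroup]:
    """Merge pair evidence from all tiers into synonym groups.

    Terms become nodes, evidence pairs become undirected edges (duplicate
    edges collapse, keeping the best score per tier), and the groups are
    the connected components.  Components smaller than ``min_group_size``
    are discarded.  Output order is deterministic (sorted by canonical).
    """
    config = config or NormalizationConfig()
    best: dict[tuple[str, str, str], MatchEvidence] = {}
    for ev in evidence:
        key = (*ev.key, ev.tier)
        if key not in best or ev.score > best[key].score:
            best[key] = ev

    graph = nx.Graph()
    for ev in best.values():
        graph.add_edge(*ev.key)

    groups: list[SynonymGroup] = []
    for component in nx.connected_components(graph):
        if len(component) < config.min_group_size:
            continue
        canonical = select_canonical(component, frequencies)
        group_evidence = sorted(
            (ev for ev in best.values() if ev.term_a in component and ev.term_b in component),
            key=lambda e: (e.key, e.tier),
        )
        groups.append(
            SynonymGroup(
                canonical=canonical,
                variants=set(component) - {canonical},
                evidence=group_evidence,
            )
        )
    groups.sort(key=lambda g: g.canonical)
    return groups


def select_canonical(members: Iterable[str], frequencies: Mapping[str, int]) -> str:
    """Pick the canonical surface form for a synonym group.

    Highest corpus frequency wins; ties break to the shortest cleaned
    string, then to the lexicographically smallest — fully deterministic.
    """
    return min(members, key=lambda t: (-frequencies.get(t, 0), len(t), t))


def build_thesaurus(groups: Sequence[SynonymGroup]) -> Thesaurus:
    """Construct the variant -> canonical thesaurus from disjoint groups.

    Overlapping groups indicate a merge bug upstream and raise
    :class:`ThesaurusIntegrityError`.
    """
    seen: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for group in groups:
        for member in group.members:
            if member in seen:
                raise ThesaurusIntegrityError(
                    f"term {member!r} appears in two groups "
                    f"({seen[member]!r} and {group.canonical!r})"
                )
            seen[member] = group.canonical
        for variant in group.variants:
            mapping[variant] = group.canonical
    return Thesaurus(mapping)


THESAURUS_HEADER = ("label", "replace by")


def write_thesaurus(thesaurus: Thesaurus, stream: io.TextIOBase, dialect: str = "tab") -> None:
    """Write a VOSviewer thesaurus file.

    The default dialect is tab-separated with the ``label`` / ``replace by``
    header VOSviewer expects; ``dialect="csv"`` produces a strict
    comma-separated variant.  Rows are sorted by variant so identical
    thesauri serialize byte-identically.
    """
    delim = {"tab": "\t", "csv": ","}.get(dialect)
    if delim is None:
        raise ValueError(f"unknown thesaurus dialect {dialect!r}")
    writer = csv.writer(stream, delimiter=delim, lineterminator="\n")
    writer.writerow(THESAURUS_HEADER)
    for variant in sorted(thesaurus.mapping):
        writer.writerow([variant, thesaurus.mapping[variant]])


def read_thesaurus(stream: io.TextIOBase | Iterable[str], dialect: str = "tab") -> Thesaurus:
    """Read a thesaurus file written by :func:`write_thesaurus`."""
    delim = {"tab": "\t", "csv": ","}.get(dialect)
    if delim is None:
        raise ValueError(f"unknown thesaurus dialect {dialect!r}")
    reader = csv.reader(iter(stream), delimiter=delim)
    try:
        header = next(reader)
    except StopIteration:
        raise ThesaurusIntegrityError("empty thesaurus file: missing header") from None
    if tuple(h.strip() for h in header) != THESAURUS_HEADER:
        raise ThesaurusIntegrityError(
            f"bad thesaurus header {header!r}; expected {list(THESAURUS_HEADER)}"
        )
    mapping = {}
    for row in reader:
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) != 2:
            raise ThesaurusIntegrityError(f"thesaurus rows need 2 columns, got {row!r}")
        mapping[row[0]] = row[1]
    return Thesaurus(mapping)


def _normalize_keywords(keywords: Sequence[str], thesaurus: Thesaurus) -> list[str]:
    out: list[str] = []
    for kw in keywords:
        try:
            cleaned = clean_term(kw)
        except TermCleaningError:
            continue
        # canonical form for mapped terms, the original spelling otherwise
        value = thesaurus.mapping.get(cleaned, kw)
        if value not in out:
            out.append(value)
    return out


def apply_thesaurus(
    corpus: Corpus, thesaurus: Thesaurus, field_selector: str = "both"
) -> Corpus:
    """Replace mapped keywords by their canonical term across a corpus.

    ``field_selector`` chooses ``author_keywords``, ``keywords_plus`` or
    ``both``.  Lookup happens on the cleaned form of each keyword;
    unmapped keywords pass through untouched, and each record's list is
    deduplicated after replacement.
    """
    if field_selector not in {"author_keywords", "keywords_plus", "both"}:
        raise ValueError(f"unknown field selector {field_selector!r}")
    records = []
    for rec in corpus:
        kwargs: dict[str, list[str]] = {}
        if field_selector in {"author_keywords", "both"}:
            kwargs["author_keywords"] = _normalize_keywords(rec.author_keywords, thesaurus)
        if field_selector in {"keywords_plus", "both"}:
            kwargs["keywords_plus"] = _normalize_keywords(rec.keywords_plus, thesaurus)
        records.append(replace(rec, **kwargs))
    return Corpus(records, provenance=dict(corpus.provenance, thesaurus_applied=True))


def extract_term_frequencies(corpus: Corpus, field_selector: str = "both") -> dict[str, int]:
    """Count, per cleaned term, the number of documents containing it."""
    if field_selector not in {"author_keywords", "keywords_plus", "both"}:
        raise ValueError(f"unknown field selector {field_selector!r}")
    counts: dict[str, int] = {}
    for rec in corpus:
        raw: list[str] = []
        if field_selector in {"author_keywords", "both"}:
            raw += rec.author_keywords
        if field_selector in {"keywords_plus", "both"}:
            raw += rec.keywords_plus
        seen: set[str] = set()
        for kw in raw:
            try:
                cleaned = clean_term(kw)
            except TermCleaningError:
                continue
            seen.add(cleaned)
        for term in seen:
            counts[term] = counts.get(term, 0) + 1
    return counts


def normalize_vocabulary(
    frequencies: Mapping[str, int],
    provider: EmbeddingProvider | None = None,
    config: NormalizationConfig | None = None,
) -> tuple[list[SynonymGroup], Thesaurus, list[MatchEvidence]]:
    """End-to-end cascade over a cleaned-term frequency table."""
    config = config or NormalizationConfig()
    terms = sorted(frequencies)
    evidence = detect_synonym_pairs(terms, provider, config)
    groups = merge_groups(evidence, frequencies, config)
    return groups, build_thesaurus(groups), evidence
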