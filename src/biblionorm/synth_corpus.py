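"""Ground-truthed synthetic vocabularies, embeddings, and corpora.

Every other module is exercised against data from this generator: known
concept groups whose surface variants are produced by recorded noise
operations, a mock embedding provider with exactly controlled within- and
between-concept cosines, and small Web of Science-format corpora with
per-document year, countries, keywords, and a recency-decaying
negative-binomial citation model.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .term_normalize import TermCleaningError, clean_term
from .wos_io import Corpus, PublicationRecord, write_wos_export

__all__ = [
    "ConceptSpec",
    "SimulationConfig",
    "GroundTruth",
    "NOISE_OPS",
    "generate_vocabulary",
    "default_concept_specs",
    "MockEmbeddingProvider",
    "mock_embedding_provider",
    "generate_corpus",
    "CANONICAL_SURFACES",
]

NOISE_OPS = (
    "case",
    "punctuation",
    "hyphen-space",
    "plural",
    "dosage-suffix",
    "abbreviation",
    "typo",
)

#: Pool of multi-word pharmaceutical concept surfaces used by the default
#: specs. All lowercase, so noise ops have room to act.
CANONICAL_SURFACES = [
    "drug-drug interactions", "adverse drug reactions", "cytochrome p450 enzymes",
    "pharmacokinetic modeling", "polypharmacy management", "therapeutic drug monitoring",
    "protease inhibitors", "selective serotonin reuptake inhibitors",
    "combination chemotherapy", "antiretroviral therapy", "drug metabolism pathways",
    "enzyme inhibition assays", "p-glycoprotein transport", "clinical risk assessment",
    "randomized controlled trials", "hepatic microsomes", "grapefruit juice interaction",
    "anticoagulant therapy", "antiepileptic drugs", "immunosuppressive agents",
    "beta-adrenergic blockers", "calcium channel blockers", "proton pump inhibitors",
    "nonsteroidal anti-inflammatory drugs", "monoamine oxidase inhibitors",
    "angiotensin converting enzyme", "drug safety surveillance", "in vitro screening",
    "molecular docking simulations", "nanoparticle drug delivery", "precision dosing",
    "population pharmacokinetics", "drug transporter proteins", "qt interval prolongation",
    "serotonin syndrome", "warfarin dose adjustment", "statin induced myopathy",
    "renal drug clearance", "hepatotoxicity biomarkers", "pharmacodynamic synergism",
    "deprescribing interventions", "medication reconciliation", "geriatric pharmacotherapy",
    "pediatric drug dosing", "herb-drug interactions", "food-drug interactions",
    "drug induced liver injury", "antimicrobial stewardship", "oncology supportive care",
    "pharmacogenomic testing", "drug interaction alerts", "clinical decision support",
    "machine learning prediction", "adverse event reporting", "bioavailability enhancement",
    "first-pass metabolism", "plasma protein binding", "volume of distribution",
    "half-life estimation", "steady state concentrations",
]


@dataclass(frozen=True)
class ConceptSpec:
    """One planted synonym group: a canonical surface plus noisy variants."""

    concept_id: str
    canonical_surface: str
    n_variants: int = 3
    noise_ops: tuple[str, ...] = ("hyphen-space", "plural", "case", "typo")

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        unknown = set(self.noise_ops) - set(NOISE_OPS)
        if unknown:
            raise ValueError(f"unknown noise ops: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Variant -> concept map, with per-variant noise-op provenance."""

    variant_to_concept: dict[str, str] = field(default_factory=dict)
    ops_applied: dict[str, str] = field(default_factory=dict)
    doc_truth: list[dict] = field(default_factory=list)

    def cleaned_concept_map(self) -> dict[str, str]:
        """Ground truth keyed on the cleaned surface form of each variant."""
        out: dict[str, str] = {}
        for variant, concept in self.variant_to_concept.items():
            try:
                cleaned = clean_term(variant)
            except TermCleaningError:
                continue
            out[cleaned] = concept
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic corpus generator.

    Citations follow a negative binomial whose mean grows with document
    age (``citation_rate_per_year`` expected citations per inclusive year)
    so that older documents accumulate more citations, as real corpora do.
    """

    n_concepts: int = 50
    n_docs: int = 2000
    year_range: tuple[int, int] = (1975, 2025)
    country_pool: tuple[str, ...] = (
        "USA", "China", "United Kingdom", "Italy", "Germany", "Canada",
        "France", "India", "Australia", "Japan", "Spain", "Netherlands",
        "Switzerland", "Brazil", "South Korea",
    )
    collaboration_prob: float = 0.3
    keywords_per_doc: tuple[int, int] = (3, 8)
    citation_rate_per_year: float = 1.5
    citation_dispersion: float = 1.0
    review_fraction: float = 0.15
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.collaboration_prob <= 1.0):
            raise ValueError("collaboration_prob must be in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("invalid year_range")


def _apply_noise_op(op: str, surface: str, rng: np.random.Generator) -> str:
    words = surface.split()
    if op == "case":
        return surface.upper() if rng.random() < 0.5 else surface.title()
    if op == "punctuation":
        return f'"{surface}"' if rng.random() < 0.5 else surface + "."
    if op == "hyphen-space":
        if "-" in surface:
            return surface.replace("-", " ", 1)
        if " " in surface:
            return surface.replace(" ", "-", 1)
        return surface + "-"
    if op == "plural":
        return surface[:-1] if surface.endswith("s") else surface + "s"
    if op == "dosage-suffix":
        return surface + " 500 mg tablet"
    if op == "abbreviation":
        if len(words) >= 2:
            return "".join(w.lstrip("-")[0] for w in words if w)
        return surface[:3]
    if op == "typo":
        pos = int(rng.integers(1, len(surface)))
        return surface[:pos] + surface[pos + 1 :]
    raise ValueError(f"unknown noise op {op!r}")


def generate_vocabulary(
    concept_specs: Sequence[ConceptSpec], seed: int = 0
) -> tuple[dict[str, int], GroundTruth]:
    """Generate a term-frequency vocabulary from planted concept groups.

    Each concept contributes its canonical surface (high frequency) and
    ``n_variants`` noisy variants (lower frequencies) produced by the
    recorded noise operations.  Surface collisions across concepts are
    regenerated; an exhausted spec raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    frequencies: dict[str, int] = {}
    used_cleaned: dict[str, str] = {}

    for spec in concept_specs:
        canonical = spec.canonical_surface
        cleaned_canonical = clean_term(canonical)
        if cleaned_canonical in used_cleaned and used_cleaned[cleaned_canonical] != spec.concept_id:
            raise ValueError(f"canonical surface collision: {canonical!r}")
        used_cleaned[cleaned_canonical] = spec.concept_id
        truth.variant_to_concept[canonical] = spec.concept_id
        truth.ops_applied[canonical] = "canonical"
        frequencies[canonical] = int(rng.integers(50, 400))

        produced: set[str] = {canonical}
        attempts = 0
        while len(produced) - 1 < spec.n_variants:
            attempts += 1
            if attempts > 50 * spec.n_variants:
                raise ValueError(
                    f"concept {spec.concept_id!r}: noise ops cannot produce "
                    f"{spec.n_variants} distinct variants"
                )
            op = spec.noise_ops[int(rng.integers(len(spec.noise_ops)))]
            variant = _apply_noise_op(op, canonical, rng)
            if variant in produced:
                continue
            try:
                cleaned = clean_term(variant)
            except TermCleaningError:
                continue
            owner = used_cleaned.get(cleaned)
            if owner is not None and owner != spec.concept_id:
                continue  # cross-concept collision: regenerate
            used_cleaned[cleaned] = spec.concept_id
            produced.add(variant)
            truth.variant_to_concept[variant] = spec.concept_id
            truth.ops_applied[variant] = op
            frequencies[variant] = int(rng.integers(1, 40))
    return frequencies, truth


def default_concept_specs(
    n_concepts: int = 50,
    n_variants: int = 3,
    noise_ops: tuple[str, ...] = ("hyphen-space", "plural", "case", "typo"),
) -> list[ConceptSpec]:
    if n_concepts > len(CANONICAL_SURFACES):
        raise ValueError(f"at most {len(CANONICAL_SURFACES)} built-in concepts available")
    return [
        ConceptSpec(
            concept_id=f"C{i:03d}",
            canonical_surface=surface,
            n_variants=n_variants,
            noise_ops=noise_ops,
        )
        for i, surface in enumerate(CANONICAL_SURFACES[:n_concepts])
    ]


class MockEmbeddingProvider:
    """Embeddings with exactly controlled concept geometry.

    Terms of one concept share an anchor direction so that every
    within-concept pair realizes cosine ``intra_cos`` exactly, while
    anchors are arranged so between-concept pairs realize
    ``intra_cos * inter_anchor <= inter_cos``.  Terms outside the ground
    truth get deterministic pseudo-random unit vectors in a reserved
    subspace.  Construction: anchor_i = sqrt(inter)*u + sqrt(1-inter)*e_i
    with orthonormal {u, e_i}; member vectors add per-term orthonormal
    noise directions scaled to sqrt(1-intra).
    """

    def __init__(
        self,
        ground_truth: GroundTruth | Mapping[str, str],
        intra_cos: float = 0.95,
        inter_cos: float = 0.20,
        dim: int | None = None,
        seed: int = 0,
    ) -> None:
        if not (0.0 <= inter_cos < intra_cos <= 1.0):
            raise ValueError("need 0 <= inter_cos < intra_cos <= 1")
        if isinstance(ground_truth, GroundTruth):
            concept_map = ground_truth.cleaned_concept_map()
        else:
            concept_map = dict(ground_truth)
        self._concept_of = concept_map
        concepts = sorted(set(concept_map.values()))
        terms = sorted(concept_map)
        required = 1 + len(concepts) + len(terms) + 4
        if dim is None:
            dim = required
        if dim < required:
            raise ValueError(
                f"dim={dim} infeasible for {len(concepts)} concepts and "
                f"{len(terms)} terms; need >= {required}"
            )
        self.dim = dim
        self._seed = seed

        anchors: dict[str, np.ndarray] = {}
        for k, concept in enumerate(concepts):
            v = np.zeros(dim)
            v[0] = np.sqrt(inter_cos)
            v[1 + k] = np.sqrt(1.0 - inter_cos)
            anchors[concept] = v

        self._vectors: dict[str, np.ndarray] = {}
        noise_base = 1 + len(concepts)
        a = np.sqrt(intra_cos)
        b = np.sqrt(1.0 - intra_cos)
        for t, term in enumerate(terms):
            noise = np.zeros(dim)
            noise[noise_base + t] = 1.0
            vec = a * anchors[concept_map[term]] + b * noise
            self._vectors[term] = vec / np.linalg.norm(vec)
        self._noise_base = noise_base + len(terms)

    def _unknown_vector(self, term: str) -> np.ndarray:
        # Deterministic pseudo-random unit vector in the reserved tail
        # subspace: orthogonal to every anchor, so it never joins a concept.
        tail = self.dim - self._noise_base
        digest = zlib.crc32(term.encode("utf-8"))
        term_seed = (self._seed * 1_000_003 + digest) % (2**31)
        rng = np.random.default_rng(term_seed)
        v = np.zeros(self.dim)
        v[self._noise_base :] = rng.normal(size=tail)
        norm = np.linalg.norm(v)
        if norm == 0:
            v[self._noise_base] = 1.0
            norm = 1.0
        return v / norm

    def embed(self, terms: Sequence[str]) -> np.ndarray:
        return np.array(
            [self._vectors.get(t, self._unknown_vector(t)) for t in terms]
        )


def mock_embedding_provider(
    ground_truth: GroundTruth | Mapping[str, str],
    intra_cos: float = 0.95,
    inter_cos: float = 0.20,
    dim: int | None = None,
    seed: int = 0,
) -> MockEmbeddingProvider:
    """Factory for :class:`MockEmbeddingProvider` (see its docstring)."""
    return MockEmbeddingProvider(ground_truth, intra_cos, inter_cos, dim, seed)


def generate_corpus(
    config: SimulationConfig,
    vocabulary: Mapping[str, int] | None = None,
    ground_truth: GroundTruth | None = None,
) -> tuple[str, GroundTruth]:
    """Generate a WoS-format export string plus its ground truth.

    Documents draw a uniform year, one country (or 2-4 distinct ones with
    probability ``collaboration_prob``), keywords sampled from the
    vocabulary proportionally to term frequency, and citations from a
    negative binomial with mean ``citation_rate_per_year * age``.
    """
    rng = np.random.default_rng(config.random_seed)
    if vocabulary is None or ground_truth is None:
        specs = default_concept_specs(config.n_concepts)
        vocabulary, ground_truth = generate_vocabulary(specs, seed=config.random_seed)
    terms = sorted(vocabulary)
    weights = np.array([vocabulary[t] for t in terms], dtype=float)
    weights /= weights.sum()

    y0, y1 = config.year_range
    ref_year = y1
    k = config.citation_dispersion
    records: list[PublicationRecord] = []
    for i in range(config.n_docs):
        year = int(rng.integers(y0, y1 + 1))
        if rng.random() < config.collaboration_prob and len(config.country_pool) >= 2:
            n_countries = int(rng.integers(2, min(4, len(config.country_pool)) + 1))
        else:
            n_countries = 1
        countries = list(
            rng.choice(config.country_pool, size=n_countries, replace=False)
        )
        lo, hi = config.keywords_per_doc
        n_kw = int(rng.integers(lo, hi + 1))
        n_kw = min(n_kw, len(terms))
        keywords = list(rng.choice(terms, size=n_kw, replace=False, p=weights))
        age = ref_year - year + 1
        mu = config.citation_rate_per_year * age
        tc = int(rng.negative_binomial(k, k / (k + mu)))
        doc_type = "Review" if rng.random() < config.review_fraction else "Article"
        records.append(
            PublicationRecord(
                record_id=f"WOS:{config.random_seed:06d}{i:08d}",
                document_type=doc_type,
                language="English",
                title=f"Synthetic document {i}",
                source_title=f"Journal {int(rng.integers(1, 21))}",
                author_keywords=keywords,
                keywords_plus=[],
                countries=countries,
                publication_year=year,
                times_cited=tc,
            )
        )
        ground_truth.doc_truth.append(
            {
                "record_id": records[-1].record_id,
                "year": year,
                "countries": countries,
                "keywords": keywords,
            }
        )
    buffer = io.StringIO()
    write_wos_export(Corpus(records), buffer)
    return buffer.getvalue(), ground_truth
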