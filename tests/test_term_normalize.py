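import io
import random
from itertools import combinations

import numpy as np
import pytest

from biblionorm import synth_corpus as sc
from biblionorm import term_normalize as tn
from biblionorm.embeddings import ProviderContractError
from biblionorm.wos_io import Corpus
from conftest import make_record


class TestCleanTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Drug–Drug  Interactions ", "drug-drug interactions"),
            ("aspirin", "aspirin"),
            ("“St John’s Wort”", "st john's wort"),
            ("Beta—blocker", "beta-blocker"),
            ("  CYP3A4;", "cyp3a4"),
        ],
    )
    def test_cleaning_rules(self, raw, expected):
        assert tn.clean_term(raw) == expected

    @pytest.mark.parametrize("raw", ["---", "...", "  ", ""])
    def test_unusable_terms_rejected(self, raw):
        with pytest.raises(tn.TermCleaningError):
            tn.clean_term(raw)


class TestComponents:
    def test_concentration_and_dosage_form_extracted(self):
        c = tn.extract_components("amoxicillin 500 mg tablet")
        assert c.core_name == "amoxicillin"
        assert c.concentration == (500.0, "mg")
        assert c.dosage_form == "tablet"

    def test_plain_term_has_no_components(self):
        c = tn.extract_components("pharmacokinetics")
        assert c == tn.TermComponents(core_name="pharmacokinetics")

    def test_compound_unit_recognized(self):
        c = tn.extract_components("insulin 100 iu/ml solution")
        assert c.concentration == (100.0, "iu/ml")
        assert c.dosage_form == "solution"
        assert c.core_name == "insulin"

    def test_parenthetical_qualifiers_captured(self):
        c = tn.extract_components("metformin (extended release)")
        assert c.qualifiers == ("extended release",)
        assert c.core_name == "metformin"

    def test_all_component_term_keeps_cleaned_string_as_core(self):
        c = tn.extract_components("500 mg tablet")
        assert c.core_name  # invariant: never empty


class TestExactTier:
    def test_hyphen_space_signature_pairs(self):
        pairs = tn.exact_variation_pairs(
            ["drug-drug interaction", "drug drug interaction", "aspirin"]
        )
        assert len(pairs) == 1
        assert pairs[0].key == ("drug drug interaction", "drug-drug interaction")
        assert pairs[0].score == 1.0 and pairs[0].tier == "exact"

    def test_identical_strings_never_self_pair(self):
        assert tn.exact_variation_pairs(["aspirin", "aspirin"]) == []

    def test_betablocker_variants_pair(self):
        pairs = tn.exact_variation_pairs(["beta-blocker", "betablocker"])
        assert len(pairs) == 1


class _StubProvider:
    """Two concepts: indices 0-1 are concept A, 2-3 concept B."""

    def __init__(self, intra=0.95, inter=0.20):
        truth = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        self._inner = sc.mock_embedding_provider(truth, intra_cos=intra, inter_cos=inter)

    def embed(self, terms):
        return self._inner.embed(terms)


class TestSemanticTier:
    def test_two_concept_mock_recovers_exactly_within_concept_pairs(self):
        pairs = tn.semantic_clusters(["a1", "a2", "b1", "b2"], _StubProvider())
        keys = {p.key for p in pairs}
        assert keys == {("a1", "a2"), ("b1", "b2")}
        assert all(p.score >= 0.85 for p in pairs)

    def test_all_subthreshold_cosines_yield_nothing(self):
        class Low:
            def embed(self, terms):
                # pairwise cosine 0.5 via shared-axis construction
                n = len(terms)
                vecs = np.zeros((n, n + 1))
                for i in range(n):
                    vecs[i, 0] = np.sqrt(0.5)
                    vecs[i, i + 1] = np.sqrt(0.5)
                return vecs

        assert tn.semantic_clusters(["x", "y", "z"], Low()) == []

    def test_nonunit_vectors_violate_contract(self):
        class Bad:
            def embed(self, terms):
                return np.ones((len(terms), 3))

        with pytest.raises(ProviderContractError, match="unit-norm"):
            tn.semantic_clusters(["x", "y"], Bad())

    def test_chaining_does_not_link_subthreshold_pairs(self):
        # a-b and b-c are similar (0.90) but a-c is 0.62: DBSCAN puts all
        # three in one cluster, yet only the threshold-passing pairs emit.
        class Chain:
            def embed(self, terms):
                theta = np.arccos(0.90)
                angles = {"a": 0.0, "b": theta, "c": 2 * theta}
                return np.array(
                    [[np.cos(angles[t]), np.sin(angles[t])] for t in terms]
                )

        pairs = tn.semantic_clusters(["a", "b", "c"], Chain())
        assert {p.key for p in pairs} == {("a", "b"), ("b", "c")}


class TestFuzzyTier:
    def test_singular_plural_pair_meets_default_threshold(self):
        pairs = tn.fuzzy_match_pairs(["statins", "statin"])
        assert len(pairs) == 1
        assert pairs[0].score == pytest.approx(12 / 13)

    def test_conflicting_concentrations_block_identical_cores(self):
        assert tn.fuzzy_match_pairs(["amoxicillin 250 mg", "amoxicillin 500 mg"]) == []

    def test_same_concentration_does_not_block(self):
        pairs = tn.fuzzy_match_pairs(["amoxicillin 500 mg", "amoxicilline 500 mg"])
        assert len(pairs) == 1

    def test_conflicting_dosage_forms_block(self):
        assert tn.fuzzy_match_pairs(["insulin tablet", "insulin injection"]) == []

    def test_dissimilar_cores_below_threshold(self):
        assert tn.fuzzy_match_pairs(["warfarin", "heparin"]) == []


class TestTierMonotonicity:
    def test_raising_thresholds_never_adds_evidence(self, small_pipeline):
        terms = sorted(small_pipeline["frequencies"])
        provider = sc.mock_embedding_provider(small_pipeline["truth"], seed=11)
        counts = []
        for cos_t, fuzzy_t in [(0.80, 85.0), (0.85, 90.0), (0.92, 95.0)]:
            config = tn.NormalizationConfig(
                cosine_threshold=cos_t, fuzzy_ratio_threshold=fuzzy_t
            )
            counts.append(len(tn.detect_synonym_pairs(terms, provider, config)))
        assert counts == sorted(counts, reverse=True)


def _union_find_groups(n_terms, edges, min_size):
    parent = list(range(n_terms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n_terms):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values() if len(g) >= min_size}


class TestMergeGroups:
    def test_cross_tier_edges_unify(self):
        evidence = [
            tn.MatchEvidence("a", "b", "exact", 1.0),
            tn.MatchEvidence("b", "c", "fuzzy", 0.92),
        ]
        groups = tn.merge_groups(evidence, {"a": 1, "b": 2, "c": 3})
        assert len(groups) == 1 and groups[0].members == {"a", "b", "c"}

    def test_disjoint_edges_stay_separate(self):
        evidence = [
            tn.MatchEvidence("a", "b", "exact", 1.0),
            tn.MatchEvidence("c", "d", "exact", 1.0),
        ]
        groups = tn.merge_groups(evidence, {})
        assert len(groups) == 2

    def test_duplicate_edges_keep_max_score_per_tier(self):
        evidence = [
            tn.MatchEvidence("a", "b", "fuzzy", 0.91),
            tn.MatchEvidence("b", "a", "fuzzy", 0.95),
        ]
        groups = tn.merge_groups(evidence, {"a": 1, "b": 1})
        assert [e.score for e in groups[0].evidence] == [0.95]

    def test_matches_union_find_oracle_on_random_evidence(self):
        rng = random.Random(42)
        for _ in range(300):
            n = rng.randint(2, 60)
            terms = [f"t{i}" for i in range(n)]
            n_edges = min(rng.randint(0, 2 * n), n * (n - 1) // 2)
            edges = set()
            while len(edges) < n_edges:
                a, b = rng.sample(range(n), 2)
                edges.add((min(a, b), max(a, b)))
            evidence = [
                tn.MatchEvidence(terms[a], terms[b], "exact", 1.0) for a, b in edges
            ]
            groups = tn.merge_groups(evidence, {})
            got = {frozenset(int(m[1:]) for m in g.members) for g in groups}
            assert got == _union_find_groups(n, edges, min_size=2)


class TestCanonicalSelection:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({"ddis": 40, "drug-drug interactions": 310}, "drug-drug interactions"),
            ({"statin": 10, "statins": 10}, "statin"),
            ({"abc": 5, "abd": 5, "abb": 5}, "abb"),
        ],
    )
    def test_frequency_then_brevity_then_lexicographic(self, freqs, expected):
        assert tn.select_canonical(freqs.keys(), freqs) == expected


class TestThesaurus:
    def test_build_maps_every_variant(self):
        group = tn.SynonymGroup(
            canonical="drug-drug interactions",
            variants={"ddis", "drug drug interactions"},
        )
        thesaurus = tn.build_thesaurus([group])
        assert len(thesaurus) == 2
        assert thesaurus.apply("ddis") == "drug-drug interactions"

    def test_no_groups_gives_empty_thesaurus(self):
        assert len(tn.build_thesaurus([])) == 0

    def test_overlapping_groups_rejected(self):
        groups = [
            tn.SynonymGroup(canonical="a", variants={"b"}),
            tn.SynonymGroup(canonical="c", variants={"b"}),
        ]
        with pytest.raises(tn.ThesaurusIntegrityError, match="'b'"):
            tn.build_thesaurus(groups)

    def test_chained_mapping_rejected(self):
        with pytest.raises(tn.ThesaurusIntegrityError, match="chains"):
            tn.Thesaurus({"a": "b", "b": "c"})

    def test_write_read_round_trip(self, small_pipeline):
        thesaurus = small_pipeline["thesaurus"]
        buffer = io.StringIO()
        tn.write_thesaurus(thesaurus, buffer)
        text = buffer.getvalue()
        assert text.startswith("label\treplace by\n")
        assert tn.read_thesaurus(io.StringIO(text)) == thesaurus

    def test_csv_dialect_round_trip(self):
        thesaurus = tn.Thesaurus({"ddis": "drug-drug interactions"})
        buffer = io.StringIO()
        tn.write_thesaurus(thesaurus, buffer, dialect="csv")
        assert tn.read_thesaurus(io.StringIO(buffer.getvalue()), dialect="csv") == thesaurus

    def test_malformed_header_rejected(self):
        with pytest.raises(tn.ThesaurusIntegrityError, match="header"):
            tn.read_thesaurus(io.StringIO("wrong\theader\n"))

    def test_serialization_is_deterministic(self, small_pipeline):
        thesaurus = small_pipeline["thesaurus"]
        out = []
        for _ in range(2):
            buffer = io.StringIO()
            tn.write_thesaurus(thesaurus, buffer)
            out.append(buffer.getvalue())
        assert out[0] == out[1]


class TestApplyThesaurus:
    @pytest.fixture
    def thesaurus(self):
        return tn.Thesaurus({"ddis": "drug-drug interactions"})

    def test_mapped_keywords_replaced(self, thesaurus):
        corpus = Corpus([make_record(1, keywords=("DDIs", "pharmacokinetics"))])
        out = tn.apply_thesaurus(corpus, thesaurus)
        assert out.records[0].author_keywords == [
            "drug-drug interactions",
            "pharmacokinetics",
        ]

    def test_empty_thesaurus_is_identity(self):
        corpus = Corpus([make_record(1, keywords=("DDIs", "safety"))])
        out = tn.apply_thesaurus(corpus, tn.Thesaurus())
        assert out.records[0].author_keywords == ["DDIs", "safety"]

    def test_two_variants_collapse_after_dedup(self):
        thesaurus = tn.Thesaurus(
            {"ddis": "drug-drug interactions", "drug drug interactions": "drug-drug interactions"}
        )
        corpus = Corpus([make_record(1, keywords=("DDIs", "Drug Drug Interactions"))])
        out = tn.apply_thesaurus(corpus, thesaurus)
        assert out.records[0].author_keywords == ["drug-drug interactions"]

    def test_application_is_idempotent(self, small_pipeline):
        once = tn.apply_thesaurus(small_pipeline["corpus"], small_pipeline["thesaurus"])
        twice = tn.apply_thesaurus(once, small_pipeline["thesaurus"])
        for a, b in zip(once, twice):
            assert a.author_keywords == b.author_keywords


def _pairwise_scores(groups, truth, observed):
    concept_map = truth.cleaned_concept_map()
    members = sorted(observed & set(concept_map))
    true_pairs = {
        (a, b)
        for a, b in combinations(members, 2)
        if concept_map[a] == concept_map[b]
    }
    pred_pairs = set()
    for group in groups:
        for a, b in combinations(sorted(group.members & observed), 2):
            pred_pairs.add((a, b))
    tp = len(true_pairs & pred_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall


class TestPipelineRecovery:
    def test_precision_and_recall_over_seeded_replicates(self):
        """Planted synonym groups are recovered with pairwise precision
        >= 0.95 and recall >= 0.90 across 20 seeded vocabularies."""
        for seed in range(20):
            specs = sc.default_concept_specs(n_concepts=12, n_variants=3)
            freqs, truth = sc.generate_vocabulary(specs, seed=seed)
            provider = sc.mock_embedding_provider(truth, seed=seed)
            cleaned = {}
            for term, freq in freqs.items():
                key = tn.clean_term(term)
                cleaned[key] = cleaned.get(key, 0) + freq
            groups, _, _ = tn.normalize_vocabulary(cleaned, provider)
            precision, recall = _pairwise_scores(groups, truth, set(cleaned))
            assert precision >= 0.95, f"seed {seed}: precision {precision:.3f}"
            assert recall >= 0.90, f"seed {seed}: recall {recall:.3f}"
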