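import io

import pytest

from biblionorm import synth_corpus as sc
from biblionorm import wos_io


def make_record(i, doc_type="Article", language="English", year=2010, tc=5,
                countries=("USA",), keywords=("pharmacokinetics",), source="Journal A"):
    return wos_io.PublicationRecord(
        record_id=f"R{i}",
        document_type=doc_type,
        language=language,
        title=f"Title {i}",
        source_title=source,
        author_keywords=list(keywords),
        keywords_plus=[],
        countries=list(countries),
        publication_year=year,
        times_cited=tc,
    )


@pytest.fixture
def toy_collab_corpus():
    """Three documents with country sets {US,CN}, {US}, {US,CN,UK}."""
    return wos_io.Corpus(
        [
            make_record(1, countries=("USA", "China")),
            make_record(2, countries=("USA",)),
            make_record(3, countries=("USA", "China", "United Kingdom")),
        ]
    )


@pytest.fixture(scope="session")
def small_pipeline():
    """A small simulated corpus parsed and normalized end to end."""
    from biblionorm import term_normalize as tn

    config = sc.SimulationConfig(n_concepts=15, n_docs=200, random_seed=11)
    export, truth = sc.generate_corpus(config)
    corpus = wos_io.parse_wos_export(io.StringIO(export))
    freqs = tn.extract_term_frequencies(corpus)
    provider = sc.mock_embedding_provider(truth, seed=11)
    groups, thesaurus, evidence = tn.normalize_vocabulary(freqs, provider)
    return {
        "config": config,
        "export": export,
        "truth": truth,
        "corpus": corpus,
        "frequencies": freqs,
        "groups": groups,
        "thesaurus": thesaurus,
        "evidence": evidence,
    }
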