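"""Co-occurrence and collaboration networks with VOSviewer/Pajek export.

Link strength follows the document-level convention: the weight of an
edge is the number of documents in which both labels occur (binary per
document), and a node's total link strength (TLS) is the sum of its
incident edge weights.  Country credit supports both full counting (each
listed country gets 1 per document) and fractional counting (1/k for a
document listing k distinct countries).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from .wos_io import Corpus

__all__ = [
    "NetworkNode",
    "CoOccurrenceNetwork",
    "country_credit",
    "collaboration_network",
    "keyword_network",
    "association_strength",
    "export_network",
    "import_network",
]


@dataclass
class NetworkNode:
    label: str
    occurrences: float
    cluster_id: str | None = None


@dataclass
class CoOccurrenceNetwork:
    """Undirected weighted co-occurrence network.

    Edges are keyed by sorted label pairs; self-loops and duplicate
    orientations cannot be represented.
    """

    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    counting_scheme: str = "full"
    thresholds: dict = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        if a not in self.nodes or b not in self.nodes:
            raise ValueError("edge endpoints must be existing nodes")
        key = (a, b) if a < b else (b, a)
        self.edges[key] = self.edges.get(key, 0.0) + weight

    def total_link_strength(self, label: str) -> float:
        return sum(w for (a, b), w in self.edges.items() if label in (a, b))

    def tls(self) -> dict[str, float]:
        out = {label: 0.0 for label in self.nodes}
        for (a, b), w in self.edges.items():
            out[a] += w
            out[b] += w
        return out


def country_credit(corpus: Corpus, scheme: str = "full") -> tuple[dict[str, float], int]:
    """Per-country publication credit under full or fractional counting.

    Returns the credit table and the number of documents skipped for
    lacking any country. Under fractional counting each document's
    credits sum to exactly 1.
    """
    if scheme not in {"full", "fractional"}:
        raise ValueError(f"unknown counting scheme {scheme!r}")
    credit: dict[str, float] = {}
    skipped = 0
    for rec in corpus:
        countries = list(dict.fromkeys(rec.countries))
        if not countries:
            skipped += 1
            continue
        share = 1.0 if scheme == "full" else 1.0 / len(countries)
        for country in countries:
            credit[country] = credit.get(country, 0.0) + share
    return credit, skipped


def _co_occurrence(
    item_sets: Iterable[list[str]], min_count: int, scheme: str, thresholds: dict
) -> CoOccurrenceNetwork:
    sets = [sorted(set(items)) for items in item_sets]
    occurrences: dict[str, int] = {}
    for items in sets:
        for label in items:
            occurrences[label] = occurrences.get(label, 0) + 1
    kept = {label for label, n in occurrences.items() if n >= min_count}

    network = CoOccurrenceNetwork(counting_scheme=scheme, thresholds=thresholds)
    for label in sorted(kept):
        network.nodes[label] = NetworkNode(label=label, occurrences=occurrences[label])
    # Thresholding applies before edge construction: edges only among kept nodes.
    for items in sets:
        for a, b in combinations([x for x in items if x in kept], 2):
            network.add_edge(a, b, 1.0)
    return network


def collaboration_network(corpus: Corpus, min_docs: int = 5) -> CoOccurrenceNetwork:
    """Country-collaboration network over documents with extracted countries.

    Nodes are countries appearing on at least ``min_docs`` documents
    (the default mirrors the usual minimum-5-publications inclusion
    threshold); edge weight counts the documents listing both countries.
    """
    if min_docs < 1:
        raise ValueError("min_docs must be >= 1")
    return _co_occurrence(
        (rec.countries for rec in corpus),
        min_docs,
        scheme="full",
        thresholds={"min_docs": min_docs},
    )


def keyword_network(
    corpus: Corpus, field_selector: str = "both", min_occurrences: int = 100
) -> CoOccurrenceNetwork:
    """Keyword co-occurrence network (thesaurus applied upstream).

    Node occurrence is the number of documents containing the term; the
    default inclusion threshold of 100 documents matches common practice
    for large corpora and should be lowered for small ones.
    """
    if field_selector not in {"author_keywords", "keywords_plus", "both"}:
        raise ValueError(f"unknown field selector {field_selector!r}")

    def fields(rec) -> list[str]:
        out: list[str] = []
        if field_selector in {"author_keywords", "both"}:
            out += rec.author_keywords
        if field_selector in {"keywords_plus", "both"}:
            out += rec.keywords_plus
        return out

    return _co_occurrence(
        (fields(rec) for rec in corpus),
        min_occurrences,
        scheme="full",
        thresholds={"min_occurrences": min_occurrences, "field": field_selector},
    )


def association_strength(
    edge_weight: float, occurrences_a: float, occurrences_b: float, total_edge_weight: float
) -> float:
    """Association-strength similarity ``2 m c_ab / (w_a w_b)``.

    Proportional to the ratio of observed to expected co-occurrences;
    variants used by visualization tools differ only by a constant
    factor, which leaves rankings unchanged.
    """
    if occurrences_a <= 0 or occurrences_b <= 0:
        raise ValueError("occurrence weights must be positive")
    if edge_weight == 0:
        return 0.0
    return 2.0 * total_edge_weight * edge_weight / (occurrences_a * occurrences_b)


def network_association_strengths(network: CoOccurrenceNetwork) -> dict[tuple[str, str], float]:
    """Association strength for every edge of a network."""
    m = sum(network.edges.values())
    return {
        (a, b): association_strength(
            w, network.nodes[a].occurrences, network.nodes[b].occurrences, m
        )
        for (a, b), w in network.edges.items()
    }


def export_network(
    network: CoOccurrenceNetwork,
    map_stream: io.TextIOBase,
    network_stream: io.TextIOBase | None = None,
    fmt: str = "vosviewer",
) -> None:
    """Write a network as a VOSviewer map+network pair or a Pajek .net file.

    VOSviewer: the map file is tab-separated ``id  label  weight`` with a
    header; the network file is headerless ``id  id  strength`` rows.
    Pajek: a single ``*Vertices``/``*Edges`` file written to ``map_stream``.
    """
    labels = sorted(network.nodes)
    ids = {label: i + 1 for i, label in enumerate(labels)}
    if fmt == "vosviewer":
        if network_stream is None:
            raise ValueError("vosviewer export needs a second stream for the network file")
        map_stream.write("id\tlabel\tweight\n")
        for label in labels:
            map_stream.write(f"{ids[label]}\t{label}\t{network.nodes[label].occurrences:g}\n")
        for (a, b), w in sorted(network.edges.items()):
            network_stream.write(f"{ids[a]}\t{ids[b]}\t{w:g}\n")
    elif fmt == "pajek":
        map_stream.write(f"*Vertices {len(labels)}\n")
        for label in labels:
            map_stream.write(f'{ids[label]} "{label}"\n')
        map_stream.write("*Edges\n")
        for (a, b), w in sorted(network.edges.items()):
            map_stream.write(f"{ids[a]} {ids[b]} {w:g}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(
    map_stream: io.TextIOBase | Iterable[str],
    network_stream: io.TextIOBase | Iterable[str] | None = None,
    fmt: str = "vosviewer",
) -> CoOccurrenceNetwork:
    """Read a network written by :func:`export_network` (round-trip inverse)."""
    network = CoOccurrenceNetwork()
    if fmt == "vosviewer":
        if network_stream is None:
            raise ValueError("vosviewer import needs the network file stream")
        lines = iter(map_stream)
        header = next(lines, None)
        if header is None or header.strip().split("\t") != ["id", "label", "weight"]:
            raise ValueError("bad VOSviewer map header")
        id_to_label: dict[int, str] = {}
        for line in lines:
            if not line.strip():
                continue
            node_id, label, weight = line.rstrip("\n").split("\t")
            id_to_label[int(node_id)] = label
            network.nodes[label] = NetworkNode(label=label, occurrences=float(weight))
        for line in network_stream:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            network.add_edge(id_to_label[int(a)], id_to_label[int(b)], float(w))
    elif fmt == "pajek":
        id_to_label = {}
        mode = None
        for line in map_stream:
            line = line.strip()
            if not line:
                continue
            if line.lower().startswith("*vertices"):
                mode = "vertices"
                continue
            if line.lower().startswith("*edges"):
                mode = "edges"
                continue
            if mode == "vertices":
                node_id, label = line.split(" ", 1)
                label = label.strip().strip('"')
                id_to_label[int(node_id)] = label
                network.nodes[label] = NetworkNode(label=label, occurrences=0.0)
            elif mode == "edges":
                a, b, w = line.split()
                network.add_edge(id_to_label[int(a)], id_to_label[int(b)], float(w))
    else:
        raise ValueError(f"unknown import format {fmt!r}")
    return network
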