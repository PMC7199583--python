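"""Shared-pathway interaction networks.

Two genes are connected when they co-occur in at least one enriched
pathway; the edge weight counts the shared pathways.  Node statistics
summarise how strongly a gene is functionally tied to the rest of the
query: its pathway count, degree, and the mean +/- sample SD of its
incident edge weights.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment import EnrichmentResult


def membership_from_enrichment(
    results: Sequence[EnrichmentResult], query: Iterable[str]
) -> dict[str, set[str]]:
    """gene -> set of surviving pathway names, from enrichment overlaps."""
    membership: dict[str, set[str]] = {g: set() for g in query}
    for r in results:
        for gene in r.overlap_genes:
            if gene in membership:
                membership[gene].add(r.set_name)
    return membership


def build_network(membership: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Graph over all genes in ``membership``; weight = shared-pathway count.

    Zero-weight pairs are non-edges; genes sharing nothing stay isolated
    nodes.  Output is independent of the mapping's iteration order.
    """
    net = nx.Graph()
    sets = {g: frozenset(m) for g, m in membership.items()}
    net.add_nodes_from(sorted(sets))
    for a, b in combinations(sorted(sets), 2):
        shared = len(sets[a] & sets[b])
        if shared >= 1:
            net.add_edge(a, b, weight=shared)
    nx.set_node_attributes(
        net, {g: len(m) for g, m in sets.items()}, name="n_pathways"
    )
    return net


def node_stats(net: nx.Graph, gene: str, *, population_sd: bool = False) -> dict:
    """Pathway count, degree and mean/SD of incident edge weights.

    The SD uses the n-1 denominator by default (``population_sd=True``
    switches to n).  Nodes with fewer than two incident edges get SD 0
    and nodes with no edges additionally mean 0, both flagged.
    """
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    weights = np.array(
        [data["weight"] for _, _, data in net.edges(gene, data=True)], dtype=float
    )
    degree = int(weights.size)
    flagged = degree < 2
    mean = float(weights.mean()) if degree else 0.0
    if degree >= 2:
        sd = float(weights.std(ddof=0 if population_sd else 1))
    else:
        sd = 0.0
    return {
        "gene": gene,
        "n_pathways": int(net.nodes[gene].get("n_pathways", 0)),
        "degree": degree,
        "mean_edge_weight": mean,
        "sd_edge_weight": sd,
        "degenerate": flagged,
    }


def all_node_stats(net: nx.Graph, *, population_sd: bool = False) -> list[dict]:
    return [node_stats(net, g, population_sd=population_sd) for g in sorted(net)]


def edge_list(net: nx.Graph) -> list[tuple[str, int, str]]:
    """Canonically sorted (geneA, weight, geneB) triples, geneA < geneB."""
    triples = []
    for a, b, data in net.edges(data=True):
        a, b = sorted((a, b))
        triples.append((a, int(data["weight"]), b))
    triples.sort(key=lambda t: (t[0], t[2]))
    return triples
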