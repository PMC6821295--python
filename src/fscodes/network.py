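"""Mutation-distance networks: amino-acid graphs weighted by codon adjacency.

Nodes are the amino acids a code encodes (sized by codon count); an edge
between amino acids a1 and a2 accumulates, over every codon pair (c1, c2)
with T(c1) = a1 and T(c2) = a2,

    w(a1, a2) = sum over pairs of p**l(c1, c2) * delta(c1, c2)

where l is the Hamming distance, p (default 1/12) downweights multi-step
paths, and the bridge indicator delta(c1, c2) is 1 when some codons
synonymously reachable from c1 and c2 (any number of same-amino-acid
point-mutation steps, including zero) lie within one point mutation of
each other.  Codes whose sense codons are mutually isolated by null codons
(ideal fail-safe codes) therefore produce edgeless networks.  Stop codons
are not nodes; null codons appear only as an optional aggregate node
carrying the null codon count for display purposes.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .codes import NULL, STOP, GeneticCode, hamming, mutation_neighbors

__all__ = [
    "DEFAULT_P",
    "synonymous_reachable",
    "edge_weight",
    "mutation_network",
    "edges_to_tsv",
    "nodes_to_tsv",
]

DEFAULT_P = 1.0 / 12.0


def synonymous_reachable(code: GeneticCode, codon: str) -> frozenset[str]:
    """Transitive closure of synonymous point mutations from ``codon``.

    Includes ``codon`` itself (zero steps).  Raises for stop/null codons,
    which have no synonymous neighborhood.
    """
    aa = code.label(codon)
    if aa in (STOP, NULL):
        raise ValueError(f"{codon} is not a sense codon")
    block = set(code.codons_for(aa))
    seen = {codon.upper().replace("T", "U")}
    frontier = list(seen)
    while frontier:
        c = frontier.pop()
        for nb in mutation_neighbors(c):
            if nb in block and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return frozenset(seen)


def edge_weight(
    code: GeneticCode, a1: str, a2: str, p: float = DEFAULT_P
) -> float:
    """Accessibility weight between two encoded amino acids."""
    if a1 == a2:
        raise ValueError("edge weights are defined between distinct amino acids")
    block1 = code.codons_for(a1)
    block2 = code.codons_for(a2)
    if not block1 or not block2:
        missing = a1 if not block1 else a2
        raise ValueError(f"amino acid {missing} is not encoded by {code.name!r}")
    reach1 = {c: synonymous_reachable(code, c) for c in block1}
    reach2 = {c: synonymous_reachable(code, c) for c in block2}
    total = 0.0
    for c1 in block1:
        for c2 in block2:
            bridged = any(
                hamming(r1, r2) <= 1 for r1 in reach1[c1] for r2 in reach2[c2]
            )
            if bridged:
                total += p ** hamming(c1, c2)
    return total


def mutation_network(
    code: GeneticCode, p: float = DEFAULT_P, include_null_node: bool = False
) -> nx.Graph:
    """Build the full amino-acid network of a code as a networkx graph.

    Node attribute ``codon_count`` carries the synonym-block size; edge
    attribute ``weight`` the accessibility weight.  Zero-weight pairs get
    no edge.  With ``include_null_node`` an isolated ``null`` node records
    the number of null codons (the display convention for fail-safe
    codes).
    """
    if not code.sense_codons:
        raise ValueError(f"code {code.name!r} has no sense codons")
    graph = nx.Graph(name=code.name, p=p)
    for aa in code.amino_acids:
        graph.add_node(aa, codon_count=len(code.codons_for(aa)))
    aas = code.amino_acids
    for i, a1 in enumerate(aas):
        for a2 in aas[i + 1 :]:
            w = edge_weight(code, a1, a2, p)
            if w > 0:
                graph.add_edge(a1, a2, weight=w)
    if include_null_node:
        graph.add_node("null", codon_count=len(code.null_codons))
    return graph


def edges_to_tsv(graph: nx.Graph, path: str | Path | None = None) -> str:
    lines = ["a1\ta2\tweight"]
    for a1, a2, data in sorted(graph.edges(data=True)):
        lines.append(f"{a1}\t{a2}\t{data['weight']:.10g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def nodes_to_tsv(graph: nx.Graph, path: str | Path | None = None) -> str:
    lines = ["aa\tcodon_count"]
    for node, data in sorted(graph.nodes(data=True)):
        lines.append(f"{node}\t{data['codon_count']}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
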