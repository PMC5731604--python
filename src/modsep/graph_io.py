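"""Interactome and disease–gene association I/O.

The interactome is an undirected, unweighted :class:`networkx.Graph` whose
nodes are gene identifiers. Identifiers are treated as opaque strings even
when they look numeric (Entrez ids), which avoids leading-zero and locale
surprises when association files come from different sources.

File dialects
-------------
Both readers accept tab- or whitespace-separated columns, skip blank lines
and lines starting with ``#``, and can skip a single header row when asked.
All readers log what they kept and what they dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .exceptions import DataError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "MappedGeneSet",
    "DiseaseModule",
    "load_interactome",
    "write_interactome",
    "load_associations",
    "write_associations",
    "map_to_graph",
    "largest_connected_component",
    "module_fraction",
    "module_qualifies",
]


@dataclass(frozen=True)
class MappedGeneSet:
    """Partition of a disease gene set into genes on / off the interactome."""

    disease: str
    in_graph: frozenset
    dropped: frozenset

    def __post_init__(self):
        if self.in_graph & self.dropped:
            raise DataError("in_graph and dropped overlap")


@dataclass(frozen=True)
class DiseaseModule:
    """Largest connected component induced by a disease's genes.

    ``n_associated`` counts the associated genes that mapped onto the graph,
    the denominator of :func:`module_fraction`.
    """

    disease: str
    members: frozenset
    n_associated: int


def _data_lines(path, header: bool):
    """Yield (lineno, stripped line) skipping blanks, comments, optional header."""
    skipped_header = not header
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            yield lineno, line


def load_interactome(path, fmt: str = "tsv-edgelist", header: bool = False) -> nx.Graph:
    """Read an undirected edge list into a graph.

    The first two whitespace/tab-separated fields of each line are the edge
    endpoints; extra columns are ignored. Repeated unordered pairs are
    collapsed; self-loops are discarded but their node is retained.
    """
    if fmt != "tsv-edgelist":
        raise DataError(f"unknown interactome format: {fmt!r}")
    g = nx.Graph()
    n_lines = n_self = n_dup = 0
    for lineno, line in _data_lines(path, header):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
        n_lines += 1
        u, v = fields[0], fields[1]
        g.add_node(u)
        g.add_node(v)
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    log.info(
        "interactome %s: %d data lines, %d nodes, %d edges kept, "
        "%d self-loops dropped, %d duplicate pairs collapsed",
        path, n_lines, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
    )
    return g


def write_interactome(g: nx.Graph, path) -> None:
    """Write a two-column edge list, sorted for byte-stable output."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def load_associations(path, header: bool = False) -> dict:
    """Read (disease, gene) rows into ``{disease: set-of-genes}``.

    The disease label is everything before the first tab when the line is
    tab-separated (labels may contain spaces); otherwise the first
    whitespace-separated token. Duplicate rows collapse silently.
    """
    entries: dict = {}
    n_rows = n_dup = 0
    for lineno, line in _data_lines(path, header):
        if "\t" in line:
            fields = [f.strip() for f in line.split("\t")]
        else:
            fields = line.split()
        disease = fields[0]
        gene = fields[1].strip() if len(fields) > 1 else ""
        if not gene:
            raise DataError(
                f"{path}:{lineno}: no gene parsed for disease {disease!r}")
        n_rows += 1
        genes = entries.setdefault(disease, set())
        if gene in genes:
            n_dup += 1
        genes.add(gene)
    if not entries:
        raise DataError(f"{path}: no association rows found")
    for disease, genes in entries.items():
        if not genes:  # pragma: no cover - unreachable given the row check
            raise DataError(f"disease {disease!r} has zero parsed genes")
    log.info(
        "associations %s: %d rows, %d diseases, %d duplicate rows collapsed",
        path, n_rows, len(entries), n_dup,
    )
    return entries


def write_associations(entries: dict, path) -> None:
    """Write a disease<TAB>gene table, sorted for byte-stable output."""
    with open(path, "wt", encoding="utf-8") as fh:
        for disease in sorted(entries):
            for gene in sorted(entries[disease]):
                fh.write(f"{disease}\t{gene}\n")


def map_to_graph(g: nx.Graph, genes, disease: str = "?") -> MappedGeneSet:
    """Split ``genes`` into those present in the graph and those absent."""
    genes = set(genes)
    in_graph = frozenset(x for x in genes if x in g)
    dropped = frozenset(genes - in_graph)
    if dropped:
        log.warning("disease %s: %d of %d genes absent from interactome",
                    disease, len(dropped), len(genes))
    return MappedGeneSet(disease=disease, in_graph=in_graph, dropped=dropped)


def largest_connected_component(g: nx.Graph, genes, disease: str = "?") -> DiseaseModule:
    """Extract the disease module: the largest induced connected component.

    Ties between equal-size components are broken by the lexicographically
    smallest sorted member list, so the result is deterministic.
    """
    genes = set(genes)
    if not genes:
        raise DataError("cannot extract a module from an empty gene set")
    missing = genes - set(g.nodes)
    if missing:
        raise DataError(f"genes not in interactome: {sorted(missing)[:5]} ...")
    sub = g.subgraph(genes)
    components = [tuple(sorted(c)) for c in nx.connected_components(sub)]
    best = min(components, key=lambda c: (-len(c), c))
    return DiseaseModule(disease=disease, members=frozenset(best),
                         n_associated=len(genes))


def module_fraction(module: DiseaseModule) -> float:
    """Module size as a fraction of the disease's mapped associated genes."""
    if module.n_associated < 1:
        raise DataError("module has zero associated genes")
    return len(module.members) / module.n_associated


def module_qualifies(module: DiseaseModule, min_size: int = 2,
                     min_fraction: float = 0.0) -> bool:
    """Configurable stand-in for a percolation-based module size criterion.

    A module qualifies when it has at least ``min_size`` members and covers at
    least ``min_fraction`` of the disease's mapped genes.
    """
    return (len(module.members) >= min_size
            and module_fraction(module) >= min_fraction)
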