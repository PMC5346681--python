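"""Reading, cleaning and writing interaction networks and gene sets.

Protein-protein interaction maps arrive as two-column edge lists over gene
identifiers (typically NCBI Entrez IDs, treated here as opaque case-sensitive
strings).  Cleaning enforces the standard conventions for unweighted,
undirected interactomes: self-interactions are dropped and redundant records
— either literal repeats or the same pair in the opposite orientation — are
collapsed to a single undirected edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "InteractionNetwork",
    "load_edge_list",
    "load_gene_set",
    "write_edge_list",
    "write_gene_set",
    "restrict_to_network",
    "EdgeListParseError",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list or gene-set file."""


@dataclass(frozen=True)
class GeneSet:
    """An unordered collection of gene identifiers with a free-text label."""

    ids: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ids

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.ids))


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """An undirected simple graph over gene identifiers.

    Invariants: no self-loops, each unordered pair stored once, every edge
    endpoint is a known gene.  Isolated genes (degree zero) are permitted
    only when declared explicitly via ``genes``; by default the gene universe
    is the union of edge endpoints.
    """

    __slots__ = ("_genes", "_edges", "_adj")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        genes: Iterable[str] = (),
    ) -> None:
        edge_set: set[tuple[str, str]] = set()
        n_self = 0
        n_raw = 0
        for a, b in edges:
            n_raw += 1
            if a == b:
                n_self += 1
                continue
            edge_set.add(_canonical(a, b))
        n_dup = n_raw - n_self - len(edge_set)
        if n_self or n_dup:
            logger.info(
                "edge cleaning dropped %d self-loop(s) and %d redundant record(s)",
                n_self,
                n_dup,
            )
        gene_set = set(genes)
        for a, b in edge_set:
            gene_set.add(a)
            gene_set.add(b)
        adj: dict[str, set[str]] = {g: set() for g in gene_set}
        for a, b in edge_set:
            adj[a].add(b)
            adj[b].add(a)
        self._genes = frozenset(gene_set)
        self._edges = frozenset(edge_set)
        self._adj = adj

    @property
    def genes(self) -> frozenset[str]:
        return self._genes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges as lexicographically ordered pairs."""
        return self._edges

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def degree(self, gene: str) -> int:
        return len(self._adj[gene])

    def neighbors(self, gene: str) -> frozenset[str]:
        return frozenset(self._adj[gene])

    def adjacency(self) -> dict[str, set[str]]:
        """Adjacency map keyed by gene; callers must not mutate it."""
        return self._adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._genes)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._genes == other._genes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._genes, self._edges))

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_genes={self.n_genes}, n_edges={self.n_edges})"


def _data_lines(path: Path, comment_prefix: str) -> Iterator[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (comment_prefix and line.startswith(comment_prefix)):
                continue
            yield lineno, line


def load_edge_list(
    path: str | Path,
    comment_prefix: str = "#",
    delimiter: str | None = None,
    node_list: str | Path | None = None,
) -> InteractionNetwork:
    """Read a two-column edge list, cleaning self-loops and duplicates.

    ``delimiter=None`` splits on any whitespace (tabs included).  Columns
    beyond the first two (edge weights, evidence codes) are ignored with a
    logged note.  ``node_list`` optionally declares genes with zero
    interactions so they enter the gene universe.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    extra_cols = 0
    for lineno, line in _data_lines(path, comment_prefix):
        fields = line.split(delimiter)
        fields = [f for f in fields if f != ""]
        if len(fields) < 2:
            raise EdgeListParseError(
                f"{path}: line {lineno} has fewer than 2 columns: {line!r}"
            )
        if len(fields) > 2:
            extra_cols += 1
        edges.append((fields[0], fields[1]))
    if extra_cols:
        logger.info(
            "%s: ignored extra columns on %d line(s) (networks are unweighted)",
            path,
            extra_cols,
        )
    declared: frozenset[str] = frozenset()
    if node_list is not None:
        declared = load_gene_set(node_list, label="declared nodes").ids
    net = InteractionNetwork(edges, genes=declared)
    logger.info("%s: loaded %d genes, %d edges", path, net.n_genes, net.n_edges)
    return net


def load_gene_set(
    path: str | Path, label: str = "", comment_prefix: str = "#"
) -> GeneSet:
    """Read a one-identifier-per-line gene set; duplicates collapse."""
    path = Path(path)
    ids = {line.split()[0] for _, line in _data_lines(path, comment_prefix)}
    if not ids:
        logger.warning("%s: empty gene set", path)
    return GeneSet(ids=frozenset(ids), label=label or path.stem)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    """Write canonicalized (lexicographically ordered pair) edges, sorted,
    one per line — stable output for reproducible diffs."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in sorted(gs.ids):
            fh.write(f"{g}\n")


def restrict_to_network(network: InteractionNetwork, gs: GeneSet) -> GeneSet:
    """Intersect a gold-standard gene set with the network's gene universe.

    Gold-standard genes present in the network are the positive class; the
    remaining network genes are the negative class.
    """
    return GeneSet(ids=gs.ids & network.genes, label=gs.label)
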