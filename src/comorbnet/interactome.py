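"""Protein-protein interactome: loading, cleaning and topological queries.

The interactome is an undirected, unweighted simple graph whose nodes are
positive integer gene identifiers (Entrez-style).  It is the substrate for
every network computation in this package: shortest-path distances, degree
statistics, degree-matched random sampling and disease-module growth.

Distance computations are delegated to ``scipy.sparse.csgraph`` on a cached
CSR adjacency matrix, which makes the thousands of breadth-first searches
needed by the permutation null affordable.  All distance-based analyses are
meant to run on the largest connected component (see
:func:`largest_connected_component`); nodes unreachable from the sources are
simply absent from the returned distance map.
"""

from __future__ import annotations

import logging
import os
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

#: Graphs up to this many nodes get a cached all-pairs distance matrix
#: (float64, ~128 MB at the limit); larger graphs fall back to per-query BFS.
APSP_MAX_NODES = 4096


class ParseError(ValueError):
    """Raised when an edge-list or gene-list file cannot be parsed."""


class Interactome:
    """Undirected simple graph over positive-integer gene identifiers.

    Invariants (enforced on construction and mutation): no self-loops, no
    duplicate edges, every edge endpoint is a node.  Backed by a
    :class:`networkx.Graph`; the wrapper adds identifier validation and
    caches a CSR adjacency matrix for fast distance queries.
    """

    def __init__(self, name: str = "interactome", graph: nx.Graph | None = None):
        self.name = name
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()
        self._matrix_cache: tuple[list[int], dict[int, int], "np.ndarray"] | None = None
        self._dist_cache: np.ndarray | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], name: str = "interactome") -> "Interactome":
        g = cls(name=name)
        for a, b in edges:
            g.add_edge(a, b)
        return g

    @staticmethod
    def _check_id(gene: int) -> int:
        gene = int(gene)
        if gene <= 0:
            raise ValueError(f"gene identifiers must be positive integers, got {gene}")
        return gene

    def add_node(self, gene: int) -> None:
        self.graph.add_node(self._check_id(gene))
        self._invalidate()

    def add_edge(self, a: int, b: int) -> None:
        a, b = self._check_id(a), self._check_id(b)
        if a == b:
            raise ValueError(f"self-loop on gene {a} is not allowed")
        self.graph.add_edge(a, b)
        self._invalidate()

    def _invalidate(self) -> None:
        self._matrix_cache = None
        self._dist_cache = None

    # -- basic queries -------------------------------------------------------

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[int, int]]:
        """Edges in deterministic order, each as (min id, max id)."""
        yield from sorted((min(a, b), max(a, b)) for a, b in self.graph.edges)

    def __contains__(self, gene: int) -> bool:
        return gene in self.graph

    def neighbors(self, gene: int) -> set[int]:
        if gene not in self.graph:
            raise KeyError(f"gene {gene} is not in network {self.name!r}")
        return set(self.graph.neighbors(gene))

    def degree_of(self, gene: int) -> int:
        """Number of distinct neighbors of ``gene``; KeyError if absent."""
        if gene not in self.graph:
            raise KeyError(f"gene {gene} is not in network {self.name!r}")
        return int(self.graph.degree[gene])

    def degrees(self) -> dict[int, int]:
        return {g: int(d) for g, d in self.graph.degree}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome({self.name!r}, {self.n_nodes} nodes, {self.n_edges} edges)"

    # -- distance machinery --------------------------------------------------

    def _matrix(self):
        """Node list, node->row index and CSR adjacency, cached."""
        if self._matrix_cache is None:
            nodes = sorted(self.graph.nodes)
            index = {g: i for i, g in enumerate(nodes)}
            adj = nx.to_scipy_sparse_array(self.graph, nodelist=nodes, format="csr", weight=None)
            self._matrix_cache = (nodes, index, adj)
        return self._matrix_cache

    def distance_matrix(self) -> tuple[np.ndarray, dict[int, int]]:
        """All-pairs hop distances (float, ``inf`` for unreachable) and node index.

        Only available for graphs up to :data:`APSP_MAX_NODES` nodes; the
        permutation null reuses this cache across thousands of resamples.
        """
        if self.n_nodes > APSP_MAX_NODES:
            raise ValueError(
                f"all-pairs distance matrix limited to {APSP_MAX_NODES} nodes "
                f"({self.n_nodes} in {self.name!r}); use bfs_distances instead"
            )
        if self._dist_cache is None:
            _, _, adj = self._matrix()
            self._dist_cache = dijkstra(adj, unweighted=True, directed=False)
        _, index, _ = self._matrix()
        return self._dist_cache, index


def load_interactome(source: str | os.PathLike | IO[str], name: str = "interactome") -> Interactome:
    """Parse a two-column edge list into an :class:`Interactome`.

    Lines starting with ``#`` are comments; a single leading header line is
    auto-detected by a non-integer first field.  Extra columns (confidence
    scores, evidence types) are ignored.  Self-loops and duplicate edges are
    dropped silently with a logged count; a malformed identifier raises
    :class:`ParseError` naming the line number.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        handle: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        g = Interactome(name=name)
        n_loops = n_dups = 0
        seen_data = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected at least 2 columns, got {len(fields)}")
            try:
                a, b = int(fields[0]), int(fields[1])
            except ValueError:
                if not seen_data:  # a single header line is tolerated
                    seen_data = True
                    continue
                raise ParseError(f"line {lineno}: non-integer gene identifier in {fields[:2]}") from None
            seen_data = True
            if a <= 0 or b <= 0:
                raise ParseError(f"line {lineno}: gene identifiers must be positive, got {a}, {b}")
            if a == b:
                n_loops += 1
                continue
            if g.graph.has_edge(a, b):
                n_dups += 1
                continue
            g.graph.add_edge(a, b)
        if g.n_nodes == 0:
            raise ParseError("edge list contains no parseable edges")
        if n_loops or n_dups:
            logger.info(
                "load_interactome(%s): dropped %d self-loops and %d duplicate edges",
                name, n_loops, n_dups,
            )
        g._invalidate()
        return g
    finally:
        if close:
            handle.close()


def write_interactome(g: Interactome, path: str | os.PathLike | IO[str]) -> None:
    """Write the edge list, one ``a<TAB>b`` per line, sorted by (min id, max id).

    Isolated nodes cannot be represented in an edge list and are not written.
    """
    close = False
    if isinstance(path, (str, os.PathLike)):
        handle: IO[str] = open(path, "w", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        handle.write(f"# network: {g.name}\n")
        for a, b in g.edges():
            handle.write(f"{a}\t{b}\n")
    finally:
        if close:
            handle.close()


def largest_connected_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest component (ties: smallest minimum id).

    Idempotent; the result carries the same name.  All proximity and module
    computations in this package are intended to run on the LCC so that every
    pairwise distance is finite.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot take the largest connected component of an empty graph")
    best = max(nx.connected_components(g.graph), key=lambda c: (len(c), -min(c)))
    sub = nx.Graph(g.graph.subgraph(best))
    return Interactome(name=g.name, graph=sub)


def bfs_distances(g: Interactome, sources: Iterable[int]) -> dict[int, int]:
    """Multi-source breadth-first hop distances.

    Returns ``{node: min over sources of hops(source, node)}`` for every node
    reachable from at least one source; unreachable nodes are absent.  Sources
    not present in the graph are ignored; if none is present, ValueError.
    """
    nodes, index, adj = g._matrix()
    idx = [index[s] for s in set(sources) if s in index]
    if not idx:
        raise ValueError(f"no source gene is present in network {g.name!r}")
    d = dijkstra(adj, unweighted=True, directed=False, indices=idx, min_only=True)
    return {nodes[i]: int(d[i]) for i in np.flatnonzero(np.isfinite(d))}


def degree_of(g: Interactome, gene: int) -> int:
    """Module-level alias for :meth:`Interactome.degree_of`."""
    return g.degree_of(gene)
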