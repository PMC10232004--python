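"""Protein–protein interactome container and edge-list I/O.

The interactome is an undirected, unweighted simple graph of protein
identifiers. It is the population for every statistic downstream: ``N``
(node count) and node degrees ``k`` enter the hypergeometric connectivity
test, and induced-subgraph largest-connected-component (LCC) sizes are the
module-size statistic.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Interactome",
    "LoadReport",
    "load_edge_list",
    "largest_connected_component_size",
]


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from parsing an edge list."""

    rows_read: int
    self_loops_dropped: int
    duplicates_collapsed: int


class Interactome:
    """Undirected simple graph of protein identifiers.

    Invariants: no self-loops, no duplicate edges, symmetric adjacency.
    Nodes that appear only in dropped self-loops are kept as isolated
    nodes so that ``N`` reflects the input's full node universe (``N``
    enters the hypergeometric population).

    Parameters
    ----------
    graph : networkx.Graph
        Backing graph; self-loops are removed defensively.
    """

    def __init__(self, graph: nx.Graph) -> None:
        if graph.number_of_nodes() == 0:
            raise ValueError("interactome is empty")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            graph = graph.copy()
            graph.remove_edges_from(loops)
        self._g = graph
        self._adj: dict[str, frozenset[str]] | None = None
        self._checksum: str | None = None

    # -- basic queries -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def N(self) -> int:
        """Population size: total node count."""
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def degree(self, node: str) -> int:
        if node not in self._g:
            raise KeyError(f"unknown protein: {node!r}")
        return self._g.degree[node]

    def neighbors(self, node: str) -> frozenset[str]:
        return self.adjacency()[node]

    def adjacency(self) -> dict[str, frozenset[str]]:
        """Node -> frozenset of neighbours; cached for the sampling hot loop."""
        if self._adj is None:
            self._adj = {v: frozenset(self._g[v]) for v in self._g}
        return self._adj

    def lcc_nodes(self) -> set[str]:
        """Nodes of the interactome's own largest connected component."""
        return set(max(nx.connected_components(self._g), key=len))

    def checksum(self) -> str:
        """SHA-256 over the sorted edge list + sorted nodes (run provenance)."""
        if self._checksum is None:
            h = hashlib.sha256()
            for v in sorted(self._g.nodes):
                h.update(v.encode())
                h.update(b"\x00")
            h.update(b"\x01")
            for a, b in sorted(tuple(sorted(e)) for e in self._g.edges):
                h.update(f"{a}\t{b}".encode())
                h.update(b"\x00")
            self._checksum = h.hexdigest()[:16]
        return self._checksum

    # -- induced-subgraph LCC ------------------------------------------
    def induced_lcc_size(self, subset: Iterable[str], *, validate: bool = True) -> int:
        """Size of the largest connected component induced by ``subset``.

        Runs a set-intersection BFS over the cached adjacency; this is the
        hot path of the null-model sampler, so it avoids building a
        networkx subgraph per call.
        """
        sub = set(subset)
        if not sub:
            return 0
        if validate:
            unknown = sub - self._g.nodes.keys()
            if unknown:
                raise KeyError(
                    "identifiers not in interactome: "
                    + ", ".join(sorted(unknown)[:10])
                )
        adj = self.adjacency()
        unvisited = set(sub)
        best = 0
        while unvisited:
            root = unvisited.pop()
            size = 1
            frontier = [root]
            while frontier:
                nxt = set()
                for v in frontier:
                    nxt |= adj[v] & unvisited
                unvisited -= nxt
                size += len(nxt)
                frontier = list(nxt)
            if size > best:
                best = size
        return best

    def induced_lcc_members(self, subset: Iterable[str]) -> set[str]:
        """Members of the largest connected component induced by ``subset``.

        Ties between equal-sized components are broken toward the component
        containing the lexicographically smallest node, so the result is
        deterministic.
        """
        sub = set(subset)
        if not sub:
            return set()
        unknown = sub - self._g.nodes.keys()
        if unknown:
            raise KeyError(
                "identifiers not in interactome: " + ", ".join(sorted(unknown)[:10])
            )
        adj = self.adjacency()
        unvisited = set(sub)
        best: set[str] = set()
        for root in sorted(sub):
            if root not in unvisited:
                continue
            comp = {root}
            unvisited.discard(root)
            frontier = [root]
            while frontier:
                nxt = set()
                for v in frontier:
                    nxt |= adj[v] & unvisited
                unvisited -= nxt
                comp |= nxt
                frontier = list(nxt)
            if len(comp) > len(best):
                best = comp
        return best

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome(N={self.N}, edges={self.n_edges})"


def _parse_row(fields: Sequence[str], dialect: str, lineno: int) -> tuple[str, str]:
    if dialect == "tsv":
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        a, b = fields[0], fields[1]
        if len(fields) > 2 and fields[2].strip():
            warnings.warn(
                f"line {lineno}: extra columns (weights?) ignored; "
                "the interactome is treated as unweighted",
                stacklevel=3,
            )
    elif dialect == "sif":
        if len(fields) != 3:
            raise ValueError(
                f"line {lineno}: SIF row needs 'nodeA relation nodeB', got "
                f"{len(fields)} fields"
            )
        a, b = fields[0], fields[2]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    a, b = a.strip(), b.strip()
    if not a or not b:
        raise ValueError(f"line {lineno}: empty identifier")
    return a, b


def load_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    *,
    header: bool = False,
) -> tuple[Interactome, LoadReport]:
    """Read an interactome from a two-column TSV or a SIF file.

    Self-loops are dropped (the node is retained as isolated), duplicate
    and reversed-duplicate edges are collapsed, identifiers are
    whitespace-trimmed. Returns the graph together with a
    :class:`LoadReport` counting what was cleaned up.
    """
    path = Path(path)
    g = nx.Graph()
    rows = loops = dups = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            a, b = _parse_row(fields, dialect, lineno)
            rows += 1
            if a == b:
                loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                dups += 1
                continue
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges or nodes parsed")
    return Interactome(g), LoadReport(rows, loops, dups)


def write_edge_list(g: Interactome, path: str | Path) -> None:
    """Write the interactome as a sorted two-column TSV (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.graph.edges):
            fh.write(f"{a}\t{b}\n")
        # isolated nodes survive as degenerate single-column rows? No:
        # emit them as self-referencing loop rows so the node universe
        # round-trips (loaders drop the loop but keep the node).
        degs = dict(g.graph.degree)
        for v in sorted(v for v, d in degs.items() if d == 0):
            fh.write(f"{v}\t{v}\n")


def largest_connected_component_size(g: Interactome, subset: Iterable[str]) -> int:
    """LCC size of the subgraph induced by ``subset``; 0 for the empty set.

    Identifiers not present in ``g`` raise ``KeyError`` listing offenders.
    """
    return g.induced_lcc_size(subset, validate=True)
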