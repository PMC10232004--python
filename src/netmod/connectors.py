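"""Connector proteins between the up- and down-regulated modules.

A connector is a protein present in both final modules (the shared nodes
of the two-module picture). For every connector the report records its
role (seed or added) in each module and its direct interactome neighbours
among each module's seeds — the query that singles out a protein binding
many proteins of both modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .interactome import Interactome
from .seeds import SeedSet
from .termination import ModuleResult

__all__ = [
    "ConnectorRecord",
    "ConnectorReport",
    "find_shared_proteins",
    "count_seed_interactions",
    "build_connector_report",
    "write_union_subgraph",
]


@dataclass(frozen=True)
class ConnectorRecord:
    protein_id: str
    in_a: str  # seed | added | none
    in_b: str
    seed_neighbors_a: int
    seed_neighbors_b: int
    neighbors_a: tuple[str, ...]
    neighbors_b: tuple[str, ...]


@dataclass
class ConnectorReport:
    shared_proteins: frozenset[str]
    records: list[ConnectorRecord]
    interactome_checksum: str
    loose: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Ranked summary: connectors ordered by total seed interactions."""
        rows = sorted(
            self.records,
            key=lambda r: (-(r.seed_neighbors_a + r.seed_neighbors_b), r.protein_id),
        )
        return pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in rows],
                "role_up": [r.in_a for r in rows],
                "role_down": [r.in_b for r in rows],
                "seed_neighbors_up": [r.seed_neighbors_a for r in rows],
                "seed_neighbors_down": [r.seed_neighbors_b for r in rows],
                "seed_partners_up": [";".join(r.neighbors_a) for r in rows],
                "seed_partners_down": [";".join(r.neighbors_b) for r in rows],
            }
        )


def _check_same_interactome(a: ModuleResult, b: ModuleResult) -> None:
    if a.interactome_checksum != b.interactome_checksum:
        raise ValueError(
            "module results come from different interactomes "
            f"({a.interactome_checksum} vs {b.interactome_checksum})"
        )


def find_shared_proteins(a: ModuleResult, b: ModuleResult) -> dict[str, tuple[str, str]]:
    """Intersection of two modules, tagged with each protein's role.

    Returns ``{protein_id: (role_in_a, role_in_b)}``. Both results must
    come from the same interactome (checksums are compared).
    """
    _check_same_interactome(a, b)
    shared = a.members & b.members
    return {p: (a.role_of(p), b.role_of(p)) for p in sorted(shared)}


def count_seed_interactions(
    g: Interactome, protein: str, seeds: SeedSet | Iterable[str]
) -> tuple[int, tuple[str, ...]]:
    """How many of the protein's interactome neighbours are in the given set."""
    if protein not in g:
        raise KeyError(f"unknown protein: {protein!r}")
    seed_set = set(seeds.proteins if isinstance(seeds, SeedSet) else seeds)
    hits = tuple(sorted(g.neighbors(protein) & seed_set))
    return len(hits), hits


def build_connector_report(
    g: Interactome,
    up: ModuleResult,
    down: ModuleResult,
    *,
    loose: bool = False,
) -> ConnectorReport:
    """Characterise the proteins shared by (or, loosely, adjacent to) both modules.

    With ``loose=True`` the report additionally includes proteins that are
    not members of both modules but have at least one interactome
    neighbour in each (off by default).
    """
    _check_same_interactome(up, down)
    if g.checksum() != up.interactome_checksum:
        raise ValueError("interactome checksum does not match the module results")
    shared = find_shared_proteins(up, down)
    candidates: dict[str, tuple[str, str]] = dict(shared)
    if loose:
        for v in sorted(g.nodes):
            if v in candidates:
                continue
            nbrs = g.neighbors(v)
            if nbrs & up.members and nbrs & down.members:
                role_a = up.role_of(v) if v in up.members else "none"
                role_b = down.role_of(v) if v in down.members else "none"
                candidates[v] = (role_a, role_b)
    records = []
    for p, (role_a, role_b) in candidates.items():
        na, hits_a = count_seed_interactions(g, p, up.seeds)
        nb, hits_b = count_seed_interactions(g, p, down.seeds)
        records.append(
            ConnectorRecord(
                protein_id=p,
                in_a=role_a,
                in_b=role_b,
                seed_neighbors_a=na,
                seed_neighbors_b=nb,
                neighbors_a=hits_a,
                neighbors_b=hits_b,
            )
        )
    return ConnectorReport(
        shared_proteins=frozenset(shared),
        records=records,
        interactome_checksum=g.checksum(),
        loose=loose,
    )


def write_union_subgraph(
    g: Interactome,
    up: ModuleResult,
    down: ModuleResult,
    path,
    *,
    fmt: str = "edgelist",
) -> None:
    """Export the subgraph induced by the union of both modules.

    ``edgelist`` writes a sorted two-column TSV; ``graphml`` writes GraphML
    with per-node ``module`` (up/down/both) and ``role`` attributes for
    external visualisation.
    """
    union = up.members | down.members
    sub = g.graph.subgraph(union)
    path = Path(path)
    if fmt == "edgelist":
        with path.open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
                fh.write(f"{a}\t{b}\n")
    elif fmt == "graphml":
        out = nx.Graph()
        for v in sorted(union):
            in_up, in_down = v in up.members, v in down.members
            module = "both" if in_up and in_down else ("up" if in_up else "down")
            role = up.role_of(v) if in_up else down.role_of(v)
            out.add_node(v, module=module, role=role)
        out.add_edges_from(sorted(tuple(sorted(e)) for e in sub.edges))
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
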