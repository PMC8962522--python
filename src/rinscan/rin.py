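"""Residue interaction network (RIN) construction.

A RIN is an undirected graph whose nodes are the residues of a structure
and whose edges mark geometric contacts: two residues are in contact when
the minimum distance over all heavy-atom pairs falls inside a closed
window, by default [2.5, 5.0] Å.  Edges carry the minimum distance as the
``min_dist`` attribute; centrality downstream treats the graph as
unweighted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "ContactParams",
    "min_inter_residue_distance",
    "build_rin",
    "inter_chain_edges",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class ContactParams:
    """Distance window (Å) of the residue-residue contact rule.

    The window is closed: boundary distances produce edges.  Sequence
    neighbours (|Δseq_num| == 1 on the same chain) are kept by default;
    some RIN tools exclude them, hence the switch.
    """

    d_min: float = 2.5
    d_max: float = 5.0
    include_sequence_neighbors: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError(f"require 0 < d_min < d_max, got [{self.d_min}, {self.d_max}]")


def min_inter_residue_distance(
    model: StructureModel, a: ResidueKey, b: ResidueKey
) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom pairs of two residues."""
    if a == b:
        raise ValueError(f"residues must differ, got {a} twice")
    xa = np.array([at.coord for at in model.atoms_of(a)])
    xb = np.array([at.coord for at in model.atoms_of(b)])
    diff = xa[:, None, :] - xb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def _sequence_adjacent(a: ResidueKey, b: ResidueKey) -> bool:
    return a.chain_id == b.chain_id and abs(a.seq_num - b.seq_num) == 1


def build_rin(model: StructureModel, params: ContactParams | None = None) -> nx.Graph:
    """Contact graph of a structure under the distance-window rule.

    Nodes are every residue of the model; an edge joins residues a, b iff
    d_min ≤ min_inter_residue_distance(a, b) ≤ d_max.  A k-d tree on all
    heavy atoms prefilters candidate pairs, so only residue pairs with at
    least one atom pair within d_max are examined exactly.
    """
    params = params or ContactParams()
    keys = list(model.residues())
    if not keys:
        raise EmptyStructureError(f"structure {model.id!r} has no residues")

    graph = nx.Graph()
    graph.add_nodes_from(keys)

    coords: list[tuple[float, float, float]] = []
    owner: list[int] = []
    for i, key in enumerate(keys):
        for atom in model.atoms_of(key):
            coords.append(atom.coord)
            owner.append(i)
    tree = cKDTree(np.asarray(coords))
    candidate_pairs = set()
    for ai, bi in tree.query_pairs(r=params.d_max):
        ra, rb = owner[ai], owner[bi]
        if ra != rb:
            candidate_pairs.add((min(ra, rb), max(ra, rb)))

    for ra, rb in sorted(candidate_pairs):
        a, b = keys[ra], keys[rb]
        if not params.include_sequence_neighbors and _sequence_adjacent(a, b):
            continue
        d = min_inter_residue_distance(model, a, b)
        if params.d_min <= d <= params.d_max:
            graph.add_edge(a, b, min_dist=d)
    return graph


def inter_chain_edges(
    graph: nx.Graph, chains_a: set[str], chains_b: set[str]
) -> set[frozenset]:
    """Edges with one endpoint in ``chains_a`` and the other in ``chains_b``."""
    overlap = set(chains_a) & set(chains_b)
    if overlap:
        raise ValueError(f"chain sets must be disjoint, both contain {sorted(overlap)}")
    out = set()
    for u, v in graph.edges:
        cu, cv = u.chain_id, v.chain_id
        if (cu in chains_a and cv in chains_b) or (cu in chains_b and cv in chains_a):
            out.add(frozenset((u, v)))
    return out


def write_edge_list(graph: nx.Graph, dest: str | Path | TextIO, **metadata) -> None:
    """3-column TSV edge list: residue_a, residue_b, min_dist.

    Residues are rendered ``chain:number[icode]:name``; metadata entries
    become ``# key: value`` header lines.
    """
    handle: TextIO
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "w")
        close = True
    else:
        handle = dest
    try:
        for k, v in metadata.items():
            handle.write(f"# {k}: {v}\n")
        for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            d = graph.edges[u, v].get("min_dist")
            dtxt = f"{d:.6g}" if d is not None else ""
            handle.write(f"{u}\t{v}\t{dtxt}\n")
    finally:
        if close:
            handle.close()


def read_edge_list(source: str | Path | TextIO) -> nx.Graph:
    """Read a 2- or 3-column TSV edge list (distance column optional)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    graph = nx.Graph()
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"edge list line has fewer than 2 columns: {line!r}")
        u, v = ResidueKey.parse(parts[0]), ResidueKey.parse(parts[1])
        if len(parts) >= 3 and parts[2]:
            graph.add_edge(u, v, min_dist=float(parts[2]))
        else:
            graph.add_edge(u, v)
    return graph
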