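"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check:

* ``brute_betweenness`` counts shortest paths by adjacency-matrix powers
  (walks of minimal length are exactly the shortest paths), not by BFS.
* ``brute_rin_edges`` applies the closed distance window with a plain
  double loop over residue pairs and atom pairs, no spatial index.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from rinscan.structure_io import StructureModel
from rinscan.synthetic import ToyStructureSpec, star_complex, toy_structure


def brute_betweenness(graph: nx.Graph) -> dict:
    """Betweenness by matrix-power path counting (unordered pairs)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    powers = [np.eye(n)]
    Ak = np.eye(n)
    for k in range(1, n):
        Ak = Ak @ A
        powers.append(Ak.copy())
        newly = np.isinf(dist) & (Ak > 0)
        np.fill_diagonal(newly, False)
        dist[newly] = k

    def sigma(i: int, j: int) -> float:
        if i == j:
            return 1.0
        d = dist[i, j]
        return 0.0 if np.isinf(d) else float(powers[int(d)][i, j])

    bc = {node: 0.0 for node in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if np.isinf(dist[s, t]):
                continue
            st = sigma(s, t)
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[nodes[v]] += sigma(s, v) * sigma(v, t) / st
    return bc


def brute_rin_edges(model: StructureModel, d_min: float = 2.5, d_max: float = 5.0):
    """Contact edges by an exhaustive double loop (closed interval)."""
    keys = list(model.residues())
    edges = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            best = math.inf
            for at_a in model.atoms_of(a):
                for at_b in model.atoms_of(b):
                    d = math.dist(at_a.coord, at_b.coord)
                    best = min(best, d)
            if d_min <= best <= d_max:
                edges[frozenset((a, b))] = best
    return edges


def random_toy_structure(seed: int, n_max: int = 12, box: float = 12.0) -> StructureModel:
    """Random single-atom-residue placements in a cube, seeded."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    placements = tuple(
        ("A", i + 1, "GLY", tuple(float(c) for c in rng.uniform(0, box, 3)))
        for i in range(n)
    )
    return toy_structure(ToyStructureSpec(placements, label=f"rand{seed}"))


@pytest.fixture
def star_model():
    return star_complex()


@pytest.fixture
def minimal_pdb(tmp_path):
    """Two single-atom residues, one chain."""
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  GLY A   2       0.000   0.000   4.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "minimal.pdb"
    path.write_text(text)
    return path
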