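"""Betweenness centrality with per-structure Z-scoring.

Raw betweenness is computed on the unweighted, undirected contact graph:
bc(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st, each unordered pair counted once and
disconnected pairs contributing nothing.  Z-scores standardise bc across
the residues of one structure; residues with Z ≥ z_threshold (default 2)
are flagged "central".  The standard-deviation convention (sample, n−1
divisor, vs population) is a switch because the convention of the tool the
field commonly uses for this step is not published; Z-scores are affine
invariant in bc either way, so central calls are robust to any constant
rescaling of betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Literal, Mapping, TextIO

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CentralityParams",
    "CentralityTable",
    "betweenness_centrality",
    "centrality_zscores",
    "central_nodes",
]


@dataclass(frozen=True)
class CentralityParams:
    z_threshold: float = 2.0
    sd_mode: Literal["sample", "population"] = "sample"

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_threshold):
            raise ValueError("z_threshold must be finite")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")


@dataclass
class CentralityTable:
    """Per-node betweenness, Z-score and central flag."""

    frame: pd.DataFrame  # index: node; columns: bc, z, central
    params: CentralityParams = field(default_factory=CentralityParams)

    def __len__(self) -> int:
        return len(self.frame)

    def z_of(self, node: Hashable) -> float:
        return float(self.frame.loc[[node], "z"].iloc[0])

    def is_central(self, node: Hashable) -> bool:
        return bool(self.frame.loc[[node], "central"].iloc[0])

    def write_tsv(self, dest: str | Path | TextIO, **metadata) -> None:
        """TSV with columns residue, bc, z, central plus # metadata header."""
        close = False
        if isinstance(dest, (str, Path)):
            handle, close = open(dest, "w"), True
        else:
            handle = dest
        try:
            handle.write(f"# z_threshold: {self.params.z_threshold}\n")
            handle.write(f"# sd_mode: {self.params.sd_mode}\n")
            for k, v in metadata.items():
                handle.write(f"# {k}: {v}\n")
            handle.write("residue\tbc\tz\tcentral\n")
            for node, row in self.frame.iterrows():
                handle.write(
                    f"{node}\t{row.bc:.6g}\t{row.z:.6g}\t{bool(row.central)}\n"
                )
        finally:
            if close:
                handle.close()


def betweenness_centrality(graph: nx.Graph) -> dict:
    """Unnormalised betweenness of every node (unordered-pair convention)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("betweenness undefined on an empty graph")
    return nx.betweenness_centrality(graph, normalized=False, weight=None)


def centrality_zscores(
    bc: Mapping[Hashable, float], params: CentralityParams | None = None
) -> CentralityTable:
    """Standardise raw betweenness and call central nodes.

    With constant bc (zero standard deviation, including the single-node
    case) all Z-scores are defined as 0 and nothing is central.
    """
    params = params or CentralityParams()
    if len(bc) == 0:
        raise ValueError("need at least one node")
    nodes = list(bc)
    values = np.array([bc[n] for n in nodes], dtype=float)
    ddof = 1 if params.sd_mode == "sample" else 0
    sd = values.std(ddof=ddof) if len(values) > ddof else 0.0
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    frame = pd.DataFrame(
        {"bc": values, "z": z, "central": z >= params.z_threshold}, index=nodes
    )
    return CentralityTable(frame=frame, params=params)


def central_nodes(table: CentralityTable) -> set:
    """Nodes whose Z-score meets the threshold (inclusive)."""
    return set(table.frame.index[table.frame.central])
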