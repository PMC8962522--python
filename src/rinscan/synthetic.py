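"""Synthetic inputs with known ground truth for every pipeline stage.

Toy structures use single-atom residues (one CA per residue) so the
inter-residue minimum distance equals the placement distance and the
contact graph is exactly designable from geometry.  Random graphs feed
the centrality oracles, and simulated titrations carry a known Kd with
multiplicative noise.  Every generator is a pure function of its
arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .binding import BindingSeries, isotherm
from .structure_io import AtomRecord, ResidueKey, StructureModel

__all__ = [
    "ToyStructureSpec",
    "toy_structure",
    "line_structure",
    "star_complex",
    "random_graph",
    "simulate_binding_series",
    "write_toy_pdb",
    "write_titration_tsv",
]

Placement = tuple[str, int, str, tuple[float, float, float]]


@dataclass(frozen=True)
class ToyStructureSpec:
    """Residue placements: (chain_id, seq_num, res_name, xyz Å)."""

    placements: tuple[Placement, ...]
    label: str = "toy"

    def __post_init__(self) -> None:
        seen = set()
        for chain, num, _name, xyz in self.placements:
            if (chain, num) in seen:
                raise ValueError(f"duplicate residue identity {chain}:{num}")
            seen.add((chain, num))
            if not all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates for {chain}:{num}")


def toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Single-atom-per-residue model at the specified coordinates."""
    if not spec.placements:
        raise ValueError("toy structure needs at least one placement")
    model = StructureModel(id=spec.label)
    for chain, num, name, xyz in spec.placements:
        key = ResidueKey(chain, num, "", name)
        atom = AtomRecord(name="CA", element="C", coord=tuple(float(c) for c in xyz))
        model.chains.setdefault(chain, {})[key] = [atom]
    return model


def line_structure(n: int, spacing: float = 4.0, chain: str = "A") -> StructureModel:
    """n residues on the z axis, ``spacing`` Å apart.

    With 2.5 ≤ spacing ≤ 5 the contact graph is the path P_n.
    """
    if n < 1:
        raise ValueError(f"need n ≥ 1, got {n}")
    placements = tuple(
        (chain, i + 1, "GLY", (0.0, 0.0, i * spacing)) for i in range(n)
    )
    return toy_structure(ToyStructureSpec(placements, label=f"line{n}"))


def star_complex() -> StructureModel:
    """Two-chain fixture whose complex RIN is a 6-node star.

    Receptor chain A: center at the origin plus leaves at (±4, 0, 0);
    partner chain B: residues at (0, ±4, 0) and (0, 0, 4).  Every residue
    sits 4 Å from the center and ≥ 4√2 ≈ 5.657 Å from every other, so the
    only contacts under the [2.5, 5] Å rule are the five spokes.  The
    receptor alone is a 3-node path.
    """
    placements = (
        ("A", 1, "GLY", (-4.0, 0.0, 0.0)),
        ("A", 2, "HIS", (0.0, 0.0, 0.0)),
        ("A", 3, "GLY", (4.0, 0.0, 0.0)),
        ("B", 1, "ASP", (0.0, 4.0, 0.0)),
        ("B", 2, "ASP", (0.0, -4.0, 0.0)),
        ("B", 3, "PHE", (0.0, 0.0, 4.0)),
    )
    return toy_structure(ToyStructureSpec(placements, label="star_complex"))


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi G(n, p) on synthetic residue labels, seeded."""
    if n < 1:
        raise ValueError(f"need n ≥ 1, got {n}")
    if not (0 <= p <= 1):
        raise ValueError(f"need 0 ≤ p ≤ 1, got {p}")
    er = nx.gnp_random_graph(n, p, seed=seed)
    mapping = {i: ResidueKey("X", i + 1, "", "GLY") for i in er.nodes}
    return nx.relabel_nodes(er, mapping)


def simulate_binding_series(
    kd: float,
    concentrations: Sequence[float],
    r_free: float = 0.0,
    r_bound: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> BindingSeries:
    """Titration responses from a 1:1 isotherm with multiplicative noise.

    response_i = R([L]_i) · (1 + ε_i), ε ~ Normal(0, noise_cv), seeded.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    conc = np.asarray(concentrations, dtype=float)
    clean = isotherm(conc, kd, r_free, r_bound)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + rng.normal(0.0, noise_cv, size=clean.shape))
    return BindingSeries.from_arrays(conc, clean)


def write_toy_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialise a model to minimal fixed-column ATOM records + END."""
    lines = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for key, atoms in residues.items():
            for atom in atoms:
                serial += 1
                x, y, z = atom.coord
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{key.res_name:>3s} "
                    f"{chain_id:1s}{key.seq_num:4d}{key.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_titration_tsv(series: BindingSeries, path: str | Path) -> None:
    """Titration TSV in the format read_titration consumes."""
    with open(path, "w") as handle:
        handle.write("conc_nM\tresponse\n")
        for c, r in zip(series.ligand_conc, series.response):
            handle.write(f"{c:.6g}\t{r:.6g}\n")
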