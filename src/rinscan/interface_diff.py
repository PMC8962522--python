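"""Interface detection and differential centrality candidate nomination.

The selection criterion that nominated the TrkA His112 hotspot: a receptor
residue is a *candidate* when it

1. sits at the receptor/partner interface (≥ 1 contact to a partner chain
   within the RIN distance window),
2. is central (Z ≥ threshold) in the RIN of the whole complex, and
3. is NOT central in the RIN of the receptor-alone reference.

The reference defaults to the receptor chains extracted from the complex
coordinates; an independently solved receptor structure may be supplied
instead, with residues matched by author numbering (chain, number,
insertion code).  Residues present in only one model are flagged
``mismatch`` and excluded from candidacy rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import pandas as pd

from .centrality import (
    CentralityParams,
    CentralityTable,
    betweenness_centrality,
    central_nodes,
    centrality_zscores,
)
from .errors import ResidueMatchError
from .rin import ContactParams, build_rin, inter_chain_edges
from .structure_io import ResidueKey, StructureModel, extract_chain_set

__all__ = ["CandidateReport", "interface_residues", "differential_candidates"]


@dataclass
class CandidateReport:
    """Per-receptor-residue flags and the nominated candidate set.

    ``frame`` is indexed by ResidueKey with boolean columns interface,
    central_complex, central_reference, mismatch, candidate;
    candidate ⇔ interface ∧ central_complex ∧ ¬central_reference ∧ ¬mismatch.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    complex_table: CentralityTable | None = None
    reference_table: CentralityTable | None = None

    @property
    def candidates(self) -> set[ResidueKey]:
        return set(self.frame.index[self.frame.candidate])

    def write_tsv(self, dest: str | Path | TextIO) -> None:
        close = False
        if isinstance(dest, (str, Path)):
            handle, close = open(dest, "w"), True
        else:
            handle = dest
        try:
            for k, v in sorted(self.provenance.items()):
                handle.write(f"# {k}: {v}\n")
            handle.write(
                "residue\tinterface\tcentral_complex\tcentral_reference"
                "\tmismatch\tcandidate\n"
            )
            for node, row in self.frame.iterrows():
                flags = "\t".join(
                    str(bool(row[c]))
                    for c in (
                        "interface",
                        "central_complex",
                        "central_reference",
                        "mismatch",
                        "candidate",
                    )
                )
                handle.write(f"{node}\t{flags}\n")
        finally:
            if close:
                handle.close()

    def write_json(self, dest: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "candidates": sorted(str(k) for k in self.candidates),
            "n_receptor_residues": int(len(self.frame)),
            "n_interface": int(self.frame.interface.sum()),
        }
        Path(dest).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def interface_residues(
    model: StructureModel,
    receptor_chains: set[str],
    partner_chains: set[str],
    params: ContactParams | None = None,
) -> set[ResidueKey]:
    """Receptor residues with ≥ 1 contact to a partner chain.

    Uses the same closed distance window as the RIN itself.
    """
    params = params or ContactParams()
    receptor_chains, partner_chains = set(receptor_chains), set(partner_chains)
    overlap = receptor_chains & partner_chains
    if overlap:
        raise ValueError(f"receptor/partner chain sets overlap: {sorted(overlap)}")
    missing = (receptor_chains | partner_chains) - set(model.chains)
    if missing:
        raise ValueError(
            f"chain(s) {sorted(missing)} absent; available: {sorted(model.chains)}"
        )
    sub = extract_chain_set(model, receptor_chains | partner_chains)
    graph = build_rin(sub, params)
    edges = inter_chain_edges(graph, receptor_chains, partner_chains)
    out: set[ResidueKey] = set()
    for edge in edges:
        for node in edge:
            if node.chain_id in receptor_chains:
                out.add(node)
    return out


def _match_key(key: ResidueKey) -> tuple:
    # reference matching ignores res_name so renamed (e.g. mutated) residues
    # still pair up by author position
    return (key.chain_id, key.seq_num, key.icode)


def differential_candidates(
    complex_model: StructureModel,
    receptor_chains: set[str],
    partner_chains: set[str],
    reference_model: StructureModel | None = None,
    cparams: ContactParams | None = None,
    zparams: CentralityParams | None = None,
    reference_zparams: CentralityParams | None = None,
) -> CandidateReport:
    """Nominate interface residues central in the complex but not the reference.

    Parameters
    ----------
    complex_model : receptor + partner structure
    receptor_chains, partner_chains : disjoint chain id sets
    reference_model : receptor-alone structure; default is the receptor
        chains extracted from ``complex_model``
    cparams, zparams : contact window and centrality calling parameters
    reference_zparams : centrality parameters for the reference structure,
        defaulting to ``zparams`` (same threshold on both sides)
    """
    cparams = cparams or ContactParams()
    zparams = zparams or CentralityParams()
    reference_zparams = reference_zparams or zparams
    receptor_chains, partner_chains = set(receptor_chains), set(partner_chains)

    if reference_model is None:
        reference_model = extract_chain_set(complex_model, receptor_chains)

    complex_rin = build_rin(complex_model, cparams)
    complex_table = centrality_zscores(betweenness_centrality(complex_rin), zparams)
    reference_rin = build_rin(reference_model, cparams)
    reference_table = centrality_zscores(
        betweenness_centrality(reference_rin), reference_zparams
    )

    iface = interface_residues(
        complex_model, receptor_chains, partner_chains, cparams
    )
    central_cx = central_nodes(complex_table)
    central_ref_matchkeys = {_match_key(k) for k in central_nodes(reference_table)}
    reference_matchkeys = {_match_key(k) for k in reference_model.residues()}

    receptor_keys = [
        k for k in complex_model.residues() if k.chain_id in receptor_chains
    ]
    if not any(_match_key(k) in reference_matchkeys for k in receptor_keys):
        raise ResidueMatchError(
            "no receptor residue of the complex matches the reference model "
            "by (chain, seq_num, icode)"
        )

    rows = []
    for key in receptor_keys:
        mismatch = _match_key(key) not in reference_matchkeys
        row = {
            "interface": key in iface,
            "central_complex": key in central_cx,
            "central_reference": _match_key(key) in central_ref_matchkeys,
            "mismatch": mismatch,
        }
        row["candidate"] = (
            row["interface"]
            and row["central_complex"]
            and not row["central_reference"]
            and not mismatch
        )
        rows.append(row)
    frame = pd.DataFrame(rows, index=receptor_keys)

    provenance = {
        "complex_structure": complex_model.id,
        "reference_structure": reference_model.id,
        "receptor_chains": ",".join(sorted(receptor_chains)),
        "partner_chains": ",".join(sorted(partner_chains)),
        "d_min": cparams.d_min,
        "d_max": cparams.d_max,
        "include_sequence_neighbors": cparams.include_sequence_neighbors,
        "z_threshold": zparams.z_threshold,
        "reference_z_threshold": reference_zparams.z_threshold,
        "sd_mode": zparams.sd_mode,
    }
    return CandidateReport(
        frame=frame,
        provenance=provenance,
        complex_table=complex_table,
        reference_table=reference_table,
    )
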