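"""Sequence-level peptide design: zone scanning, mutants, controls, identity.

The CD44 variant-exon-3 region (42 residues) is scanned by cutting it into
contiguous zones of roughly equal length; each zone is a candidate mimetic
peptide.  The module also produces the standard companion constructs —
zone deletions, point mutants, composition-preserving scramble controls —
and pairwise global alignment / percent identity for comparing variant
exons (e.g. v3 vs v6).

Zone lengths: with ``n`` zones and remainder ``r = len mod n``, the extra
residue goes to the LAST ``r`` zones.  This C-terminal-loaded rule is the
unique "approximately 10 residues" split of the 42-mer that reproduces the
four published zones (10/10/11/11).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CD44V3_SEQUENCE",
    "AMINO_ACIDS",
    "PeptideZone",
    "POLARITY_PUBLISHED",
    "POLARITY_STANDARD",
    "split_zones",
    "residue_at",
    "delete_zone",
    "apply_point_mutation",
    "scramble_peptide",
    "global_align",
    "alignment_score",
    "percent_identity",
    "classify_polarity",
    "read_fasta",
    "write_zones_fasta",
]

#: CD44 variant exon 3 region, N→C; zone 4 (C-terminal, IDDDEDFISST) is the
#: TrkA-binding mimetic peptide.
CD44V3_SEQUENCE = "STSSNTISAGWEPNEENEDERDRHLSFSGSGIDDDEDFISST"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Polarity classification as published alongside the His112 hydrogen-bond
# argument: H, K, Q and G called polar; L and A nonpolar.  The conventional
# chemistry table differs on glycine (no polar side-chain atom).
_PUBLISHED_POLAR = frozenset("STCYNQDEKRHG")
_STANDARD_POLAR = frozenset("STCYNQDEKRH")

POLARITY_PUBLISHED: dict[str, str] = {
    aa: ("polar" if aa in _PUBLISHED_POLAR else "nonpolar") for aa in AMINO_ACIDS
}
POLARITY_STANDARD: dict[str, str] = {
    aa: ("polar" if aa in _STANDARD_POLAR else "nonpolar") for aa in AMINO_ACIDS
}


def _validate_sequence(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{what} contains non-amino-acid characters: {sorted(bad)}")


@dataclass(frozen=True)
class PeptideZone:
    """One contiguous zone of a parent sequence (1-based inclusive span)."""

    label: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.label}: span {self.start}..{self.end} does not match "
                f"length {len(self.sequence)}"
            )


def split_zones(seq: str, n_zones: int) -> list[PeptideZone]:
    """Tile ``seq`` into ``n_zones`` contiguous zones, lengths differing ≤ 1.

    The remainder is assigned to the C-terminal zones, so a 42-mer with
    n_zones=4 splits 10/10/11/11.
    """
    _validate_sequence(seq)
    if not (1 <= n_zones <= len(seq)):
        raise ValueError(f"need 1 ≤ n_zones ≤ {len(seq)}, got {n_zones}")
    base, rem = divmod(len(seq), n_zones)
    zones = []
    pos = 0
    for i in range(n_zones):
        length = base + (1 if i >= n_zones - rem else 0)
        zones.append(
            PeptideZone(
                label=f"zone {i + 1}",
                sequence=seq[pos : pos + length],
                start=pos + 1,
                end=pos + length,
            )
        )
        pos += length
    return zones


def residue_at(seq: str, pos: int) -> str:
    """1-based residue lookup (exon coordinates)."""
    if not (1 <= pos <= len(seq)):
        raise ValueError(f"position {pos} outside 1..{len(seq)}")
    return seq[pos - 1]


def delete_zone(seq: str, zones: Iterable[PeptideZone], label: str) -> str:
    """Parent sequence with one zone's span removed (deletion construct)."""
    for zone in zones:
        if zone.label == label:
            return seq[: zone.start - 1] + seq[zone.end :]
    raise KeyError(f"no zone labelled {label!r}")


def apply_point_mutation(seq: str, pos: int, wt: str, mut: str) -> str:
    """Single-residue substitution with wild-type verification (e.g. H112A)."""
    actual = residue_at(seq, pos)
    if actual != wt:
        raise ValueError(
            f"expected {wt} at position {pos} but sequence has {actual}"
        )
    _validate_sequence(mut, "mutant residue")
    return seq[: pos - 1] + mut + seq[pos:]


def scramble_peptide(seq: str, seed: int, max_retries: int = 100) -> str:
    """Composition-preserving seeded shuffle (negative-control peptide).

    For sequences with ≥ 2 distinct residues the output is guaranteed to
    differ from the input (bounded re-draws); homopolymers are returned
    unchanged.
    """
    if len(seq) < 1:
        raise ValueError("cannot scramble an empty sequence")
    if len(set(seq)) < 2:
        return seq
    rng = np.random.default_rng(seed)
    letters = list(seq)
    for _ in range(max_retries):
        perm = rng.permutation(len(letters))
        out = "".join(letters[i] for i in perm)
        if out != seq:
            return out
    raise RuntimeError(f"could not scramble {seq!r} in {max_retries} draws")


def _make_aligner(
    substitution: str, gap_open: float, gap_extend: float
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Needleman–Wunsch global alignment with affine gaps.

    Returns the two gapped rows of the optimal alignment (first reported
    alignment of the deterministic traceback).  Default scoring BLOSUM62,
    open 10, extend 1.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    _validate_sequence(a, "first sequence")
    _validate_sequence(b, "second sequence")
    aligner = _make_aligner(substitution, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def alignment_score(
    a: str,
    b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global alignment score under the same scoring as global_align."""
    aligner = _make_aligner(substitution, gap_open, gap_extend)
    return float(aligner.score(a, b))


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity % over aligned rows: identical columns / columns excluding gap–gap."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned rows differ in length: {len(aligned_a)} vs {len(aligned_b)}"
        )
    columns = 0
    identical = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            identical += 1
    if columns == 0:
        raise ValueError("alignment has no non-gap columns")
    return 100.0 * identical / columns


def classify_polarity(
    residue: str, table: Literal["published", "standard"] | dict = "standard"
) -> str:
    """Polar/nonpolar class of a 1-letter residue under the chosen table."""
    mapping: dict[str, str]
    if table == "published":
        mapping = POLARITY_PUBLISHED
    elif table == "standard":
        mapping = POLARITY_STANDARD
    else:
        mapping = table
    try:
        return mapping[residue]
    except KeyError:
        raise KeyError(f"unknown residue {residue!r}") from None


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id → sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_zones_fasta(
    zones: Iterable[PeptideZone], parent_id: str, path: str | Path
) -> None:
    """Write zones as FASTA with structured headers: parent, label, span."""
    records = [
        SeqRecord(
            Seq(z.sequence),
            id=f"{parent_id}|{z.label.replace(' ', '')}|{z.start}-{z.end}",
            description="",
        )
        for z in zones
    ]
    SeqIO.write(records, str(path), "fasta")
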