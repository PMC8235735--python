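"""Tryptic digestion, N-glycosylation sequon detection, and FASTA input.

Trypsin cleaves C-terminal to lysine or arginine except when the next
residue is proline — the standard specific rule.  N-glycosylation sites
are the sequon N-X-S/T with X != P.  For human haptoglobin (UniProt
P00738 numbering) this recovers exactly the four β-subunit sites
Asn184, Asn207, Asn211 and Asn241, split across three tryptic
glycopeptide backbones conventionally called GP1, GP2 and GP3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from Bio import SeqIO

from .masses import peptide_mass, validate_sequence


@dataclass
class PeptideBackbone:
    """A tryptic peptide with its glycosylation sequons and neutral mass.

    ``protein_start``/``protein_end`` are 1-based inclusive coordinates
    in the parent protein; ``sequon_positions`` are the 1-based protein
    positions of the sequon asparagines.
    """

    sequence: str
    protein_start: int
    protein_end: int
    missed_cleavages: int = 0
    sequon_positions: list[int] = field(default_factory=list)
    neutral_mass: float = 0.0
    group_label: str = ""

    @property
    def n_sequons(self) -> int:
        return len(self.sequon_positions)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.protein_end - self.protein_start + 1 != len(self.sequence):
            raise ValueError("protein coordinates inconsistent with sequence length")
        for p in self.sequon_positions:
            if not self.protein_start <= p <= self.protein_end:
                raise ValueError(f"sequon position {p} outside peptide coordinates")


def find_sequons(sequence: str) -> list[int]:
    """0-based indices i where sequence[i:i+3] matches N-X(!=P)-[S/T].

    The third residue must lie inside the sequence, so a trailing ``N``
    or ``N-X`` never counts.  Returns an empty list when no sequon is
    present.
    """
    validate_sequence(sequence)
    return [
        i
        for i in range(len(sequence) - 2)
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST"
    ]


def cleavage_sites(sequence: str) -> list[int]:
    """0-based cut positions (cut before index) for trypsin K/R, not before P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    max_missed_cleavages: int = 0,
    fixed_mods: Optional[Mapping[str, float]] = None,
) -> list[PeptideBackbone]:
    """Tryptic digest of a protein into peptide backbones.

    At 0 missed cleavages the peptides tile the protein without gaps;
    peptides with k missed cleavages are concatenations of k+1 adjacent
    fully-tryptic peptides.  Every peptide records the protein positions
    of its N-glycosylation sequons (a sequon is evaluated on the peptide
    sequence, so a sequon whose S/T falls beyond the peptide's C-terminus
    does not count for that peptide).
    """
    validate_sequence(protein_sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    bounds = [0] + cleavage_sites(protein_sequence) + [len(protein_sequence)]
    peptides: list[PeptideBackbone] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for mc in range(max_missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            seq = protein_sequence[start:end]
            peptides.append(
                PeptideBackbone(
                    sequence=seq,
                    protein_start=start + 1,
                    protein_end=end,
                    missed_cleavages=mc,
                    sequon_positions=[start + 1 + k for k in find_sequons(seq)],
                    neutral_mass=peptide_mass(seq, fixed_mods),
                )
            )
    return peptides


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a protein FASTA; returns (record id, uppercase sequence).

    If the file holds several records the first is used with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records found; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def packaged_haptoglobin_fasta() -> Path:
    """Path to the packaged haptoglobin precursor FASTA.

    The record is a synthetic stand-in whose β-subunit region (residues
    162–406, carrying all four glycosites with canonical P00738
    numbering) matches the published tryptic glycopeptides; the
    signal/α region is filler that preserves length, numbering and
    tryptic boundaries and contains no sequon.
    """
    ref = resources.files("glycomud.data") / "haptoglobin_p00738_synthetic.fasta"
    with resources.as_file(ref) as p:
        return Path(p)
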