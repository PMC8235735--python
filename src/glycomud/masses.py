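"""Monoisotopic mass arithmetic for peptides and glycan residues.

All masses in this package are neutral monoisotopic masses in daltons.
Peptide masses follow the usual convention: sum of amino-acid residue
masses plus one water, plus any fixed modification deltas.  Glycan
masses use *residue* (dehydrated) monosaccharide masses, because a
glycan condenses onto the peptide through glycosidic bonds and
contributes no extra water of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Optional

from pyteomics import mass as _ptmass

WATER: float = 18.010565
"""Monoisotopic mass of H2O (Da)."""

CARBAMIDOMETHYL: float = 57.02146
"""Mass delta of carbamidomethylation (iodoacetamide alkylation), Da."""

STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses of the 20 standard amino acids (Da).
AA_RESIDUE_MASS: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

#: Default fixed modifications: carbamidomethyl on cysteine, the standard
#: consequence of DTT reduction followed by iodoacetamide alkylation.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}


@dataclass(frozen=True)
class MonosaccharideMassTable:
    """Monoisotopic residue masses of the four monosaccharide classes.

    The defaults are the standard residue (dehydrated) masses used
    throughout serum N-glycomics; they reproduce published haptoglobin
    glycopeptide masses to three decimal places.
    """

    hex_mass: float = 162.05282
    hexnac_mass: float = 203.07937
    fuc_mass: float = 146.05791
    neuac_mass: float = 291.09542
    water_mass: float = WATER

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")


DEFAULT_MASS_TABLE = MonosaccharideMassTable()


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` naming the first non-standard residue, if any."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(
                f"non-standard residue {aa!r} at position {i + 1} in sequence"
            )


def peptide_mass(
    sequence: str, fixed_mods: Optional[Mapping[str, float]] = None
) -> float:
    """Neutral monoisotopic mass of a peptide.

    Parameters
    ----------
    sequence:
        Uppercase amino-acid string drawn from the 20 standard residues.
    fixed_mods:
        Mapping of residue letter to mass delta applied to *every*
        occurrence of that residue.  Defaults to carbamidomethyl-C
        (+57.02146 Da); pass ``{}`` for unmodified masses.
    """
    validate_sequence(sequence)
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    total = WATER
    for aa in sequence:
        total += AA_RESIDUE_MASS[aa]
        total += fixed_mods.get(aa, 0.0)
    return total


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: 1e6 * (obs - theo) / theo."""
    return 1e6 * (observed - theoretical) / theoretical
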