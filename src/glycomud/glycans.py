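"""N-glycan compositions, masses, biosynthetic classes, and CSV I/O.

A glycan is represented purely by its monosaccharide composition —
counts of hexose (Hex), N-acetylhexosamine (HexNAc), fucose (Fuc) and
N-acetylneuraminic acid (NeuAc) — never by topology.  Identification
downstream is by accurate mass alone, and equal compositions imply
equal masses, so composition is the natural unit.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .masses import DEFAULT_MASS_TABLE, MonosaccharideMassTable


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Integer monosaccharide counts. Equality/order ignore the label."""

    hex: int
    hexnac: int
    fuc: int = 0
    neuac: int = 0
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.fuc, self.neuac)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )

    @property
    def is_empty(self) -> bool:
        return self.as_tuple() == (0, 0, 0, 0)

    def short_name(self) -> str:
        """Compact composition string, zero counts omitted, e.g. ``Hex4HexNAc3NeuAc1``."""
        parts = []
        for name, count in zip(("Hex", "HexNAc", "Fuc", "NeuAc"), self.as_tuple()):
            if count:
                parts.append(f"{name}{count}")
        return "".join(parts) or "unglycosylated"

    @classmethod
    def from_short_name(cls, text: str) -> "GlycanComposition":
        """Parse a compact composition string produced by :meth:`short_name`."""
        if text == "unglycosylated":
            return cls(0, 0, 0, 0)
        counts = {"Hex": 0, "HexNAc": 0, "Fuc": 0, "NeuAc": 0}
        pos = 0
        for m in re.finditer(r"(HexNAc|Hex|Fuc|NeuAc)(\d+)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse glycan composition {text!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse glycan composition {text!r}")
        return cls(counts["Hex"], counts["HexNAc"], counts["Fuc"], counts["NeuAc"])


class GlycanClass(enum.Enum):
    """The five biosynthetic N-glycan classes used for group comparisons."""

    HM = "HM"          # high mannose
    CH = "C/H"         # complex/hybrid, undecorated
    CH_F = "C/H-F"     # complex/hybrid, fucosylated
    CH_S = "C/H-S"     # complex/hybrid, sialylated
    CH_FS = "C/H-FS"   # complex/hybrid, fucosylated and sialylated


def classify_glycan(comp: GlycanComposition) -> GlycanClass:
    """Assign a composition to one of the five biosynthetic classes.

    High mannose means exactly two HexNAc (the chitobiose core), five to
    nine hexoses (Man5–Man9) and no decoration.  Everything else is
    complex/hybrid, subdivided by the presence of fucose and/or sialic
    acid.  The rule is total: every valid composition gets exactly one
    class.
    """
    if comp.hexnac == 2 and 5 <= comp.hex <= 9 and comp.fuc == 0 and comp.neuac == 0:
        return GlycanClass.HM
    if comp.fuc > 0 and comp.neuac > 0:
        return GlycanClass.CH_FS
    if comp.fuc > 0:
        return GlycanClass.CH_F
    if comp.neuac > 0:
        return GlycanClass.CH_S
    return GlycanClass.CH


def glycan_mass(
    comp: GlycanComposition, table: MonosaccharideMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Monoisotopic residue mass contributed by a glycan composition (Da).

    Residue masses are used (no terminal water): the glycan condenses
    onto the peptide, so its mass adds linearly in the counts.
    """
    return (
        comp.hex * table.hex_mass
        + comp.hexnac * table.hexnac_mass
        + comp.fuc * table.fuc_mass
        + comp.neuac * table.neuac_mass
    )


GLYCAN_CSV_COLUMNS = ["label", "hex", "hexnac", "fuc", "neuac"]


def read_glycan_csv(path: str | Path) -> list[GlycanComposition]:
    """Read a glycan list CSV with header ``label,hex,hexnac,fuc,neuac``."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(GLYCAN_CSV_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: glycan CSV must have columns {','.join(GLYCAN_CSV_COLUMNS)}"
            )
        out = []
        for row in reader:
            out.append(
                GlycanComposition(
                    int(row["hex"]),
                    int(row["hexnac"]),
                    int(row["fuc"]),
                    int(row["neuac"]),
                    label=row["label"] or None,
                )
            )
    if not out:
        raise ValueError(f"{path}: glycan CSV contains no rows")
    return out


def write_glycan_csv(glycans: Iterable[GlycanComposition], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GLYCAN_CSV_COLUMNS)
        for g in glycans:
            writer.writerow([g.label or g.short_name(), g.hex, g.hexnac, g.fuc, g.neuac])


def default_glycans() -> list[GlycanComposition]:
    """The packaged default 41-composition serum N-glycan panel.

    A representative panel for a mature serum glycoprotein (synthetic
    stand-in, see the packaged CSV): the Man5–Man9 high-mannose series,
    undecorated, fucosylated, sialylated and fucosylated-sialylated
    complex/hybrid glycans, dominated in typical profiles by the
    bi-antennary di-sialylated composition Hex5HexNAc4NeuAc2.
    """
    ref = resources.files("glycomud.data") / "default_nglycans_synthetic.csv"
    with resources.as_file(ref) as p:
        return read_glycan_csv(p)


def check_distinct(glycans: Sequence[GlycanComposition]) -> None:
    """Raise if any two glycans share a composition (would inflate counts)."""
    seen: dict[tuple[int, int, int, int], GlycanComposition] = {}
    for g in glycans:
        key = g.as_tuple()
        if key in seen:
            raise ValueError(f"duplicate glycan composition in list: {g.short_name()}")
        seen[key] = g
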