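"""In silico glycopeptide library construction.

For each sequon-bearing tryptic backbone, glycoforms are enumerated by
attaching at most one glycan per sequon with at least one site
occupied.  Because identification downstream is by accurate mass alone,
site identity is not distinguished: a two-site backbone yields all
unordered pairs with repetition plus all single-occupancy forms (for a
41-glycan list: C(41,2) + 41 pairs + 41 singles = 902 glycoforms), and
glycoforms whose *total* composition coincides are merged into a single
library entry, with every contributing site assignment retained for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .digest import PeptideBackbone, digest, read_fasta
from .glycans import (
    GlycanComposition,
    check_distinct,
    glycan_mass,
    read_glycan_csv,
)
from .masses import DEFAULT_MASS_TABLE, MonosaccharideMassTable


@dataclass
class Glycoform:
    """A pre-deduplication glycoform: a backbone plus one site assignment."""

    backbone: PeptideBackbone
    assignment: tuple[GlycanComposition, ...]

    @property
    def total_composition(self) -> GlycanComposition:
        total = GlycanComposition(0, 0, 0, 0)
        for g in self.assignment:
            total = total + g
        return total


@dataclass
class GlycopeptideEntry:
    """One library record: backbone + total glycan composition + mass.

    ``site_assignments`` lists every multiset of glycans consistent with
    the total composition (sorted, deterministic); ``occupied_sites`` is
    the occupancy of the largest consistent assignment.
    """

    backbone: PeptideBackbone
    occupied_sites: int
    total_composition: GlycanComposition
    site_assignments: list[tuple[GlycanComposition, ...]]
    theoretical_mass: float
    group_label: str

    @property
    def key(self) -> str:
        """Stable identifier, e.g. ``GP1:Hex4HexNAc3NeuAc1``."""
        return f"{self.group_label}:{self.total_composition.short_name()}"


@dataclass
class GlycopeptideLibrary:
    entries: list[GlycopeptideEntry]
    glycan_list: list[GlycanComposition]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group_label, None)
        return list(seen)

    def entries_for_group(self, group: str) -> list[GlycopeptideEntry]:
        return [e for e in self.entries if e.group_label == group]

    def masses(self) -> list[float]:
        return [e.theoretical_mass for e in self.entries]

    def by_key(self) -> dict[str, GlycopeptideEntry]:
        return {e.key: e for e in self.entries}


def enumerate_glycoforms(
    backbone: PeptideBackbone,
    glycans: Sequence[GlycanComposition],
    pairs_only: bool = False,
) -> list[Glycoform]:
    """All glycoforms of one backbone, before deduplication.

    One glycan per sequon, at least one sequon occupied, site order not
    distinguished: for n sequons this is all multisets of the glycan
    list of size 1..n (or exactly n when ``pairs_only`` is set, for the
    convention in which partial occupancy is excluded).
    """
    if not glycans:
        raise ValueError("glycan list is empty")
    check_distinct(glycans)
    if backbone.n_sequons < 1:
        raise ValueError("backbone has no glycosylation sequon")
    sizes = (
        [backbone.n_sequons]
        if pairs_only
        else range(1, backbone.n_sequons + 1)
    )
    out: list[Glycoform] = []
    for size in sizes:
        for combo in combinations_with_replacement(sorted(glycans), size):
            out.append(Glycoform(backbone, combo))
    return out


def deduplicate_by_total_composition(
    glycoforms: Sequence[Glycoform],
    mass_table: MonosaccharideMassTable = DEFAULT_MASS_TABLE,
) -> list[GlycopeptideEntry]:
    """Merge glycoforms of one backbone that share a total composition.

    Equal totals imply equal masses and are indistinguishable by
    accurate mass, so they form a single entry; all contributing site
    assignments are kept for reporting.
    """
    if not glycoforms:
        return []
    backbone = glycoforms[0].backbone
    for gf in glycoforms:
        if gf.backbone is not backbone and gf.backbone != backbone:
            raise ValueError("all glycoforms must share one backbone")
    grouped: dict[tuple[int, int, int, int], list[tuple[GlycanComposition, ...]]] = {}
    for gf in glycoforms:
        grouped.setdefault(gf.total_composition.as_tuple(), []).append(gf.assignment)
    entries = []
    for total_tuple in sorted(grouped):
        total = GlycanComposition(*total_tuple)
        assignments = sorted(grouped[total_tuple], key=lambda a: (len(a), a))
        entries.append(
            GlycopeptideEntry(
                backbone=backbone,
                occupied_sites=max(len(a) for a in assignments),
                total_composition=total,
                site_assignments=assignments,
                theoretical_mass=backbone.neutral_mass
                + glycan_mass(total, mass_table),
                group_label=backbone.group_label,
            )
        )
    return entries


def build_library(
    protein: str | Path | tuple[str, str],
    glycans: str | Path | Sequence[GlycanComposition],
    max_missed_cleavages: int = 0,
    fixed_mods: Optional[Mapping[str, float]] = None,
    mass_table: MonosaccharideMassTable = DEFAULT_MASS_TABLE,
    pairs_only: bool = False,
) -> GlycopeptideLibrary:
    """Build the full in silico glycopeptide library for one protein.

    ``protein`` is a FASTA path or an ``(id, sequence)`` tuple;
    ``glycans`` a CSV path or a list of compositions.  Sequon-bearing
    tryptic backbones are labelled GP1, GP2, ... in protein order
    (for haptoglobin this reproduces the conventional GP1/GP2/GP3
    covering Asn184; Asn207+Asn211; Asn241).  Entries are sorted by
    (group label, theoretical mass).
    """
    if isinstance(protein, (str, Path)) :
        protein_id, sequence = read_fasta(protein)
    else:
        protein_id, sequence = protein
    if isinstance(glycans, (str, Path)):
        glycan_list = read_glycan_csv(glycans)
    else:
        glycan_list = list(glycans)
    check_distinct(glycan_list)

    backbones = [
        b
        for b in digest(sequence, max_missed_cleavages, fixed_mods)
        if b.n_sequons > 0
    ]
    # one group per distinct sequon-bearing fully-tryptic region, in protein order
    backbones.sort(key=lambda b: (b.protein_start, b.missed_cleavages))
    for i, b in enumerate(backbones, start=1):
        b.group_label = f"GP{i}"

    if not backbones:
        raise ValueError("no glycosites found: no tryptic peptide carries a sequon")

    entries: list[GlycopeptideEntry] = []
    for b in backbones:
        entries.extend(
            deduplicate_by_total_composition(
                enumerate_glycoforms(b, glycan_list, pairs_only=pairs_only),
                mass_table,
            )
        )
    entries.sort(key=lambda e: (e.group_label, e.theoretical_mass))
    return GlycopeptideLibrary(
        entries=entries,
        glycan_list=glycan_list,
        provenance={
            "protein_id": protein_id,
            "max_missed_cleavages": max_missed_cleavages,
            "n_glycans": len(glycan_list),
            "pairs_only": pairs_only,
            "mass_table": {
                "hex": mass_table.hex_mass,
                "hexnac": mass_table.hexnac_mass,
                "fuc": mass_table.fuc_mass,
                "neuac": mass_table.neuac_mass,
            },
        },
    )


LIBRARY_TSV_COLUMNS = [
    "group",
    "peptide",
    "protein_start",
    "protein_end",
    "missed_cleavages",
    "sequon_positions",
    "occupied_sites",
    "hex",
    "hexnac",
    "fuc",
    "neuac",
    "theoretical_mass",
    "assignments",
]


def _format_assignment(assignment: tuple[GlycanComposition, ...]) -> str:
    return "+".join(g.short_name() for g in assignment)


def write_library_tsv(library: GlycopeptideLibrary, path: str | Path) -> None:
    """Write the library as a headered TSV (masses printed to 5 dp)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(LIBRARY_TSV_COLUMNS) + "\n")
        for e in library.entries:
            b = e.backbone
            fh.write(
                "\t".join(
                    [
                        e.group_label,
                        b.sequence,
                        str(b.protein_start),
                        str(b.protein_end),
                        str(b.missed_cleavages),
                        ";".join(map(str, b.sequon_positions)),
                        str(e.occupied_sites),
                        str(e.total_composition.hex),
                        str(e.total_composition.hexnac),
                        str(e.total_composition.fuc),
                        str(e.total_composition.neuac),
                        f"{e.theoretical_mass:.5f}",
                        ";".join(_format_assignment(a) for a in e.site_assignments),
                    ]
                )
                + "\n"
            )


def read_library_tsv(
    path: str | Path,
    fixed_mods: Optional[Mapping[str, float]] = None,
    mass_table: MonosaccharideMassTable = DEFAULT_MASS_TABLE,
) -> GlycopeptideLibrary:
    """Read a library TSV back; masses are recomputed, so the round trip
    through :func:`write_library_tsv` is lossless."""
    from .masses import peptide_mass

    path = Path(path)
    entries: list[GlycopeptideEntry] = []
    glycans: dict[tuple[int, int, int, int], GlycanComposition] = {}
    backbones: dict[tuple[str, int], PeptideBackbone] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LIBRARY_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected library TSV header")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            bkey = (f["peptide"], int(f["protein_start"]))
            if bkey not in backbones:
                backbones[bkey] = PeptideBackbone(
                    sequence=f["peptide"],
                    protein_start=int(f["protein_start"]),
                    protein_end=int(f["protein_end"]),
                    missed_cleavages=int(f["missed_cleavages"]),
                    sequon_positions=[
                        int(x) for x in f["sequon_positions"].split(";") if x
                    ],
                    neutral_mass=peptide_mass(f["peptide"], fixed_mods),
                    group_label=f["group"],
                )
            b = backbones[bkey]
            total = GlycanComposition(
                int(f["hex"]), int(f["hexnac"]), int(f["fuc"]), int(f["neuac"])
            )
            assignments = [
                tuple(
                    GlycanComposition.from_short_name(part)
                    for part in a.split("+")
                )
                for a in f["assignments"].split(";")
                if a
            ]
            for a in assignments:
                for g in a:
                    glycans.setdefault(g.as_tuple(), g)
            written = float(f["theoretical_mass"])
            mass = b.neutral_mass + glycan_mass(total, mass_table)
            if abs(mass - written) > 1e-3:
                raise ValueError(
                    f"{path}: stored mass {written} inconsistent with "
                    f"recomputed {mass:.5f} for {f['group']} {total.short_name()}"
                )
            entries.append(
                GlycopeptideEntry(
                    backbone=b,
                    occupied_sites=int(f["occupied_sites"]),
                    total_composition=total,
                    site_assignments=assignments,
                    theoretical_mass=mass,
                    group_label=f["group"],
                )
            )
    return GlycopeptideLibrary(
        entries=entries,
        glycan_list=sorted(glycans.values()),
        provenance={"source": str(path)},
    )
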