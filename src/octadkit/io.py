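"""Data model and I/O for octad genotype tables.

*Schizosaccharomyces japonicus* packs eight ascospores per ascus: each of
the four meiotic products undergoes one post-meiotic mitosis, so spores
come in four genotypically identical "sister" pairs.  This module defines
the in-memory containers for such crosses — markers, cross definitions,
spore records, octads and octad tables — together with TSV readers and
writers and structural/Mendelian validation.

File formats
------------
Octad tables are UTF-8 tab-separated files with one spore per row and a
mandatory header::

    ascus  spore  viable  [linear]  [imputed]  <marker 1>  <marker 2> ...

``spore`` is the positional label A–H along the ascus (file order within
an ascus must follow A→H), ``viable`` is 0/1, and each marker column
carries an allele symbol from the cross definition or the unknown token
``?`` (permitted only on non-viable rows).  ``linear`` (per ascus,
defaults to 1) records whether the physical spore order is meaningful;
``imputed`` (per spore, defaults to 0) records deduction provenance for
dead-spore genotypes.

Cross definitions are YAML files listing parent names and, per marker:
name, chromosome, arm, distance from the centromere in centimorgans, and
the allele symbol carried by each parent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "UNKNOWN",
    "POSITIONS",
    "OctadError",
    "StructureError",
    "AlleleError",
    "MendelianError",
    "SisterMatchError",
    "MarkerDef",
    "CrossDef",
    "SporeRecord",
    "Octad",
    "OctadTable",
    "read_cross_config",
    "write_cross_config",
    "read_octad_table",
    "write_octad_table",
    "segregation_counts",
    "is_four_four",
]

#: Token for an unscorable genotype entry (dead spores only).
UNKNOWN = "?"

#: Ordered spore position labels along a linear ascus.
POSITIONS = ("A", "B", "C", "D", "E", "F", "G", "H")

Genotype = tuple[str, ...]


class OctadError(ValueError):
    """Base class for octad data errors."""


class StructureError(OctadError):
    """File or table violates the octad structure (8 spores, positions A–H)."""


class AlleleError(OctadError):
    """A genotype cell carries a symbol outside the cross's allele set."""


class MendelianError(OctadError):
    """Segregation violates Mendelian expectation (4:4 / 2:2) or genotypes
    are incomplete where complete ones are required."""


class SisterMatchError(OctadError):
    """The spores of an ascus cannot be completed into four identical
    sister pairs."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MarkerDef:
    """A scored locus.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"mat1"`` or ``"ade6"``.
    chromosome : str
        Chromosome identifier.
    arm : {"left", "right"}
        Chromosome arm carrying the locus.
    position_cM : float
        Genetic distance from the centromere in centimorgans (>= 0).
    allele_p1, allele_p2 : str
        Allele symbols carried by parent 1 and parent 2; must differ.
    """

    name: str
    chromosome: str
    arm: str
    position_cM: float
    allele_p1: str
    allele_p2: str

    def __post_init__(self) -> None:
        if self.arm not in ("left", "right"):
            raise ValueError(f"marker {self.name}: arm must be 'left' or 'right'")
        if self.position_cM < 0:
            raise ValueError(f"marker {self.name}: position_cM must be >= 0")
        if self.allele_p1 == self.allele_p2:
            raise ValueError(f"marker {self.name}: parental alleles must differ")
        if UNKNOWN in (self.allele_p1, self.allele_p2):
            raise ValueError(f"marker {self.name}: {UNKNOWN!r} is reserved")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_p1, self.allele_p2)


@dataclass(frozen=True)
class CrossDef:
    """A two-parent cross: ordered marker list plus parent names."""

    markers: tuple[MarkerDef, ...]
    parent1_name: str = "parent1"
    parent2_name: str = "parent2"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("a cross needs at least one marker")
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique within a cross")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def index(self, marker: Union[str, MarkerDef]) -> int:
        name = marker.name if isinstance(marker, MarkerDef) else marker
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} is not part of this cross") from None

    def marker(self, name: str) -> MarkerDef:
        return self.markers[self.index(name)]

    def parental_genotypes(self) -> tuple[Genotype, Genotype]:
        """Genotype vectors of parent 1 and parent 2, in marker order."""
        p1 = tuple(m.allele_p1 for m in self.markers)
        p2 = tuple(m.allele_p2 for m in self.markers)
        return p1, p2


@dataclass(frozen=True)
class SporeRecord:
    """One spore of an octad: position label, viability, genotype.

    ``genotype`` is aligned to the cross's marker order; entries may be the
    unknown token only when ``viable`` is False.  ``imputed`` marks a
    genotype deduced by sister matching rather than scored directly.
    """

    ascus_id: str
    position: str
    viable: bool
    genotype: Genotype
    imputed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", tuple(self.genotype))
        if self.position not in POSITIONS:
            raise StructureError(
                f"ascus {self.ascus_id}: spore position {self.position!r} "
                f"is not one of A-H"
            )
        if self.viable and UNKNOWN in self.genotype:
            raise AlleleError(
                f"ascus {self.ascus_id} spore {self.position}: viable spores "
                f"must be fully genotyped"
            )


@dataclass(frozen=True)
class Octad:
    """An 8-spored ascus in positional order A→H.

    ``linear`` is True when the physical spore order is meaningful (the
    ascus was dissected in order); adjacency statistics only apply then.
    """

    ascus_id: str
    spores: tuple[SporeRecord, ...]
    linear: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "spores", tuple(self.spores))
        if len(self.spores) != 8:
            raise StructureError(f"ascus {self.ascus_id}: {len(self.spores)} spores")
        positions = [s.position for s in self.spores]
        if sorted(positions) != sorted(POSITIONS):
            dup = [p for p, c in Counter(positions).items() if c > 1]
            missing = sorted(set(POSITIONS) - set(positions))
            raise StructureError(
                f"ascus {self.ascus_id}: duplicate positions {dup} / "
                f"missing positions {missing}"
            )
        if positions != sorted(positions):
            # keep canonical A→H order internally
            object.__setattr__(
                self, "spores", tuple(sorted(self.spores, key=lambda s: s.position))
            )

    def spore(self, position: str) -> SporeRecord:
        for s in self.spores:
            if s.position == position:
                return s
        raise KeyError(position)

    @property
    def dead_positions(self) -> tuple[str, ...]:
        return tuple(s.position for s in self.spores if not s.viable)


@dataclass(frozen=True)
class OctadTable:
    """A validated collection of octads sharing one cross definition."""

    cross: CrossDef
    octads: tuple[Octad, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "octads", tuple(self.octads))
        ids = [o.ascus_id for o in self.octads]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise StructureError(f"duplicate ascus ids: {dup}")
        n_markers = len(self.cross.markers)
        for octad in self.octads:
            for spore in octad.spores:
                if len(spore.genotype) != n_markers:
                    raise StructureError(
                        f"ascus {octad.ascus_id} spore {spore.position}: "
                        f"{len(spore.genotype)} genotype entries for "
                        f"{n_markers} markers"
                    )
                for marker, allele in zip(self.cross.markers, spore.genotype):
                    if allele == UNKNOWN:
                        continue  # SporeRecord already restricts ? to dead spores
                    if allele not in marker.alleles:
                        raise AlleleError(
                            f"ascus {octad.ascus_id} spore {spore.position} "
                            f"marker {marker.name}: allele {allele!r} not in "
                            f"{marker.alleles}"
                        )

    def __len__(self) -> int:
        return len(self.octads)

    def octad(self, ascus_id: str) -> Octad:
        for o in self.octads:
            if o.ascus_id == ascus_id:
                return o
        raise KeyError(ascus_id)


# ---------------------------------------------------------------------------
# cross config I/O


def read_cross_config(path: Union[str, Path]) -> CrossDef:
    """Read a YAML cross definition (parents + marker list)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "markers" not in doc:
        raise StructureError(f"{path}: cross config must map 'markers' to a list")
    markers = tuple(
        MarkerDef(
            name=str(m["name"]),
            chromosome=str(m["chromosome"]),
            arm=str(m["arm"]),
            position_cM=float(m["position_cM"]),
            allele_p1=str(m["allele_p1"]),
            allele_p2=str(m["allele_p2"]),
        )
        for m in doc["markers"]
    )
    return CrossDef(
        markers=markers,
        parent1_name=str(doc.get("parent1", "parent1")),
        parent2_name=str(doc.get("parent2", "parent2")),
        notes=str(doc.get("notes", "")),
    )


def write_cross_config(cross: CrossDef, path: Union[str, Path]) -> None:
    doc = {
        "parent1": cross.parent1_name,
        "parent2": cross.parent2_name,
        "notes": cross.notes,
        "markers": [
            {
                "name": m.name,
                "chromosome": m.chromosome,
                "arm": m.arm,
                "position_cM": m.position_cM,
                "allele_p1": m.allele_p1,
                "allele_p2": m.allele_p2,
            }
            for m in cross.markers
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# octad table I/O

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_flag(value: str, what: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise StructureError(f"{where}: cannot parse {what} value {value!r}")


def read_octad_table(path: Union[str, Path], cross: CrossDef) -> OctadTable:
    """Read a one-spore-per-row TSV into a validated :class:`OctadTable`.

    The header must name ``ascus``, ``spore``, ``viable`` and one column per
    marker of *cross* (``linear`` and ``imputed`` are optional).  Row order
    within an ascus defines positional order and must follow labels A→H.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["ascus", "spore", "viable", *cross.marker_names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: missing columns {missing}")
    has_linear = "linear" in df.columns
    has_imputed = "imputed" in df.columns

    octads: list[Octad] = []
    for ascus_id, group in df.groupby("ascus", sort=False):
        spores = []
        linear = True
        for _, row in group.iterrows():
            where = f"ascus {ascus_id} spore {row['spore']}"
            genotype = tuple(str(row[m]).strip() for m in cross.marker_names)
            spores.append(
                SporeRecord(
                    ascus_id=str(ascus_id),
                    position=str(row["spore"]).strip(),
                    viable=_parse_flag(row["viable"], "viable", where),
                    genotype=genotype,
                    imputed=(
                        _parse_flag(row["imputed"], "imputed", where)
                        if has_imputed
                        else False
                    ),
                )
            )
            if has_linear:
                linear = _parse_flag(row["linear"], "linear", where)
        octads.append(Octad(ascus_id=str(ascus_id), spores=tuple(spores), linear=linear))
    return OctadTable(cross=cross, octads=tuple(octads))


def write_octad_table(table: OctadTable, path: Union[str, Path]) -> None:
    """Write *table* as TSV; inverse of :func:`read_octad_table`.

    ``linear`` and ``imputed`` columns are always emitted so that imputation
    provenance survives a round trip.
    """
    rows = []
    for octad in table.octads:
        for spore in octad.spores:
            row = {
                "ascus": octad.ascus_id,
                "spore": spore.position,
                "viable": int(spore.viable),
                "linear": int(octad.linear),
                "imputed": int(spore.imputed),
            }
            row.update(dict(zip(table.cross.marker_names, spore.genotype)))
            rows.append(row)
    columns = ["ascus", "spore", "viable", "linear", "imputed", *table.cross.marker_names]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segregation


def segregation_counts(
    octad: Octad, marker: Union[str, MarkerDef], cross: CrossDef
) -> dict[str, int]:
    """Allele counts over the 8 spores of *octad* at *marker*.

    A fully viable (or imputed) octad of a well-behaved cross segregates
    4:4.  Raises :class:`MendelianError` if any spore is still ungenotyped —
    impute dead spores via sister matching first.
    """
    idx = cross.index(marker)
    counts: Counter[str] = Counter()
    for spore in octad.spores:
        allele = spore.genotype[idx]
        if allele == UNKNOWN:
            raise MendelianError(
                f"ascus {octad.ascus_id}: unknown genotype at spore "
                f"{spore.position}; impute dead spores (match_sisters) before "
                f"counting segregation"
            )
        counts[allele] += 1
    return dict(counts)


def is_four_four(counts: Mapping[str, int]) -> bool:
    """True when the counts are exactly 4:4 over two alleles."""
    return sorted(counts.values()) == [4, 4]
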