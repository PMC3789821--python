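"""Shared vs species-specific peptide classification and inclusion lists.

A tryptic peptide of one ortholog is *shared* when the identical sequence
occurs among the tryptic peptides (same digestion parameters) of the other
species' ortholog, and *species-specific* (diagnostic) otherwise. Detecting
a species-specific peptide in a pulldown attributes that complex member to
that parental species; shared peptides are uninformative.

Isoleucine and leucine are isobaric and indistinguishable on the instrument
class modelled here, so by default peptides differing only by I↔L are
treated as shared (``il_equivalent=True``); the strict sequence-identity
behaviour is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .digestion import (
    DEFAULT_MASS_TABLE,
    MassTable,
    Peptide,
    PeptideMap,
    digest,
    peptide_mass,
    precursor_mz,
)
from .proteomes import OrthologGroup

Classification = Literal["shared", "specific"]


@dataclass(frozen=True)
class DigestParams:
    """Digestion and catalog bounds used for classification.

    Length bounds (default 6–30 residues) delimit the typically detectable
    tryptic peptide range and apply to catalog entries; the comparison
    universe for sharedness is the full digest of the partner ortholog.
    """

    max_missed: int = 1
    min_len: int = 6
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(
                f"inverted length bounds: min_len {self.min_len} > max_len "
                f"{self.max_len}"
            )
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


def collapse_il(sequence: str) -> str:
    """Collapse isobaric isoleucine onto leucine for comparison."""
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class ClassifiedPeptide:
    """A peptide with its shared/specific verdict."""

    peptide: Peptide
    classification: Classification
    specific_to: Optional[str]
    il_collapsed: bool

    def __post_init__(self) -> None:
        if (self.classification == "specific") != (self.specific_to is not None):
            raise ValueError(
                "specific_to must be set exactly when classification is 'specific'"
            )


@dataclass(frozen=True)
class DiagnosticCatalog:
    """Every catalog peptide of an ortholog group, classified per species."""

    group: OrthologGroup
    entries: Mapping[str, tuple[ClassifiedPeptide, ...]]
    digest_params: DigestParams
    il_equivalence: bool

    def _key(self, sequence: str) -> str:
        return collapse_il(sequence) if self.il_equivalence else sequence

    @property
    def shared_sequences(self) -> frozenset[str]:
        return frozenset(
            self._key(e.peptide.sequence)
            for entries in self.entries.values()
            for e in entries
            if e.classification == "shared"
        )

    def specific_sequences(self, species: str) -> frozenset[str]:
        return frozenset(
            self._key(e.peptide.sequence)
            for e in self.entries.get(species, ())
            if e.classification == "specific"
        )

    def lookup(self, sequence: str) -> tuple[str, Optional[str]]:
        """Classify an observed sequence: shared / specific(species) / unmatched."""
        key = self._key(sequence)
        if key in self.shared_sequences:
            return "shared", None
        for species in self.group.species:
            if key in self.specific_sequences(species):
                return "specific", species
        return "unmatched", None


@dataclass(frozen=True)
class InclusionEntry:
    """One precursor m/z targeting a species-specific peptide."""

    sequence: str
    species: str
    charge: int
    mz: float
    selected: bool = True


def _digest_universe(
    group: OrthologGroup, species: str, params: DigestParams, il_equivalent: bool
) -> frozenset[str]:
    """All digest-peptide sequences of one species' ortholog, as comparison keys."""
    record = group.records[species]
    peptides = digest(record.sequence, max_missed=params.max_missed,
                      parent_id=record.protein_id)
    if il_equivalent:
        return frozenset(collapse_il(p.sequence) for p in peptides)
    return frozenset(p.sequence for p in peptides)


def classify_peptide(
    peptide: Peptide,
    group: OrthologGroup,
    own_species: str,
    il_equivalent: bool = True,
    digest_params: DigestParams = DigestParams(),
) -> ClassifiedPeptide:
    """Classify one digest peptide of ``own_species`` as shared or specific.

    The peptide is shared iff its (optionally I/L-collapsed) sequence occurs
    among the digest peptides, at the same digestion parameters, of any
    other species' ortholog in the group.

    Raises
    ------
    ValueError
        If the peptide is not derivable from the claimed parent record.
    """
    record = group.records[own_species]
    if record.sequence[peptide.start - 1:peptide.end] != peptide.sequence:
        raise ValueError(
            f"peptide {peptide.sequence!r} at [{peptide.start}, {peptide.end}] "
            f"is not a substring of {record.protein_id!r} at those coordinates"
        )
    key = collapse_il(peptide.sequence) if il_equivalent else peptide.sequence
    for other in group.other_species(own_species):
        if key in _digest_universe(group, other, digest_params, il_equivalent):
            return ClassifiedPeptide(peptide, "shared", None, il_equivalent)
    return ClassifiedPeptide(peptide, "specific", own_species, il_equivalent)


def build_catalog(
    group: OrthologGroup,
    max_missed: int = 1,
    min_len: int = 6,
    max_len: int = 30,
    il_equivalent: bool = True,
) -> DiagnosticCatalog:
    """Catalog every digest peptide of every species within the length bounds.

    Entries are deterministically ordered by (species, start, length).
    """
    params = DigestParams(max_missed=max_missed, min_len=min_len, max_len=max_len)
    universes = {
        species: _digest_universe(group, species, params, il_equivalent)
        for species in group.species
    }
    entries: dict[str, tuple[ClassifiedPeptide, ...]] = {}
    for species in group.species:
        record = group.records[species]
        other_union: set[str] = set()
        for other in group.other_species(species):
            other_union |= universes[other]
        classified = []
        peptides = digest(record.sequence, max_missed=params.max_missed,
                          parent_id=record.protein_id)
        for peptide in sorted(peptides, key=lambda p: (p.start, len(p))):
            if not (params.min_len <= len(peptide) <= params.max_len):
                continue
            key = collapse_il(peptide.sequence) if il_equivalent else peptide.sequence
            if key in other_union:
                classified.append(
                    ClassifiedPeptide(peptide, "shared", None, il_equivalent))
            else:
                classified.append(
                    ClassifiedPeptide(peptide, "specific", species, il_equivalent))
        entries[species] = tuple(classified)
    return DiagnosticCatalog(group=group, entries=entries, digest_params=params,
                             il_equivalence=il_equivalent)


def build_inclusion_list(
    catalog: DiagnosticCatalog,
    target_species: str,
    charges: Sequence[int] = (2, 3),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[InclusionEntry]:
    """Targeted-acquisition inclusion list for one species' diagnostic peptides.

    One entry per (specific peptide, charge), sorted by m/z. An empty list
    (no diagnostic peptides, as for identical orthologs) is returned with a
    warning rather than an error — a targeted search that can find nothing
    is still a well-posed, if futile, experiment.
    """
    if target_species not in catalog.entries:
        raise KeyError(f"species {target_species!r} not in catalog "
                       f"({sorted(catalog.entries)})")
    if any(c < 1 for c in charges):
        raise ValueError(f"charges must be >= 1, got {list(charges)}")
    specific = [e.peptide for e in catalog.entries[target_species]
                if e.classification == "specific"]
    # miscleaved peptides can repeat a sequence; target each sequence once
    sequences = sorted({p.sequence for p in specific})
    entries = []
    for sequence in sequences:
        mass = peptide_mass(sequence, "monoisotopic", table)
        for charge in charges:
            entries.append(InclusionEntry(
                sequence=sequence, species=target_species, charge=charge,
                mz=precursor_mz(mass, charge, table),
            ))
    if not entries:
        warnings.warn(
            f"no species-specific peptides for {target_species!r} in "
            f"{catalog.group.complex_name}/{catalog.group.member_name}; "
            "inclusion list is empty",
            stacklevel=2,
        )
    return sorted(entries, key=lambda e: e.mz)


def render_peptide_map(
    pmap: PeptideMap,
    catalog: DiagnosticCatalog,
    detections: Optional[Iterable[tuple[str, str]]] = None,
) -> str:
    """Text rendering of a peptide map with class tags and replicate asterisks.

    ``detections`` is a set of ``(peptide_sequence, replicate_id)`` pairs;
    a peptide detected in at least two distinct biological replicates is
    marked with an asterisk, following the peptide-map figure convention.
    """
    species = None
    for sp, record in catalog.group.records.items():
        if record.protein_id == pmap.parent_id:
            species = sp
            break
    if species is None:
        raise ValueError(
            f"peptide map parent {pmap.parent_id!r} does not match any record "
            f"in catalog group {catalog.group.complex_name}/"
            f"{catalog.group.member_name}"
        )
    by_sequence: dict[str, set[str]] = {}
    for sequence, replicate in detections or ():
        by_sequence.setdefault(sequence, set()).add(replicate)

    class_of = {
        e.peptide.sequence: e for e in catalog.entries[species]
    }
    lines = [f"# {pmap.parent_id} ({species}) "
             f"{catalog.group.complex_name}/{catalog.group.member_name}"]
    for peptide in pmap.tryptic_peptides:
        entry = class_of.get(peptide.sequence)
        if entry is None:
            tag = "UNCATALOGUED"  # outside the length bounds
        elif entry.classification == "shared":
            tag = "SHARED"
        else:
            tag = f"SPECIFIC({entry.specific_to})"
        replicates = by_sequence.get(peptide.sequence, set())
        flags = ""
        if replicates:
            flags = f" detected[{','.join(sorted(replicates))}]"
            if len(replicates) >= 2:
                flags += " *"
        lines.append(
            f"{peptide.t_label}\t{peptide.start}-{peptide.end}\t"
            f"{peptide.sequence}\t{tag}{flags}"
        )
    return "\n".join(lines)


def catalog_to_frame(catalog: DiagnosticCatalog,
                     table: MassTable = DEFAULT_MASS_TABLE) -> pd.DataFrame:
    """Flatten a catalog to the tabular form used by the CLI and on disk."""
    rows = []
    for species in catalog.group.species:
        for entry in catalog.entries[species]:
            rows.append({
                "complex": catalog.group.complex_name,
                "member": catalog.group.member_name,
                "species": species,
                "t_label": entry.peptide.t_label,
                "sequence": entry.peptide.sequence,
                "class": entry.classification,
                "specific_to": entry.specific_to or "",
                "mono_mass": round(
                    peptide_mass(entry.peptide.sequence, "monoisotopic", table), 5
                ),
            })
    return pd.DataFrame(
        rows, columns=["complex", "member", "species", "t_label", "sequence",
                       "class", "specific_to", "mono_mass"])
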