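"""Parental proteomes and ortholog groups.

In an interspecies hybrid both parental proteomes are co-resident: for each
member of a protein complex there is one ortholog per parental species.
This module loads protein sequences (FASTA) together with their species
identity and assembles them into :class:`OrthologGroup` objects, the unit on
which diagnostic-peptide classification operates.

Species identity travels with each sequence through a key=value header
convention (``>id species=Scer gene=TRP2``); a whole-file species label may
be supplied instead for plain proteome files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids. Ambiguity codes (B, J, O, U, X, Z) are
#: rejected: diagnostic classification depends on exact residue identity.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

MEMBERSHIP_COLUMNS = ["complex", "member", "species", "protein_id"]


class ProteomeError(ValueError):
    """Malformed proteome input (bad residue, missing species, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species identity.

    Parameters
    ----------
    protein_id
        Identifier unique within a species.
    species
        Parental species label (e.g. ``Scer``, ``Suva``).
    gene_name
        Gene name, may be empty.
    sequence
        Amino-acid sequence over the 20 standard one-letter codes,
        upper case. The initiator methionine is kept as given.
    """

    protein_id: str
    species: str
    gene_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ProteomeError("protein_id must be non-empty")
        if not self.species:
            raise ProteomeError(
                f"record {self.protein_id!r}: species label must be non-empty"
            )
        validate_sequence(self.sequence, self.protein_id)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, record_id: str = "<unnamed>") -> None:
    """Reject empty sequences and residues outside the 20-letter alphabet."""
    if not sequence:
        raise ProteomeError(f"record {record_id!r}: empty sequence")
    for pos, residue in enumerate(sequence, start=1):
        if residue not in _AA_SET:
            raise ProteomeError(
                f"record {record_id!r}: illegal residue {residue!r} at position "
                f"{pos}; allowed alphabet is the 20 standard amino acids "
                f"({AMINO_ACIDS})"
            )


@dataclass(frozen=True)
class OrthologGroup:
    """The orthologs of one complex member across parental species."""

    member_name: str
    complex_name: str
    records: Mapping[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ProteomeError(
                f"ortholog group {self.complex_name}/{self.member_name}: "
                f"needs at least 2 species, got {sorted(self.records)}"
            )
        for species, record in self.records.items():
            if record.species != species:
                raise ProteomeError(
                    f"ortholog group {self.complex_name}/{self.member_name}: "
                    f"record {record.protein_id!r} has species "
                    f"{record.species!r}, keyed under {species!r}"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.records)

    def other_species(self, own: str) -> list[str]:
        if own not in self.records:
            raise KeyError(
                f"species {own!r} not in group "
                f"{self.complex_name}/{self.member_name} ({self.species})"
            )
        return [s for s in self.species if s != own]


def _parse_header(description: str, default_species: str | None) -> tuple[str, str, str]:
    """Parse ``id key=value ...`` FASTA headers into (id, species, gene)."""
    tokens = description.split()
    if not tokens:
        raise ProteomeError("empty FASTA header")
    record_id = tokens[0]
    fields = {}
    for token in tokens[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            fields[key] = value
    species = fields.get("species", default_species)
    if not species:
        raise ProteomeError(
            f"record {record_id!r}: header lacks a 'species=' token and no "
            "file-wide species label was supplied"
        )
    return record_id, species, fields.get("gene", "")


def read_fasta(path: str | Path, species: str | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, in file order.

    Parameters
    ----------
    path
        FASTA file with headers ``>id species=X gene=Y`` (key=value tokens
        after the identifier).
    species
        Optional file-wide species label, used when a header carries no
        ``species=`` token (a header token still takes precedence).

    Raises
    ------
    ProteomeError
        Missing/empty file, header without species, illegal residue,
        or duplicate ``(protein_id, species)`` pair.
    """
    path = Path(path)
    if not path.exists():
        raise ProteomeError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[tuple[str, str]] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        record_id, record_species, gene = _parse_header(
            seq_record.description, species
        )
        sequence = "".join(str(seq_record.seq).split()).upper()
        record = ProteinRecord(record_id, record_species, gene, sequence)
        key = (record.protein_id, record.species)
        if key in seen:
            raise ProteomeError(
                f"duplicate record: protein_id {record.protein_id!r} for "
                f"species {record.species!r} appears more than once"
            )
        seen.add(key)
        records.append(record)
    if not records:
        raise ProteomeError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with the ``id species=X gene=Y`` header convention."""
    seq_records = []
    for record in records:
        description = f"species={record.species}"
        if record.gene_name:
            description += f" gene={record.gene_name}"
        seq_records.append(
            SeqRecord(Seq(record.sequence), id=record.protein_id,
                      description=description)
        )
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def read_membership(path: str | Path) -> pd.DataFrame:
    """Read a complex-membership table (TSV: complex, member, species, protein_id)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MEMBERSHIP_COLUMNS if c not in table.columns]
    if missing:
        raise ProteomeError(
            f"membership table {path} lacks columns {missing}; expected "
            f"{MEMBERSHIP_COLUMNS}"
        )
    return table[MEMBERSHIP_COLUMNS]


def build_ortholog_groups(
    records: Sequence[ProteinRecord],
    membership: pd.DataFrame,
) -> list[OrthologGroup]:
    """Assemble ortholog groups from loaded records and a membership table.

    Each membership row ``(complex, member, species, protein_id)`` binds one
    loaded record into the group for that complex member. Groups are returned
    sorted by complex name then member name, independent of input order.

    Raises
    ------
    ProteomeError
        Unresolved protein_id, a member covered by fewer than 2 species, or
        two records claimed for one (member, species).
    """
    index: dict[tuple[str, str], ProteinRecord] = {}
    for record in records:
        index[(record.species, record.protein_id)] = record

    grouped: dict[tuple[str, str], dict[str, ProteinRecord]] = {}
    for row in membership.itertuples(index=False):
        complex_name = str(row.complex)
        member = str(row.member)
        species = str(row.species)
        protein_id = str(row.protein_id)
        record = index.get((species, protein_id))
        if record is None:
            raise ProteomeError(
                f"membership row ({complex_name}, {member}, {species}, "
                f"{protein_id}): no loaded record with that species and id"
            )
        key = (complex_name, member)
        members = grouped.setdefault(key, {})
        if species in members:
            raise ProteomeError(
                f"member {complex_name}/{member}: two records claimed for "
                f"species {species!r}"
            )
        members[species] = record

    groups = []
    for (complex_name, member), members in sorted(grouped.items()):
        groups.append(
            OrthologGroup(member_name=member, complex_name=complex_name,
                          records=dict(sorted(members.items())))
        )
    return groups
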