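"""Evidence filtering and per-complex chimericity calls.

The experimental logic: a complex member is TAP-tagged in one parental
species (the bait) and pulled down from hybrid cells. If the complex
assembles chimericly, orthologs from the *other* parental species
co-purify and their species-specific peptides appear in the identification
tables; if assembly is uni-specific only bait-species (and shared)
peptides appear. A mixed-lysate control — parental cultures grown
separately and combined only at lysis — flags chimeric interactions that
form in vitro rather than in vivo.

Filtering follows the probability-threshold scheme of the identification
pipeline the tables come from: peptides above 50% probability, proteins
above 95% with at least two identified peptides, and a contiguous run of
at least four b or y ions per peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .diagnostics import DiagnosticCatalog

Condition = Literal["hybrid", "mixed_lysate_control"]
Status = Literal["chimeric", "uni_specific", "inconclusive"]

PSM_COLUMNS = ["peptide", "complex", "member", "pep_prob", "prot_prob",
               "contig_ions", "replicate", "condition"]


@dataclass(frozen=True)
class FilterThresholds:
    """Identification acceptance thresholds.

    Probability thresholds are strict (">"), mirroring the "greater than"
    acceptance wording of the upstream validation tools; the contiguous-ion
    and peptide-count thresholds are inclusive ("at least").
    """

    min_peptide_probability: float = 0.50
    min_protein_probability: float = 0.95
    min_peptides_per_protein: int = 2
    min_contiguous_ions: int = 4

    def __post_init__(self) -> None:
        for name, p in (("min_peptide_probability", self.min_peptide_probability),
                        ("min_protein_probability", self.min_protein_probability)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.min_peptides_per_protein < 1 or self.min_contiguous_ions < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass(frozen=True)
class PSMRecord:
    """One observed peptide identification with its quality metadata."""

    peptide_sequence: str
    complex_name: str
    member_name: str
    peptide_probability: float
    protein_probability: float
    contiguous_ion_count: int
    replicate_id: str
    condition: Condition = "hybrid"

    def __post_init__(self) -> None:
        if self.condition not in ("hybrid", "mixed_lysate_control"):
            raise ValueError(
                f"condition must be 'hybrid' or 'mixed_lysate_control', "
                f"got {self.condition!r}"
            )


@dataclass(frozen=True)
class PresenceRule:
    """When does specific-peptide evidence establish a species as present?

    A species is present for a member when it has at least
    ``min_distinct_peptides`` distinct accepted specific peptides, OR at
    least one specific peptide accepted in ``min_replicates`` distinct
    biological replicates (the replicated-detection asterisk convention of
    the peptide-map figures).
    """

    min_distinct_peptides: int = 2
    min_replicates: int = 2


@dataclass
class MemberEvidence:
    """Accepted specific/shared peptide evidence for one complex member."""

    member_name: str
    specific_peptides: dict[str, set[str]] = field(default_factory=dict)
    replicates_with_specific: dict[str, set[str]] = field(default_factory=dict)
    shared_peptides: set[str] = field(default_factory=set)
    unmatched_peptides: set[str] = field(default_factory=set)
    presence: dict[str, bool] = field(default_factory=dict)

    def present_species(self) -> list[str]:
        return sorted(s for s, p in self.presence.items() if p)


@dataclass(frozen=True)
class ComplexCall:
    """Per-complex verdict with its supporting evidence summary."""

    complex_name: str
    bait_member: str
    bait_species: str
    status: Status
    artefact_flag: bool
    evidence: tuple[MemberEvidence, ...]
    control_evidence: tuple[MemberEvidence, ...]

    def summary(self) -> dict:
        """JSON-ready summary of the call."""
        def member_dict(ev: MemberEvidence) -> dict:
            return {
                "member": ev.member_name,
                "specific_peptides": {
                    sp: sorted(seqs) for sp, seqs in ev.specific_peptides.items()
                },
                "replicates_with_specific": {
                    sp: sorted(reps)
                    for sp, reps in ev.replicates_with_specific.items()
                },
                "shared_peptide_count": len(ev.shared_peptides),
                "unmatched_peptide_count": len(ev.unmatched_peptides),
                "present": ev.present_species(),
            }
        return {
            "complex": self.complex_name,
            "bait_member": self.bait_member,
            "bait_species": self.bait_species,
            "status": self.status,
            "artefact_flag": self.artefact_flag,
            "members": [member_dict(ev) for ev in self.evidence],
            "control_members": [member_dict(ev) for ev in self.control_evidence],
        }


def filter_psms(
    psms: Sequence[PSMRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[PSMRecord]:
    """Apply the peptide- and protein-level acceptance filters.

    Stage 1 keeps records with peptide probability strictly above the
    peptide threshold, protein probability strictly above the protein
    threshold, and a contiguous b/y ion run of at least the ion threshold.
    Stage 2 drops every record of a (complex, member) whose accepted
    distinct-peptide count falls below the per-protein minimum.
    """
    stage1 = [
        p for p in psms
        if p.peptide_probability > thresholds.min_peptide_probability
        and p.protein_probability > thresholds.min_protein_probability
        and p.contiguous_ion_count >= thresholds.min_contiguous_ions
    ]
    distinct: dict[tuple[str, str], set[str]] = {}
    for p in stage1:
        distinct.setdefault((p.complex_name, p.member_name), set()).add(
            p.peptide_sequence)
    return [
        p for p in stage1
        if len(distinct[(p.complex_name, p.member_name)])
        >= thresholds.min_peptides_per_protein
    ]


def assign_species(
    psm: PSMRecord, catalog: DiagnosticCatalog
) -> tuple[str, Optional[str]]:
    """Look an observed peptide up in the member's diagnostic catalog.

    Returns ``("shared", None)``, ``("specific", species)`` or
    ``("unmatched", None)`` for sequences absent from the catalog
    (contaminants or out-of-bounds peptides; these are logged by the
    aggregation step, not errors).
    """
    if psm.member_name != catalog.group.member_name:
        raise KeyError(
            f"PSM member {psm.member_name!r} does not match catalog member "
            f"{catalog.group.member_name!r}"
        )
    return catalog.lookup(psm.peptide_sequence)


def aggregate_member_evidence(
    psms: Iterable[PSMRecord],
    catalog: DiagnosticCatalog,
    presence_rule: PresenceRule = PresenceRule(),
) -> MemberEvidence:
    """Aggregate accepted PSMs of one member into per-species evidence.

    All records must come from a single condition (the caller splits hybrid
    and control runs). Shared peptides are tallied but never contribute to
    species presence — they are consistent with either parent.
    """
    member = catalog.group.member_name
    evidence = MemberEvidence(member_name=member)
    for species in catalog.group.species:
        evidence.specific_peptides[species] = set()
        evidence.replicates_with_specific[species] = set()
    conditions = set()
    for psm in psms:
        if psm.member_name != member:
            continue
        conditions.add(psm.condition)
        outcome, species = assign_species(psm, catalog)
        if outcome == "specific":
            evidence.specific_peptides[species].add(psm.peptide_sequence)
            evidence.replicates_with_specific[species].add(psm.replicate_id)
        elif outcome == "shared":
            evidence.shared_peptides.add(psm.peptide_sequence)
        else:
            evidence.unmatched_peptides.add(psm.peptide_sequence)
    if len(conditions) > 1:
        raise ValueError(
            f"member {member!r}: PSMs mix conditions {sorted(conditions)}; "
            "aggregate hybrid and control runs separately"
        )
    for species in catalog.group.species:
        evidence.presence[species] = (
            len(evidence.specific_peptides[species])
            >= presence_rule.min_distinct_peptides
            or len(evidence.replicates_with_specific[species])
            >= presence_rule.min_replicates
        )
    return evidence


def call_complex(
    evidences: Sequence[MemberEvidence],
    bait: tuple[str, str],
    control_psms: Sequence[PSMRecord],
    catalogs: Mapping[str, DiagnosticCatalog],
    thresholds: FilterThresholds = FilterThresholds(),
    presence_rule: PresenceRule = PresenceRule(),
) -> ComplexCall:
    """Call one complex chimeric, uni-specific, or inconclusive.

    ``evidences`` is the aggregated hybrid-run evidence per member; ``bait``
    is the (member, species) carrying the tag. Control handling is
    per-(member, species) subtraction: a non-bait-species presence observed
    in the hybrid run counts toward chimericity only if the same (member,
    species) is absent from the mixed-lysate control; presences seen in the
    control alone raise ``artefact_flag``.

    status:
      * ``chimeric`` — at least one non-bait member shows a non-bait-species
        presence that survives control subtraction (bait must pass filters);
      * ``uni_specific`` — bait-species members present and no
        non-bait-species presence anywhere in the hybrid evidence;
      * ``inconclusive`` — otherwise (bait fails filters, or every
        non-bait-species presence also appears in the control).
    """
    bait_member, bait_species = bait
    by_member = {ev.member_name: ev for ev in evidences}
    if bait_member not in by_member:
        raise KeyError(f"bait member {bait_member!r} absent from evidence")
    complex_name = next(iter(catalogs.values())).group.complex_name

    accepted_control = filter_psms(list(control_psms), thresholds)
    control_evidence = []
    for member, catalog in sorted(catalogs.items()):
        member_psms = [p for p in accepted_control if p.member_name == member]
        control_evidence.append(
            aggregate_member_evidence(member_psms, catalog, presence_rule))
    control_present = {
        (ev.member_name, species)
        for ev in control_evidence
        for species in ev.present_species()
    }

    hybrid_nonbait = {
        (ev.member_name, species)
        for ev in evidences
        for species in ev.present_species()
        if species != bait_species and ev.member_name != bait_member
    }
    surviving = hybrid_nonbait - control_present
    control_nonbait = {
        (member, species) for member, species in control_present
        if species != bait_species and member != bait_member
    }
    artefact_flag = bool(control_nonbait)

    bait_ok = by_member[bait_member].presence.get(bait_species, False)
    any_bait_species_presence = any(
        ev.presence.get(bait_species, False) for ev in evidences
    )
    any_nonbait_presence = any(
        species != bait_species
        for ev in evidences
        for species in ev.present_species()
    )

    if bait_ok and surviving:
        status: Status = "chimeric"
    elif any_bait_species_presence and not any_nonbait_presence:
        status = "uni_specific"
    else:
        status = "inconclusive"

    return ComplexCall(
        complex_name=complex_name,
        bait_member=bait_member,
        bait_species=bait_species,
        status=status,
        artefact_flag=artefact_flag,
        evidence=tuple(evidences),
        control_evidence=tuple(control_evidence),
    )


def call_from_psms(
    psms: Sequence[PSMRecord],
    catalogs: Mapping[str, DiagnosticCatalog],
    bait: tuple[str, str],
    thresholds: FilterThresholds = FilterThresholds(),
    presence_rule: PresenceRule = PresenceRule(),
) -> ComplexCall:
    """End-to-end convenience: filter, split by condition, aggregate, call."""
    hybrid = [p for p in psms if p.condition == "hybrid"]
    control = [p for p in psms if p.condition == "mixed_lysate_control"]
    accepted = filter_psms(hybrid, thresholds)
    evidences = []
    for member, catalog in sorted(catalogs.items()):
        member_psms = [p for p in accepted if p.member_name == member]
        evidences.append(
            aggregate_member_evidence(member_psms, catalog, presence_rule))
    return call_complex(evidences, bait, control, catalogs,
                        thresholds, presence_rule)


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read a PSM table (TSV with the documented column set)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        records.append(PSMRecord(
            peptide_sequence=row.peptide,
            complex_name=row.complex,
            member_name=row.member,
            peptide_probability=float(row.pep_prob),
            protein_probability=float(row.prot_prob),
            contiguous_ion_count=int(row.contig_ions),
            replicate_id=str(row.replicate),
            condition=row.condition,
        ))
    return records


def psms_to_frame(psms: Sequence[PSMRecord]) -> pd.DataFrame:
    """Flatten PSM records to the on-disk TSV layout."""
    rows = [{
        "peptide": p.peptide_sequence,
        "complex": p.complex_name,
        "member": p.member_name,
        "pep_prob": p.peptide_probability,
        "prot_prob": p.protein_probability,
        "contig_ions": p.contiguous_ion_count,
        "replicate": p.replicate_id,
        "condition": p.condition,
    } for p in psms]
    return pd.DataFrame(rows, columns=PSM_COLUMNS)
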