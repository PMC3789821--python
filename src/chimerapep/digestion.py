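"""In-silico tryptic digestion, peptide masses and fragment-ion series.

Trypsin cleaves C-terminal to lysine and arginine (K-X, R-X) but not when
the next residue is proline (K-P, R-P). Digestion allows a configurable
number of missed cleavages (default one per site, the setting used for the
peptide maps this package emulates). Zero-miscleavage peptides are labelled
T1…Tn from the N-terminus; miscleaved peptides are labelled by the span of
T-indices they cover (e.g. ``T42–T43``).

Masses are theoretical: monoisotopic by default, average as an option.
Fragment ions are restricted to the b and y series, the series used when
spectra are checked for a contiguous ion run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Literal, Mapping

from .proteomes import ProteinRecord, validate_sequence

# Monoisotopic / average residue (not free amino acid) masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
})
AVERAGE_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
})

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.0153
PROTON_MASS = 1.007276

#: Carbamidomethylation of cysteine, the common fixed alkylation; not
#: applied by default since the protocol modelled here does not state it.
CARBAMIDOMETHYL = 57.021464

MassMode = Literal["monoisotopic", "average"]


@dataclass(frozen=True)
class MassTable:
    """Residue masses plus the water/proton constants used throughout.

    ``fixed_modifications`` maps a residue letter to an added mass in Da
    (e.g. ``{"C": CARBAMIDOMETHYL}``), applied in both mass modes.
    """

    monoisotopic: Mapping[str, float] = field(
        default_factory=lambda: MONOISOTOPIC_RESIDUE_MASSES)
    average: Mapping[str, float] = field(
        default_factory=lambda: AVERAGE_RESIDUE_MASSES)
    water_monoisotopic: float = WATER_MONOISOTOPIC
    water_average: float = WATER_AVERAGE
    proton: float = PROTON_MASS
    fixed_modifications: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("monoisotopic", self.monoisotopic),
                            ("average", self.average)):
            missing = [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa not in table]
            if missing:
                raise ValueError(f"{name} mass table lacks residues {missing}")
            bad = [aa for aa, m in table.items() if m <= 0]
            if bad:
                raise ValueError(f"{name} mass table has non-positive masses for {bad}")

    def residue_mass(self, residue: str, mode: MassMode = "monoisotopic") -> float:
        table = self.monoisotopic if mode == "monoisotopic" else self.average
        try:
            base = table[residue]
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None
        return base + self.fixed_modifications.get(residue, 0.0)

    def water(self, mode: MassMode = "monoisotopic") -> float:
        return self.water_monoisotopic if mode == "monoisotopic" else self.water_average


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with 1-based inclusive coordinates on its parent."""

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    t_label: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates [{self.start}, {self.end}] for peptide "
                f"{self.sequence!r}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.sequence!r} length {len(self.sequence)} does "
                f"not match span [{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion at a given charge."""

    series: Literal["b", "y"]
    index: int
    charge: int
    mz: float


@dataclass(frozen=True)
class PeptideMap:
    """The ordered tryptic map of one protein.

    ``tryptic_peptides`` are the zero-miscleavage fragments T1…Tn whose
    concatenation reconstructs the parent; ``extended_peptides`` carry
    1..max missed cleavages and span consecutive T-indices.
    """

    parent_id: str
    tryptic_peptides: tuple[Peptide, ...]
    extended_peptides: tuple[Peptide, ...]

    @property
    def all_peptides(self) -> tuple[Peptide, ...]:
        return tuple(sorted(self.tryptic_peptides + self.extended_peptides,
                            key=lambda p: (p.start, len(p))))


def cleavage_sites(sequence: str) -> list[int]:
    """Tryptic cleavage positions: cut occurs *after* each listed 1-based position.

    Position p is a site iff residue p is K or R, p is not the last residue,
    and residue p+1 is not proline.
    """
    validate_sequence(sequence)
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def _t_label(first_segment: int, last_segment: int) -> str:
    if first_segment == last_segment:
        return f"T{first_segment}"
    return f"T{first_segment}–T{last_segment}"  # en dash, map convention


def _fragment_spans(boundaries: list[int], max_missed: int) -> Iterator[tuple[int, int, int, int]]:
    """Yield (segment_index, start0, end0, missed) spans over a boundary list.

    ``boundaries`` is [0, site1, ..., len]; a fragment runs between two
    boundaries and spans ``missed`` internal cleavage sites. Ordered by
    start then length. ``segment_index`` is the 1-based T-index of the
    fragment's first zero-miscleavage segment.
    """
    n = len(boundaries) - 1  # number of zero-miscleavage segments
    for i in range(n):
        for j in range(i, min(i + max_missed, n - 1) + 1):
            yield i + 1, boundaries[i], boundaries[j + 1], j - i


def digest(sequence: str, max_missed: int = 1, parent_id: str = "") -> list[Peptide]:
    """Tryptic digest allowing up to ``max_missed`` missed cleavages.

    Returns every fragment delimited by the sequence ends and the cleavage
    sites whose spanned internal-site count is at most ``max_missed``,
    ordered by start position then length. T-labels follow the peptide-map
    convention (zero-miscleavage segments are T1…Tn N-to-C).
    """
    if max_missed < 0:
        raise ValueError(f"max_missed must be >= 0, got {max_missed}")
    sites = cleavage_sites(sequence)
    boundaries = [0, *sites, len(sequence)]
    peptides = []
    for first_seg, start0, end0, missed in _fragment_spans(boundaries, max_missed):
        peptides.append(Peptide(
            parent_id=parent_id,
            start=start0 + 1,
            end=end0,
            sequence=sequence[start0:end0],
            missed_cleavages=missed,
            t_label=_t_label(first_seg, first_seg + missed),
        ))
    return peptides


def peptide_mass(
    sequence: str,
    mode: MassMode = "monoisotopic",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral peptide mass: sum of residue masses (+ fixed mods) + water."""
    validate_sequence(sequence)
    return sum(table.residue_mass(aa, mode) for aa in sequence) + table.water(mode)


def precursor_mz(mass: float, charge: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Precursor m/z of a neutral mass at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * table.proton) / charge


def fragment_series(
    sequence: str,
    charge: int = 1,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[FragmentIon]:
    """b- and y-series fragment ions b1..b(n-1), y1..y(n-1) at one charge.

    ``b_i`` covers the first i residues, ``y_i`` the last i (plus water);
    full-length ions are not emitted.
    """
    validate_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("fragment series require peptide length >= 2")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    n = len(sequence)
    residue = [table.residue_mass(aa, "monoisotopic") for aa in sequence]
    ions = []
    running = 0.0
    for i in range(1, n):
        running += residue[i - 1]
        ions.append(FragmentIon("b", i, charge,
                                (running + charge * table.proton) / charge))
    running = table.water("monoisotopic")
    y_ions = []
    for i in range(1, n):
        running += residue[n - i]
        y_ions.append(FragmentIon("y", i, charge,
                                  (running + charge * table.proton) / charge))
    return ions + y_ions


def build_peptide_map(
    protein: ProteinRecord | str,
    max_missed: int = 1,
    parent_id: str | None = None,
) -> PeptideMap:
    """T-indexed peptide map of a protein.

    Accepts a :class:`ProteinRecord` or a bare sequence (then ``parent_id``
    names the parent).
    """
    if isinstance(protein, ProteinRecord):
        sequence = protein.sequence
        pid = protein.protein_id
    else:
        sequence = protein
        pid = parent_id or ""
    peptides = digest(sequence, max_missed=max_missed, parent_id=pid)
    tryptic = tuple(p for p in peptides if p.missed_cleavages == 0)
    extended = tuple(p for p in peptides if p.missed_cleavages > 0)
    return PeptideMap(parent_id=pid, tryptic_peptides=tryptic,
                      extended_peptides=extended)
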