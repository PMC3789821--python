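"""Synthetic inputs: diverged ortholog proteomes, pulldown PSM tables and
competition counts.

Every stage of the pipeline can be exercised without external data:

* :func:`diverge_protein` / :func:`synth_complex` emulate pairs of ortholog
  proteomes at a controlled per-site divergence (a stand-in for the few
  percent of sites separating closely related sibling species);
* :func:`simulate_pulldown` emulates the peptide-identification tables of a
  tagged-bait pulldown under a known ground truth (chimeric vs
  uni-specific assembly), with stochastic peptide detection, parametric
  identification scores, contaminant noise and the mixed-lysate control
  condition;
* :func:`simulate_competition` draws flow-cytometry style counts under a
  known selection coefficient.

All generators are bit-reproducible under a fixed seed; the seed fans out
to independent per-replicate streams so that adding replicates does not
perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FilterThresholds, PresenceRule, PSMRecord, call_from_psms
from .diagnostics import DiagnosticCatalog, build_catalog
from .fitness import CompetitionObservation
from .proteomes import AMINO_ACIDS, OrthologGroup, ProteinRecord

Truth = Literal["chimeric", "uni_specific"]

_AA = np.array(list(AMINO_ACIDS))
_CLEAVAGE_SET = frozenset("KRP")


@dataclass(frozen=True)
class DivergenceConfig:
    """Per-site substitution model between a pair of ortholog sequences.

    With ``preserve_cleavage_pattern`` (default) K, R and P residues are
    never created or destroyed, so both orthologs share one digestion
    pattern and divergence moves only the peptide *sequences*; turning it
    off also lets tryptic boundaries drift.
    """

    substitution_rate: float = 0.05
    preserve_cleavage_pattern: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError(
                f"substitution_rate must be in [0, 1], got {self.substitution_rate}")


@dataclass(frozen=True)
class ScoreModel:
    """Parametric score distributions for simulated identifications.

    Peptide and protein probabilities are Beta-distributed; contiguous-ion
    counts uniform on an integer range. Defaults for true identifications
    sit mostly above the 0.5/0.95 acceptance thresholds, contaminant
    defaults mostly below.
    """

    pep_prob_alpha: float = 9.0
    pep_prob_beta: float = 1.0
    prot_prob_alpha: float = 60.0
    prot_prob_beta: float = 1.0
    contig_ions_min: int = 4
    contig_ions_max: int = 12


CONTAMINANT_SCORES = ScoreModel(
    pep_prob_alpha=2.0, pep_prob_beta=4.0,
    prot_prob_alpha=2.0, prot_prob_beta=8.0,
    contig_ions_min=1, contig_ions_max=6,
)


@dataclass(frozen=True)
class PulldownConfig:
    """One simulated pulldown experiment.

    ``truth`` is the ground-truth assembly mode; the bait (member, species)
    is the tagged protein. Each eligible catalog peptide is detected
    independently with probability ``detectability`` in each replicate.
    ``contaminant_rate`` is the expected number of contaminant PSMs per
    eligible peptide per replicate (Poisson). A ``control_condition`` run
    emulates the mixed-lysate control: lysates are combined only after
    growth, so only bait-species complexes are pulled down regardless of
    ``truth``, and records carry the control condition label.
    """

    truth: Truth = "chimeric"
    bait_member: str = ""
    bait_species: str = ""
    detectability: float = 0.9
    replicates: int = 3
    contaminant_rate: float = 0.0
    true_scores: ScoreModel = field(default_factory=ScoreModel)
    contaminant_scores: ScoreModel = field(default_factory=lambda: CONTAMINANT_SCORES)
    control_condition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detectability <= 1.0:
            raise ValueError(f"detectability must be in [0, 1], got {self.detectability}")
        if self.contaminant_rate < 0:
            raise ValueError("contaminant_rate must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.truth not in ("chimeric", "uni_specific"):
            raise ValueError(f"truth must be 'chimeric' or 'uni_specific', "
                             f"got {self.truth!r}")


@dataclass(frozen=True)
class CompetitionConfig:
    """One simulated competition assay under a known selection coefficient."""

    true_s: float = 0.0
    generations: float = 10.0
    initial_ratio: float = 4.0       # hybrid : reference at inoculation
    cells_per_timepoint: int = 50_000
    replicates: int = 3
    seed: int = 0
    strain_id: str = "hybrid"

    def __post_init__(self) -> None:
        if self.cells_per_timepoint < 1:
            raise ValueError("cells_per_timepoint must be >= 1")
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if self.initial_ratio <= 0:
            raise ValueError("initial_ratio must be > 0")


def _rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed)


def diverge_protein(sequence: str, config: DivergenceConfig) -> str:
    """Substitute each site independently at the configured rate.

    Replacements are uniform over eligible residues (excluding the original
    residue, and excluding K/R/P both as source and target when the
    cleavage pattern is preserved). Length is preserved; identical seeds
    give identical output.
    """
    rng = _rng(config.seed)
    residues = list(sequence)
    hits = rng.random(len(residues)) < config.substitution_rate
    for i in np.flatnonzero(hits):
        original = residues[i]
        if config.preserve_cleavage_pattern:
            if original in _CLEAVAGE_SET:
                continue
            pool = [aa for aa in AMINO_ACIDS
                    if aa != original and aa not in _CLEAVAGE_SET]
        else:
            pool = [aa for aa in AMINO_ACIDS if aa != original]
        residues[i] = pool[rng.integers(len(pool))]
    return "".join(residues)


def random_protein(length: int, rng: np.random.Generator) -> str:
    """A uniform-random sequence over the 20 standard residues."""
    return "".join(_AA[rng.integers(len(_AA), size=length)])


def synth_complex(
    members: int = 3,
    species: Sequence[str] = ("Scer", "Suva"),
    length_range: tuple[int, int] = (200, 600),
    divergence: DivergenceConfig = DivergenceConfig(),
    complex_name: str = "CPX1",
) -> list[OrthologGroup]:
    """Synthesise ortholog groups for one complex across parental species.

    The first species is the reference: each member gets a random base
    sequence of a length drawn from ``length_range``; every other species
    receives an independently diverged copy. Deterministic under the
    divergence config's seed.
    """
    if members < 1:
        raise ValueError("members must be >= 1")
    if len(set(species)) < 2:
        raise ValueError(f"need >= 2 distinct species, got {list(species)}")
    root = np.random.SeedSequence(divergence.seed)
    member_seeds = root.spawn(members)
    groups = []
    reference = species[0]
    for m, member_seed in enumerate(member_seeds, start=1):
        base_seed, *diverge_seeds = member_seed.spawn(len(species))
        rng = _rng(base_seed)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        base = random_protein(length, rng)
        member_name = f"M{m}"
        records = {
            reference: ProteinRecord(f"{member_name}_{reference}", reference,
                                     member_name, base)
        }
        for sp, sp_seed in zip(species[1:], diverge_seeds):
            derived_seed = int(sp_seed.generate_state(1)[0] % (2**31))
            diverged = diverge_protein(
                base, replace(divergence, seed=derived_seed))
            records[sp] = ProteinRecord(f"{member_name}_{sp}", sp,
                                        member_name, diverged)
        groups.append(OrthologGroup(member_name=member_name,
                                    complex_name=complex_name,
                                    records=dict(sorted(records.items()))))
    return groups


def _draw_scores(rng: np.random.Generator, model: ScoreModel) -> tuple[float, float, int]:
    pep = float(rng.beta(model.pep_prob_alpha, model.pep_prob_beta))
    prot = float(rng.beta(model.prot_prob_alpha, model.prot_prob_beta))
    contig = int(rng.integers(model.contig_ions_min, model.contig_ions_max + 1))
    return pep, prot, contig


def _contaminant_sequence(rng: np.random.Generator,
                          forbidden: frozenset[str]) -> str:
    while True:
        seq = random_protein(int(rng.integers(8, 16)), rng)
        if seq not in forbidden:
            return seq


def simulate_pulldown(
    groups: Sequence[OrthologGroup],
    catalogs: Mapping[str, DiagnosticCatalog],
    config: PulldownConfig,
) -> list[PSMRecord]:
    """Simulate the PSM table of one pulldown experiment.

    Eligibility encodes the ground truth: under a chimeric assembly every
    catalog peptide of every species is eligible; under a uni-specific
    assembly (or the mixed-lysate control run) only bait-species peptides
    are — which automatically includes the shared peptides, since those are
    sequence-identical between the parents and indistinguishable by the
    instrument. Contaminant PSMs carry random sequences absent from the
    catalog.
    """
    members = {g.member_name for g in groups}
    if config.bait_member not in members:
        raise KeyError(
            f"bait member {config.bait_member!r} not among complex members "
            f"{sorted(members)}")
    complex_name = groups[0].complex_name
    condition = "mixed_lysate_control" if config.control_condition else "hybrid"
    bait_only = config.control_condition or config.truth == "uni_specific"

    eligible: list[tuple[str, str]] = []  # (member, peptide sequence)
    forbidden: set[str] = set()
    for group in groups:
        catalog = catalogs[group.member_name]
        for species in group.species:
            for entry in catalog.entries[species]:
                forbidden.add(entry.peptide.sequence)
                if bait_only and species != config.bait_species:
                    continue
                eligible.append((group.member_name, entry.peptide.sequence))
    # miscleavage variants can duplicate (member, sequence); detect each once
    eligible = sorted(set(eligible))
    forbidden_set = frozenset(forbidden)

    root = np.random.SeedSequence(config.seed)
    psms: list[PSMRecord] = []
    for rep_index, rep_seed in enumerate(root.spawn(config.replicates), start=1):
        rng = _rng(rep_seed)
        replicate_id = f"R{rep_index}"
        detected = rng.random(len(eligible)) < config.detectability
        for keep, (member, sequence) in zip(detected, eligible):
            if not keep:
                continue
            pep, prot, contig = _draw_scores(rng, config.true_scores)
            psms.append(PSMRecord(
                peptide_sequence=sequence, complex_name=complex_name,
                member_name=member, peptide_probability=pep,
                protein_probability=prot, contiguous_ion_count=contig,
                replicate_id=replicate_id, condition=condition,
            ))
        n_contaminants = int(rng.poisson(config.contaminant_rate * len(eligible)))
        member_list = sorted(members)
        for _ in range(n_contaminants):
            member = member_list[int(rng.integers(len(member_list)))]
            pep, prot, contig = _draw_scores(rng, config.contaminant_scores)
            psms.append(PSMRecord(
                peptide_sequence=_contaminant_sequence(rng, forbidden_set),
                complex_name=complex_name, member_name=member,
                peptide_probability=pep, protein_probability=prot,
                contiguous_ion_count=contig, replicate_id=replicate_id,
                condition=condition,
            ))
    return psms


def simulate_competition(config: CompetitionConfig) -> list[CompetitionObservation]:
    """Draw competition counts under a known selection coefficient.

    The expected final hybrid:reference ratio is
    ``initial_ratio * exp(true_s * generations)``; at each timepoint the
    configured number of cells is sampled from the true proportions
    (binomial), so hybrid and reference counts sum to the sample size.
    """
    p0 = config.initial_ratio / (1.0 + config.initial_ratio)
    odds_f = config.initial_ratio * float(np.exp(config.true_s * config.generations))
    pf = odds_f / (1.0 + odds_f)
    n = config.cells_per_timepoint
    root = np.random.SeedSequence(config.seed)
    observations = []
    for rep_index, rep_seed in enumerate(root.spawn(config.replicates), start=1):
        rng = _rng(rep_seed)
        while True:  # redraw the vanishingly rare empty gate
            h0 = int(rng.binomial(n, p0))
            hf = int(rng.binomial(n, pf))
            if 0 < h0 < n and 0 < hf < n:
                break
        observations.append(CompetitionObservation(
            strain_id=config.strain_id, replicate_id=f"B{rep_index}",
            h0=h0, r0=n - h0, hf=hf, rf=n - hf,
            g0=0.0, gf=config.generations,
        ))
    return observations


def simulate_and_call(
    divergence: float,
    detectability: float,
    seed: int,
    truth: Truth = "chimeric",
    members: int = 3,
    species: Sequence[str] = ("Scer", "Suva"),
    length_range: tuple[int, int] = (200, 600),
    replicates: int = 3,
    contaminant_rate: float = 0.0,
    thresholds: FilterThresholds = FilterThresholds(),
    presence_rule: PresenceRule = PresenceRule(),
    max_missed: int = 1,
    il_equivalent: bool = True,
):
    """One closed-loop run: synthesise, digest, catalog, simulate, call.

    Returns the :class:`~chimerapep.calling.ComplexCall`. The bait is the
    first member tagged in the first (reference) species.
    """
    root = np.random.SeedSequence(seed)
    complex_seed, pulldown_seed = root.spawn(2)
    div_config = DivergenceConfig(
        substitution_rate=divergence,
        seed=int(complex_seed.generate_state(1)[0] % (2**31)),
    )
    groups = synth_complex(members=members, species=species,
                           length_range=length_range, divergence=div_config)
    catalogs = {
        g.member_name: build_catalog(g, max_missed=max_missed,
                                     il_equivalent=il_equivalent)
        for g in groups
    }
    config = PulldownConfig(
        truth=truth, bait_member=groups[0].member_name,
        bait_species=species[0], detectability=detectability,
        replicates=replicates, contaminant_rate=contaminant_rate,
        seed=int(pulldown_seed.generate_state(1)[0] % (2**31)),
    )
    psms = simulate_pulldown(groups, catalogs, config)
    bait = (config.bait_member, config.bait_species)
    return call_from_psms(psms, catalogs, bait, thresholds, presence_rule)


def detection_power(
    divergences: Sequence[float],
    detectabilities: Sequence[float],
    reps: int = 50,
    seed: int = 0,
    **scenario,
) -> pd.DataFrame:
    """Chimeric-call power over a divergence x detectability grid.

    For each grid cell, ``reps`` truly-chimeric pulldowns are simulated and
    the fraction called chimeric reported. Replicate seeds are shared
    across cells (coupled seeds), so comparisons along either axis are
    paired rather than confounded by Monte-Carlo noise.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(reps)]
    rows = []
    for divergence in divergences:
        for detectability in detectabilities:
            n_chimeric = 0
            for rep_seed in rep_seeds:
                call = simulate_and_call(
                    divergence=divergence, detectability=detectability,
                    seed=rep_seed, truth="chimeric", **scenario)
                n_chimeric += call.status == "chimeric"
            rows.append({
                "divergence": divergence,
                "detectability": detectability,
                "n_reps": reps,
                "power": n_chimeric / reps,
            })
    return pd.DataFrame(rows, columns=["divergence", "detectability",
                                       "n_reps", "power"])
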