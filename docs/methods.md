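# Methods

## The experimental logic being modelled

A hybrid cell between two sibling yeast species carries both parental
proteomes. For a protein complex with members M1…Mk, each member exists as
an ortholog pair (one per parent) differing at a small fraction of residues.
One member is affinity-tagged in one parental background (the *bait*); the
complex is purified and its peptides identified by LC-MS/MS against a
database containing both parents' proteins. Because shared peptides are
sequence-identical between the orthologs, only *species-specific* peptides
carry information about which parent contributed a subunit. The decision
problem is therefore: given a table of peptide identifications with quality
scores, did any non-bait member contribute diagnostic peptides of the
non-tagged species (chimeric assembly), or not (uni-specific), or is the
evidence insufficient (inconclusive)?

## Digestion model

Trypsin cleaves after K and R except before proline. We implement exactly
that rule — no further exceptions (some cleavage-rule catalogues add W-K-P /
M-R-P exceptions; the simple proline-suppression rule is the one used for
the peptide maps this package emulates, and our pyteomics cross-check is
run with the same plain rule). The C-terminal residue is never a cleavage
site. Missed cleavages default to 1 per peptide and are configurable.
Zero-miscleavage fragments are labelled T1…Tn from the N-terminus (1-based
inclusive coordinates); miscleaved fragments are labelled by their T-span
(`T42–T43`).

Masses are theoretical: monoisotopic residue masses by default (average
available), water 18.010565 Da (mono) / 18.0153 (average), proton
1.007276 Da. Fixed modifications default to none; carbamidomethyl-C can be
added through `MassTable(fixed_modifications={"C": CARBAMIDOMETHYL})`.
Fragment ions are b and y only — the series used when spectra are manually
checked for a contiguous ion run — with b_i/y_i for i < n and
`(fragment residue sum [+ water for y] + z·proton)/z`. Precursor m/z is
`(M + z·proton)/z`. Observed masses printed in experimental reports can
deviate from these theoretical values (calibration, deamidation and other
modifications); this package intentionally reports theory only.

## Diagnostic classification

A peptide of species A is *shared* if its sequence occurs among the tryptic
peptides — same missed-cleavage allowance — of any other species' ortholog
in the group, else *specific*. Two deliberate choices:

* **Comparison universe = digest peptides**, not arbitrary substrings. The
  instrument observes tryptic peptides; a sequence that happens to occur as
  an untryptic substring of the partner ortholog could never be observed
  from it, so it remains diagnostic.
* **I/L equivalence ON by default.** Isoleucine and leucine are isobaric
  and not distinguished by the CID instruments this workflow targets, so a
  peptide differing only by I↔L is not safely diagnostic. The strict
  behaviour is a flag, and every classified peptide records which
  convention produced it. Collapsing I onto L can only convert specific →
  shared, never the reverse.

Catalog entries are restricted to 6–30 residues by default, the typically
detectable tryptic range; the bounds are explicit configuration. Inclusion
lists enumerate each specific peptide once per charge state (default 2+ and
3+) at its theoretical precursor m/z, sorted by m/z; an ortholog pair with
no diagnostic peptides yields an empty list with a warning, since a
targeted search for a protein with no diagnostic peptides is well-posed but
necessarily futile.

## Evidence filtering and calling

Acceptance thresholds mirror the upstream validation pipeline the PSM
tables come from: peptide probability strictly greater than 0.50, protein
probability strictly greater than 0.95 ("greater than" is implemented as a
strict inequality), at least 2 distinct accepted peptides per protein, and
a contiguous b/y series of at least 4 ions per peptide. The relatively
permissive peptide threshold reflects that shared peptides of homologous
proteins receive depressed scores because their protein of origin is
ambiguous.

A species is *present* for a member when it has ≥ 2 distinct accepted
specific peptides, or ≥ 1 specific peptide accepted in ≥ 2 distinct
biological replicates (the replicated-detection convention peptide-map
figures mark with asterisks). Both branch thresholds are configurable
because no formal presence rule is standard. Shared peptides are tallied
but never establish species presence. Sequences absent from the catalog
(contaminants) are logged and ignored rather than treated as errors.

The call: *chimeric* requires the bait to pass its own filters and at least
one non-bait member to show a non-bait-species presence that is absent from
the mixed-lysate control for that same (member, species) pair; control
subtraction is per pair rather than a global abort, so a contaminated
member does not erase evidence from other members. *Uni-specific* requires
bait-species presence and no non-bait-species presence anywhere.
Everything else is *inconclusive*. The artefact flag is raised whenever the
control evidence alone would have looked chimeric.

## Selection coefficient

`s_g = [ln(Hf/Rf) − ln(H0/R0)]/(gf − g0)` with H/R the hybrid and reference
counts and g the generation counts; natural log for the ratio, and the
helper `generations_elapsed` uses log2 of total fold-change (the standard
doubling definition — the generation inputs are user-supplied because
assays may derive them from either total or reference growth).

Numerically the log-ratio change is evaluated through the exact rational
cross-ratio `Fraction(Hf·R0)/Fraction(Rf·H0)` reduced to lowest terms, then
`ln(numerator) − ln(denominator)`. This makes three calibration identities
bit-exact in floating point, not merely close: equal initial and final
ratios give exactly 0.0; swapping the hybrid and reference roles negates
s_g exactly; and rescaling all four counts by a common exactly-representable
factor leaves s_g unchanged. Zero counts are rejected rather than smoothed
(cytometry samples of 50,000 events make true zeros pathological); a
pseudocount parameter exists for simulated edge cases. Technical replicates
are averaged within their biological replicate before the per-strain mean
and (n−1) standard deviation are formed, to avoid pseudo-replication;
this is switchable.

## Synthetic data: what it emulates, and what it does not

The generators define the conditions under which the pipeline is validated.

* **Divergence.** Each site of a member's base sequence is substituted
  independently with probability `substitution_rate` (default 0.05,
  matching the few-percent protein divergence of sibling species that can
  still hybridise), uniformly over replacement residues — no substitution
  matrix, since the generator only needs to control diagnostic-peptide
  density, not mimic evolution. With `preserve_cleavage_pattern` (default)
  K/R/P are never created or destroyed, so both orthologs share one
  digestion pattern and classification effects are isolated from
  digestion-pattern effects.
* **Complexes.** Default 3 members of 200–600 residues across 2 species,
  spanning the small complexes this kind of pulldown interrogates.
* **Pulldowns.** Under a chimeric truth all catalog peptides of both
  species are eligible; under a uni-specific truth (and in the mixed-lysate
  control run) only bait-species peptides are — which automatically emits
  the shared peptides, encoding the central identifiability constraint that
  shared peptides cannot distinguish the hypotheses. Detection is an
  independent Bernoulli per eligible peptide per replicate (default 0.9 in
  validation scenarios); identification scores are Beta-distributed with
  true-identification defaults concentrated above the 0.5/0.95 thresholds
  and contaminant defaults below, contiguous-ion counts uniform on 4–12
  (true) and 1–6 (contaminant); contaminant PSMs appear at a configurable
  Poisson rate with random non-catalog sequences. Replicates default to 3,
  the usual biological-replicate structure.
* **Competitions.** Hybrid:reference inoculation 4:1; the final expected
  odds are `4·e^{s·g}`; each timepoint draws 50,000 cells binomially from
  the true proportions (defaults matching standard cytometry practice).

What the generator does **not** model: peptide detectability as a function
of sequence physicochemistry, correlated detection across replicates,
retention-time or spectral simulation, homologous mis-assignment between
paralogs, and real evolutionary substitution processes. Passing the
closed-loop tests therefore demonstrates the *logic* of the pipeline —
filters, classification, control subtraction, calling, estimation — under
controlled truth, not instrument-level realism.

All generators draw from `numpy` Generator streams fanned out from a single
seed via `SeedSequence.spawn`, so runs are bit-reproducible and adding
replicates does not perturb earlier draws. The power-grid helper reuses one
set of per-replicate seeds across grid cells, making comparisons along
either axis paired.

## Validation problem sizes

The shipped test-suite anchors use: exhaustive digest-vs-enumeration
equivalence over every sequence of length ≤ 12 on the cleavage-relevant
alphabet {A, K, R, P} at 0–2 missed cleavages (the span comparison is
memoised on the cleavage boundary list, which fully determines it; the
public `digest()` object path is additionally run exhaustively to length 8
and on 200 random length-100 sequences); 500 simulated ortholog pairs at
divergence 0–0.3 for the classification oracle; 200 simulated pulldowns per
truth for the end-to-end call rates; and 100 simulated competitions for
selection-coefficient recovery.

## Known limitations

* Ortholog mapping is user-supplied; no homology inference is attempted.
* Ambiguous residues (B, J, O, U, X, Z) are rejected rather than expanded,
  because diagnostic classification depends on exact residue identity.
* Only trypsin is modelled, b/y ions only, no neutral losses or isotope
  envelopes.
* The chimericity caller treats members independently; it does not model
  stoichiometry or partial occupancy.
* No FDR estimation — acceptance is by the probability thresholds the
  upstream tools report, as in the workflow this package mirrors.
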