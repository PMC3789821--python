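"""Shared/specific classification, catalogs, inclusion lists, map rendering."""

from __future__ import annotations

import numpy as np
import pytest

from chimerapep import (
    DivergenceConfig,
    OrthologGroup,
    ProteinRecord,
    build_catalog,
    build_inclusion_list,
    build_peptide_map,
    classify_peptide,
    collapse_il,
    digest,
    peptide_mass,
    precursor_mz,
    render_peptide_map,
    synth_complex,
)
from chimerapep.diagnostics import DigestParams


def two_species_group(seq_a: str, seq_b: str) -> OrthologGroup:
    return OrthologGroup("M1", "CPX", {
        "Scer": ProteinRecord("a", "Scer", "", seq_a),
        "Suva": ProteinRecord("b", "Suva", "", seq_b),
    })


def brute_force_class(peptide_seq, group, own_species, il_equivalent, max_missed):
    """Oracle: enumerate every digest peptide of every other ortholog."""
    key = collapse_il(peptide_seq) if il_equivalent else peptide_seq
    for other in group.other_species(own_species):
        universe = {
            collapse_il(p.sequence) if il_equivalent else p.sequence
            for p in digest(group.records[other].sequence, max_missed)
        }
        if key in universe:
            return "shared"
    return "specific"


class TestClassifyPeptide:
    def test_identical_orthologs_all_shared(self, identical_group):
        record = identical_group.records["Scer"]
        for peptide in digest(record.sequence, 1, record.protein_id):
            out = classify_peptide(peptide, identical_group, "Scer")
            assert out.classification == "shared"
            assert out.specific_to is None

    def test_single_substitution_marks_covering_peptides(self, trp2_group):
        """Only peptides overlapping the substituted site become specific."""
        record = trp2_group.records["Scer"]
        diff_pos = 21  # the L/M difference (1-based)
        for peptide in digest(record.sequence, 1, record.protein_id):
            out = classify_peptide(peptide, trp2_group, "Scer",
                                   digest_params=DigestParams(min_len=1))
            covers = peptide.start <= diff_pos <= peptide.end
            assert (out.classification == "specific") == covers

    def test_il_substitution_collapses_to_shared(self):
        group = two_species_group("MAAIAAK", "MAALAAK")
        peptide = digest("MAAIAAK", 0, "a")[0]
        strict = classify_peptide(peptide, group, "Scer", il_equivalent=False)
        collapsed = classify_peptide(peptide, group, "Scer", il_equivalent=True)
        assert strict.classification == "specific"
        assert collapsed.classification == "shared"
        assert collapsed.il_collapsed

    def test_underivable_peptide_rejected(self, trp2_group):
        foreign = digest("WWWWK", 0, "zzz")[0]
        with pytest.raises(ValueError, match="not a substring"):
            classify_peptide(foreign, trp2_group, "Scer")

    @pytest.mark.parametrize("il_equivalent", [False, True])
    def test_brute_force_oracle_short_groups(self, il_equivalent):
        """Exhaustive membership oracle over simulated short orthologs."""
        rng = np.random.default_rng(42)
        for trial in range(40):
            divergence = float(rng.uniform(0.0, 0.35))
            groups = synth_complex(
                members=1, length_range=(15, 30),
                divergence=DivergenceConfig(divergence, True, seed=int(trial)))
            group = groups[0]
            for species in group.species:
                record = group.records[species]
                for peptide in digest(record.sequence, 1, record.protein_id):
                    got = classify_peptide(peptide, group, species,
                                           il_equivalent=il_equivalent)
                    assert got.classification == brute_force_class(
                        peptide.sequence, group, species, il_equivalent, 1)


class TestCatalog:
    def test_identical_group_no_specific_entries(self, identical_group):
        catalog = build_catalog(identical_group, min_len=1)
        for entries in catalog.entries.values():
            assert all(e.classification == "shared" for e in entries)

    def test_fully_dissimilar_all_specific(self):
        group = two_species_group("MADEFGHSTK", "WYWCNQWCNW")
        catalog = build_catalog(group, min_len=1)
        for entries in catalog.entries.values():
            assert entries and all(e.classification == "specific"
                                   for e in entries)

    def test_length_bounds_filter_entries(self, trp2_group):
        catalog = build_catalog(trp2_group, min_len=6, max_len=30)
        for entries in catalog.entries.values():
            assert all(6 <= len(e.peptide) <= 30 for e in entries)

    def test_inverted_bounds_rejected(self, trp2_group):
        with pytest.raises(ValueError, match="inverted"):
            build_catalog(trp2_group, min_len=10, max_len=6)

    def test_deterministic_ordering(self, trp2_group):
        catalog = build_catalog(trp2_group, min_len=1)
        for entries in catalog.entries.values():
            keys = [(e.peptide.start, len(e.peptide)) for e in entries]
            assert keys == sorted(keys)

    def test_symmetry_of_sharedness(self):
        """In a 2-species group, sharedness is the same from both sides."""
        for seed in range(10):
            group = synth_complex(
                members=1, length_range=(40, 80),
                divergence=DivergenceConfig(0.08, True, seed=seed))[0]
            catalog = build_catalog(group, min_len=1)
            shared_sets = []
            for species in group.species:
                shared_sets.append({
                    collapse_il(e.peptide.sequence)
                    for e in catalog.entries[species]
                    if e.classification == "shared"
                })
            assert shared_sets[0] == shared_sets[1]

    def test_il_collapse_only_converts_specific_to_shared(self):
        for seed in range(10):
            group = synth_complex(
                members=1, length_range=(40, 80),
                divergence=DivergenceConfig(0.1, True, seed=seed))[0]
            strict = build_catalog(group, il_equivalent=False, min_len=1)
            collapsed = build_catalog(group, il_equivalent=True, min_len=1)
            for species in group.species:
                strict_class = {e.peptide.sequence: e.classification
                                for e in strict.entries[species]}
                for entry in collapsed.entries[species]:
                    if strict_class[entry.peptide.sequence] == "shared":
                        assert entry.classification == "shared"

    def test_specific_fraction_increases_with_divergence(self):
        """More substitutions -> more diagnostic peptides (monotone trend)."""
        fractions = []
        for divergence in (0.01, 0.05, 0.1, 0.2):
            specific = total = 0
            for seed in range(8):
                group = synth_complex(
                    members=1, length_range=(150, 250),
                    divergence=DivergenceConfig(divergence, True, seed=seed))[0]
                catalog = build_catalog(group)
                for entries in catalog.entries.values():
                    total += len(entries)
                    specific += sum(e.classification == "specific"
                                    for e in entries)
            fractions.append(specific / total)
        assert fractions == sorted(fractions)

    def test_lookup_outcomes(self, trp2_group):
        catalog = build_catalog(trp2_group, min_len=4)
        assert catalog.lookup("LIELEFK") == ("shared", None)
        assert catalog.lookup("ALGMK") == ("specific", "Scer")
        assert catalog.lookup("AMGMK") == ("specific", "Suva")
        assert catalog.lookup("WWWWWW") == ("unmatched", None)


class TestInclusionList:
    def test_entries_per_specific_peptide_and_charge(self, trp2_group):
        catalog = build_catalog(trp2_group, min_len=4)
        entries = build_inclusion_list(catalog, "Suva", charges=(2, 3))
        # Suva specific sequences: AMGMK and the miscleaved DTLQEAERAMGMK
        assert {e.sequence for e in entries} == {"AMGMK", "DTLQEAERAMGMK"}
        assert len(entries) == 4
        assert [e.mz for e in entries] == sorted(e.mz for e in entries)

    def test_mz_rederives_from_mass(self, trp2_group):
        catalog = build_catalog(trp2_group, min_len=4)
        for entry in build_inclusion_list(catalog, "Scer", charges=(1, 2, 3)):
            expected = precursor_mz(peptide_mass(entry.sequence), entry.charge)
            assert entry.mz == pytest.approx(expected, abs=1e-9)

    def test_identical_orthologs_empty_with_warning(self, identical_group):
        catalog = build_catalog(identical_group, min_len=4)
        with pytest.warns(UserWarning, match="no species-specific"):
            assert build_inclusion_list(catalog, "Scer") == []

    def test_unknown_species_and_bad_charges(self, trp2_group):
        catalog = build_catalog(trp2_group)
        with pytest.raises(KeyError, match="Smik"):
            build_inclusion_list(catalog, "Smik")
        with pytest.raises(ValueError, match="charges"):
            build_inclusion_list(catalog, "Scer", charges=(0,))


class TestRenderPeptideMap:
    def test_line_count_matches_t_peptides(self, trp2_group):
        record = trp2_group.records["Scer"]
        pmap = build_peptide_map(record)
        catalog = build_catalog(trp2_group, min_len=1)
        lines = render_peptide_map(pmap, catalog).splitlines()
        assert len(lines) == 1 + len(pmap.tryptic_peptides)  # header + rows

    def test_no_detections_no_asterisks(self, trp2_group):
        pmap = build_peptide_map(trp2_group.records["Scer"])
        catalog = build_catalog(trp2_group, min_len=1)
        assert "*" not in render_peptide_map(pmap, catalog)

    def test_replicated_detection_gets_asterisk(self, trp2_group):
        pmap = build_peptide_map(trp2_group.records["Scer"])
        catalog = build_catalog(trp2_group, min_len=1)
        twice = render_peptide_map(
            pmap, catalog, detections={("ALGMK", "R1"), ("ALGMK", "R2")})
        once = render_peptide_map(pmap, catalog, detections={("ALGMK", "R1")})
        (starred,) = [l for l in twice.splitlines() if "ALGMK" in l]
        assert starred.endswith("*") and "SPECIFIC(Scer)" in starred
        (unstarred,) = [l for l in once.splitlines() if "ALGMK" in l]
        assert "*" not in unstarred and "detected" in unstarred

    def test_mismatched_protein_rejected(self, trp2_group, identical_group):
        pmap = build_peptide_map(identical_group.records["Scer"])
        catalog = build_catalog(trp2_group, min_len=1)
        with pytest.raises(ValueError, match="does not match"):
            render_peptide_map(pmap, catalog)
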