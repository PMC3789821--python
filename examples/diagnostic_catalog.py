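"""Species-diagnostic peptides for an ortholog pair, plus a targeted list.

Builds a two-species ortholog group differing at a single residue,
classifies every tryptic peptide as shared or species-specific, renders
the annotated peptide map, and derives the targeted-MS inclusion list for
the second species' diagnostic peptides.
"""

from chimerapep import (
    OrthologGroup,
    ProteinRecord,
    build_catalog,
    build_inclusion_list,
    build_peptide_map,
    render_peptide_map,
)

group = OrthologGroup("Trp2", "TRP", {
    "Scer": ProteinRecord("trp2_sc", "Scer", "TRP2",
                          "MTTKLIELEFKDTLQEAERALGMK"),
    "Suva": ProteinRecord("trp2_su", "Suva", "TRP2",
                          "MTTKLIELEFKDTLQEAERAMGMK"),
})

catalog = build_catalog(group, min_len=4)
print(render_peptide_map(build_peptide_map(group.records["Scer"]), catalog,
                         detections={("ALGMK", "R1"), ("ALGMK", "R2")}))
print()
print("A SPECIFIC peptide occurs in no tryptic digest of the other species'")
print("ortholog, so observing it attributes the protein to that parent;")
print("the asterisk marks detection in two independent replicates.\n")

print("inclusion list targeting Suva-diagnostic peptides (charges 2+, 3+):")
for entry in build_inclusion_list(catalog, "Suva", charges=(2, 3)):
    print(f"  {entry.sequence:16} {entry.charge}+  m/z {entry.mz:9.4f}")
print("\nThese m/z values would direct a targeted acquisition run.")
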