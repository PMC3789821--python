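"""Tryptic digestion and the T-indexed peptide map of one protein.

Digests a short protein with up to one missed cleavage and prints every
fragment with its coordinates, missed-cleavage count, monoisotopic mass and
doubly-charged precursor m/z. T-labels number the zero-miscleavage
fragments from the N-terminus; spans like T1–T2 mark miscleaved peptides.
"""

from chimerapep import build_peptide_map, peptide_mass, precursor_mz

SEQUENCE = "MTTKLIELEFKDTLQEAERALGMKINTEILENFKK"

pmap = build_peptide_map(SEQUENCE, parent_id="demo")
print(f"protein demo: {len(SEQUENCE)} residues, "
      f"{len(pmap.tryptic_peptides)} tryptic peptides\n")
print(f"{'label':8} {'span':9} {'missed':6} {'sequence':22} "
      f"{'mono Da':>10} {'m/z (2+)':>10}")
for peptide in pmap.all_peptides:
    mass = peptide_mass(peptide.sequence)
    print(f"{peptide.t_label:8} {peptide.start:>3}-{peptide.end:<5} "
          f"{peptide.missed_cleavages:^6} {peptide.sequence:22} "
          f"{mass:>10.4f} {precursor_mz(mass, 2):>10.4f}")

print("\nEach row is one candidate peptide an LC-MS/MS run could observe;")
print("the masses are theoretical (no modifications).")
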