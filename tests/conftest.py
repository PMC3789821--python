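"""Shared fixtures: small hand-built ortholog groups and file factories."""

from __future__ import annotations

import pytest

from chimerapep import OrthologGroup, ProteinRecord


@pytest.fixture
def trp2_group() -> OrthologGroup:
    """A two-species ortholog pair differing at one internal residue (L/M)."""
    scer = ProteinRecord("p1", "Scer", "TRP2", "MTTKLIELEFKDTLQEAERALGMK")
    suva = ProteinRecord("p2", "Suva", "TRP2", "MTTKLIELEFKDTLQEAERAMGMK")
    return OrthologGroup("Trp2", "TRP", {"Scer": scer, "Suva": suva})


@pytest.fixture
def identical_group() -> OrthologGroup:
    """Orthologs with identical sequences: every peptide is shared."""
    seq = "MTTKLIELEFKDTLQEAERALGMK"
    return OrthologGroup("Trp3", "TRP", {
        "Scer": ProteinRecord("q1", "Scer", "TRP3", seq),
        "Suva": ProteinRecord("q2", "Suva", "TRP3", seq),
    })


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (header, sequence) pairs."""
    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{header}\n{seq}\n" for header, seq in entries))
        return path
    return _write
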