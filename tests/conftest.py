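"""Shared fixtures: small records, labeled alignments, a hand-built PDB."""

import pytest

from rhoselect import (Alignment, SequenceRecord, ToyAlignmentSpec,
                       generate_toy_alignment)


@pytest.fixture
def simple_records():
    return {
        "plain": SequenceRecord("plain", "ACDEFGHIKLMNPQRSTVWY"),
        "neutral": SequenceRecord("neutral", "GGGG"),
        "charged": SequenceRecord("charged", "KKRDE"),
    }


@pytest.fixture
def labeled_alignment():
    """Tiny gapless labeled alignment with known discriminating columns.

    Columns (=positions, gapless): 5 and 12 discriminate perfectly; 8 is
    variable among binders; 30 discriminates but sits in switch I.
    """
    length = 40
    rows = []
    binder_seqs = []
    for i in range(3):
        s = list("A" * length)
        s[4] = "M"            # pos 5: perfectly conserved in binders
        s[7] = "TSG"[i]       # pos 8: variable within binders
        s[11] = "K"           # pos 12: conserved
        s[29] = "M"           # pos 30: discriminates but excluded (switch I)
        binder_seqs.append("".join(s))
    nonbinder_seqs = []
    for i in range(3):
        s = list("A" * length)
        s[4] = "E"            # deviates in class at pos 5
        s[7] = "Q"
        s[11] = "D"           # deviates at pos 12
        s[29] = "E"
        nonbinder_seqs.append("".join(s))
    for i, s in enumerate(binder_seqs):
        rows.append((SequenceRecord(f"b{i}", s, label="binder"), s))
    for i, s in enumerate(nonbinder_seqs):
        rows.append((SequenceRecord(f"n{i}", s, label="nonbinder"), s))
    return Alignment(rows, reference_id="b0")


@pytest.fixture
def planted_spec():
    return ToyAlignmentSpec(
        n_binders=5, n_nonbinders=8, length=100,
        planted={10: ("M", "E"), 45: ("K", "D"), 90: ("F", "S")},
        background="A", seed=11,
    )


@pytest.fixture
def planted_alignment(planted_spec):
    return generate_toy_alignment(planted_spec)


def pdb_atom_line(serial, name, res, chain, resseq, x, y, z, element,
                  altloc=" ", icode=" ", record="ATOM"):
    return (f"{record:<6s}{serial:5d} {name:^4s}{altloc:1s}{res:>3s} "
            f"{chain:1s}{resseq:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}")


@pytest.fixture
def tiny_pdb(tmp_path):
    """Two chains, one contact pair at 4.0 Å, one distal pair, extras."""
    lines = [
        "REMARK synthetic two-chain test structure",
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_atom_line(2, "CA", "ALA", "B", 1, 0.0, 4.0, 0.0, "C"),
        pdb_atom_line(3, "CA", "GLY", "A", 2, 30.0, 0.0, 0.0, "C"),
        pdb_atom_line(4, "CA", "GLY", "B", 2, 30.0, 30.0, 0.0, "C"),
        "TER",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
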