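"""Interface mapping on atomic coordinates.

Reads PDB files (via biotite) into plain atom records, finds the residues
two chain groups present to each other within a heavy-atom distance cutoff
(default 4.5 Å), and classifies sequence hotspot positions as part of the
interface, proximal to it, or distal — the distance-geometry counterpart
of asking whether selectivity-determining residues sit near an effector
footprint.

Hydrogens are ignored throughout (crystal structures mostly lack them);
author residue numbering is preserved and insertion codes are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParseError, ValidationError

ResidueKey = tuple[str, int, str]  # (chain, residue number, residue name)


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str

    def __post_init__(self):
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValidationError("atom coordinates must be finite")
        if self.res_number < 1:
            raise ValidationError("residue number must be >= 1")


@dataclass(frozen=True)
class InterfaceReport:
    """Minimal heavy-atom distances of each residue to the partner group."""

    side_a: Mapping[ResidueKey, float]
    side_b: Mapping[ResidueKey, float]
    cutoff: float

    @property
    def interface_a(self) -> set[ResidueKey]:
        return {k for k, d in self.side_a.items() if d <= self.cutoff}

    @property
    def interface_b(self) -> set[ResidueKey]:
        return {k for k, d in self.side_b.items() if d <= self.cutoff}


def read_structure(path, include_hetatm: bool = False) -> list[AtomRecord]:
    """Parse a PDB file into atom records.

    HETATM records are skipped unless ``include_hetatm``; for alternate
    locations only the first ('A'/blank) is kept; insertion codes are
    rejected because downstream numbering assumes plain author numbers.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="first",
                                       extra_fields=[])
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse PDB file: {exc}") from exc
    if "ins_code" in atoms.get_annotation_categories():
        ins = atoms.get_annotation("ins_code")
        bad = np.nonzero(ins != "")[0]
        if len(bad):
            i = int(bad[0])
            raise ValidationError(
                f"{path}: insertion code {ins[i]!r} at residue "
                f"{atoms.chain_id[i]}/{atoms.res_id[i]} is not supported"
            )
    records = []
    for i in range(atoms.array_length()):
        if atoms.hetero[i] and not include_hetatm:
            continue
        x, y, z = (float(c) for c in atoms.coord[i])
        records.append(AtomRecord(
            chain=str(atoms.chain_id[i]), res_number=int(atoms.res_id[i]),
            res_name=str(atoms.res_name[i]), atom_name=str(atoms.atom_name[i]),
            x=x, y=y, z=z, element=str(atoms.element[i]).upper() or "X",
        ))
    return records


def _heavy(atoms: Iterable[AtomRecord], chains: set[str]) -> list[AtomRecord]:
    return [a for a in atoms if a.chain in chains and a.element != "H"]


def _min_res_distances(group: list[AtomRecord], partner: list[AtomRecord]
                       ) -> dict[ResidueKey, float]:
    tree = cKDTree(np.array([[a.x, a.y, a.z] for a in partner]))
    dists, _ = tree.query(np.array([[a.x, a.y, a.z] for a in group]))
    out: dict[ResidueKey, float] = {}
    for atom, d in zip(group, dists):
        key = (atom.chain, atom.res_number, atom.res_name)
        if d < out.get(key, np.inf):
            out[key] = float(d)
    return out


def interface_residues(atoms: Sequence[AtomRecord], group_a: set[str],
                       group_b: set[str], cutoff: float = 4.5
                       ) -> InterfaceReport:
    """Residues of each chain group within ``cutoff`` Å of the other group.

    A residue is interfacial iff any of its heavy atoms lies within the
    cutoff of any heavy atom on the other side (distances exactly at the
    cutoff included).  All per-residue minimal distances are reported, so
    the same report also supports looser 'proximal' queries.
    """
    if not group_a or not group_b:
        raise ValidationError("both chain groups must be non-empty")
    if group_a & group_b:
        raise ValidationError(f"chain groups overlap: {group_a & group_b}")
    a_atoms, b_atoms = _heavy(atoms, group_a), _heavy(atoms, group_b)
    if not a_atoms or not b_atoms:
        raise ValidationError("a chain group selects no heavy atoms")
    return InterfaceReport(
        side_a=_min_res_distances(a_atoms, b_atoms),
        side_b=_min_res_distances(b_atoms, a_atoms),
        cutoff=cutoff,
    )


def hotspot_proximity(report: InterfaceReport, hotspots: Sequence[int],
                      near: float = 8.0, chain: str | None = None
                      ) -> dict[int, str]:
    """Classify hotspot residue numbers against a computed interface.

    Positions are looked up on side A (optionally restricted to one
    chain): ``interface`` if within the report cutoff, ``proximal`` if the
    minimal distance is <= ``near`` Å, ``distal`` otherwise, and
    ``unresolved`` when the residue is absent from the structure.
    """
    out = {}
    for pos in hotspots:
        cands = [d for (ch, num, _), d in report.side_a.items()
                 if num == pos and (chain is None or ch == chain)]
        if not cands:
            out[pos] = "unresolved"
            continue
        d = min(cands)
        if d <= report.cutoff:
            out[pos] = "interface"
        elif d <= near:
            out[pos] = "proximal"
        else:
            out[pos] = "distal"
    return out


def interface_table(report: InterfaceReport):
    """Per-residue report as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for side, data in (("A", report.side_a), ("B", report.side_b)):
        for (chain, num, name), d in sorted(data.items()):
            rows.append({"side": side, "chain": chain, "resnum": num,
                         "resname": name, "min_distance": d,
                         "interface": d <= report.cutoff})
    return pd.DataFrame(rows)
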