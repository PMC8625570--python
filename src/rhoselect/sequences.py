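"""Sequence and alignment primitives.

Protein constructs are carried as :class:`SequenceRecord` objects holding the
residues of a 1-based, inclusive slice of a full-length protein, together
with an optional UniProt-style accession and a binder/nonbinder label for
the IQGAP interaction screen.  On top of these the module provides the
net-charge statistic used to compare GTPase G-domains (+1 for Lys/Arg, -1
for Asp/Glu, His uncharged), charged-locus reduction of alignments,
pairwise global percent identity, residue substitution (variant
construction), average molecular mass, and reference-numbering maps for
alignments.

FASTA header dialect
--------------------
Records travel in plain FASTA.  The description line is whitespace-split as

    >id [accession=P60953] [range=1-178 | 1-178] [label=binder] [free text]

Unrecognised tokens are kept verbatim as the description.  Unspecified
fields default to ``accession=""``, ``range`` starting at 1, and
``label=unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ParseError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
LABELS = ("binder", "nonbinder", "unknown")

#: average residue (amino-acid minus water) masses in Da
RESIDUE_MASS_DA: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS_DA = 18.0153


@dataclass(frozen=True)
class SequenceRecord:
    """A protein construct: a residue slice of a full-length protein."""

    id: str
    residues: str
    accession: str = ""
    description: str = ""
    range_start: int = 1
    range_end: int = 0  # 0 -> derived from range_start and length
    label: str = "unknown"

    def __post_init__(self):
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if self.range_end == 0:
            object.__setattr__(
                self, "range_end", self.range_start + len(self.residues) - 1
            )
        if self.range_start < 1:
            raise ValidationError(f"{self.id}: range_start must be >= 1")
        if self.range_end - self.range_start + 1 != len(self.residues):
            raise ValidationError(
                f"{self.id}: range {self.range_start}-{self.range_end} does "
                f"not match sequence length {len(self.residues)}"
            )
        if self.label not in LABELS:
            raise ValidationError(
                f"{self.id}: label {self.label!r} not one of {LABELS}"
            )
        for i, aa in enumerate(self.residues):
            if aa not in AMINO_ACIDS:
                raise ValidationError(
                    f"{self.id}: non-standard residue code {aa!r} at "
                    f"position {self.range_start + i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based full-length position."""
        if not self.range_start <= position <= self.range_end:
            raise ValidationError(
                f"{self.id}: position {position} outside range "
                f"{self.range_start}-{self.range_end}"
            )
        return self.residues[position - self.range_start]


@dataclass(frozen=True)
class Substitution:
    """A single residue replacement in full-length numbering, e.g. K27T."""

    wild_type: str
    position: int
    replacement: str

    def __post_init__(self):
        if self.wild_type == self.replacement:
            raise ValidationError(f"{self}: wild type equals replacement")
        for aa in (self.wild_type, self.replacement):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"{self}: non-standard code {aa!r}")

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.replacement}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", text.strip())
        if not m:
            raise ParseError(f"cannot parse substitution {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))


@dataclass(frozen=True)
class ChargeReport:
    """Charged-residue counts and the net charge q = (K+R) - (D+E)."""

    id: str
    n_K: int
    n_R: int
    n_D: int
    n_E: int
    domain_range: tuple[int, int]

    @property
    def net_charge(self) -> int:
        return (self.n_K + self.n_R) - (self.n_D + self.n_E)


class RegionSet:
    """Named reference-numbered intervals (1-based, inclusive)."""

    def __init__(self, intervals: Mapping[str, tuple[int, int]]):
        for name, (lo, hi) in intervals.items():
            if lo > hi:
                raise ValidationError(f"region {name}: start {lo} > end {hi}")
        self.intervals = dict(intervals)

    @classmethod
    def switch_regions(cls) -> "RegionSet":
        """The conformationally mobile switch I/II effector-binding regions."""
        return cls({"switch_I": (29, 42), "switch_II": (62, 68)})

    def __contains__(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.intervals.values())

    def __repr__(self) -> str:
        return f"RegionSet({self.intervals!r})"


class Alignment:
    """A gapped multiple alignment of SequenceRecords with a numbering reference.

    Columns are 1-based.  ``column_to_ref`` maps each column in which the
    reference row has a residue to that residue's full-length number.
    """

    def __init__(self, rows: Sequence[tuple[SequenceRecord, str]],
                 reference_id: str | None = None):
        if not rows:
            raise ValidationError("alignment has no rows")
        width = len(rows[0][1])
        for rec, gapped in rows:
            if len(gapped) != width:
                raise ValidationError(
                    f"{rec.id}: gapped length {len(gapped)} != {width}"
                )
            if gapped.replace("-", "") != rec.residues:
                raise ValidationError(
                    f"{rec.id}: gapped row does not reduce to its residues"
                )
        self.rows = list(rows)
        self.width = width
        self.reference_id = reference_id or rows[0][0].id
        if self.reference_id not in {r.id for r, _ in rows}:
            raise ValidationError(
                f"reference id {self.reference_id!r} not among rows"
            )

    @property
    def reference_row(self) -> tuple[SequenceRecord, str]:
        for rec, gapped in self.rows:
            if rec.id == self.reference_id:
                return rec, gapped
        raise AssertionError("unreachable")

    @property
    def column_to_ref(self) -> dict[int, int]:
        rec, gapped = self.reference_row
        out, pos = {}, rec.range_start - 1
        for col, aa in enumerate(gapped, start=1):
            if aa != "-":
                pos += 1
                out[col] = pos
        return out

    def records(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.rows]

    def column(self, col: int) -> list[str]:
        """Symbols of a 1-based column, top to bottom ('-' for gaps)."""
        if not 1 <= col <= self.width:
            raise ValidationError(f"column {col} outside 1-{self.width}")
        return [gapped[col - 1] for _, gapped in self.rows]


# ---------------------------------------------------------------------------
# FASTA I/O

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_header(header: str) -> dict:
    tokens = header.split()
    rec_id, rest = tokens[0], tokens[1:]
    fields = {"id": rec_id, "accession": "", "label": "unknown",
              "range_start": 1, "range_end": 0}
    free: list[str] = []
    for tok in rest:
        if tok.startswith("accession="):
            fields["accession"] = tok[len("accession="):]
        elif tok.startswith("label="):
            fields["label"] = tok[len("label="):]
        elif tok.startswith("range="):
            m = _RANGE_RE.match(tok[len("range="):])
            if not m:
                raise ParseError(f"bad range token {tok!r} in header {header!r}")
            fields["range_start"], fields["range_end"] = map(int, m.groups())
        elif _RANGE_RE.match(tok):
            m = _RANGE_RE.match(tok)
            fields["range_start"], fields["range_end"] = map(int, m.groups())
        else:
            free.append(tok)
    fields["description"] = " ".join(free)
    return fields


def _format_header(rec: SequenceRecord) -> str:
    parts = [rec.id]
    if rec.accession:
        parts.append(f"accession={rec.accession}")
    parts.append(f"range={rec.range_start}-{rec.range_end}")
    parts.append(f"label={rec.label}")
    if rec.description:
        parts.append(rec.description)
    return " ".join(parts)


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into records, parsing the header dialect (module docstring)."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    for sr in parsed:
        fields = _parse_header(sr.description)
        records.append(SequenceRecord(
            id=fields["id"], residues=str(sr.seq).upper().replace("-", ""),
            accession=fields["accession"], description=fields["description"],
            range_start=fields["range_start"], range_end=fields["range_end"],
            label=fields["label"],
        ))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path, reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA ('-' gaps, same header dialect)."""
    rows = []
    for sr in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(sr.description)
        gapped = str(sr.seq).upper()
        rows.append((SequenceRecord(
            id=fields["id"], residues=gapped.replace("-", ""),
            accession=fields["accession"], description=fields["description"],
            range_start=fields["range_start"], range_end=fields["range_end"],
            label=fields["label"],
        ), gapped))
    return Alignment(rows, reference_id=reference_id)


def write_alignment(alignment: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec, gapped in alignment.rows:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(gapped), width):
                fh.write(gapped[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Statistics and operations


def net_charge(record: SequenceRecord,
               domain: tuple[int, int] | None = None) -> ChargeReport:
    """Net charge of a record (or a full-length-numbered sub-domain).

    The convention counts +1 per Lys/Arg and -1 per Asp/Glu; histidine is
    uncharged.  ``domain`` is a 1-based inclusive interval in full-length
    numbering and defaults to the whole record.
    """
    if domain is None:
        lo, hi = record.range_start, record.range_end
    else:
        lo, hi = domain
        if lo > hi or lo < record.range_start or hi > record.range_end:
            raise ValidationError(
                f"{record.id}: domain {lo}-{hi} outside record range "
                f"{record.range_start}-{record.range_end}"
            )
    seg = record.residues[lo - record.range_start: hi - record.range_start + 1]
    return ChargeReport(
        id=record.id,
        n_K=seg.count("K"), n_R=seg.count("R"),
        n_D=seg.count("D"), n_E=seg.count("E"),
        domain_range=(lo, hi),
    )


def charged_locus_columns(alignment: Alignment,
                          polarity: str = "either") -> list[int]:
    """Columns (1-based) holding at least one charged residue of a polarity.

    ``polarity`` is ``positive`` (K/R), ``negative`` (D/E) or ``either``.
    This is the alignment reduction used to visualise how charged loci are
    distributed across GTPase paralogs.
    """
    wanted = {"positive": POSITIVE, "negative": NEGATIVE,
              "either": POSITIVE | NEGATIVE}.get(polarity)
    if wanted is None:
        raise ValidationError(f"unknown polarity {polarity!r}")
    return [col for col in range(1, alignment.width + 1)
            if any(aa in wanted for aa in alignment.column(col))]


_aligner = None


def _global_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def percent_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity from a global BLOSUM62 alignment (gap open 10, extend 0.5).

    Identity is counted as identical aligned pairs over all alignment
    columns excluding terminal-gap columns (internal gaps count against
    identity).
    """
    if not a.residues or not b.residues:
        raise ValidationError("percent_identity requires non-empty sequences")
    aln = _global_aligner().align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim columns belonging to a terminal gap in either row
    start = max(len(r) - len(r.lstrip("-")) for r in (row_a, row_b))
    end = min(len(r.rstrip("-")) for r in (row_a, row_b))
    cols = end - start
    if cols <= 0:
        return 0.0
    same = sum(1 for x, y in zip(row_a[start:end], row_b[start:end])
               if x == y and x != "-")
    return 100.0 * same / cols


def apply_substitutions(record: SequenceRecord,
                        subs: Sequence[Substitution]) -> SequenceRecord:
    """Return a variant record with the given substitutions applied.

    Positions are full-length numbers; the stated wild-type residue is
    checked against the record to guard against numbering-offset mistakes.
    """
    residues = list(record.residues)
    for sub in subs:
        if not record.range_start <= sub.position <= record.range_end:
            raise ValidationError(
                f"{record.id}: substitution position {sub.position} outside "
                f"range {record.range_start}-{record.range_end}"
            )
        idx = sub.position - record.range_start
        if residues[idx] != sub.wild_type:
            raise ValidationError(
                f"{record.id}: wild-type mismatch at {sub.position}: "
                f"expected {sub.wild_type}, found {residues[idx]}"
            )
        residues[idx] = sub.replacement
    suffix = "_".join(str(s) for s in subs)
    return replace(record, id=f"{record.id}_{suffix}" if subs else record.id,
                   residues="".join(residues))


def molecular_mass(record: SequenceRecord) -> float:
    """Average molecular mass in kDa (residue masses + one water), 3 decimals."""
    if not record.residues:
        raise ValidationError("empty sequence has no mass")
    da = sum(RESIDUE_MASS_DA[aa] for aa in record.residues) + WATER_MASS_DA
    return round(da / 1000.0, 3)


def map_reference_positions(alignment: Alignment,
                            positions: Iterable[int]) -> dict[int, int]:
    """Map reference residue numbers to the alignment columns holding them."""
    ref_map = {pos: col for col, pos in alignment.column_to_ref.items()}
    out = {}
    for pos in positions:
        if pos not in ref_map:
            rec, _ = alignment.reference_row
            raise ValidationError(
                f"position {pos} not covered by reference {rec.id} "
                f"({rec.range_start}-{rec.range_end})"
            )
        out[pos] = ref_map[pos]
    return out


def charge_table(records: Iterable[SequenceRecord],
                 domain: tuple[int, int] | None = None):
    """Net-charge report for many records as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for rec in records:
        rep = net_charge(rec, domain=domain)
        rows.append({"id": rep.id, "nK": rep.n_K, "nR": rep.n_R,
                     "nD": rep.n_D, "nE": rep.n_E,
                     "net_charge": rep.net_charge})
    return pd.DataFrame(rows)
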