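"""Synthetic inputs for every stage of the pipeline.

Real inputs to these analyses are instrument traces, labeled alignments,
elution profiles and crystal structures.  This module generates seeded,
deterministic stand-ins for all of them so the whole pipeline is testable
offline:

* a ground-truth kinetic fixture table whose Kd values and ratios encode
  the anchor numbers of the underlying study conditions (27 nM for the
  highest-affinity RAC paralog, 34-fold and 3-fold Kd ratios, 2.37 µM for
  the constitutively active CDC42 variant/GRD pair, 7-17-fold losses for
  the hotspot-swap variants) — the absolute kon scale is a package choice
  in the typical effector range and is recorded per entry;
* noisy association/displacement trace sets for parameter-recovery tests;
* toy labeled alignments with planted discriminating columns;
* Gaussian elution profiles on a 0.02-mL grid;
* toy two-chain complexes with an exact number of atomic contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .kinetics import (MixConfig, RateConstants, Trace, simulate_association,
                       simulate_displacement)
from .sec import ColumnGeometry, ElutionProfile
from .sequences import AMINO_ACIDS, Alignment, RegionSet, SequenceRecord
from .structure import AtomRecord


@dataclass(frozen=True)
class FixtureEntry:
    """A named ground-truth kinetic parameter set."""

    rates: RateConstants
    binder: bool
    provenance: str

    @property
    def kd(self) -> float:
        return self.rates.kd


def make_kinetics_fixture() -> dict[str, FixtureEntry]:
    """Deterministic ground-truth table of kon/koff per GTPase construct.

    Kd anchors and ratios are fixed study-condition values; absolute kon
    values are package choices in the 0.5-10 1/(µM s) effector range.
    The 34-fold rac1/rac2 Kd ratio is authoritative and split 4.25x (kon)
    by 8x (koff).  Nonbinder entries carry a vanishing affinity (Kd in the
    mM range) so that screens show no association signal.
    """
    rac2 = RateConstants(kon=8.0, koff=0.216)            # Kd = 27 nM anchor
    rac1 = RateConstants(kon=8.0 / 4.25, koff=0.216 * 8)  # Kd = 34x rac2
    table: dict[str, FixtureEntry] = {
        "rac2": FixtureEntry(rac2, True,
                             "Kd anchored at 27 nM; absolute kon scale "
                             "package choice"),
        "rac1": FixtureEntry(rac1, True,
                             "Kd = 34x rac2 (kon 4.25x slower, koff 8x "
                             "faster than rac2)"),
        "cdc42": FixtureEntry(RateConstants(kon=3.0, koff=rac1.kd),  # Kd/3
                              True,
                              "Kd = rac1/3 (faster kon, slower koff); "
                              "absolute scale package choice"),
        "rac3": FixtureEntry(RateConstants(kon=2.2, koff=1.9), True,
                             "similar range to rac1; values package choice"),
        "rhog": FixtureEntry(RateConstants(kon=1.6, koff=1.35), True,
                             "similar range to rac1; values package choice"),
        "grd_cdc42q61l": FixtureEntry(
            RateConstants(kon=0.5, koff=0.5 * 2.37), True,
            "Kd anchored at 2.37 µM; absolute scale package choice"),
        # hotspot-swap variants: Kd losses between 7x and 17x vs rac1,
        # slower association and faster dissociation
        "rac1_T25K_N26D": FixtureEntry(
            RateConstants(rac1.kon / 2, rac1.koff * 4.5), True,
            "9x Kd loss vs rac1; split package choice"),
        "rac1_M45E_N52E": FixtureEntry(
            RateConstants(rac1.kon / 3, rac1.koff * 5), True,
            "15x Kd loss vs rac1; split package choice"),
        "rac1_Q74D": FixtureEntry(
            RateConstants(rac1.kon / 1.75, rac1.koff * 4), True,
            "7x Kd loss vs rac1; split package choice"),
        "rac1_V85D_S88D": FixtureEntry(
            RateConstants(rac1.kon / 4.25, rac1.koff * 4), True,
            "17x Kd loss vs rac1; split package choice"),
    }
    for name in ("rhoa", "rhob", "rhoc", "rhod", "rif",
                 "tc10", "rnd1", "rnd2", "rnd3"):
        table[name] = FixtureEntry(
            RateConstants(kon=0.01, koff=50.0), False,
            "nonbinder: vanishing affinity (Kd 5 mM), no detectable signal")
    return table


@dataclass
class TraceSet:
    """One seeded replicate of the full estimation protocol's raw data."""

    name: str
    association: list  # [(E0 µM, Trace), ...]
    displacement: Trace
    sigma: float
    seed: Optional[int]


def generate_trace_set(entry, concentrations: Sequence[float] = (2, 4, 6, 8),
                       sigma: float = 0.0, seed: Optional[int] = 0,
                       mix: MixConfig | None = None) -> TraceSet:
    """Association traces at several effector concentrations + displacement.

    ``entry`` is a fixture name or a RateConstants.  Sub-seeds for the
    individual traces are derived deterministically from ``seed`` with the
    same scheme the estimation protocol uses, so generated sets are
    byte-identical across runs.
    """
    if isinstance(entry, str):
        table = make_kinetics_fixture()
        if entry not in table:
            raise ValidationError(f"unknown fixture entry {entry!r}")
        rates, name = table[entry].rates, entry
    else:
        rates, name = entry, "custom"
    mix = mix or MixConfig()
    assoc = []
    for i, conc in enumerate(concentrations):
        sub = (seed * 1009 + i) % (2 ** 31) if seed is not None else None
        m = dc_replace(mix, E0=float(conc), duration=None)
        assoc.append((float(conc), simulate_association(rates, m, sigma, sub)))
    sub = (seed * 1009 + 97) % (2 ** 31) if seed is not None else None
    disp = simulate_displacement(rates, dc_replace(mix, duration=None),
                                 sigma, sub)
    return TraceSet(name, assoc, disp, sigma, seed)


@dataclass
class ToyAlignmentSpec:
    """Recipe for a labeled alignment with planted discriminating columns."""

    n_binders: int = 5
    n_nonbinders: int = 8
    length: int = 100
    planted: dict = field(default_factory=lambda: {})  # pos -> (b_res, n_res)
    background: str = "A"
    variable_columns: tuple = ()
    seed: int = 0
    excluded: RegionSet = field(default_factory=RegionSet.switch_regions)

    def __post_init__(self):
        if self.n_binders < 1 or self.n_nonbinders < 1:
            raise ValidationError("need at least one binder and one nonbinder")
        for pos, (b, n) in self.planted.items():
            if not 1 <= pos <= self.length:
                raise ValidationError(f"planted position {pos} outside 1-"
                                      f"{self.length}")
            if pos in self.excluded:
                raise ValidationError(
                    f"planted position {pos} lies inside an excluded region")
            if b == n:
                raise ValidationError(
                    f"planted position {pos}: binder and nonbinder residues "
                    "must differ")
        for pos in self.variable_columns:
            if pos in self.planted:
                raise ValidationError(
                    f"column {pos} cannot be both planted and variable")


def generate_toy_alignment(spec: ToyAlignmentSpec) -> Alignment:
    """Build the gapless labeled alignment a ToyAlignmentSpec describes.

    Background columns are identical across all rows; planted columns carry
    the binder residue in binders and the nonbinder residue in nonbinders;
    variable columns get per-row seeded uniform residues.  The first binder
    is the numbering reference (columns = positions, gapless).
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = []
    for kind, count in (("binder", spec.n_binders),
                        ("nonbinder", spec.n_nonbinders)):
        for i in range(count):
            seq = [spec.background] * spec.length
            for pos, (b_res, n_res) in spec.planted.items():
                seq[pos - 1] = b_res if kind == "binder" else n_res
            for pos in spec.variable_columns:
                seq[pos - 1] = str(rng.choice(aa))
            s = "".join(seq)
            rec = SequenceRecord(id=f"{kind[0]}{i + 1}", residues=s,
                                 label=kind)
            rows.append((rec, s))
    return Alignment(rows, reference_id=rows[0][0].id)


def generate_elution_profile(peaks: Sequence[tuple[float, float, float]],
                             noise: float = 0.0, seed: Optional[int] = None,
                             geometry: ColumnGeometry | None = None,
                             grid_step: float = 0.02) -> ElutionProfile:
    """Sum-of-Gaussians elution profile on a fixed grid over [V0, Vc].

    ``peaks`` are (center mL, height, standard deviation mL) triples; all
    centers must lie on the column.  Optional seeded Gaussian baseline
    noise with standard deviation ``noise``.
    """
    geometry = geometry or ColumnGeometry()
    v = np.arange(geometry.V0, geometry.Vc + grid_step / 2, grid_step)
    a = np.zeros_like(v)
    for center, height, width in peaks:
        if not geometry.V0 <= center <= geometry.Vc:
            raise ValidationError(
                f"peak center {center} mL outside the column "
                f"[{geometry.V0}, {geometry.Vc}] mL")
        if width <= 0 or height <= 0:
            raise ValidationError("peak height and width must be > 0")
        a += height * np.exp(-0.5 * ((v - center) / width) ** 2)
    if noise > 0:
        a = a + np.random.default_rng(seed).normal(0, noise, size=v.shape)
    return ElutionProfile(volumes=v, absorbance=a)


def generate_toy_complex(n_contact_pairs: int, separation: float = 4.0,
                         seed: Optional[int] = 0, n_extra: int = 3
                         ) -> list[AtomRecord]:
    """Two chains with exactly ``n_contact_pairs`` heavy-atom contacts.

    Contact residue pairs sit ``separation`` Å apart (must stay under the
    4.5 Å contact cutoff); every other cross-chain atom pair is farther
    than 8 Å.  One heavy atom per residue; coordinates get a small seeded
    jitter so equal seeds give identical structures.
    """
    if separation <= 0:
        raise ValidationError("separation must be > 0")
    if separation >= 4.4:
        raise ValidationError(
            f"separation {separation} Å cannot realise contacts under the "
            "4.5 Å cutoff")
    if n_contact_pairs < 0:
        raise ValidationError("n_contact_pairs must be >= 0")
    rng = np.random.default_rng(seed)

    def jitter():
        return rng.uniform(-0.02, 0.02)

    atoms = []
    res = 0
    for i in range(n_contact_pairs):
        res += 1
        x = 12.0 * i
        atoms.append(AtomRecord("A", res, "ALA", "CA", x + jitter(),
                                jitter(), jitter(), "C"))
        atoms.append(AtomRecord("B", res, "ALA", "CA", x + jitter(),
                                separation + jitter(), jitter(), "C"))
    for j in range(n_extra):
        res += 1
        x = 12.0 * (n_contact_pairs + j)
        atoms.append(AtomRecord("A", res, "GLY", "CA", x + jitter(),
                                40.0 + jitter(), jitter(), "C"))
        atoms.append(AtomRecord("B", res, "GLY", "CA", x + jitter(),
                                -40.0 + jitter(), jitter(), "C"))
    return atoms
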