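"""Specificity-determining position (hotspot) discovery.

Given a labeled multiple alignment of GTPases (binders vs nonbinders of an
effector), find reference-numbered positions that are highly conserved
within the binders and whose nonbinder residues deviate in physicochemical
class, excluding the switch I/II regions, which are nearly identical across
the family and therefore carry no selectivity information.  Nearby
positions are grouped into hotspot sites.

Thresholds are explicit and configurable: a column is a candidate when the
binder consensus frequency reaches ``theta_cons`` and at least
``theta_dev`` of nonbinders differ in class from that consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LabelingError, ValidationError
from .sequences import Alignment, RegionSet

#: default physicochemical classes (disjoint cover of the 20 codes)
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFGILMPVW"),
    "polar": frozenset("HNQSTY"),
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
}


def residue_class(aa: str, classes=None) -> str:
    classes = classes or DEFAULT_CLASSES
    for name, members in classes.items():
        if aa in members:
            return name
    return "gap"  # '-' and anything non-standard


@dataclass
class HotspotConfig:
    """Tunable rule for what counts as a discriminating column."""

    theta_cons: float = 0.8    # min binder consensus frequency
    theta_dev: float = 0.6     # min fraction of class-deviating nonbinders
    group_window: int = 7      # max reference-position gap inside one site
    excluded: RegionSet = field(default_factory=RegionSet.switch_regions)
    classes: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))

    def __post_init__(self):
        for name, val in (("theta_cons", self.theta_cons),
                          ("theta_dev", self.theta_dev)):
            if not 0.0 < val <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1], got {val}")
        covered = sorted("".join(sorted(m)) for m in self.classes.values())
        flat = "".join(covered)
        if len(set(flat)) != len(flat) or set(flat) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValidationError("classes must partition the 20 residue codes")


@dataclass(frozen=True)
class ColumnStats:
    """Per-column conservation/deviation summary."""

    column: int              # 1-based alignment column
    ref_position: int        # reference residue number
    consensus: str           # binder consensus residue ('-' possible)
    f_b: float               # binder consensus frequency
    d: float                 # class-deviating nonbinder fraction
    candidate: bool


@dataclass(frozen=True)
class HotspotSite:
    """A group of nearby discriminating reference positions."""

    positions: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])

    def __str__(self) -> str:
        return "/".join(str(p) for p in self.positions)


def _split_rows(alignment: Alignment):
    binders, nonbinders = [], []
    for rec, gapped in alignment.rows:
        if rec.label == "binder":
            binders.append(gapped)
        elif rec.label == "nonbinder":
            nonbinders.append(gapped)
    if not binders or not nonbinders:
        raise LabelingError(
            "alignment needs at least one binder and one nonbinder row "
            f"(found {len(binders)} binders, {len(nonbinders)} nonbinders)"
        )
    return binders, nonbinders


def column_statistics(alignment: Alignment,
                      config: HotspotConfig | None = None) -> list[ColumnStats]:
    """Conservation/deviation statistics for every reference-numbered column.

    Columns where the reference row is gapped are skipped (they have no
    reference name).  Gaps in other rows count as a distinct symbol: a gap
    is never the basis of conservation and always deviates in class.
    """
    config = config or HotspotConfig()
    binders, nonbinders = _split_rows(alignment)
    stats = []
    for col, ref_pos in alignment.column_to_ref.items():
        b_res = [row[col - 1] for row in binders]
        n_res = [row[col - 1] for row in nonbinders]
        counts: dict[str, int] = {}
        for aa in b_res:
            counts[aa] = counts.get(aa, 0) + 1
        # ties broken alphabetically for deterministic reports
        consensus = min(
            (aa for aa in counts if counts[aa] == max(counts.values())),
        )
        f_b = counts[consensus] / len(b_res)
        cons_class = residue_class(consensus, config.classes)
        d = sum(
            1 for aa in n_res
            if aa == "-" or residue_class(aa, config.classes) != cons_class
        ) / len(n_res)
        candidate = (
            consensus != "-"
            and f_b >= config.theta_cons
            and d >= config.theta_dev
            and ref_pos not in config.excluded
        )
        stats.append(ColumnStats(col, ref_pos, consensus, f_b, d, candidate))
    return stats


def find_discriminating_positions(alignment: Alignment,
                                  config: HotspotConfig | None = None
                                  ) -> list[int]:
    """Ascending reference positions that pass the discrimination rule."""
    return [s.ref_position for s in column_statistics(alignment, config)
            if s.candidate]


def group_sites(positions: list[int],
                config: HotspotConfig | None = None) -> list[HotspotSite]:
    """Greedy left-to-right grouping of nearby positions into sites."""
    config = config or HotspotConfig()
    if sorted(positions) != list(positions):
        raise ValidationError("positions must be ascending")
    sites: list[HotspotSite] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[-1] > config.group_window:
            sites.append(HotspotSite(tuple(current)))
            current = []
        current.append(pos)
    if current:
        sites.append(HotspotSite(tuple(current)))
    return sites


def find_hotspots(alignment: Alignment,
                  config: HotspotConfig | None = None) -> list[HotspotSite]:
    """End-to-end: discriminating positions grouped into hotspot sites."""
    return group_sites(find_discriminating_positions(alignment, config), config)


def stats_table(stats: list[ColumnStats]):
    """Column statistics as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [{"column": s.column, "ref_pos": s.ref_position,
          "consensus": s.consensus, "f_b": s.f_b, "d": s.d,
          "candidate": s.candidate} for s in stats]
    )
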