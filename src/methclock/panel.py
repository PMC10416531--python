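"""Target-panel registry for CG/CA methylation markers.

A *panel* is an ordered list of :class:`TargetCytosine` records describing
the cytosines interrogated by a targeted bisulfite assay: genomic location
(1-based, on the cytosine itself), sequence context (CG or CA), which DNA
strands the assay reads (Watson, Crick, or both), and which epigenetic
clocks the marker feeds.  QC spike-in markers (unmethylated lambda phage
amplicons) are ordinary panel rows on the reserved chromosome ``lambda``
with an empty clock set, so downstream quantification needs no special
case.

Panels are stored as tab-separated text with a fixed header
(``marker_id  chrom  pos  context  strands  region  clocks``); lines
starting with ``#`` are comments.  Coordinates are 1-based throughout the
package; conversion to 0-based half-open happens only at format
boundaries (see :mod:`methclock.quantify` for Bismark coverage I/O).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID_CONTEXTS = frozenset({"CG", "CA"})
VALID_STRANDS = frozenset({"W", "C", "both"})
#: Canonical clock identifiers: two chronological-age clocks, a
#: pace-of-aging estimator and a mortality risk score.
CLOCK_NAMES = ("HANNUM", "VISAGE", "POAM", "MRS")
#: Reserved chromosome name for unmethylated lambda spike-in controls.
LAMBDA_CHROM = "lambda"

PANEL_COLUMNS = ("marker_id", "chrom", "pos", "context", "strands", "region", "clocks")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class TargetCytosine:
    """One target marker of the panel.

    Parameters
    ----------
    marker_id
        CpG identifier, e.g. ``"cg16867657"``. Unique within a panel.
    chrom
        Chromosome name; ``"lambda"`` marks a conversion-control spike-in.
    pos
        1-based genomic coordinate of the cytosine.
    context
        Dinucleotide context, ``"CG"`` or ``"CA"``.
    strands
        Strands available to the assay: ``"W"``, ``"C"`` or ``"both"``.
    region
        Free-text locus / gene label.
    clocks
        Clock memberships, a subset of :data:`CLOCK_NAMES`.  Empty for
        QC-only markers.
    """

    marker_id: str
    chrom: str
    pos: int
    context: str
    strands: str
    region: str = ""
    clocks: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise PanelError("marker_id must be non-empty")
        if self.pos < 1:
            raise PanelError(f"marker {self.marker_id!r}: pos must be >= 1, got {self.pos}")
        if self.context not in VALID_CONTEXTS:
            raise PanelError(
                f"marker {self.marker_id!r}: context must be one of {sorted(VALID_CONTEXTS)}, "
                f"got {self.context!r}"
            )
        if self.strands not in VALID_STRANDS:
            raise PanelError(
                f"marker {self.marker_id!r}: strands must be one of {sorted(VALID_STRANDS)}, "
                f"got {self.strands!r}"
            )
        unknown = set(self.clocks) - set(CLOCK_NAMES)
        if unknown:
            raise PanelError(f"marker {self.marker_id!r}: unknown clocks {sorted(unknown)}")

    @property
    def is_control(self) -> bool:
        """Whether this row is a QC spike-in rather than a clock marker."""
        return self.chrom == LAMBDA_CHROM


@dataclass(frozen=True)
class ClockPanel:
    """The ordered marker list of one clock."""

    name: str
    markers: tuple

    def __post_init__(self) -> None:
        if not self.markers:
            raise PanelError(f"clock panel {self.name!r} has no markers")
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if list(self.markers).count(m) > 1})
            raise PanelError(f"clock panel {self.name!r} has duplicate markers: {dupes}")


def load_panel(path) -> list[TargetCytosine]:
    """Load and validate a panel TSV.

    Row order is preserved.  Raises :class:`PanelError` naming the
    offending row for missing columns, duplicate ids, unparseable
    positions, or invalid context/strand values.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        raise PanelError(f"{path}: empty panel file")
    missing = set(PANEL_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise PanelError(f"{path}: missing required columns {sorted(missing)}")

    markers: list[TargetCytosine] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):
        mid = (row["marker_id"] or "").strip()
        if mid in seen:
            raise PanelError(f"{path} row {i}: duplicate marker_id {mid!r}")
        try:
            pos = int(row["pos"])
        except (TypeError, ValueError):
            raise PanelError(f"{path} row {i} ({mid!r}): unparseable pos {row['pos']!r}") from None
        clocks = frozenset(c for c in (row["clocks"] or "").split(";") if c)
        try:
            marker = TargetCytosine(
                marker_id=mid,
                chrom=(row["chrom"] or "").strip(),
                pos=pos,
                context=(row["context"] or "").strip(),
                strands=(row["strands"] or "").strip(),
                region=(row["region"] or "").strip(),
                clocks=clocks,
            )
        except PanelError as exc:
            raise PanelError(f"{path} row {i}: {exc}") from None
        seen.add(mid)
        markers.append(marker)
    return markers


def write_panel(markers: Iterable[TargetCytosine], path, header_comment: str | None = None) -> None:
    """Write a panel TSV that :func:`load_panel` round-trips exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for m in markers:
            writer.writerow(
                [
                    m.marker_id,
                    m.chrom,
                    m.pos,
                    m.context,
                    m.strands,
                    m.region,
                    ";".join(sorted(m.clocks)),
                ]
            )


def clock_panels(markers: Sequence[TargetCytosine]) -> dict[str, ClockPanel]:
    """Group panel markers into per-clock :class:`ClockPanel` objects.

    Marker order within each clock follows panel row order.  QC-only
    markers (empty clock set) are skipped.
    """
    by_clock: dict[str, list[str]] = {}
    for m in markers:
        for c in m.clocks:
            by_clock.setdefault(c, []).append(m.marker_id)
    return {name: ClockPanel(name, tuple(ids)) for name, ids in by_clock.items()}


def union_size(panels: Sequence[ClockPanel]) -> int:
    """Number of distinct markers across a set of clock panels."""
    if not panels:
        raise PanelError("union_size requires at least one clock panel")
    return len(set().union(*(set(p.markers) for p in panels)))


def strand_breakdown(markers: Sequence[TargetCytosine]) -> dict[str, int]:
    """Tally markers by strand availability.

    Returns a dict with keys ``both``, ``W``, ``C``; values always sum to
    ``len(markers)``.
    """
    counts = {"both": 0, "W": 0, "C": 0}
    for m in markers:
        counts[m.strands] += 1
    return counts


def design_success_rate(panel: Sequence[TargetCytosine], designed_ids: Iterable[str]) -> float:
    """Percentage of non-control panel markers covered by an assay design.

    ``designed_ids`` are the markers for which primer/probe design
    succeeded; ids outside the panel are ignored.
    """
    targets = {m.marker_id for m in panel if not m.is_control}
    if not targets:
        raise PanelError("panel contains no non-control markers")
    return 100.0 * len(targets & set(designed_ids)) / len(targets)
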