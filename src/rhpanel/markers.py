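"""Marker definitions and per-chromosome marker maps for the D genome.

An RH panel is scored at named marker loci (SSR, RJM or EST assays), each
assigned to one of the seven D-genome chromosomes (1D..7D) and optionally to
a cytogenetic deletion bin, a physical position in bp and a genetic position
in cM.  All physical coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

D_CHROMOSOMES: tuple[str, ...] = ("1D", "2D", "3D", "4D", "5D", "6D", "7D")
MARKER_SYSTEMS: tuple[str, ...] = ("SSR", "RJM", "EST")


@dataclass(frozen=True)
class MarkerDef:
    """A single marker locus."""

    marker_id: str
    chromosome: str
    bin_label: str | None = None
    pos_bp: int | None = None
    pos_cM: float | None = None
    system: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in D_CHROMOSOMES:
            raise ValueError(
                f"unknown chromosome {self.chromosome!r} for marker "
                f"{self.marker_id!r}; expected one of {D_CHROMOSOMES}"
            )
        if self.pos_bp is not None and self.pos_bp < 0:
            raise ValueError(f"negative pos_bp for marker {self.marker_id!r}")
        if self.system is not None and self.system not in MARKER_SYSTEMS:
            raise ValueError(
                f"unknown marker system {self.system!r}; expected one of "
                f"{MARKER_SYSTEMS}"
            )


@dataclass
class MarkerMap:
    """Ordered marker definitions plus chromosome geometry.

    Markers are kept grouped by chromosome and sorted by ``pos_bp`` within a
    chromosome when positions are present.  ``chrom_length_bp`` and
    ``centromere_bp`` give the physical length and centromere position of
    each chromosome carrying markers (required by the simulator; optional
    for purely analytical use).
    """

    markers: list[MarkerDef]
    chrom_length_bp: dict[str, int] = field(default_factory=dict)
    centromere_bp: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker ids: {dup}")
        for chrom, cen in self.centromere_bp.items():
            length = self.chrom_length_bp.get(chrom)
            if length is not None and not 0 <= cen < length:
                raise ValueError(
                    f"centromere_bp of {chrom} must lie in [0, {length})"
                )
        self._sort_markers()

    def _sort_markers(self) -> None:
        by_chrom: dict[str, list[MarkerDef]] = {c: [] for c in D_CHROMOSOMES}
        for m in self.markers:
            by_chrom[m.chromosome].append(m)
        out: list[MarkerDef] = []
        for chrom in D_CHROMOSOMES:
            group = by_chrom[chrom]
            pos = [m.pos_bp for m in group if m.pos_bp is not None]
            if pos and pos != sorted(pos):
                warnings.warn(
                    f"markers on {chrom} not sorted by pos_bp; sorting",
                    stacklevel=3,
                )
            group.sort(key=lambda m: (m.pos_bp is None, m.pos_bp or 0))
            out.extend(group)
        self.markers = out

    # -- lookups -------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def chromosomes(self) -> list[str]:
        seen = {m.chromosome for m in self.markers}
        return [c for c in D_CHROMOSOMES if c in seen]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def __contains__(self, marker_id: str) -> bool:
        return any(m.marker_id == marker_id for m in self.markers)

    def markers_on(self, chromosome: str) -> list[MarkerDef]:
        return [m for m in self.markers if m.chromosome == chromosome]

    def chromosome_of(self, marker_id: str) -> str:
        return self[marker_id].chromosome

    def subset(self, marker_ids: Iterable[str]) -> "MarkerMap":
        keep = set(marker_ids)
        return MarkerMap(
            markers=[m for m in self.markers if m.marker_id in keep],
            chrom_length_bp=dict(self.chrom_length_bp),
            centromere_bp=dict(self.centromere_bp),
        )


# Approximate physical scale of the Ae. tauschii D genome (~4.3 Gb over
# seven chromosomes); lengths are round figures adequate for simulation,
# with metacentric-ish centromeres.
DEFAULT_CHROM_LENGTH_BP: dict[str, int] = {
    "1D": 495_000_000,
    "2D": 655_000_000,
    "3D": 620_000_000,
    "4D": 510_000_000,
    "5D": 565_000_000,
    "6D": 495_000_000,
    "7D": 640_000_000,
}
DEFAULT_CENTROMERE_BP: dict[str, int] = {
    c: length // 2 for c, length in DEFAULT_CHROM_LENGTH_BP.items()
}


def uniform_marker_map(
    n_per_chromosome: int = 5,
    chromosomes: Sequence[str] = D_CHROMOSOMES,
    system: str = "SSR",
    chrom_length_bp: dict[str, int] | None = None,
    centromere_bp: dict[str, int] | None = None,
) -> MarkerMap:
    """Evenly spaced markers on each chromosome.

    Mirrors the whole-genome screening design of the study panel: five SSR
    loci per D-genome chromosome, one per major deletion bin.  Markers are
    placed at the midpoints of ``n_per_chromosome`` equal physical segments.
    """
    lengths = dict(chrom_length_bp or DEFAULT_CHROM_LENGTH_BP)
    cens = dict(
        centromere_bp or {c: lengths[c] // 2 for c in lengths}
    )
    markers = []
    for chrom in chromosomes:
        length = lengths[chrom]
        for i in range(n_per_chromosome):
            pos = int((i + 0.5) * length / n_per_chromosome)
            markers.append(
                MarkerDef(
                    marker_id=f"{system.lower()}_{chrom}_{i + 1:02d}",
                    chromosome=chrom,
                    bin_label=f"{chrom}bin{i + 1}",
                    pos_bp=pos,
                    system=system,
                )
            )
    return MarkerMap(
        markers=markers,
        chrom_length_bp={c: lengths[c] for c in chromosomes},
        centromere_bp={c: cens[c] for c in chromosomes},
    )
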