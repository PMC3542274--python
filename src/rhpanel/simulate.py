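"""Generative model of an irradiated-seed RH panel with a chimeric germline.

The simulated experiment mirrors the construction of a seed-irradiation
radiation hybrid panel: a hexaploid seed is gamma-irradiated, the embryo's
germline comprises G independent cell lineages (the genetically effective
cell number, GECN), each lineage independently accumulates chromosome breaks
and loses acentric fragments on both homologs of each D-genome chromosome,
and the surviving RH0 plant is backcrossed so that every RH1 sibling
inherits exactly one D homolog drawn from one germline cell.  A deletion
present in a single cell on a single homolog is therefore transmitted to
each sibling with probability 1/(2G) — the segregation law that the GECN
estimator inverts.

Breakage is a homogeneous Poisson process along each homolog at rate
``break_rate_per_Gb_per_Gy * dose``; each resulting fragment that does not
carry the centromere is deleted with probability ``fragment_loss_prob``,
while the centric fragment is always retained (a viability convention: lines
keep most of each chromosome and marker loss stays at a few percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .genotype import GenotypeMatrix
from .markers import MarkerMap, uniform_marker_map

Interval = tuple[int, int]

#: Seedling survival anchors (dose Gy -> percent surviving after 1 month)
#: observed for 100-seed batches of the synthetic hexaploid donor.
SURVIVAL_ANCHORS: dict[float, float] = {
    150.0: 93.0,
    250.0: 83.0,
    350.0: 70.0,
    450.0: 44.0,
    550.0: 10.0,
}

#: Mean per-marker loss (percent) by dose observed on the real panel with
#: the 35-SSR whole-genome screen; used to calibrate the breakage model.
MARKER_LOSS_ANCHORS: dict[float, float] = {
    150.0: 1.2,
    250.0: 1.7,
    350.0: 1.9,
    450.0: 2.4,
}


def survival_curve(
    dose_Gy: float, anchors: Mapping[float, float] | None = None
) -> float:
    """Percent seedling survival at ``dose_Gy``.

    Piecewise-linear interpolation through the dose anchors plus the
    control point (0 Gy, 100%).  Doses outside [0, max anchor] raise.
    """
    anchors = dict(anchors) if anchors is not None else dict(SURVIVAL_ANCHORS)
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if len(set(anchors)) != len(anchors):  # dict already dedups; keep guard
        raise ValueError("anchor doses must be distinct")
    anchors.setdefault(0.0, 100.0)
    doses = np.array(sorted(anchors))
    if not 0.0 <= dose_Gy <= doses[-1]:
        raise ValueError(
            f"dose {dose_Gy} Gy outside anchor hull [0, {doses[-1]}]; "
            "refusing to extrapolate"
        )
    vals = np.array([anchors[d] for d in doses])
    return float(np.interp(dose_Gy, doses, vals))


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelScenario:
    """Parameters of one simulated panel.

    Defaults reproduce the study conditions of the real panel: 450 Gy seed
    dose, 312 RH1 families averaging 4.8 siblings (~1,510 lines), a
    germline of G = 5 effective cells, breakage/loss rates calibrated so
    per-marker loss lands on the observed 1.2-2.4% dose curve, and a 1%
    ambiguous-call (missing) rate.
    """

    dose_Gy: float = 450.0
    n_families: int = 312
    siblings_per_family: int | float = 4.8
    G: int = 5
    break_rate_per_Gb_per_Gy: float = 0.01775
    fragment_loss_prob: float = 0.04058
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.dose_Gy < 0 or self.break_rate_per_Gb_per_Gy < 0:
            raise ValueError("dose and break rate must be non-negative")
        if not 0.0 <= self.fragment_loss_prob <= 1.0:
            raise ValueError("fragment_loss_prob must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# germline structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GermlineCell:
    """Deletion realization of one germline lineage.

    ``deletions[chrom][homolog]`` is a sorted tuple of non-overlapping
    half-open bp intervals deleted on that homolog.
    """

    deletions: Mapping[str, tuple[tuple[Interval, ...], tuple[Interval, ...]]]

    def homolog_deletions(self, chrom: str, homolog: int) -> tuple[Interval, ...]:
        return self.deletions.get(chrom, ((), ()))[homolog]


@dataclass(frozen=True)
class RH0Plant:
    """An irradiated plant: G independent germline cells."""

    G: int
    cells: tuple[GermlineCell, ...]
    dose_Gy: float

    def __post_init__(self) -> None:
        if len(self.cells) != self.G:
            raise ValueError("number of cells must equal G")


@dataclass(frozen=True)
class RH1Line:
    """One backcross progeny: a single transmitted D homolog."""

    line_id: str
    family_id: str
    source_cell: int
    source_homolog: int
    calls: tuple[float, ...]  # per marker: 1.0 retained / 0.0 lost


def _merge_intervals(intervals: list[Interval]) -> tuple[Interval, ...]:
    if not intervals:
        return ()
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


def _covers(intervals: Sequence[Interval], pos: int) -> bool:
    for s, e in intervals:
        if s <= pos < e:
            return True
        if s > pos:
            break
    return False


def simulate_rh0(
    scenario: PanelScenario,
    marker_map: MarkerMap,
    rng: np.random.Generator | int,
) -> RH0Plant:
    """Draw the chimeric germline of one irradiated plant.

    Each of the G cells independently receives Poisson breaks on each
    homolog of each chromosome; each acentric fragment is deleted with
    probability ``fragment_loss_prob``; the centric fragment survives.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not marker_map.chrom_length_bp:
        raise ValueError("marker map lacks chromosome lengths")
    rate_per_bp = scenario.break_rate_per_Gb_per_Gy * scenario.dose_Gy / 1e9
    cells = []
    for _ in range(scenario.G):
        dels: dict[str, tuple[tuple[Interval, ...], tuple[Interval, ...]]] = {}
        for chrom, length in marker_map.chrom_length_bp.items():
            cen = marker_map.centromere_bp[chrom]
            homologs = []
            for _h in range(2):
                n_breaks = rng.poisson(rate_per_bp * length)
                lost: list[Interval] = []
                if n_breaks > 0:
                    cuts = np.sort(rng.integers(0, length, size=n_breaks))
                    bounds = [0, *cuts.tolist(), length]
                    for s, e in zip(bounds[:-1], bounds[1:]):
                        if s == e:
                            continue
                        if s <= cen < e:
                            continue  # centric fragment always retained
                        if rng.random() < scenario.fragment_loss_prob:
                            lost.append((s, e))
                homologs.append(_merge_intervals(lost))
            dels[chrom] = (homologs[0], homologs[1])
        cells.append(GermlineCell(deletions=dels))
    return RH0Plant(G=scenario.G, cells=tuple(cells), dose_Gy=scenario.dose_Gy)


def simulate_rh1_family(
    rh0: RH0Plant,
    n_siblings: int,
    marker_map: MarkerMap,
    rng: np.random.Generator | int,
    family_id: str = "F1",
) -> list[RH1Line]:
    """Backcross progeny of one RH0 plant.

    Each sibling draws a source cell uniformly from the G germline cells and
    one of that cell's two homologs uniformly; its calls reflect the
    deletions of the transmitted homolog only, so any single-cell
    single-homolog deletion is carried with probability 1/(2G).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if n_siblings < 0:
        raise ValueError("n_siblings must be >= 0")
    lines = []
    for k in range(n_siblings):
        cell_idx = int(rng.integers(0, rh0.G))
        homolog = int(rng.integers(0, 2))
        cell = rh0.cells[cell_idx]
        calls = []
        for m in marker_map.markers:
            dels = cell.homolog_deletions(m.chromosome, homolog)
            lost = m.pos_bp is not None and _covers(dels, m.pos_bp)
            calls.append(0.0 if lost else 1.0)
        lines.append(
            RH1Line(
                line_id=f"{family_id}_{k + 1:03d}",
                family_id=family_id,
                source_cell=cell_idx,
                source_homolog=homolog,
                calls=tuple(calls),
            )
        )
    return lines


def genotype_with_noise(
    lines: Sequence[RH1Line],
    marker_map: MarkerMap,
    missing_rate: float,
    rng: np.random.Generator | int,
) -> GenotypeMatrix:
    """Score the lines, replacing each true call by missing with
    probability ``missing_rate``.

    PCR failure produces an ambiguous result recorded as missing; a true
    retained call is never flipped to lost or vice versa (the multiplexed
    control band guards against exactly that).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    grid = np.array([line.calls for line in lines], dtype=float)
    grid = grid.reshape(len(lines), len(marker_map))
    if missing_rate > 0 and grid.size:
        mask = rng.random(grid.shape) < missing_rate
        grid[mask] = np.nan
    return GenotypeMatrix(
        grid,
        [line.line_id for line in lines],
        marker_map.marker_ids,
        {line.line_id: line.family_id for line in lines},
    )


def spiked_rh0(
    G: int,
    marker_map: MarkerMap,
    rng: np.random.Generator | int,
    loci: Sequence[str] | None = None,
    dose_Gy: float = 450.0,
) -> RH0Plant:
    """A germline with exactly one engineered deletion per locus.

    For each requested marker locus one germline cell and one homolog are
    drawn uniformly and given a minimal deletion covering that marker.
    Every deletion is therefore single-cell and single-homolog by
    construction — the regime in which the segregation-ratio GECN estimator
    is derived — making this the generator of choice for estimator
    parameter-recovery studies, free of the carrier-count inflation that
    dose-driven breakage can produce when independent deletions hit the
    same locus in several cells.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if G < 1:
        raise ValueError("G must be >= 1")
    ids = list(loci) if loci is not None else marker_map.marker_ids
    pending: list[dict[str, tuple[list[Interval], list[Interval]]]] = [
        {} for _ in range(G)
    ]
    for mid in ids:
        m = marker_map[mid]
        if m.pos_bp is None:
            raise ValueError(f"marker {mid!r} has no physical position")
        c = int(rng.integers(0, G))
        h = int(rng.integers(0, 2))
        pending[c].setdefault(m.chromosome, ([], []))[h].append(
            (m.pos_bp, m.pos_bp + 1)
        )
    cells = []
    for c in range(G):
        dels = {
            chrom: (_merge_intervals(h0), _merge_intervals(h1))
            for chrom, (h0, h1) in pending[c].items()
        }
        cells.append(GermlineCell(deletions=dels))
    return RH0Plant(G=G, cells=tuple(cells), dose_Gy=dose_Gy)


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueDeletion:
    family_id: str
    cell: int
    homolog: int
    chromosome: str
    start_bp: int
    end_bp: int


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    G: int
    marker_order: list[str]
    rh0_deletions: list[TrueDeletion]
    line_source: dict[str, tuple[str, int, int]]  # line -> (family, cell, hom)
    line_deletions: dict[str, list[tuple[str, int, int]]]  # line -> (chrom, s, e)


@dataclass
class PanelSimulation:
    matrix: GenotypeMatrix
    family_of: dict[str, str]
    truth: TruthRecord


def _family_sizes(
    scenario: PanelScenario, rng: np.random.Generator
) -> list[int]:
    n = scenario.n_families
    s = scenario.siblings_per_family
    if isinstance(s, int) or float(s).is_integer():
        return [int(s)] * n
    # Poisson family sizes around the target mean, clipped to >= 1 sibling
    # (a family with zero recovered progeny would not enter the panel).
    return [max(1, int(k)) for k in rng.poisson(float(s), size=n)]


def simulate_panel(
    scenario: PanelScenario, marker_map: MarkerMap | None = None
) -> PanelSimulation:
    """Simulate a whole RH1 panel plus its ground truth.

    Child RNG streams are spawned deterministically per family and for the
    scoring-noise stage, so identical (scenario, seed) pairs reproduce the
    panel bitwise.
    """
    if marker_map is None:
        marker_map = uniform_marker_map()
    root = np.random.SeedSequence(scenario.seed)
    size_seq, noise_seq, *family_seqs = root.spawn(scenario.n_families + 2)
    sizes = _family_sizes(scenario, np.random.default_rng(size_seq))

    all_lines: list[RH1Line] = []
    truth = TruthRecord(
        G=scenario.G,
        marker_order=marker_map.marker_ids,
        rh0_deletions=[],
        line_source={},
        line_deletions={},
    )
    for f_idx, (fam_seq, n_sib) in enumerate(zip(family_seqs, sizes)):
        fam_id = f"FAM{f_idx + 1:04d}"
        rng = np.random.default_rng(fam_seq)
        rh0 = simulate_rh0(scenario, marker_map, rng)
        for c_idx, cell in enumerate(rh0.cells):
            for chrom, (h0, h1) in cell.deletions.items():
                for hom, dels in enumerate((h0, h1)):
                    for s, e in dels:
                        truth.rh0_deletions.append(
                            TrueDeletion(fam_id, c_idx, hom, chrom, s, e)
                        )
        lines = simulate_rh1_family(rh0, n_sib, marker_map, rng, fam_id)
        for line in lines:
            truth.line_source[line.line_id] = (
                fam_id,
                line.source_cell,
                line.source_homolog,
            )
            cell = rh0.cells[line.source_cell]
            dels = []
            for chrom in marker_map.chrom_length_bp:
                for s, e in cell.homolog_deletions(chrom, line.source_homolog):
                    dels.append((chrom, s, e))
            truth.line_deletions[line.line_id] = dels
        all_lines.extend(lines)

    matrix = genotype_with_noise(
        all_lines,
        marker_map,
        scenario.missing_rate,
        np.random.default_rng(noise_seq),
    )
    return PanelSimulation(
        matrix=matrix, family_of=dict(matrix.family_of), truth=truth
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def expected_marker_loss(
    scenario: PanelScenario, marker_map: MarkerMap
) -> float:
    """Closed-form expected per-marker loss fraction in RH1 lines.

    A marker ends up on an acentric fragment iff at least one break falls
    between it and the centromere, and is then deleted with probability
    ``fragment_loss_prob``; transmission averages over cells and homologs
    without changing the marginal rate.
    """
    lam = scenario.break_rate_per_Gb_per_Gy * scenario.dose_Gy / 1e9
    probs = []
    for m in marker_map.markers:
        if m.pos_bp is None:
            continue
        d = abs(m.pos_bp - marker_map.centromere_bp[m.chromosome])
        probs.append(
            scenario.fragment_loss_prob * (1.0 - math.exp(-lam * d))
        )
    if not probs:
        raise ValueError("no positioned markers to average over")
    return float(np.mean(probs))


def calibrate_scenario(
    marker_map: MarkerMap | None = None,
    loss_anchors: Mapping[float, float] | None = None,
    base: PanelScenario | None = None,
) -> PanelScenario:
    """Fit breakage parameters to the observed dose -> marker-loss curve.

    Least-squares fit of (break_rate_per_Gb_per_Gy, fragment_loss_prob) so
    that ``expected_marker_loss`` matches the percent-loss anchors at each
    dose.  Returns a scenario with the fitted rates (other fields from
    ``base`` or the defaults).
    """
    if marker_map is None:
        marker_map = uniform_marker_map()
    anchors = dict(loss_anchors or MARKER_LOSS_ANCHORS)
    base = base or PanelScenario()
    doses = np.array(sorted(anchors))
    targets = np.array([anchors[d] / 100.0 for d in doses])

    def residuals(params: np.ndarray) -> np.ndarray:
        rate, floss = params
        preds = [
            expected_marker_loss(
                replace(
                    base,
                    dose_Gy=float(d),
                    break_rate_per_Gb_per_Gy=float(rate),
                    fragment_loss_prob=float(min(max(floss, 0.0), 1.0)),
                ),
                marker_map,
            )
            for d in doses
        ]
        return np.asarray(preds) - targets

    fit = optimize.least_squares(
        residuals,
        x0=np.array([0.02, 0.05]),
        bounds=([1e-6, 1e-4], [10.0, 1.0]),
    )
    rate, floss = fit.x
    return replace(
        base,
        break_rate_per_Gb_per_Gy=float(rate),
        fragment_loss_prob=float(floss),
    )
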