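"""Two-point RH analysis and anchored iterative framework mapping.

Model
-----
The haploid equal-retention two-point model: between two markers a radiation
break occurs in a given line with probability theta (the breakage fraction);
each fragment is retained with probability r.  Per-line pattern
probabilities are

    P(R, R) = (1 - theta) r + theta r^2
    P(R, L) = P(L, R) = theta r (1 - r)
    P(L, L) = (1 - theta)(1 - r) + theta (1 - r)^2

Distances are expressed in centiRays, cR = -100 ln(1 - theta), so 1 cR is a
1% breakage probability at the panel's dose.

Ordering
--------
Orders are scored with the Markov-chain multipoint likelihood.  Because the
chain factorizes over adjacent pairs, an order's log-likelihood is the sum
of adjacent-pair joint log-likelihoods (each at its own breakage MLE) minus
the marginal log-likelihoods of the interior markers — exact when no calls
are missing, a pairwise-complete composite likelihood otherwise.  Framework
construction follows the anchored iterative procedure: anchors are fixed,
each unplaced marker is assigned to the interval it fits best, the
placement is accepted only when the best interval beats the runner-up by a
log10-likelihood margin (the LOD threshold, default 3), accepted markers
are re-ordered within their interval (exhaustively for small groups, by
greedy insertion plus pairwise flips and sliding-window polish otherwise),
and the pass repeats with the leftovers until nothing more can be placed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .markers import MarkerMap

LN10 = math.log(10.0)
_THETA_UNLINKED = 1.0 - 1e-12


# ---------------------------------------------------------------------------
# theta <-> centiRay
# ---------------------------------------------------------------------------


def cr_from_theta(theta: float) -> float:
    """Cox transform: cR = -100 ln(1 - theta); infinite at theta = 1."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    if theta >= 1.0:
        return math.inf
    return -100.0 * math.log1p(-theta)


def theta_from_cr(cr: float) -> float:
    if cr < 0:
        raise ValueError("cR must be >= 0")
    return -math.expm1(-cr / 100.0)


# ---------------------------------------------------------------------------
# two-point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    theta: float
    lod: float
    cR: float
    n_informative: int
    linked: bool


def _theta_mle(a: float, b: float, c: float, r: float) -> float:
    """Closed-form MLE of theta from counts a=RR, b=discordant, c=LL.

    The score equation is quadratic: p r n theta^2 - (b + a p + c r) theta
    + b = 0 with p = 1 - r; the root in [0, 1] is the smaller one.
    """
    if b == 0:
        return 0.0
    if a + c == 0:
        return 1.0
    p = 1.0 - r
    A = p * r * (a + b + c)
    B = -(b + a * p + c * r)
    C = b
    disc = B * B - 4.0 * A * C
    disc = max(disc, 0.0)
    theta = (-B - math.sqrt(disc)) / (2.0 * A)
    return min(max(theta, 0.0), 1.0)


def _pair_loglik(a: float, b: float, c: float, r: float, theta: float) -> float:
    p = 1.0 - r
    ll = 0.0
    if a:
        ll += a * math.log(r * (1.0 - theta * p))
    if b:
        ll += b * math.log(theta * r * p) if theta > 0 else -math.inf
    if c:
        ll += c * math.log(p * (1.0 - theta * r))
    return ll


def two_point(
    matrix: GenotypeMatrix,
    marker_a: str,
    marker_b: str,
    retention: float | None = None,
) -> TwoPointResult:
    """Maximum-likelihood breakage fraction between two markers.

    Lines with a missing call at either marker are dropped pairwise.  LOD
    compares the MLE against theta = 1 (independent retention); theta at
    (numerically) 1 is flagged unlinked with infinite cR.
    """
    xa = matrix.marker_calls(marker_a)
    xb = matrix.marker_calls(marker_b)
    both = ~np.isnan(xa) & ~np.isnan(xb)
    if not both.any():
        raise ValueError(
            f"no line scored at both {marker_a!r} and {marker_b!r}"
        )
    xa, xb = xa[both], xb[both]
    a = int(np.sum((xa == 1) & (xb == 1)))
    b = int(np.sum(xa != xb))
    c = int(np.sum((xa == 0) & (xb == 0)))
    if retention is None:
        retention = float(np.concatenate([xa, xb]).mean())
    if not 0.0 < retention < 1.0:
        retention = min(max(retention, 1e-6), 1.0 - 1e-6)
    theta = _theta_mle(a, b, c, retention)
    ll_hat = _pair_loglik(a, b, c, retention, min(theta, _THETA_UNLINKED))
    # at theta = 1 the model reduces to independent retention
    ll_unlinked = (
        a * math.log(retention**2)
        + (b * math.log(retention * (1 - retention)) if b else 0.0)
        + c * math.log((1 - retention) ** 2)
    )
    lod = (ll_hat - ll_unlinked) / LN10
    linked = theta < _THETA_UNLINKED
    return TwoPointResult(
        marker_a=marker_a,
        marker_b=marker_b,
        theta=theta,
        lod=max(lod, 0.0),
        cR=cr_from_theta(theta) if linked else math.inf,
        n_informative=a + b + c,
        linked=linked,
    )


def estimate_retention(
    matrix: GenotypeMatrix,
    chromosome: str | None = None,
    marker_map: MarkerMap | None = None,
) -> float:
    """Mean per-marker retention frequency (1 - loss) over a chromosome's
    markers, or over all markers when no chromosome is given."""
    if chromosome is not None:
        if marker_map is None:
            raise ValueError("chromosome selection needs a marker map")
        ids = [
            m.marker_id
            for m in marker_map.markers_on(chromosome)
            if m.marker_id in matrix._marker_index
        ]
        if not ids:
            raise ValueError(f"no markers of {chromosome} in matrix")
        matrix = matrix.subset_markers(ids)
    retained = matrix.is_retained.sum(axis=0)
    scored = matrix.is_scored.sum(axis=0)
    if not (scored > 0).any():
        raise ValueError("no scored calls")
    per_marker = retained[scored > 0] / scored[scored > 0]
    return float(per_marker.mean())


# ---------------------------------------------------------------------------
# chain scorer: fast multipoint order likelihood
# ---------------------------------------------------------------------------


class ChainScorer:
    """Precomputed pairwise terms for O(n)-per-order likelihood scoring.

    score(order) = sum over adjacent pairs of the pair's joint
    log-likelihood at its breakage MLE, minus the marginal log-likelihood
    of every interior marker.  Natural-log units; divide differences by
    ln(10) for LOD margins.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        markers: Sequence[str],
        retention: float | None = None,
    ) -> None:
        self.markers = list(markers)
        self.index = {m: i for i, m in enumerate(self.markers)}
        sub = matrix.subset_markers(self.markers)
        X = sub.calls
        R = (X == 1.0).astype(float)
        L = (X == 0.0).astype(float)
        self.n_rr = R.T @ R
        self.n_ll = L.T @ L
        self.n_disc = R.T @ L + L.T @ R
        if retention is None:
            retention = estimate_retention(sub)
        self.r = min(max(retention, 1e-6), 1.0 - 1e-6)
        self._pair_terms()
        nR = R.sum(axis=0)
        nL = L.sum(axis=0)
        self.marg = nR * math.log(self.r) + nL * math.log(1.0 - self.r)

    def _pair_terms(self) -> None:
        r, p = self.r, 1.0 - self.r
        a, b, c = self.n_rr, self.n_disc, self.n_ll
        n = a + b + c
        A = p * r * n
        B = -(b + a * p + c * r)
        disc = np.maximum(B * B - 4.0 * A * b, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = (-B - np.sqrt(disc)) / (2.0 * A)
        theta = np.where(b == 0, 0.0, theta)
        theta = np.where((a + c) == 0, 1.0, theta)
        self.theta = np.clip(theta, 0.0, 1.0)
        th = np.clip(self.theta, 1e-300, _THETA_UNLINKED)
        with np.errstate(divide="ignore", invalid="ignore"):
            joint = (
                np.where(a > 0, a * np.log(r * (1.0 - th * p)), 0.0)
                + np.where(b > 0, b * np.log(th * r * p), 0.0)
                + np.where(c > 0, c * np.log(p * (1.0 - th * r)), 0.0)
            )
        self.joint = joint

    def pair_theta(self, m1: str, m2: str) -> float:
        return float(self.theta[self.index[m1], self.index[m2]])

    def score_ids(self, order: Sequence[str]) -> float:
        return self.score(np.fromiter(
            (self.index[m] for m in order), dtype=int, count=len(order)
        ))

    def score(self, order: np.ndarray) -> float:
        if len(order) < 2:
            return 0.0
        s = float(self.joint[order[:-1], order[1:]].sum())
        if len(order) > 2:
            s -= float(self.marg[order[1:-1]].sum())
        return s


# ---------------------------------------------------------------------------
# order search
# ---------------------------------------------------------------------------


def _search_segment(
    scorer: ChainScorer,
    free: list[int],
    left: int | None,
    right: int | None,
    exhaustive_limit: int = 8,
) -> list[int]:
    """Best order of ``free`` markers between fixed endpoints.

    Exhaustive for small groups; greedy insertion + adjacent/pairwise flips
    + sliding-window polish otherwise.  Deterministic: candidates are
    visited in sorted order and ties resolved toward the first-found
    (lexicographically smallest) order.
    """

    def full(seq: list[int]) -> np.ndarray:
        pre = [left] if left is not None else []
        post = [right] if right is not None else []
        return np.array(pre + seq + post, dtype=int)

    free = sorted(free)
    if len(free) <= 1:
        return free
    if len(free) <= exhaustive_limit:
        best, best_score = None, -math.inf
        for perm in permutations(free):
            s = scorer.score(full(list(perm)))
            if s > best_score + 1e-12:
                best, best_score = list(perm), s
        return best
    # greedy insertion
    seq: list[int] = []
    for m in free:
        best_pos, best_score = 0, -math.inf
        for pos in range(len(seq) + 1):
            s = scorer.score(full(seq[:pos] + [m] + seq[pos:]))
            if s > best_score + 1e-12:
                best_pos, best_score = pos, s
        seq.insert(best_pos, m)
    # pairwise flips + window polish until no improvement
    improved = True
    current = scorer.score(full(seq))
    while improved:
        improved = False
        for i in range(len(seq) - 1):
            for j in range(i + 1, len(seq)):
                cand = seq.copy()
                cand[i], cand[j] = cand[j], cand[i]
                s = scorer.score(full(cand))
                if s > current + 1e-12:
                    seq, current, improved = cand, s, True
        w = 4
        for start in range(0, max(1, len(seq) - w + 1)):
            window = seq[start : start + w]
            for perm in permutations(window):
                cand = seq[:start] + list(perm) + seq[start + w :]
                s = scorer.score(full(cand))
                if s > current + 1e-12:
                    seq, current, improved = cand, s, True
    return seq


def order_markers(
    matrix: GenotypeMatrix,
    markers: Sequence[str],
    retention: float | None = None,
    exhaustive_limit: int = 8,
) -> list[str]:
    """Best-scoring order of a marker set under the chain likelihood."""
    scorer = ChainScorer(matrix, markers, retention)
    idx = _search_segment(
        scorer,
        list(range(len(scorer.markers))),
        None,
        None,
        exhaustive_limit,
    )
    return [scorer.markers[i] for i in idx]


# ---------------------------------------------------------------------------
# retention-pattern bins
# ---------------------------------------------------------------------------


@dataclass
class Bins:
    groups: list[list[str]]
    conflicts: list[tuple[str, str]]  # contradictory pairs merged via wildcard


def bin_markers(matrix: GenotypeMatrix, markers: Sequence[str]) -> Bins:
    """Partition markers into retention-pattern bins.

    Two markers are pattern-identical when no line scored at both carries
    opposing calls (missing acts as a wildcard).  The relation is closed
    transitively (union-find); pairs inside one component that do
    contradict each other — possible under heavy missingness — are
    reported as conflicts.
    """
    markers = list(markers)
    sub = matrix.subset_markers(markers)
    X = sub.calls
    R = (X == 1.0).astype(float)
    L = (X == 0.0).astype(float)
    opposing = (R.T @ L) + (L.T @ R)
    parent = list(range(len(markers)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if opposing[i, j] == 0:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(len(markers)):
        comps.setdefault(find(i), []).append(i)
    groups = [
        [markers[i] for i in sorted(members)]
        for _, members in sorted(comps.items(), key=lambda kv: min(kv[1]))
    ]
    conflicts = []
    for members in comps.values():
        for i in members:
            for j in members:
                if i < j and opposing[i, j] > 0:
                    conflicts.append((markers[i], markers[j]))
    return Bins(groups=groups, conflicts=conflicts)


# ---------------------------------------------------------------------------
# framework map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapPosition:
    marker_id: str
    position_cR: float
    bin_id: int


@dataclass
class FrameworkMap:
    chromosome: str | None
    positions: list[MapPosition]  # cumulative cR, non-decreasing
    anchors: list[str]
    bins: list[list[str]]  # placed bins in map order
    total_cR: float
    obligate_breaks_total: int
    unplaced: list[str] = field(default_factory=list)

    @property
    def ordered_markers(self) -> list[str]:
        return [p.marker_id for p in self.positions]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker_id": p.marker_id,
                    "position_cR": p.position_cR,
                    "bin_id": p.bin_id,
                }
                for p in self.positions
            ]
        )


def obligate_breaks(calls: Sequence[float]) -> int:
    """Retained<->lost transitions along ordered markers in one line.

    Missing calls are skipped; chromosome ends contribute no break, so a
    terminal deletion counts one break and an interior deletion two.
    Requires at least two scored calls.
    """
    arr = np.asarray(calls, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ValueError("need >=2 scored calls to count obligate breaks")
    return int(np.sum(arr[1:] != arr[:-1]))


def obligate_breaks_total(
    matrix: GenotypeMatrix, ordered_markers: Sequence[str]
) -> int:
    """Sum of per-line obligate breaks; lines with <2 scored calls skip."""
    sub = matrix.subset_markers(ordered_markers)
    total = 0
    for i in range(sub.n_lines):
        row = sub.calls[i, :]
        row = row[~np.isnan(row)]
        if len(row) >= 2:
            total += int(np.sum(row[1:] != row[:-1]))
    return total


def build_framework(
    matrix: GenotypeMatrix,
    markers: Sequence[str],
    anchors: Sequence[str],
    lod_threshold: float = 3.0,
    retention: float | None = None,
    chromosome: str | None = None,
    exhaustive_limit: int = 8,
) -> FrameworkMap:
    """Anchored iterative framework mapping.

    ``anchors`` fix the backbone order; every other marker must earn its
    place by beating its second-best position by ``lod_threshold`` units of
    log10 likelihood.  Markers sharing a retention pattern are binned first
    and placed through one representative (pattern-identical markers can
    never separate, and map to the same position).  Iterates until a full
    pass places nothing; leftovers are reported unplaced.
    """
    markers = list(markers)
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("need >=2 anchors")
    for a in anchors:
        if a not in markers:
            raise ValueError(f"anchor {a!r} not among the markers")
        if not (~np.isnan(matrix.marker_calls(a))).any():
            raise ValueError(f"anchor {a!r} has no scored calls")

    bins = bin_markers(matrix, markers)
    rep_of: dict[str, str] = {}
    bin_of_rep: dict[str, list[str]] = {}
    for group in bins.groups:
        in_group_anchors = [a for a in anchors if a in group]
        if len(in_group_anchors) > 1:
            warnings.warn(
                f"anchors {in_group_anchors} share a retention pattern; "
                "using the first as representative"
            )
        rep = in_group_anchors[0] if in_group_anchors else group[0]
        bin_of_rep[rep] = group
        for m in group:
            rep_of[m] = rep
    anchor_reps = []
    for a in anchors:
        if rep_of[a] not in anchor_reps:
            anchor_reps.append(rep_of[a])
    if len(anchor_reps) < 2:
        raise ValueError("anchors collapse into a single retention bin")

    reps = sorted(bin_of_rep)
    scorer = ChainScorer(matrix, reps, retention)

    # sanity-check the stated anchor order against the data: warn only when
    # some other order is better by the same evidence margin used for
    # placement (distant anchors are weakly linked, so noise-level
    # differences between permutations are expected)
    if len(anchor_reps) <= exhaustive_limit:
        given = scorer.score_ids(anchor_reps)
        best_perm, best_score = None, given + lod_threshold * LN10
        for perm in permutations(anchor_reps):
            s = scorer.score_ids(list(perm))
            if s > best_score + 1e-9:
                best_perm, best_score = list(perm), s
        if best_perm is not None and best_perm != list(
            reversed(anchor_reps)
        ):
            warnings.warn(
                "anchor order contradicts the data: stated order log10-L "
                f"{given / LN10:.2f} vs best {best_score / LN10:.2f} "
                f"for {best_perm}"
            )

    framework = [scorer.index[a] for a in anchor_reps]
    unplaced = sorted(
        scorer.index[r] for r in reps if scorer.index[r] not in framework
    )

    while unplaced:
        accepted: dict[int, list[int]] = {}
        still: list[int] = []
        for m in unplaced:
            slot_scores = []
            for s in range(len(framework) + 1):
                cand = framework[:s] + [m] + framework[s:]
                slot_scores.append(
                    (scorer.score(np.array(cand, dtype=int)), s)
                )
            slot_scores.sort(reverse=True)
            (best, best_slot), (second, _) = slot_scores[0], slot_scores[1]
            if (best - second) / LN10 >= lod_threshold:
                accepted.setdefault(best_slot, []).append(m)
            else:
                still.append(m)
        if not accepted:
            break
        new_framework: list[int] = []
        for s in range(len(framework) + 1):
            if s in accepted:
                left = framework[s - 1] if s > 0 else None
                right = framework[s] if s < len(framework) else None
                new_framework.extend(
                    _search_segment(
                        scorer, accepted[s], left, right, exhaustive_limit
                    )
                )
            if s < len(framework):
                new_framework.append(framework[s])
        framework = new_framework
        unplaced = still

    # orientation tie-break: the chain score is reversal-invariant, so fix
    # the orientation by the stated anchor order
    placed_anchor_pos = [
        framework.index(scorer.index[a])
        for a in anchor_reps
        if scorer.index[a] in framework
    ]
    if placed_anchor_pos != sorted(placed_anchor_pos):
        framework = framework[::-1]

    order_reps = [scorer.markers[i] for i in framework]
    positions: list[MapPosition] = []
    placed_bins: list[list[str]] = []
    pos = 0.0
    prev = None
    for bin_id, rep in enumerate(order_reps):
        if prev is not None:
            theta = scorer.pair_theta(prev, rep)
            if theta >= _THETA_UNLINKED:
                warnings.warn(
                    f"adjacent framework markers {prev!r} and {rep!r} "
                    "appear unlinked; capping the gap"
                )
                theta = 0.99
            pos += cr_from_theta(theta)
        group = bin_of_rep[rep]
        placed_bins.append(group)
        for m in group:
            positions.append(MapPosition(m, pos, bin_id))
        prev = rep
    unplaced_ids = sorted(
        m
        for i in unplaced
        for m in bin_of_rep[scorer.markers[i]]
    )
    return FrameworkMap(
        chromosome=chromosome,
        positions=positions,
        anchors=anchors,
        bins=placed_bins,
        total_cR=pos,
        obligate_breaks_total=obligate_breaks_total(
            matrix, [p.marker_id for p in positions]
        ),
        unplaced=unplaced_ids,
    )


# ---------------------------------------------------------------------------
# resolution and summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResolutionEstimate:
    """Upper-bound mapping resolution from obligate breaks in a known span.

    23 obligate breaks in a 3.2 Mbp region give 3,200/23 = 139.13 kb per
    break, i.e. a resolution better than 140 kb.
    """

    span_bp: int
    n_breaks: int
    kb_per_break: float


def resolution_estimate(span_bp: int, n_breaks: int) -> ResolutionEstimate:
    if n_breaks < 1:
        raise ValueError("need at least one obligate break")
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    return ResolutionEstimate(
        span_bp=span_bp,
        n_breaks=n_breaks,
        kb_per_break=span_bp / 1000.0 / n_breaks,
    )


@dataclass(frozen=True)
class MapSummary:
    total_cR: float
    n_markers: int
    n_bins: int
    obligate_breaks_total: int
    cr_per_cm: float | None  # the x of a 1:x cM/cR ratio


def map_summary(
    framework: FrameworkMap, genetic_length_cM: float | None = None
) -> MapSummary:
    """Totals of a built map; supplies the cM:cR ratio when the genetic
    length of the same interval is known (1 : total_cR/length)."""
    ratio = None
    if genetic_length_cM:
        ratio = framework.total_cR / genetic_length_cM
    return MapSummary(
        total_cR=framework.total_cR,
        n_markers=len(framework.positions),
        n_bins=len(framework.bins),
        obligate_breaks_total=framework.obligate_breaks_total,
        cr_per_cm=ratio,
    )


def graphical_genotype(
    matrix: GenotypeMatrix,
    framework: FrameworkMap,
    lines: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Lines x ordered-markers call grid ('1' retained, '0' lost, 'NA')."""
    order = framework.ordered_markers
    sub = matrix.subset_markers(order)
    if lines is not None:
        sub = sub.subset_lines(list(lines))
    grid = np.where(
        np.isnan(sub.calls), "NA", np.where(sub.calls == 1.0, "1", "0")
    )
    return pd.DataFrame(grid, index=sub.line_ids, columns=order)
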