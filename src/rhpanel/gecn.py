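"""Genetically effective cell number (GECN) estimation.

The germline of a mature embryo comprises several meristematic cell
lineages.  When a seed is irradiated, a deletion arises in one lineage on
one homolog, so among the backcross progeny (an RH1 family) it segregates
carriers : non-carriers as 1 : (2G - 1), where G is the number of
genetically effective cells.  Inverting this law, a family of t scored
siblings in which d carry the same deletion gives the estimate

    GECN = t / (2 d).

In a selfed M2 family a recessive mutation instead segregates 1 : (4G - 1)
visible mutants, hence GECN = t / (4 d) there.  The estimator is applied per
unique deletion mutation; the panel-level GECN is the unweighted average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .markers import MarkerMap


class NoDeletionError(ValueError):
    """Raised when no deletion segregates at the requested locus."""


def gecn_from_counts(t: int, d: int) -> float:
    """GECN = t/(2d) for an RH1 family of t scored siblings, d carriers."""
    if d < 1:
        raise NoDeletionError("d must be >= 1; no deletion to estimate from")
    if t < d:
        raise ValueError(f"t ({t}) must be >= d ({d})")
    return t / (2.0 * d)


def ratio_to_gecn(
    carriers: int, non_carriers: int, population: str = "RH1"
) -> float:
    """GECN from a carrier : non-carrier segregation ratio.

    RH1 backcross progeny: (carriers + non_carriers) / (2 * carriers);
    selfed M2 progeny:     (carriers + non_carriers) / (4 * carriers).
    An RH1 ratio of 9:1 non-carriers:carriers therefore gives GECN 5.
    """
    if carriers < 1:
        raise NoDeletionError("carriers must be >= 1")
    if non_carriers < 0:
        raise ValueError("non_carriers must be >= 0")
    total = carriers + non_carriers
    if population == "RH1":
        return total / (2.0 * carriers)
    if population == "M2":
        return total / (4.0 * carriers)
    raise ValueError(f"unknown population {population!r}")


def family_segregation(
    matrix: GenotypeMatrix, family_id: str, marker_id: str
) -> tuple[int, int]:
    """(t, d) at one locus in one family.

    t counts siblings with a non-missing call at the marker; d counts those
    scored lost.  Raises NoDeletionError when d = 0 (nothing segregates).
    """
    lines = matrix.lines_in_family(family_id)
    if not lines:
        raise ValueError(f"unknown or empty family {family_id!r}")
    j = matrix.marker_index(marker_id)
    calls = matrix.calls[[matrix.line_index(l) for l in lines], j]
    t = int(np.sum(~np.isnan(calls)))
    if t == 0:
        raise ValueError(
            f"family {family_id!r} has no scored call at {marker_id!r}"
        )
    d = int(np.sum(calls == 0.0))
    if d == 0:
        raise NoDeletionError(
            f"no deletion at locus {marker_id!r} in family {family_id!r}"
        )
    return t, d


@dataclass(frozen=True)
class GecnEstimate:
    """One unique deletion mutation's segregation-based GECN estimate."""

    family_id: str
    chromosome: str
    marker_ids: tuple[str, ...]  # adjacent markers sharing the carrier set
    t: int
    d: int
    value: float
    fixed: bool  # d == t: inconsistent with the chimeric-germline model


def unique_deletion_estimates(
    matrix: GenotypeMatrix, marker_map: MarkerMap
) -> list[GecnEstimate]:
    """One estimate per unique deletion mutation per family.

    Within a family and chromosome, adjacent markers (map order) with
    identical carrier sets are collapsed into a single deletion mutation;
    t is taken at the run's best-scored marker.  Deletions on different
    chromosomes are treated separately.  Families where the deletion is
    fixed (d = t) are flagged ``fixed`` — a deletion carried by every
    sibling contradicts a chimeric germline and would read GECN 0.5.
    """
    out: list[GecnEstimate] = []
    for family_id in matrix.family_ids:
        fam = matrix.subset_lines(matrix.lines_in_family(family_id))
        for chrom in marker_map.chromosomes:
            ids = [
                m.marker_id
                for m in marker_map.markers_on(chrom)
                if m.marker_id in fam._marker_index
            ]
            runs: list[tuple[list[str], frozenset]] = []
            for mid in ids:
                calls = fam.marker_calls(mid)
                carriers = frozenset(
                    l for l, c in zip(fam.line_ids, calls) if c == 0.0
                )
                if not carriers:
                    runs.append(([], frozenset()))  # breaks adjacency runs
                    continue
                if runs and runs[-1][1] == carriers:
                    runs[-1][0].append(mid)
                else:
                    runs.append(([mid], carriers))
            for mids, carriers in runs:
                if not mids:
                    continue
                scored = [
                    int(np.sum(~np.isnan(fam.marker_calls(m)))) for m in mids
                ]
                best = mids[int(np.argmax(scored))]
                t, d = family_segregation(matrix, family_id, best)
                out.append(
                    GecnEstimate(
                        family_id=family_id,
                        chromosome=chrom,
                        marker_ids=tuple(mids),
                        t=t,
                        d=d,
                        value=gecn_from_counts(t, d),
                        fixed=(d == t),
                    )
                )
    return out


def average_gecn(
    estimates: list[GecnEstimate],
    by_chromosome: bool = False,
    include_fixed: bool = False,
):
    """Unweighted mean GECN, overall or per chromosome.

    Per-chromosome output is a DataFrame with mean, range and the number of
    families studied (the shape of the study's per-chromosome summary).
    Fixed-deletion estimates are excluded unless ``include_fixed``.
    """
    kept = [e for e in estimates if include_fixed or not e.fixed]
    if not kept:
        raise ValueError("no usable estimates")
    if not by_chromosome:
        return float(np.mean([e.value for e in kept]))
    rows = {}
    for chrom in sorted({e.chromosome for e in kept}):
        sub = [e for e in kept if e.chromosome == chrom]
        vals = [e.value for e in sub]
        rows[chrom] = {
            "mean_gecn": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "n_families": len({e.family_id for e in sub}),
            "n_deletions": len(sub),
        }
    return pd.DataFrame(rows).T


def recovery_probability(n_siblings: int, G: float) -> float:
    """Probability a specific single-cell deletion appears at least once
    among n siblings: 1 - (1 - 1/(2G))^n.

    Increases with family size and decreases with GECN; at G = 5 and ~5
    siblings per family roughly 40% of the deletions present in the
    germline are recovered.
    """
    if n_siblings < 0:
        raise ValueError("n_siblings must be >= 0")
    if G < 0.5:
        raise ValueError("G must be >= 0.5")
    return 1.0 - (1.0 - 1.0 / (2.0 * G)) ** n_siblings


def min_family_size(G: float, confidence: float) -> int:
    """Smallest family size recovering a given deletion at the stated
    confidence: ceil(ln(1-c) / ln(1 - 1/(2G))).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if G < 0.5:
        raise ValueError("G must be >= 0.5")
    if G == 0.5:
        return 1  # transmission probability 1/(2G) = 1: one sibling suffices
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - 1.0 / (2.0 * G)))
    # guard the closed form against float rounding at the boundary
    while n > 0 and recovery_probability(n - 1, G) >= confidence:
        n -= 1
    while recovery_probability(n, G) < confidence:
        n += 1
    return n
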