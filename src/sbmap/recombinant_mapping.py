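"""Marker indexes from individual genotypes, recombinant detection and
interval narrowing.

All plants in the matrix are assumed to be selected mutant-phenotype carriers.
In a homozygous F2 design the causal genotype is HOM_A, so any other call at a
fully linked marker marks a recombinant; in a heterozygous backcross design
the causal genotype is HET and the informative (mutant-derived) gamete is
recombinant when it lost the A allele (HOM_B call). A HOM_A call in a
backcross is impossible and is flagged as a scoring error.

Narrowing places the causal locus in the marker gap(s) compatible with every
plant under two assumptions the flanking-recombinant argument rests on: a
plant's recombinant markers all sit on one side of the locus (one breakpoint
region per plant), and there is no double crossover between the locus and
any single marker, so reading outward from a candidate gap the number of
recombinant gametes per marker can only stay level or increase, never
decrease. Gaps violated by no plant are merged into the reported interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

from .types import Call, GenotypeMatrix, Interval, MarkerDef


class Mode(str, Enum):
    HOM_F2 = "hom_f2"    # homozygous mutants selected from an F2
    HET_BC = "het_bc"    # heterozygous mutants selected from a BCnF1


@dataclass(frozen=True)
class MappingDesign:
    mode: Mode
    n_backcross: int = 3

    @property
    def expected_causal_index(self) -> float:
        return 1.0 if self.mode is Mode.HOM_F2 else 0.5

    @property
    def n_gametes(self) -> int:
        """Informative gametes per plant: both in an F2, one in a backcross."""
        return 2 if self.mode is Mode.HOM_F2 else 1


def genotype_marker_index(calls: Sequence[Call], design: Optional[MappingDesign] = None) -> float:
    """Fraction of mutant-background (A) alleles among non-missing diploid calls.

    (2*#HOM_A + #HET) / (2*#non-missing); NaN when every call is missing.
    The formula is design-independent; ``design`` is accepted for symmetry
    with the other operations.
    """
    scored = [c for c in calls if c is not Call.MISSING]
    if not scored:
        return math.nan
    a_alleles = 2 * sum(c is Call.HOM_A for c in scored) + sum(c is Call.HET for c in scored)
    return a_alleles / (2 * len(scored))


def recombinant_dose(call: Call, design: MappingDesign) -> Optional[int]:
    """Number of recombinant gametes implied by one call (None = missing/invalid).

    HOM_F2: HOM_A -> 0, HET -> 1, HOM_B -> 2. HET_BC: HET -> 0, HOM_B -> 1;
    HOM_A cannot occur in a backcross and yields None after the caller flags it.
    """
    if call is Call.MISSING:
        return None
    if design.mode is Mode.HOM_F2:
        return {Call.HOM_A: 0, Call.HET: 1, Call.HOM_B: 2}[call]
    if call is Call.HOM_A:
        return None
    return {Call.HET: 0, Call.HOM_B: 1}[call]


class RecombinantSet(set):
    """Set of recombinant plant ids with missing/inconsistent plants carried along."""

    def __init__(self, ids=(), missing=(), inconsistent=()):
        super().__init__(ids)
        self.missing = set(missing)
        self.inconsistent = set(inconsistent)


def find_recombinants(matrix: GenotypeMatrix, marker: str, design: MappingDesign) -> RecombinantSet:
    """Plants whose call at ``marker`` is inconsistent with full linkage.

    HOM_F2: recombinant iff call != HOM_A. HET_BC: recombinant iff call is
    HOM_B; a HOM_A call is flagged inconsistent (possible scoring error) and
    MISSING plants are reported separately, never as recombinants.
    """
    recs, missing, bad = [], [], []
    for pid, call in zip(matrix.plant_ids, matrix.column(marker)):
        if call is Call.MISSING:
            missing.append(pid)
        elif design.mode is Mode.HET_BC and call is Call.HOM_A:
            warnings.warn(f"plant {pid}: HOM_A at {marker} is impossible in a backcross; flagged")
            bad.append(pid)
        else:
            dose = recombinant_dose(call, design)
            if dose:
                recs.append(pid)
    return RecombinantSet(recs, missing, bad)


@dataclass
class MarkerReport:
    marker: MarkerDef
    marker_index: float
    recombinants: RecombinantSet


@dataclass
class NarrowResult:
    interval: Interval
    consistent_gaps: list[int]              # gap g lies between marker g-1 and g
    per_marker: list[MarkerReport]
    conflicts_per_gap: list[list[str]]      # plant ids inconsistent with each gap
    excluded_plants: set[str] = field(default_factory=set)


class NoConsistentGapError(ValueError):
    """No marker gap is compatible with every plant (genotyping error or two loci)."""

    def __init__(self, best_gaps: list[int], conflicts: list[str]):
        self.best_gaps = best_gaps
        self.conflicts = conflicts
        super().__init__(
            f"no gap consistent with all plants; minimal-conflict gap(s) {best_gaps} "
            f"still conflict with plants {sorted(conflicts)}"
        )


def _side_consistent(doses_outward: list[Optional[int]]) -> bool:
    """Outward from the gap, recombinant dose must never decrease (missing skipped)."""
    last = 0
    for d in doses_outward:
        if d is None:
            continue
        if d < last:
            return False
        last = d
    return True


def plant_consistent_with_gap(doses: list[Optional[int]], gap: int) -> bool:
    """Single-crossover consistency of one plant's dose vector with gap ``gap``.

    ``doses[j]`` is the recombinant-gamete count at marker j; the candidate gap
    sits between markers gap-1 and gap (0 and len(doses) are the chromosome-end
    gaps). Two conditions: (a) all the plant's recombinant markers lie on one
    side of the gap — a plant is taken to carry one breakpoint region, as the
    flanking-recombinant argument requires; and (b) on that side a gamete
    recombinant at a marker is recombinant at every marker farther from the
    locus (dose never decreases moving outward).
    """
    left = doses[:gap][::-1]   # outward: nearest-to-gap first
    right = doses[gap:]
    if any(d for d in left if d) and any(d for d in right if d):
        return False
    return _side_consistent(left) and _side_consistent(right)


def narrow_interval(
    matrix: GenotypeMatrix,
    design: MappingDesign,
    chrom: Optional[str] = None,
    chrom_length: Optional[int] = None,
) -> NarrowResult:
    """Locate the causal locus in the gap(s) consistent with every plant.

    Uses the markers on ``chrom`` (default: the chromosome of the first
    marker; requires >= 2 markers there). Contiguous consistent gaps are
    merged; interior gaps are bounded by their flanking markers' positions,
    end gaps extend to position 1 or to ``chrom_length`` (falling back to the
    outermost marker when the length is unknown). Raises
    :class:`NoConsistentGapError` when every gap is contradicted.
    """
    if chrom is None:
        chrom = matrix.markers[0].chrom
    idx = [j for j, m in enumerate(matrix.markers) if m.chrom == chrom]
    if len(idx) < 2:
        raise ValueError(f"need >= 2 markers on {chrom} to narrow an interval")
    markers = [matrix.markers[j] for j in idx]
    markers, idx = _drop_position_ties(markers, idx)
    k = len(markers)

    excluded: set[str] = set()
    plant_doses: dict[str, list[Optional[int]]] = {}
    for pid, row in zip(matrix.plant_ids, matrix.calls):
        doses: list[Optional[int]] = []
        bad = False
        for j in idx:
            call = row[j]
            if design.mode is Mode.HET_BC and call is Call.HOM_A:
                bad = True
            doses.append(recombinant_dose(call, design))
        if bad:
            warnings.warn(f"plant {pid}: HOM_A call(s) in a backcross design; excluded from narrowing")
            excluded.add(pid)
        else:
            plant_doses[pid] = doses

    conflicts: list[list[str]] = []
    for gap in range(k + 1):
        conflicts.append(
            [pid for pid, doses in plant_doses.items() if not plant_consistent_with_gap(doses, gap)]
        )
    consistent = [g for g in range(k + 1) if not conflicts[g]]
    if not consistent:
        n_min = min(len(c) for c in conflicts)
        best = [g for g in range(k + 1) if len(conflicts[g]) == n_min]
        raise NoConsistentGapError(best, conflicts[best[0]])
    runs = _contiguous(consistent)
    if len(runs) > 1:
        warnings.warn(
            f"consistent gaps are non-contiguous ({consistent}); reporting their bounding interval"
        )
    g_lo, g_hi = consistent[0], consistent[-1]
    start = markers[g_lo - 1].pos if g_lo > 0 else 1
    if g_hi < k:
        end = markers[g_hi].pos
    else:
        end = chrom_length if chrom_length is not None else markers[-1].pos
    per_marker = [
        MarkerReport(
            marker=m,
            marker_index=genotype_marker_index([row[j] for row in matrix.calls], design),
            recombinants=find_recombinants(matrix, m.name, design),
        )
        for m, j in zip(markers, idx)
    ]
    interval = Interval(chrom=chrom, start=start, end=max(end, start), label="narrowed", source="marker_pair")
    return NarrowResult(
        interval=interval,
        consistent_gaps=consistent,
        per_marker=per_marker,
        conflicts_per_gap=conflicts,
        excluded_plants=excluded,
    )


def _drop_position_ties(markers: list[MarkerDef], idx: list[int]):
    seen: dict[int, str] = {}
    keep_m, keep_i = [], []
    for m, j in zip(markers, idx):
        if m.pos in seen:
            warnings.warn(f"marker {m.name} at {m.chrom}:{m.pos} duplicates {seen[m.pos]}; dropped")
            continue
        seen[m.pos] = m.name
        keep_m.append(m)
        keep_i.append(j)
    return keep_m, keep_i


def _contiguous(values: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for v in values:
        if runs and v == runs[-1][-1] + 1:
            runs[-1].append(v)
        else:
            runs.append([v])
    return runs


def interval_size_mbp(a_pos: int, b_pos: int) -> float:
    """|b - a| in Mbp, rounded half-up to 2 decimals."""
    mbp = Decimal(abs(b_pos - a_pos)) / Decimal(1_000_000)
    return float(mbp.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_recombinant_report(result: NarrowResult, path) -> None:
    from pathlib import Path

    lines = ["marker\tchrom\tpos\tmarker_index\tn_recombinants\trecombinants"]
    for rep in result.per_marker:
        ids = ",".join(sorted(rep.recombinants, key=str)) or "."
        mi = "NA" if math.isnan(rep.marker_index) else f"{rep.marker_index:.4f}"
        lines.append(
            f"{rep.marker.name}\t{rep.marker.chrom}\t{rep.marker.pos}\t{mi}\t{len(rep.recombinants)}\t{ids}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
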