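"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from the definition (brute force,
enumeration, or an established library routine), not by calling the code
under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import chi2_contingency

from sbmap.recombinant_mapping import MappingDesign, Mode, recombinant_dose
from sbmap.types import GenotypeMatrix


def g_oracle(n1: int, n2: int, n3: int, n4: int) -> float:
    """Log-likelihood-ratio statistic of the 2x2 table via scipy."""
    if min(n1 + n2, n3 + n4, n1 + n3, n2 + n4) == 0:
        return 0.0
    res = chi2_contingency([[n1, n2], [n3, n4]], lambda_="log-likelihood", correction=False)
    return float(res.statistic)


def window_means_brute(positions, deltas, starts, window, min_sites):
    """O(sites x windows) window membership, straight from the definition."""
    means, counts = [], []
    for s in starts:
        inside = [d for p, d in zip(positions, deltas) if s <= p <= s + window - 1]
        counts.append(len(inside))
        means.append(sum(inside) / len(inside) if len(inside) >= min_sites else float("nan"))
    return np.array(means), np.array(counts)


def _side_patterns(k: int, n_gametes: int):
    """All achievable recombinant-dose vectors on one side (outward order s0..sk-1).

    Each gamete contributes a suffix of the outward order: the a outermost
    markers (one crossover between the locus and the innermost of them).
    """
    patterns = set()
    for cfg in itertools.product(range(k + 1), repeat=n_gametes):
        doses = tuple(sum(1 for a in cfg if i >= k - a) for i in range(k))
        patterns.add(doses)
    return patterns


def narrow_gaps_oracle(matrix: GenotypeMatrix, design: MappingDesign) -> list[int]:
    """Exhaustive single-crossover consistency: for every gap, every plant must
    admit per-gamete suffix breakpoints reproducing its non-missing doses."""
    k = len(matrix.markers)
    n_g = 2 if design.mode is Mode.HOM_F2 else 1
    plant_doses = []
    for row in matrix.calls:
        doses = [recombinant_dose(c, design) for c in row]
        if design.mode is Mode.HET_BC and any(
            d is None and c.value == "A" for d, c in zip(doses, row)
        ):
            continue  # scoring-error plant, excluded by contract
        plant_doses.append(doses)

    consistent = []
    for gap in range(k + 1):
        ok = True
        for doses in plant_doses:
            left = doses[:gap][::-1]
            right = doses[gap:]
            if any(d for d in left if d) and any(d for d in right if d):
                ok = False  # breakpoints on both sides of the candidate gap
                break
            if not (_side_matches(left, n_g) and _side_matches(right, n_g)):
                ok = False
                break
        if ok:
            consistent.append(gap)
    return consistent


def _side_matches(observed, n_gametes: int) -> bool:
    k = len(observed)
    for pattern in _side_patterns(k, n_gametes):
        if all(o is None or o == p for o, p in zip(observed, pattern)):
            return True
    return False


def filter_candidates_brute(sites, interval, delta_min):
    """Exhaustive double filter for candidate extraction."""
    keep = []
    for s in sites:
        if s.chrom != interval.chrom:
            continue
        if not (interval.start <= s.pos <= interval.end):
            continue
        if np.isnan(s.delta_index) or s.delta_index < delta_min:
            continue
        keep.append((s.chrom, s.pos))
    return set(keep)
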