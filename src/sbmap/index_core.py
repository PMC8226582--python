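"""Per-site statistics of the sequencing-based mapping scan.

The marker index of a site is the fraction of pooled reads carrying the
mutant-background parent's allele, ``alt / (alt + ref)`` after the counts have
been oriented so the "alt" slot holds that allele. The delta index is the
mutant-pool index minus the control-pool index: near a causal locus it
approaches 0.5 in a heterozygous (BCnF1) design and 1 in a homozygous (F2)
design, and hovers near the design's background level elsewhere. The G
statistic is the log-likelihood-ratio test of allele-by-pool independence on
the 2x2 read-count table, computed per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import PooledVariant, SiteStat, VariantClass

#: sites whose control-pool index falls inside this open band cannot be
#: assigned a parental allele and are dropped from scans as ambiguous
FIXED_LOW = 0.1
FIXED_HIGH = 0.9


def marker_index(alt_count: int, ref_count: int) -> float:
    """alt / (alt + ref); NaN sentinel (never a division error) on zero support."""
    total = alt_count + ref_count
    if total <= 0:
        return math.nan
    return alt_count / total


def delta_index(mut_index: float, ctrl_index: float) -> float:
    """Mutant-pool index minus control-pool index, in [-1, 1]."""
    return mut_index - ctrl_index


def classify_background(v: PooledVariant, low: float = FIXED_LOW, high: float = FIXED_HIGH) -> Optional[bool]:
    """Infer from the control pool whether the mutant-background parent carries REF.

    The control pool proxies the mapping parent: fixed for ALT (index >= high)
    means the mapping parent carries ALT, hence the background parent carries
    REF (returns True); fixed for REF returns False. An intermediate control
    index means the parental state is ambiguous -> None.
    """
    ci = marker_index(v.ctrl_alt, v.ctrl_ref)
    if math.isnan(ci):
        return None
    if ci >= high:
        return True
    if ci <= low:
        return False
    return None


def orient_to_mutant_background(v: PooledVariant, background_is_ref: bool) -> PooledVariant:
    """Swap counts (and allele strings) so "alt" slots hold the background allele.

    Idempotent: a variant already marked ``oriented`` is returned unchanged.
    """
    from dataclasses import replace

    if v.oriented:
        return v
    out = v.swapped() if background_is_ref else v
    return replace(out, oriented=True)


def orient_all(
    variants: Iterable[PooledVariant],
    low: float = FIXED_LOW,
    high: float = FIXED_HIGH,
) -> tuple[list[PooledVariant], list[PooledVariant]]:
    """Orient every variant via the control-pool proxy.

    Returns (oriented, ambiguous); ambiguous sites (control index strictly
    inside (low, high)) are excluded from scans.
    """
    oriented: list[PooledVariant] = []
    ambiguous: list[PooledVariant] = []
    for v in variants:
        flag = classify_background(v, low=low, high=high)
        if flag is None:
            ambiguous.append(v)
        else:
            oriented.append(orient_to_mutant_background(v, flag))
    return oriented, ambiguous


@dataclass(frozen=True)
class GTable:
    """2x2 allele-by-pool read counts: (n1, n2) mutant pool, (n3, n4) control pool."""

    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self):
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("counts must be non-negative")


def g_statistic(t: GTable) -> float:
    """G = 2 * sum n_i ln(n_i / n^_i) with expectations from the table margins.

    Conventions: 0*ln(0/x) = 0, and a zero row or column margin yields G = 0
    (degenerate table), so the scan never emits non-finite values.
    """
    n = np.array([t.n1, t.n2, t.n3, t.n4], dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("G statistic requires a positive grand total")
    r1, r2 = t.n1 + t.n2, t.n3 + t.n4
    c1, c2 = t.n1 + t.n3, t.n2 + t.n4
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    expected = np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2], dtype=float) / total
    mask = n > 0
    g = 2.0 * float(np.sum(n[mask] * np.log(n[mask] / expected[mask])))
    return max(g, 0.0)


def site_g(v: PooledVariant) -> float:
    return g_statistic(GTable(v.mut_alt, v.mut_ref, v.ctrl_alt, v.ctrl_ref))


def compute_site_stats(
    variants: Iterable[PooledVariant],
    classes: Sequence[VariantClass] = (VariantClass.SNP, VariantClass.INDEL),
) -> list[SiteStat]:
    """Marker indexes, delta index and G for every variant of the scanned classes.

    SV/CNV records are excluded from index scans (they feed the coverage-gap
    scan instead); counts are assumed already oriented.
    """
    out: list[SiteStat] = []
    for v in variants:
        if v.vclass not in classes:
            continue
        mi = marker_index(v.mut_alt, v.mut_ref)
        ci = marker_index(v.ctrl_alt, v.ctrl_ref)
        out.append(
            SiteStat(
                chrom=v.chrom, pos=v.pos,
                support_mut=v.mut_support, support_ctrl=v.ctrl_support,
                mut_index=mi, ctrl_index=ci,
                delta_index=delta_index(mi, ci) if not (math.isnan(mi) or math.isnan(ci)) else math.nan,
                g_value=site_g(v),
                variant=v,
            )
        )
    return out


def depth_filter(sites: list[SiteStat], min_exceeded: int = 8) -> list[SiteStat]:
    """Keep sites whose read support strictly exceeds ``min_exceeded`` in each pool.

    The rule is "more than 8 supported reads", so a support of exactly 8
    fails; it is applied per pool, which protects both indexes. Order is
    preserved; NaN-index sites are removed by the same pass (zero support
    never exceeds the threshold).
    """
    return [s for s in sites if s.support_mut > min_exceeded and s.support_ctrl > min_exceeded]
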