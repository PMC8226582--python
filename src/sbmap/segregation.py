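"""Mendelian segregation chi-square tests and abortion-rate arithmetic.

Pearson's goodness-of-fit statistic against an expected integer ratio
(3:1, 15:1, 1:2:1, ...) with no continuity correction — the convention that
reproduces the printed p-values of the worked examples — plus the seed
abortion-rate percentage used to diagnose recessive heterozygous mutants.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from scipy import stats


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    ratio: tuple[int, ...]
    expected: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float
    ratio_text: str


def chi_square_segregation(observed: Sequence[int], ratio: Sequence[int]) -> SegregationResult:
    """Pearson chi-square of observed class counts against an integer ratio.

    ``ratio_text`` reports observed[first]/observed[last] to 2 decimals, the
    "green : mutant = x.xx:1" convention.
    """
    observed = tuple(int(x) for x in observed)
    ratio = tuple(int(r) for r in ratio)
    if len(observed) < 2 or len(observed) != len(ratio):
        raise ValueError("need >= 2 classes and one ratio term per class")
    total = sum(observed)
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(r <= 0 for r in ratio):
        raise ValueError("expected ratio terms must be positive")
    expected = tuple(total * r / sum(ratio) for r in ratio)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    rt = _round2(observed[0] / observed[-1])
    return SegregationResult(
        observed=observed, ratio=ratio, expected=expected,
        chi_square=float(chi2), df=df, p_value=p, ratio_text=f"{rt:.2f}:1",
    )


def abortion_rate(abortive: int, total: int) -> float:
    """100 * abortive / total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= abortive <= total):
        raise ValueError("require 0 <= abortive <= total")
    return _round2(100.0 * abortive / total)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
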