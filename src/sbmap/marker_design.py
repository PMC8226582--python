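"""Screening of resequencing variants for gel-resolvable PCR markers.

A marker is usable on 4% agarose only when the two parental alleles differ in
length by more than 5 bp, so screening keeps InDel variants whose
ref/alt length difference strictly exceeds ``min_diff``. Externally supplied
SSR/SSLP marker lists are verified against the variant calls by the same
length-difference rule rather than re-detected from repeat motifs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from . import index_core
from .types import MarkerDef, MarkerLocus, PooledVariant, VariantClass


def screen_gel_markers(
    variants: Iterable[PooledVariant],
    min_diff: int = 5,
    require_fixed: bool = True,
) -> list[MarkerLocus]:
    """Keep InDels with allele-length difference > min_diff (strict).

    With ``require_fixed`` the control pool must be fixed for one allele
    (index <= 0.1 or >= 0.9) and the mutant pool must show the opposite
    allele at >= 10% — evidence the site truly segregates between the two
    parents rather than being a pooled-sequencing artefact. Order-preserving;
    names default to ``<chrom>_<pos>``.
    """
    out: list[MarkerLocus] = []
    for v in variants:
        if v.vclass is not VariantClass.INDEL or v.length_diff <= min_diff:
            continue
        if require_fixed and not _fixed_opposite(v):
            continue
        out.append(
            MarkerLocus(
                name=f"{v.chrom}_{v.pos}",
                chrom=v.chrom, pos=v.pos,
                length_diff=v.length_diff, marker_type="InDel",
                ref_allele=v.ref_allele, alt_allele=v.alt_allele,
            )
        )
    return out


def _fixed_opposite(v: PooledVariant) -> bool:
    ci = index_core.marker_index(v.ctrl_alt, v.ctrl_ref)
    mi = index_core.marker_index(v.mut_alt, v.mut_ref)
    if ci != ci or mi != mi:  # NaN support
        return False
    if ci >= index_core.FIXED_HIGH:
        return mi <= 1 - 0.1  # mutant pool carries the other allele at >= 10%
    if ci <= index_core.FIXED_LOW:
        return mi >= 0.1
    return False


def verify_external_markers(
    markers: Iterable[MarkerDef],
    variants: Iterable[PooledVariant],
    min_diff: int = 5,
    tolerance_bp: int = 0,
) -> list[MarkerLocus]:
    """Verify downloaded SSR/SSLP markers against the resequencing variants.

    A marker passes when an InDel call with length difference > min_diff lies
    within ``tolerance_bp`` of its catalogued position.
    """
    by_chrom: dict[str, list[PooledVariant]] = {}
    for v in variants:
        if v.vclass is VariantClass.INDEL and v.length_diff > min_diff:
            by_chrom.setdefault(v.chrom, []).append(v)
    out: list[MarkerLocus] = []
    for m in markers:
        for v in by_chrom.get(m.chrom, []):
            if abs(v.pos - m.pos) <= tolerance_bp:
                out.append(
                    MarkerLocus(
                        name=m.name, chrom=m.chrom, pos=v.pos,
                        length_diff=v.length_diff, marker_type="SSR",
                        ref_allele=v.ref_allele, alt_allele=v.alt_allele,
                    )
                )
                break
    return out


def extract_flanks(reference: str | Path | "pyfaidx.Fasta", locus: MarkerLocus, flank: int = 250) -> MarkerLocus:
    """Fill flank_left/flank_right with up-to-``flank`` bp of reference sequence.

    flank_left ends at pos-1; flank_right starts just after the reference
    allele. Flanks are truncated at contig edges and uppercased. Unknown
    chromosome is fatal.
    """
    import pyfaidx

    fa = reference if isinstance(reference, pyfaidx.Fasta) else pyfaidx.Fasta(str(reference))
    if locus.chrom not in fa:
        raise ValueError(f"chromosome {locus.chrom!r} absent from FASTA (has {list(fa.keys())})")
    seq = fa[locus.chrom]
    left_start = max(locus.pos - 1 - flank, 0)  # 0-based slice bounds
    locus.flank_left = str(seq[left_start : locus.pos - 1]).upper()
    right_start = locus.pos - 1 + max(len(locus.ref_allele), 1)
    locus.flank_right = str(seq[right_start : right_start + flank]).upper()
    return locus


def write_marker_table(loci: Iterable[MarkerLocus], path: str | Path) -> None:
    lines = ["name\tchrom\tpos\ttype\tlength_diff"]
    for m in loci:
        lines.append(f"{m.name}\t{m.chrom}\t{m.pos}\t{m.marker_type}\t{m.length_diff}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_flank_fasta(loci: Iterable[MarkerLocus], path: str | Path) -> None:
    """Two records per marker (suffixes _L/_R) for primer design input."""
    lines = []
    for m in loci:
        lines.append(f">{m.name}_L")
        lines.append(m.flank_left or "N")
        lines.append(f">{m.name}_R")
        lines.append(m.flank_right or "N")
    Path(path).write_text("\n".join(lines) + "\n")
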