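"""Candidate-mutation extraction inside a narrowed interval.

After the genome scan and recombinant narrowing have produced a target
interval, the remaining work is a sieve: keep sites whose delta index clears
the design's causal level, subtract the ordinary parental polymorphisms of
the cross (exact chrom/pos/ref/alt matching, so a causal change coinciding
with a polymorphic position survives), classify the survivors against the
gene models, and separately scan binned depth tracks for mutant-private
coverage gaps — the signature of a large deletion such as a multi-kb event
present in the mutant pool but in no control.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CandidateVariant,
    CoverageGap,
    DepthTrack,
    GeneModelSet,
    Interval,
    PooledVariant,
    SiteStat,
    VariantClass,
)


def candidates_in_interval(
    sites: list[SiteStat],
    interval: Interval,
    delta_min: float,
) -> list[CandidateVariant]:
    """Sites inside the closed interval with delta_index >= delta_min.

    Sorted by descending delta then position. Sites must carry their source
    variant (depth-filtered and oriented upstream).
    """
    out = []
    for s in sites:
        if s.variant is None:
            raise ValueError(f"site {s.chrom}:{s.pos} carries no source variant")
        if interval.contains(s.chrom, s.pos) and not np.isnan(s.delta_index) and s.delta_index >= delta_min:
            out.append(CandidateVariant(variant=s.variant, delta_index=s.delta_index))
    out.sort(key=lambda c: (-c.delta_index, c.pos))
    return out


def subtract_parental(
    cands: list[CandidateVariant],
    parent_sites: list[PooledVariant],
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Split candidates into (kept, parental) by exact (chrom,pos,ref,alt) match.

    Matching is on the allele pair, not the position alone: a true causal site
    that happens to coincide with a parental SNP position is retained as long
    as its alleles differ. Matched candidates are flagged and returned in the
    side list.
    """
    parental_keys = {(p.chrom, p.pos, p.ref_allele, p.alt_allele) for p in parent_sites}
    # parental lists may be stored in either orientation
    parental_keys |= {(p.chrom, p.pos, p.alt_allele, p.ref_allele) for p in parent_sites}
    kept, removed = [], []
    for c in cands:
        if c.key() in parental_keys:
            c.parental_polymorphism = True
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def parental_from_control(
    variants: list[PooledVariant],
    min_index: float = 0.9,
) -> list[PooledVariant]:
    """Parental polymorphisms inferred from the control pool.

    The control pool resequences the mapping parent, so a site where it is
    fixed for the non-reference allele is an ordinary sequence difference of
    the cross, not a candidate mutation. Expects reference-oriented
    (unswapped) counts.
    """
    out = []
    for v in variants:
        total = v.ctrl_alt + v.ctrl_ref
        if total > 0 and v.ctrl_alt / total >= min_index:
            out.append(v)
    return out


def annotate_location(cands: list[CandidateVariant], genes: GeneModelSet) -> list[CandidateVariant]:
    """Attach exonic/intronic/intergenic class and gene id to each candidate.

    A variant occupies the reference bases [pos, pos + len(ref) - 1]; overlap
    with any exon makes it exonic, otherwise containment in a gene span makes
    it intronic. Exonic InDels whose length difference is not a multiple of 3
    get the frameshift flag.
    """
    by_chrom: dict[str, list] = {}
    for g in genes.genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in cands:
        v = c.variant
        lo, hi = v.pos, v.pos + max(len(v.ref_allele), 1) - 1
        c.location_class, c.gene_id = "intergenic", None
        for g in by_chrom.get(c.chrom, []):
            if hi < g.start or lo > g.end:
                continue
            c.location_class, c.gene_id = "intronic", g.gene_id
            if any(not (hi < s or lo > e) for s, e in g.exons):
                c.location_class = "exonic"
                break
        c.frameshift = (
            c.location_class == "exonic"
            and v.vclass is VariantClass.INDEL
            and v.length_diff % 3 != 0
        )
    return cands


def coverage_gap_scan(
    tracks: list[DepthTrack],
    mutant: str,
    controls: list[str],
    gap_max_depth: float = 2.0,
    ctrl_min_depth: float = 10.0,
    min_len: int = 5_000,
) -> list[CoverageGap]:
    """Mutant-private low-coverage runs: candidate large deletions.

    A gap is a maximal run of bins with mutant depth <= gap_max_depth while
    every control stays >= ctrl_min_depth, of total length >= min_len. Regions
    where controls also drop out (unsequenceable repeats) are not gaps. The
    thresholds suit 20-40x pools and are exposed on the CLI.
    """
    gaps: list[CoverageGap] = []
    for track in tracks:
        n = track.n_bins()
        for label in [mutant, *controls]:
            if label not in track.depths:
                raise ValueError(f"sample {label!r} missing from depth track {track.chrom}")
        mut = np.asarray(track.depths[mutant], dtype=float)
        ctrl = np.vstack([track.depths[c] for c in controls]).astype(float)
        ok = (mut <= gap_max_depth) & np.all(ctrl >= ctrl_min_depth, axis=0)
        i = 0
        while i < n:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            length = (j - i + 1) * track.bin_size
            if length >= min_len:
                gaps.append(
                    CoverageGap(
                        chrom=track.chrom,
                        start=i * track.bin_size + 1,
                        end=(j + 1) * track.bin_size,
                        mutant_mean_depth=float(mut[i : j + 1].mean()),
                        control_mean_depths={
                            c: float(ctrl[k, i : j + 1].mean()) for k, c in enumerate(controls)
                        },
                    )
                )
            i = j + 1
    return gaps


def write_candidate_table(cands: list[CandidateVariant], path) -> None:
    from pathlib import Path

    lines = ["chrom\tpos\tref\talt\tvclass\tdelta_index\tlocation\tgene\tframeshift\tparental"]
    for c in cands:
        v = c.variant
        lines.append(
            "\t".join(
                [
                    v.chrom, str(v.pos), v.ref_allele, v.alt_allele, v.vclass.value,
                    f"{c.delta_index:.4f}", c.location_class, c.gene_id or ".",
                    "yes" if c.frameshift else "no",
                    "yes" if c.parental_polymorphism else "no",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
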