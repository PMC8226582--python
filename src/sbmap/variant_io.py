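"""Readers and writers for the standard formats the pipeline touches.

Pooled variant calls come in either as VCF 4.x (two named samples carrying
per-allele AD depths) or as an explicit-count TSV; genotype matrices, gene
models, depth tracks and BED regions round out the I/O surface. Internal
coordinates are 1-based inclusive everywhere; only the BED writer converts.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    Call,
    DepthTrack,
    GeneModel,
    GeneModelSet,
    GenotypeMatrix,
    Interval,
    MarkerDef,
    PooledVariant,
    VariantClass,
)

SITE_TSV_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "vclass",
    "mut_ref", "mut_alt", "ctrl_ref", "ctrl_alt",
]

DEFAULT_CALL_CODING = {"A": Call.HOM_A, "H": Call.HET, "B": Call.HOM_B, "-": Call.MISSING}


# ---------------------------------------------------------------------------
# pooled variants

def read_pooled_variants(
    path: str | Path,
    mutant_sample: str,
    control_sample: str,
    stats: Optional[dict] = None,
) -> list[PooledVariant]:
    """Read biallelic pooled variant records from a VCF (via the AD field) or TSV.

    Multi-allelic records are skipped (not decomposed) and counted in ``stats``
    under ``n_multiallelic``; malformed records are skipped with a warning and
    counted under ``n_malformed``. Output is sorted by (chrom, pos).
    """
    path = Path(path)
    if stats is None:
        stats = {}
    stats.setdefault("n_multiallelic", 0)
    stats.setdefault("n_malformed", 0)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        variants = _read_vcf(path, mutant_sample, control_sample, stats)
    else:
        variants = _read_site_tsv(path)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def _read_vcf(path: Path, mutant_sample: str, control_sample: str, stats: dict) -> list[PooledVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mutant_sample, control_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF; available samples: {samples}")
    i_mut = samples.index(mutant_sample)
    i_ctrl = samples.index(control_sample)
    out: list[PooledVariant] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            stats["n_multiallelic"] += 1
            continue
        ad = rec.format("AD")
        if ad is None or ad.shape[1] < 2:
            stats["n_malformed"] += 1
            warnings.warn(f"record {rec.CHROM}:{rec.POS} lacks AD values; skipped")
            continue
        mut_ref, mut_alt = (max(int(x), 0) for x in ad[i_mut][:2])
        ctrl_ref, ctrl_alt = (max(int(x), 0) for x in ad[i_ctrl][:2])
        out.append(
            PooledVariant(
                chrom=rec.CHROM, pos=rec.POS,
                ref_allele=rec.REF, alt_allele=rec.ALT[0],
                mut_alt=mut_alt, mut_ref=mut_ref,
                ctrl_alt=ctrl_alt, ctrl_ref=ctrl_ref,
            )
        )
    return out


def _read_site_tsv(path: Path) -> list[PooledVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SITE_TSV_COLUMNS[:4] + SITE_TSV_COLUMNS[5:]) - set(df.columns)
    if missing:
        raise ValueError(f"site TSV {path} is missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        vclass = VariantClass(getattr(row, "vclass")) if hasattr(row, "vclass") else None
        out.append(
            PooledVariant(
                chrom=row.chrom, pos=int(row.pos),
                ref_allele=str(row.ref_allele), alt_allele=str(row.alt_allele),
                mut_alt=int(row.mut_alt), mut_ref=int(row.mut_ref),
                ctrl_alt=int(row.ctrl_alt), ctrl_ref=int(row.ctrl_ref),
                vclass=vclass,
            )
        )
    return out


def write_pooled_variants(variants: Iterable[PooledVariant], path: str | Path) -> None:
    """Write pooled variants as a site TSV (the AD-free count dialect)."""
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos,
            "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
            "vclass": v.vclass.value,
            "mut_ref": v.mut_ref, "mut_alt": v.mut_alt,
            "ctrl_ref": v.ctrl_ref, "ctrl_alt": v.ctrl_alt,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=SITE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_vcf(
    variants: Iterable[PooledVariant],
    path: str | Path,
    mutant_sample: str = "MUT",
    control_sample: str = "CTRL",
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write a minimal VCF 4.2 with GT:AD for the two pools (fixture emitter)."""
    variants = list(variants)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + f"{mutant_sample}\t{control_sample}"
    )
    for v in variants:
        mut = f"./.:{v.mut_ref},{v.mut_alt}"
        ctrl = f"./.:{v.ctrl_ref},{v.ctrl_alt}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT:AD\t{mut}\t{ctrl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotype matrices

def read_genotype_table(
    path: str | Path,
    coding: Optional[dict[str, Call]] = None,
) -> GenotypeMatrix:
    """Parse a plants x markers genotype TSV.

    Layout: first row = 'plant' + marker names; rows beginning ``#chrom`` and
    ``#pos`` carry per-marker coordinates; remaining rows are one plant each.
    Markers are returned sorted by (chrom, pos). Unknown cell tokens become
    MISSING with a warning.
    """
    coding = dict(DEFAULT_CALL_CODING if coding is None else coding)
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    marker_names = header[1:]
    if len(set(marker_names)) != len(marker_names):
        raise ValueError("duplicate marker name in genotype table header")
    chroms: Optional[list[str]] = None
    positions: Optional[list[int]] = None
    plant_ids: list[str] = []
    calls: list[list[Call]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if cells[0] == "#chrom":
            chroms = cells[1:]
            continue
        if cells[0] == "#pos":
            positions = [int(x) for x in cells[1:]]
            continue
        if len(cells) != len(header):
            raise ValueError(f"row {lineno}: expected {len(header)} columns, got {len(cells)}")
        plant_ids.append(cells[0])
        row = []
        for tok in cells[1:]:
            if tok not in coding:
                warnings.warn(f"row {lineno}: unknown genotype token {tok!r}; treated as missing")
                row.append(Call.MISSING)
            else:
                row.append(coding[tok])
        calls.append(row)
    if chroms is None or positions is None:
        raise ValueError("genotype table lacks #chrom/#pos marker coordinate rows")
    markers = [MarkerDef(n, c, p) for n, c, p in zip(marker_names, chroms, positions)]
    return GenotypeMatrix(plant_ids=plant_ids, markers=markers, calls=calls)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    lines = ["plant\t" + "\t".join(m.name for m in matrix.markers)]
    lines.append("#chrom\t" + "\t".join(m.chrom for m in matrix.markers))
    lines.append("#pos\t" + "\t".join(str(m.pos) for m in matrix.markers))
    for pid, row in zip(matrix.plant_ids, matrix.calls):
        lines.append(pid + "\t" + "\t".join(c.value for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(path: str | Path) -> GeneModelSet:
    """Load gene/exon structure from GFF3 (1-based inclusive, per the standard).

    Exons are grouped under their gene (via mRNA parents when present); strand
    is recorded but coordinates are never flipped. Genes without exons are kept
    with an empty exon list and a warning.
    """
    import gffutils

    out = GeneModelSet()
    text = Path(path).read_text()
    if not text.strip() or not any(ln and not ln.startswith("#") for ln in text.splitlines()):
        return out
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for gene in db.features_of_type("gene"):
        exons = sorted(
            {(f.start, f.end) for f in db.children(gene, featuretype="exon")}
        )
        if not exons:
            warnings.warn(f"gene {gene.id} has no exon features")
        out.add(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand or ".",
                start=gene.start, end=gene.end, exons=exons,
            )
        )
    return out


def write_gene_models(genes: GeneModelSet, path: str | Path) -> None:
    """Emit a minimal gene/mRNA/exon GFF3 (fixture emitter)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes.genes.values(), key=lambda g: (g.chrom, g.start)):
        lines.append(f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}")
        mrna = f"{g.gene_id}.1"
        lines.append(f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}")
        for k, (s, e) in enumerate(g.exons, start=1):
            lines.append(f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{k};Parent={mrna}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# regions and depth tracks

def write_regions(regions: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED: 0-based half-open, name column = label."""
    lines = []
    for iv in regions:
        if iv.end < iv.start:  # Interval enforces this, but guard raw tuples
            raise ValueError(f"interval end {iv.end} < start {iv.start}")
        lines.append(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label or '.'}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_depth_table(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        n = t.n_bins()
        df = pd.DataFrame({"chrom": t.chrom, "bin_start": np.arange(n) * t.bin_size + 1, "bin_size": t.bin_size})
        for label, depths in t.depths.items():
            df[label] = np.asarray(depths)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_depth_table(path: str | Path) -> list[DepthTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    labels = [c for c in df.columns if c not in {"chrom", "bin_start", "bin_size"}]
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("bin_start")
        bin_size = int(sub["bin_size"].iloc[0])
        tracks.append(
            DepthTrack(chrom=chrom, bin_size=bin_size,
                       depths={lab: sub[lab].to_numpy(float) for lab in labels})
        )
    return tracks
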