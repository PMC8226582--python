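"""Shared domain types for the sequencing-based mapping toolkit.

Coordinates are 1-based and inclusive throughout (VCF/GFF3 convention);
conversion to BED's 0-based half-open happens only in the BED writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

#: allele-length threshold separating small InDels from structural variants
SV_LENGTH_THRESHOLD = 50


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "InDel"
    SV = "SV"
    CNV = "CNV"


class Call(str, Enum):
    """Diploid call at a marker. A = mutant-background parent, B = mapping parent."""

    HOM_A = "A"
    HET = "H"
    HOM_B = "B"
    MISSING = "-"


def classify_alleles(ref_allele: str, alt_allele: str) -> VariantClass:
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return VariantClass.SNP
    if len(ref_allele) != len(alt_allele) and max(len(ref_allele), len(alt_allele)) <= SV_LENGTH_THRESHOLD:
        return VariantClass.INDEL
    return VariantClass.SV


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic site with per-pool allele read depths — the atom of the scan.

    ``oriented`` records whether the counts have already been swapped so that the
    "alt" slots hold the mutant-background parent's allele (see
    :func:`sbmap.index_core.orient_to_mutant_background`).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    mut_alt: int
    mut_ref: int
    ctrl_alt: int
    ctrl_ref: int
    vclass: Optional[VariantClass] = None
    oriented: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("mut_alt", "mut_ref", "ctrl_alt", "ctrl_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vclass is None:
            object.__setattr__(self, "vclass", classify_alleles(self.ref_allele, self.alt_allele))

    @property
    def mut_support(self) -> int:
        return self.mut_alt + self.mut_ref

    @property
    def ctrl_support(self) -> int:
        return self.ctrl_alt + self.ctrl_ref

    @property
    def length_diff(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    def swapped(self) -> "PooledVariant":
        """Counts and allele strings exchanged between ref and alt slots."""
        return replace(
            self,
            ref_allele=self.alt_allele,
            alt_allele=self.ref_allele,
            mut_alt=self.mut_ref,
            mut_ref=self.mut_alt,
            ctrl_alt=self.ctrl_ref,
            ctrl_ref=self.ctrl_alt,
        )


@dataclass(frozen=True)
class MarkerDef:
    name: str
    chrom: str
    pos: int


@dataclass
class GenotypeMatrix:
    """Plants x ordered markers with diploid calls (substrate of recombinant mapping)."""

    plant_ids: list[str]
    markers: list[MarkerDef]
    calls: list[list[Call]]  # calls[plant][marker]

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        order = sorted(range(len(self.markers)), key=lambda j: (self.markers[j].chrom, self.markers[j].pos))
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[j] for j in order]
            self.calls = [[row[j] for j in order] for row in self.calls]
        for i, row in enumerate(self.calls):
            if len(row) != len(self.markers):
                raise ValueError(f"row {i} has {len(row)} calls for {len(self.markers)} markers")

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    def marker_index_of(self, name: str) -> int:
        for j, m in enumerate(self.markers):
            if m.name == name:
                return j
        raise KeyError(name)

    def column(self, name: str) -> list[Call]:
        j = self.marker_index_of(name)
        return [row[j] for row in self.calls]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModelSet:
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add(self, gene: GeneModel) -> None:
        self.genes[gene.gene_id] = gene

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DepthTrack:
    """Binned mean read depth along one chromosome, one vector per sample label."""

    chrom: str
    bin_size: int
    depths: dict[str, "np.ndarray"]  # label -> per-bin mean depth

    def n_bins(self) -> int:
        lengths = {len(v) for v in self.depths.values()}
        if len(lengths) != 1:
            raise ValueError(f"bin grids differ between samples on {self.chrom}: {sorted(lengths)}")
        return lengths.pop()


@dataclass(frozen=True)
class Interval:
    """A candidate genomic region, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    label: str = ""
    source: str = "manual"  # window_scan | marker_pair | manual
    score: Optional[float] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class SiteStat:
    """Per-site scan statistics derived from one PooledVariant."""

    chrom: str
    pos: int
    support_mut: int
    support_ctrl: int
    mut_index: float
    ctrl_index: float
    delta_index: float
    g_value: float
    variant: Optional[PooledVariant] = None

    def is_defined(self) -> bool:
        return not (math.isnan(self.mut_index) or math.isnan(self.ctrl_index))


@dataclass
class MarkerLocus:
    """A gel-resolvable PCR marker site with flanking sequence for primer design."""

    name: str
    chrom: str
    pos: int
    length_diff: int
    marker_type: str  # InDel | SSR | SSLP
    ref_allele: str = ""
    alt_allele: str = ""
    flank_left: str = ""
    flank_right: str = ""


@dataclass
class CandidateVariant:
    variant: PooledVariant
    delta_index: float
    location_class: str = "intergenic"  # exonic | intronic | intergenic
    gene_id: Optional[str] = None
    parental_polymorphism: bool = False
    frameshift: bool = False

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    def key(self) -> tuple:
        return (self.variant.chrom, self.variant.pos, self.variant.ref_allele, self.variant.alt_allele)


@dataclass
class CoverageGap:
    chrom: str
    start: int
    end: int  # 1-based inclusive
    mutant_mean_depth: float
    control_mean_depths: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start + 1
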