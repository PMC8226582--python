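"""Forward simulation of the crossing schemes behind sequencing-based mapping.

The simulator builds two inbred parents — A, the mutant-background parent
whose (pre-mutagenesis) sequence is the reference, and B, the mapping parent
carrying the ALT allele at every parental polymorphism — plus a causal
mutation (and optionally further private mutations) carried only by the
mutant line. Crossing schemes are run forward with Haldane recombination
(Poisson crossover counts, uniform positions, no interference) and phenotype
selection each generation: homozygous-mutant selection in an F2 design,
heterozygous-carrier selection in a backcross design, where the backcross
lineage passes through a single selected plant per generation exactly as a
breeding program does. Pooled sequencing is modelled as Poisson total depth
and binomial allele sampling with symmetric per-read error.

Everything downstream of read alignment can be exercised from these outputs:
pooled VCFs, genotype tables at gel markers, gene models, reference FASTA and
binned depth tracks with an optional planted deletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .recombinant_mapping import Mode
from .types import Call, GeneModel, GeneModelSet, GenotypeMatrix, MarkerDef, DepthTrack, PooledVariant
from . import variant_io

_MORGAN_PER_CM = 0.01
_MAX_REJECT = 10_000

# named sub-streams so every operation draws from its own child of the user seed
_STREAMS = {"parents": 1, "population": 2, "reads": 3, "reference": 4, "depth": 5}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, _STREAMS[stream], extra]))


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    a_is_alt: bool       # True for mutant-line private mutations (incl. the causal one)
    is_causal: bool = False
    private: bool = False


@dataclass
class ParentSim:
    """Two parental haplotype sets expressed as a per-site truth table."""

    genome: list[tuple[str, int]]
    sites: list[TruthSite]
    causal_index: int
    seed: int

    @property
    def causal(self) -> TruthSite:
        return self.sites[self.causal_index]

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([s.pos for s in self.sites if s.chrom == chrom])


@dataclass(frozen=True)
class PedigreeSpec:
    """Declarative crossing scheme: design mode, backcross depth, selection size."""

    mode: Mode
    n_selected: int
    n_backcross: int = 3
    cM_per_Mb: float = 4.0
    effect: str = "recessive"

    def __post_init__(self):
        if self.n_selected < 1:
            raise ValueError("n_selected must be >= 1")


@dataclass(frozen=True)
class PoolSpec:
    depth: float = 40.0
    error_rate: float = 0.002

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass
class PopulationSim:
    parents: ParentSim
    spec: PedigreeSpec
    a_dose: np.ndarray        # (n_plants, n_sites) copies of the A-origin allele
    n_offspring_drawn: int    # offspring generated before selection, final generation

    @property
    def n_plants(self) -> int:
        return self.a_dose.shape[0]

    @property
    def a_freq(self) -> np.ndarray:
        """Exact mutant-background allele frequency per site across selected plants."""
        return self.a_dose.sum(axis=0) / (2.0 * self.n_plants)

    @property
    def alt_freq(self) -> np.ndarray:
        a_is_alt = np.array([s.a_is_alt for s in self.parents.sites])
        return np.where(a_is_alt, self.a_freq, 1.0 - self.a_freq)


# ---------------------------------------------------------------------------
# parents

def simulate_parents(
    n_sites: int,
    chrom_length: int = 2_000_000,
    indel_fraction: float = 0.15,
    seed: int = 0,
    genome: Optional[list[tuple[str, int]]] = None,
    n_private_mutations: int = 25,
    causal_chrom: Optional[str] = None,
    causal_pos: Optional[int] = None,
    causal_type: str = "snp",
) -> ParentSim:
    """Biallelic parental polymorphisms plus mutant-private mutations.

    Parental polymorphisms (A=REF, B=ALT) land on a fine position lattice
    (spacing keeps InDel alleles from overlapping); ``n_private_mutations``
    additional ALT sites, including the designated causal one, are private to
    the mutant line. Deterministic for a fixed seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if genome is None:
        genome = [("Chr1", int(chrom_length))]
    rng = _rng(seed, "parents")
    chrom_names = [c for c, _ in genome]
    if causal_chrom is None:
        causal_chrom = chrom_names[0]
    if causal_pos is None:
        causal_pos = dict(genome)[causal_chrom] // 2

    lengths = np.array([l for _, l in genome], dtype=float)
    per_chrom = np.maximum(1, np.round(n_sites * lengths / lengths.sum()).astype(int))
    sites: list[TruthSite] = []
    taken: set[tuple[str, int]] = {(causal_chrom, causal_pos)}

    def draw_positions(chrom: str, length: int, k: int) -> list[int]:
        lattice = np.arange(200, max(length - 200, 400), 20)
        k = min(k, len(lattice))
        pos = rng.choice(lattice, size=k, replace=False)
        return [int(p) for p in np.sort(pos) if (chrom, int(p)) not in taken]

    for (chrom, length), k in zip(genome, per_chrom):
        for pos in draw_positions(chrom, length, int(k)):
            taken.add((chrom, pos))
            ref, alt = _draw_alleles(rng, indel_fraction)
            sites.append(TruthSite(chrom, pos, ref, alt, a_is_alt=False))

    # mutant-line private mutations, spread genome-wide
    for _ in range(n_private_mutations):
        ci = rng.integers(len(genome))
        chrom, length = genome[ci]
        pos = int(rng.integers(300, length - 300) // 20 * 20 + 10)  # off-lattice, no collision
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref, alt = _draw_alleles(rng, indel_fraction=0.2)
        sites.append(TruthSite(chrom, pos, ref, alt, a_is_alt=True, private=True))

    ref, alt = _causal_alleles(rng, causal_type)
    sites.append(TruthSite(causal_chrom, causal_pos, ref, alt, a_is_alt=True,
                           is_causal=True, private=True))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    causal_index = next(i for i, s in enumerate(sites) if s.is_causal)
    return ParentSim(genome=genome, sites=sites, causal_index=causal_index, seed=seed)


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator, indel_fraction: float) -> tuple[str, str]:
    base = str(rng.choice(_BASES))
    if rng.random() < indel_fraction:
        length = int(rng.integers(1, 13))
        insert = "".join(rng.choice(_BASES, size=length))
        if rng.random() < 0.5:
            return base, base + insert      # insertion in B
        return base + insert, base          # deletion in B
    other = str(rng.choice([b for b in "ACGT" if b != base]))
    return base, other


def _causal_alleles(rng: np.random.Generator, causal_type: str) -> tuple[str, str]:
    base = str(rng.choice(_BASES))
    if causal_type == "insertion":
        return base, base + str(rng.choice(_BASES))  # +1 bp frameshift-style insertion
    other = str(rng.choice([b for b in "ACGT" if b != base]))
    return base, other


# ---------------------------------------------------------------------------
# meiosis and crossing schemes

class _Engine:
    """Per-chromosome meiosis over the concatenated site array."""

    def __init__(self, parents: ParentSim, cM_per_Mb: float):
        self.slices: list[slice] = []
        self.pos_m: list[np.ndarray] = []
        self.map_len: list[float] = []
        chrom_of = [s.chrom for s in parents.sites]
        morgan_per_bp = cM_per_Mb * _MORGAN_PER_CM / 1e6
        start = 0
        for chrom, length in parents.genome:
            n = sum(1 for c in chrom_of if c == chrom)
            sl = slice(start, start + n)
            self.slices.append(sl)
            self.pos_m.append(np.array([s.pos for s in parents.sites[sl]]) * morgan_per_bp)
            self.map_len.append(length * morgan_per_bp)
            start += n
        self.n_sites = start
        self.causal_index = parents.causal_index

    def gamete(self, rng: np.random.Generator, hap1: np.ndarray, hap2: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=np.int8)
        for sl, pos_m, L in zip(self.slices, self.pos_m, self.map_len):
            n_x = rng.poisson(L)
            if n_x == 0:
                src = hap1 if rng.random() < 0.5 else hap2
                out[sl] = src[sl]
                continue
            breaks = np.sort(rng.random(n_x) * L)
            seg = np.searchsorted(breaks, pos_m)
            phase = (seg + rng.integers(2)) % 2
            out[sl] = np.where(phase == 0, hap1[sl], hap2[sl])
        return out

    def gamete_carrying_causal(self, rng: np.random.Generator, hap1, hap2) -> np.ndarray:
        for _ in range(_MAX_REJECT):
            g = self.gamete(rng, hap1, hap2)
            if g[self.causal_index] == 1:
                return g
        raise RuntimeError("selection impossible: no causal-carrying gamete produced")


def sample_gametes(pos_morgans: Sequence[float], n: int, seed: int = 0, map_len: Optional[float] = None) -> np.ndarray:
    """n Haldane-model gametes from an all-1 x all-0 heterozygote (test utility)."""
    pos = np.asarray(pos_morgans, dtype=float)
    L = float(map_len) if map_len is not None else float(pos.max()) if len(pos) else 0.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 99]))
    out = np.empty((n, len(pos)), dtype=np.int8)
    for i in range(n):
        n_x = rng.poisson(L)
        if n_x == 0:
            out[i] = 1 if rng.random() < 0.5 else 0
            continue
        breaks = np.sort(rng.random(n_x) * L)
        phase = (np.searchsorted(breaks, pos) + rng.integers(2)) % 2
        out[i] = (phase == 0).astype(np.int8)
    return out


def simulate_population(
    parents: ParentSim,
    spec: PedigreeSpec,
    seed: int = 0,
    select: bool = True,
) -> PopulationSim:
    """Run the crossing scheme and return selected-plant genotypes at all sites.

    HOM_F2: F1 (A/B) is selfed; plants homozygous for the causal mutation are
    kept. HET_BC: the F1 carrier is backcrossed to parent B through
    ``n_backcross`` generations, selecting one heterozygous carrier each
    generation; the final population are carrier siblings from the last cross.
    With ``select=False`` the final generation is returned unselected (the
    intermediate backcross generations still select carriers, as the scheme
    requires a carrier to cross at all).
    """
    eng = _Engine(parents, spec.cM_per_Mb)
    rng = _rng(seed, "population")
    hap_a = np.ones(eng.n_sites, dtype=np.int8)
    hap_b = np.zeros(eng.n_sites, dtype=np.int8)
    doses = np.empty((spec.n_selected, eng.n_sites), dtype=np.int8)
    drawn = 0

    if spec.mode is Mode.HOM_F2:
        for i in range(spec.n_selected):
            for attempt in range(_MAX_REJECT):
                g1 = eng.gamete(rng, hap_a, hap_b)
                g2 = eng.gamete(rng, hap_a, hap_b)
                drawn += 1
                ok = (g1[eng.causal_index] == 1 and g2[eng.causal_index] == 1) or not select
                if ok:
                    doses[i] = g1 + g2
                    break
            else:
                raise RuntimeError("selection impossible in F2 scheme")
    else:
        cur = hap_a  # mutant-lineage haplotype of the current heterozygous plant
        for _ in range(max(spec.n_backcross - 1, 0)):
            cur = eng.gamete_carrying_causal(rng, cur, hap_b)
        for i in range(spec.n_selected):
            for attempt in range(_MAX_REJECT):
                g = eng.gamete(rng, cur, hap_b)
                drawn += 1
                if g[eng.causal_index] == 1 or not select:
                    doses[i] = g  # the other gamete is pure parent B
                    break
            else:
                raise RuntimeError("selection impossible in backcross scheme")

    return PopulationSim(parents=parents, spec=spec, a_dose=doses, n_offspring_drawn=drawn)


# ---------------------------------------------------------------------------
# pooled reads

def sample_pool_reads(
    freqs: np.ndarray,
    pool: PoolSpec,
    seed: int = 0,
    stream_extra: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref_count, alt_count): Poisson total depth, binomial ALT reads.

    ``freqs`` are ALT allele frequencies; sequencing error flips reads
    symmetrically toward the other allele.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = _rng(seed, "reads", stream_extra)
    total = rng.poisson(pool.depth, size=freqs.shape)
    eff = freqs * (1 - pool.error_rate) + (1 - freqs) * pool.error_rate
    alt = rng.binomial(total, eff)
    return total - alt, alt


def make_pooled_variants(
    parents: ParentSim,
    pop: PopulationSim,
    mutant_pool: PoolSpec,
    control_pool: PoolSpec,
    seed: int = 0,
) -> list[PooledVariant]:
    """Sample both pools and assemble reference-oriented PooledVariant records.

    The control pool is the mapping parent (B) resequencing pool: ALT-fixed at
    parental polymorphisms, REF-fixed at mutant-private sites.
    """
    mut_freq = pop.alt_freq
    ctrl_freq = np.where([s.a_is_alt for s in parents.sites], 0.0, 1.0)
    mut_ref, mut_alt = sample_pool_reads(mut_freq, mutant_pool, seed=seed, stream_extra=0)
    ctrl_ref, ctrl_alt = sample_pool_reads(ctrl_freq, control_pool, seed=seed, stream_extra=1)
    out = []
    for i, s in enumerate(parents.sites):
        out.append(
            PooledVariant(
                chrom=s.chrom, pos=s.pos, ref_allele=s.ref_allele, alt_allele=s.alt_allele,
                mut_alt=int(mut_alt[i]), mut_ref=int(mut_ref[i]),
                ctrl_alt=int(ctrl_alt[i]), ctrl_ref=int(ctrl_ref[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full file fixtures

@dataclass
class Fixture:
    outdir: Path
    parents: ParentSim
    population: PopulationSim
    variants: list[PooledVariant]
    genotypes: GenotypeMatrix
    genes: GeneModelSet
    paths: dict[str, Path] = field(default_factory=dict)


def make_reference(genome: list[tuple[str, int]], sites: list[TruthSite], seed: int = 0) -> dict[str, str]:
    """Random nucleotide sequence per chromosome, patched to match REF alleles."""
    rng = _rng(seed, "reference")
    ref: dict[str, list[str]] = {}
    for chrom, length in genome:
        ref[chrom] = list(rng.choice(_BASES, size=length))
    for s in sites:
        seq = ref[s.chrom]
        seq[s.pos - 1 : s.pos - 1 + len(s.ref_allele)] = list(s.ref_allele)
    return {c: "".join(seq) for c, seq in ref.items()}


def _toy_gene_models(parents: ParentSim, gene_spacing: int = 50_000) -> GeneModelSet:
    """Tile 4-kb two-exon genes along each chromosome; the causal site is exonic."""
    causal = parents.causal
    genes = GeneModelSet()
    k = 0
    for chrom, length in parents.genome:
        for start in range(10_000, length - 5_000, gene_spacing):
            end = start + 4_000
            if chrom == causal.chrom and start - 5_000 <= causal.pos <= end + 5_000:
                continue  # leave room for the dedicated causal gene
            k += 1
            genes.add(GeneModel(
                gene_id=f"GENE{k:04d}", chrom=chrom, strand="+" if k % 2 else "-",
                start=start, end=end,
                exons=[(start, start + 1_500), (end - 1_500, end)],
            ))
    genes.add(GeneModel(
        gene_id="GENE_CAUSAL", chrom=causal.chrom, strand="+",
        start=causal.pos - 1_000, end=causal.pos + 3_000,
        exons=[(causal.pos - 500, causal.pos + 500), (causal.pos + 2_000, causal.pos + 3_000)],
    ))
    return genes


def _marker_subset(parents: ParentSim, pop: PopulationSim, n_markers: int, min_diff: int = 5) -> GenotypeMatrix:
    chrom = parents.causal.chrom
    candidates = [
        i for i, s in enumerate(parents.sites)
        if s.chrom == chrom and not s.private and abs(len(s.ref_allele) - len(s.alt_allele)) > min_diff
    ]
    if len(candidates) > n_markers:
        picks = [candidates[int(round(x))] for x in np.linspace(0, len(candidates) - 1, n_markers)]
        picks = sorted(set(picks))
    else:
        picks = candidates
    markers = [MarkerDef(f"M{j + 1}", parents.sites[i].chrom, parents.sites[i].pos) for j, i in enumerate(picks)]
    dose_to_call = {2: Call.HOM_A, 1: Call.HET, 0: Call.HOM_B}
    calls = [[dose_to_call[int(pop.a_dose[p, i])] for i in picks] for p in range(pop.n_plants)]
    ids = [str(p + 1) for p in range(pop.n_plants)]
    return GenotypeMatrix(plant_ids=ids, markers=markers, calls=calls)


def make_depth_tracks(
    parents: ParentSim,
    mutant_depth: float,
    control_depths: dict[str, float],
    bin_size: int = 500,
    read_length: int = 150,
    deletion: Optional[tuple[str, int, int]] = None,
    seed: int = 0,
) -> list[DepthTrack]:
    """Binned mean depth per sample (Poisson read starts per bin, scaled back
    to coverage); an optional (chrom, start, end) deletion zeroes the mutant
    pool over the covered bins."""
    rng = _rng(seed, "depth")
    reads_per_unit = bin_size / read_length  # reads per bin at 1x coverage

    def bin_depths(mean_depth: float, n: int) -> np.ndarray:
        return rng.poisson(mean_depth * reads_per_unit, size=n) / reads_per_unit

    tracks = []
    for chrom, length in parents.genome:
        n = -(-length // bin_size)
        depths = {"mutant_pool": bin_depths(mutant_depth, n)}
        for label, d in control_depths.items():
            depths[label] = bin_depths(d, n)
        if deletion and deletion[0] == chrom:
            _, dstart, dend = deletion
            b0 = (dstart - 1) // bin_size
            b1 = (dend - 1) // bin_size
            depths["mutant_pool"][b0 : b1 + 1] = 0.0
        tracks.append(DepthTrack(chrom=chrom, bin_size=bin_size, depths=depths))
    return tracks


def make_fixture(
    spec: PedigreeSpec,
    pool: PoolSpec,
    outdir: str | Path,
    seed: int = 0,
    n_sites: int = 400,
    genome: Optional[list[tuple[str, int]]] = None,
    control_pool: Optional[PoolSpec] = None,
    n_markers: int = 6,
    deletion: Optional[tuple[str, int, int]] = None,
    causal_type: str = "insertion",
    write_fasta: bool = True,
) -> Fixture:
    """Emit a complete on-disk dataset: VCF, genotype TSV, GFF3, FASTA, depth
    TSV and a truth JSON — enough to run the whole pipeline end to end."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    control_pool = control_pool or PoolSpec(depth=20.0, error_rate=pool.error_rate)
    parents = simulate_parents(n_sites, seed=seed, genome=genome, causal_type=causal_type)
    pop = simulate_population(parents, spec, seed=seed)
    variants = make_pooled_variants(parents, pop, pool, control_pool, seed=seed)
    genotypes = _marker_subset(parents, pop, n_markers)
    genes = _toy_gene_models(parents)
    tracks = make_depth_tracks(
        parents, pool.depth, {"control_a": control_pool.depth, "control_b": control_pool.depth},
        deletion=deletion, seed=seed,
    )

    paths = {
        "vcf": outdir / "pools.vcf",
        "sites": outdir / "sites.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "gff": outdir / "genes.gff3",
        "depth": outdir / "depth.tsv",
        "truth": outdir / "truth.json",
    }
    contigs = dict(parents.genome)
    variant_io.write_vcf(variants, paths["vcf"], contigs=contigs)
    variant_io.write_pooled_variants(variants, paths["sites"])
    variant_io.write_genotype_table(genotypes, paths["genotypes"])
    variant_io.write_gene_models(genes, paths["gff"])
    variant_io.write_depth_table(tracks, paths["depth"])
    if write_fasta:
        paths["fasta"] = outdir / "ref.fa"
        ref = make_reference(parents.genome, parents.sites, seed=seed)
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in ref.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    causal = parents.causal
    truth = {
        "seed": seed,
        "mode": spec.mode.value,
        "causal": {
            "chrom": causal.chrom, "pos": causal.pos,
            "ref": causal.ref_allele, "alt": causal.alt_allele,
        },
        "n_sites": len(parents.sites),
        "markers": [{"name": m.name, "chrom": m.chrom, "pos": m.pos} for m in genotypes.markers],
        "parental_polymorphisms": sum(1 for s in parents.sites if not s.private),
        "deletion": list(deletion) if deletion else None,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return Fixture(outdir=outdir, parents=parents, population=pop, variants=variants,
                   genotypes=genotypes, genes=genes, paths=paths)
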