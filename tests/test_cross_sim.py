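"""Forward-simulator contracts: determinism, Mendelian expectations, Haldane
recombination, pooled read sampling and fixture integrity."""

import json
import math

import numpy as np
import pytest
from scipy import stats as sps

from sbmap import cross_sim as cs
from sbmap.recombinant_mapping import Mode
from sbmap.types import VariantClass


class TestSimulateParents:
    def test_fixed_seed_reproduces_truth_table(self):
        a = cs.simulate_parents(100, seed=7)
        b = cs.simulate_parents(100, seed=7)
        assert a.sites == b.sites

    def test_indel_fraction_zero_gives_all_snps(self):
        parents = cs.simulate_parents(150, seed=1, indel_fraction=0.0, n_private_mutations=0)
        assert all(len(s.ref_allele) == len(s.alt_allele) == 1 for s in parents.sites if not s.is_causal)

    def test_sites_sorted_and_causal_designated(self):
        parents = cs.simulate_parents(100, seed=2)
        pos = [(s.chrom, s.pos) for s in parents.sites]
        assert pos == sorted(pos)
        assert sum(s.is_causal for s in parents.sites) == 1
        assert parents.causal.a_is_alt  # the mutation is private to the mutant line


class TestSimulatePopulation:
    def test_causal_frequency_exact_under_selection(self):
        parents = cs.simulate_parents(50, seed=3)
        hom = cs.simulate_population(
            parents, cs.PedigreeSpec(mode=Mode.HOM_F2, n_selected=25), seed=3)
        assert hom.a_freq[parents.causal_index] == 1.0
        het = cs.simulate_population(
            parents, cs.PedigreeSpec(mode=Mode.HET_BC, n_selected=25), seed=3)
        assert het.a_freq[parents.causal_index] == 0.5

    def test_backcross_unlinked_frequency_one_sixteenth(self):
        """Mean mutant-background allele frequency at an unlinked locus after
        a cross plus three carrier-selected backcrosses is 1/16, within 3
        standard errors across replicate populations."""
        genome = [("Chr1", 2_000_000), ("Chr2", 1_000_000)]
        parents = cs.simulate_parents(10, genome=genome, seed=4, n_private_mutations=0)
        unlinked = [i for i, s in enumerate(parents.sites) if s.chrom == "Chr2"]
        spec = cs.PedigreeSpec(mode=Mode.HET_BC, n_selected=100, n_backcross=3)
        means = []
        for seed in range(400):
            pop = cs.simulate_population(parents, spec, seed=seed)
            means.append(pop.a_freq[unlinked].mean())
        mean = np.mean(means)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(mean - 1 / 16) <= 3 * se

    def test_unselected_f2_fits_1_2_1(self):
        """Unselected F2 genotype counts at the causal locus follow 1:2:1."""
        parents = cs.simulate_parents(5, seed=5, n_private_mutations=0)
        spec = cs.PedigreeSpec(mode=Mode.HOM_F2, n_selected=10_000)
        pop = cs.simulate_population(parents, spec, seed=5, select=False)
        doses = pop.a_dose[:, parents.causal_index]
        counts = [(doses == k).sum() for k in (0, 1, 2)]
        p = sps.chisquare(counts, f_exp=[2_500, 5_000, 2_500]).pvalue
        assert p > 0.001

    def test_selected_mutant_fraction_quarter_and_two_locus_sixteenth(self):
        parents = cs.simulate_parents(
            10, genome=[("Chr1", 2_000_000), ("Chr2", 2_000_000)], seed=6,
            n_private_mutations=0)
        spec = cs.PedigreeSpec(mode=Mode.HOM_F2, n_selected=2_000)
        pop = cs.simulate_population(parents, spec, seed=6)
        frac = pop.n_plants / pop.n_offspring_drawn
        assert frac == pytest.approx(0.25, abs=3 * math.sqrt(0.25 * 0.75 / pop.n_offspring_drawn))
        # duplicate-recessive two-locus fraction: hom at two unlinked loci ~ 1/16
        un = cs.simulate_population(parents, spec, seed=7, select=False)
        i = parents.causal_index
        j = next(k for k, s in enumerate(parents.sites) if s.chrom != parents.causal.chrom)
        both = ((un.a_dose[:, i] == 2) & (un.a_dose[:, j] == 2)).mean()
        assert both == pytest.approx(1 / 16, abs=3 * math.sqrt((1 / 16) * (15 / 16) / un.n_plants))

    def test_haldane_recombination_fraction(self):
        """Realized recombination fraction between two loci matches
        (1 - exp(-2d))/2 within 3 SE over 10,000 gametes."""
        for d in (0.05, 0.2, 0.5):
            gam = cs.sample_gametes([0.0, d], 10_000, seed=int(d * 100), map_len=d)
            r_hat = (gam[:, 0] != gam[:, 1]).mean()
            r = (1 - math.exp(-2 * d)) / 2
            assert abs(r_hat - r) <= 3 * math.sqrt(r * (1 - r) / 10_000)

    def test_determinism(self):
        parents = cs.simulate_parents(30, seed=8)
        spec = cs.PedigreeSpec(mode=Mode.HET_BC, n_selected=20)
        a = cs.simulate_population(parents, spec, seed=9)
        b = cs.simulate_population(parents, spec, seed=9)
        assert np.array_equal(a.a_dose, b.a_dose)


class TestSamplePoolReads:
    def test_zero_frequency_zero_error_never_alt(self):
        ref, alt = cs.sample_pool_reads(np.zeros(500), cs.PoolSpec(40, error_rate=0.0), seed=1)
        assert alt.sum() == 0

    def test_binomial_moments_at_half(self):
        ref, alt = cs.sample_pool_reads(np.full(10_000, 0.5), cs.PoolSpec(40, 0.0), seed=2)
        frac = alt.sum() / (alt + ref).sum()
        n_reads = (alt + ref).sum()
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / n_reads)

    def test_depth_is_poisson_mean(self):
        ref, alt = cs.sample_pool_reads(np.full(10_000, 0.5), cs.PoolSpec(40, 0.0), seed=3)
        total = ref + alt
        assert total.mean() == pytest.approx(40, abs=3 * math.sqrt(40 / 10_000))

    def test_fixed_seed_identical_counts(self):
        a = cs.sample_pool_reads(np.full(100, 0.3), cs.PoolSpec(40), seed=4)
        b = cs.sample_pool_reads(np.full(100, 0.3), cs.PoolSpec(40), seed=4)
        assert np.array_equal(a[1], b[1])

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            cs.sample_pool_reads(np.array([1.2]), cs.PoolSpec(40))


class TestMakeFixture:
    def test_same_seed_identical_files(self, tmp_path):
        spec = cs.PedigreeSpec(mode=Mode.HOM_F2, n_selected=12)
        fx1 = cs.make_fixture(spec, cs.PoolSpec(40), tmp_path / "a", seed=3, n_sites=80)
        fx2 = cs.make_fixture(spec, cs.PoolSpec(40), tmp_path / "b", seed=3, n_sites=80)
        for key in fx1.paths:
            assert fx1.paths[key].read_bytes() == fx2.paths[key].read_bytes(), key

    def test_truth_json_schema(self, hom_fixture):
        truth = json.loads(hom_fixture.paths["truth"].read_text())
        assert truth["mode"] == "hom_f2"
        assert truth["causal"]["pos"] == hom_fixture.parents.causal.pos
        assert truth["deletion"] == ["Chr1", 1_500_001, 1_523_500]

    def test_fixture_vcf_reparses_to_identical_counts(self, hom_fixture):
        from sbmap import variant_io

        back = variant_io.read_pooled_variants(hom_fixture.paths["vcf"], "MUT", "CTRL")
        assert back == sorted(hom_fixture.variants, key=lambda v: (v.chrom, v.pos))

    def test_reference_carries_ref_alleles(self, hom_fixture):
        import pyfaidx

        fa = pyfaidx.Fasta(str(hom_fixture.paths["fasta"]))
        for site in hom_fixture.parents.sites[:25]:
            got = str(fa[site.chrom][site.pos - 1 : site.pos - 1 + len(site.ref_allele)])
            assert got.upper() == site.ref_allele

    def test_causal_site_is_exonic_in_toy_models(self, hom_fixture):
        causal = hom_fixture.parents.causal
        gene = hom_fixture.genes.genes["GENE_CAUSAL"]
        assert any(s <= causal.pos <= e for s, e in gene.exons)

    def test_genotype_matrix_markers_are_gel_screenable(self, hom_fixture):
        truth = {(s.chrom, s.pos): s for s in hom_fixture.parents.sites}
        assert hom_fixture.genotypes.markers
        for m in hom_fixture.genotypes.markers:
            site = truth[(m.chrom, m.pos)]
            assert abs(len(site.ref_allele) - len(site.alt_allele)) > 5
            assert not site.private


class TestEndToEndRecovery:
    def test_default_fixture_pipeline_recovers_causal_site(self, hom_fixture):
        """index -> scan -> candidates on the default fixture places the
        planted causal variant in the candidate list."""
        from sbmap import candidate_calling, genome_scan, index_core

        oriented, _ = index_core.orient_all(hom_fixture.variants)
        stats = index_core.depth_filter(index_core.compute_site_stats(oriented))
        cfg = genome_scan.ScanConfig(window=100_000, step=20_000)
        chrom_len = dict(hom_fixture.parents.genome)["Chr1"]
        prof = genome_scan.sliding_window_profile(
            [s for s in stats if s.chrom == "Chr1"], cfg, chrom_len)
        regions = genome_scan.call_candidate_regions(prof, 0.6)
        causal = hom_fixture.parents.causal
        region = next(r for r in regions if r.contains(causal.chrom, causal.pos))
        cands = candidate_calling.candidates_in_interval(stats, region, 0.5)
        parental = [v for v, s in zip(hom_fixture.variants, hom_fixture.parents.sites)
                    if not s.private]
        kept, _ = candidate_calling.subtract_parental(cands, parental)
        keys = {c.key() for c in kept}
        assert (causal.chrom, causal.pos, causal.ref_allele, causal.alt_allele) in keys
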