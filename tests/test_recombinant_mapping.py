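"""Genotype marker indexes, recombinant detection and interval narrowing."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sbmap import cross_sim
from sbmap import recombinant_mapping as rm
from sbmap.types import Call, GenotypeMatrix, MarkerDef

from .oracles import narrow_gaps_oracle

HOM = rm.MappingDesign(mode=rm.Mode.HOM_F2)
HET = rm.MappingDesign(mode=rm.Mode.HET_BC, n_backcross=3)


def matrix_from(marker_pos, rows, ids=None, chrom="Chr1"):
    markers = [MarkerDef(f"m{i+1}", chrom, p) for i, p in enumerate(marker_pos)]
    calls = [[Call(c) for c in row] for row in rows]
    ids = ids or [str(i + 1) for i in range(len(rows))]
    return GenotypeMatrix(plant_ids=ids, markers=markers, calls=calls)


class TestGenotypeMarkerIndex:
    def test_backcross_worked_example(self):
        """38 heterozygous + 1 mapping-parent-homozygous of 39 BC2F1 plants."""
        calls = [Call.HET] * 38 + [Call.HOM_B]
        assert round(rm.genotype_marker_index(calls, HET), 4) == 0.4872

    def test_f2_worked_example(self):
        """6 homozygous-mutant + 1 heterozygous of 7 F2 mutants."""
        calls = [Call.HOM_A] * 6 + [Call.HET]
        assert round(rm.genotype_marker_index(calls, HOM), 4) == 0.9286

    def test_all_hom_a_is_one(self):
        assert rm.genotype_marker_index([Call.HOM_A] * 5, HOM) == 1.0

    def test_missing_ignored_and_all_missing_nan(self):
        assert rm.genotype_marker_index([Call.HET, Call.MISSING], HET) == 0.5
        assert math.isnan(rm.genotype_marker_index([Call.MISSING], HET))


class TestFindRecombinants:
    def test_backcross_single_recombinant(self):
        rows = [["H"]] * 12 + [["B"]] + [["H"]] * 26
        m = matrix_from([100], rows)
        recs = rm.find_recombinants(m, "m1", HET)
        assert recs == {"13"}

    def test_f2_het_calls_are_recombinants(self):
        rows = [["A"], ["A"], ["A"], ["H"], ["A"]] + [["A"]] * 8 + [["H"]] + [["A"]] * 11
        m = matrix_from([747_262], rows, chrom="Chr12")
        assert rm.find_recombinants(m, "m1", HOM) == {"4", "14"}

    def test_all_hom_a_in_f2_no_recombinants(self):
        m = matrix_from([100], [["A"]] * 10)
        assert rm.find_recombinants(m, "m1", HOM) == set()

    def test_hom_a_in_backcross_flagged_inconsistent(self):
        m = matrix_from([100], [["H"], ["A"], ["-"]])
        with pytest.warns(UserWarning, match="impossible in a backcross"):
            recs = rm.find_recombinants(m, "m1", HET)
        assert recs == set()
        assert recs.inconsistent == {"2"} and recs.missing == {"3"}


class TestNarrowInterval:
    def test_fine_mapping_matrix_locates_flanked_gap(self, abs_matrix):
        """Breakpoints at InDel2-4 on one side and RM27694/97 on the other pin
        the locus between InDel4 (4,403,614) and RM27694 (4,814,750)."""
        res = rm.narrow_interval(abs_matrix, HOM)
        assert res.interval.chrom == "Chr12"
        assert (res.interval.start, res.interval.end) == (4_403_614, 4_814_750)
        assert res.consistent_gaps == [4]
        by_name = {r.marker.name: r.recombinants for r in res.per_marker}
        assert by_name["InDel3"] == {"17", "24", "42", "66", "84", "94", "104"}
        assert by_name["RM27697"] == {"14", "64"}

    def test_flanking_recombinants_bound_the_interior(self):
        """One plant recombinant only at the leftmost marker and one only at
        the rightmost exclude both chromosome-end gaps; the interval is the
        interior span bounded by those two markers."""
        m = matrix_from([100, 500, 900], [["H", "A", "A"], ["A", "A", "H"]])
        res = rm.narrow_interval(m, HOM, chrom_length=2_000)
        assert 0 not in res.consistent_gaps and 3 not in res.consistent_gaps
        assert (res.interval.start, res.interval.end) == (100, 900)

    def test_recombinant_at_every_marker_extends_to_chromosome_end(self):
        """A plant recombinant at the whole marker run is consistent with the
        locus lying beyond it; with another plant clean everywhere, the
        interval reaches from the near chromosome end to the first marker."""
        m = matrix_from(
            [747_262, 906_291, 3_804_685],
            [["H", "H", "H"], ["A", "A", "A"], ["A", "A", "H"]],
            chrom="Chr12",
        )
        res = rm.narrow_interval(m, HOM, chrom_length=27_000_000)
        assert res.consistent_gaps == [0]
        assert (res.interval.start, res.interval.end) == (1, 747_262)

    def test_no_consistent_gap_is_fatal_with_conflict_report(self):
        # two plants with interleaved double-recombinant patterns
        m = matrix_from([100, 200, 300], [["H", "A", "H"], ["A", "H", "A"]])
        with pytest.raises(rm.NoConsistentGapError) as err:
            rm.narrow_interval(m, HOM)
        assert err.value.best_gaps and err.value.conflicts

    def test_position_tie_drops_later_marker(self):
        m = matrix_from([100, 100, 300], [["A", "A", "H"], ["H", "A", "A"]])
        with pytest.warns(UserWarning, match="duplicates"):
            res = rm.narrow_interval(m, HOM)
        assert len(res.per_marker) == 2

    def test_agrees_with_exhaustive_gamete_oracle_on_random_matrices(self):
        """200 random 8-plant x 6-marker matrices from unrestricted simulator
        draws: the gap set must equal the brute-force enumeration of every
        per-gamete single-crossover configuration."""
        genome = [("Chr1", 10_000_000)]
        parents = cross_sim.simulate_parents(
            60, genome=genome, seed=5, n_private_mutations=0, indel_fraction=0.0)
        marker_idx = [int(round(x)) for x in np.linspace(0, len(parents.sites) - 1, 6)]
        markers = [MarkerDef(f"m{k}", "Chr1", parents.sites[i].pos) for k, i in enumerate(marker_idx)]
        dose_to_call = {
            rm.Mode.HOM_F2: {2: Call.HOM_A, 1: Call.HET, 0: Call.HOM_B},
            rm.Mode.HET_BC: {1: Call.HET, 0: Call.HOM_B},
        }
        for rep in range(200):
            mode = rm.Mode.HOM_F2 if rep % 2 else rm.Mode.HET_BC
            design = rm.MappingDesign(mode=mode)
            spec = cross_sim.PedigreeSpec(mode=mode, n_selected=8)
            pop = cross_sim.simulate_population(parents, spec, seed=100 + rep)
            calls = [
                [dose_to_call[mode][int(pop.a_dose[p, i])] for i in marker_idx]
                for p in range(8)
            ]
            matrix = GenotypeMatrix(
                plant_ids=[str(p + 1) for p in range(8)], markers=list(markers), calls=calls)
            expected = narrow_gaps_oracle(matrix, design)
            if expected:
                res = rm.narrow_interval(matrix, design, chrom_length=10_000_000)
                assert res.consistent_gaps == expected, (rep, mode)
            else:
                with pytest.raises(rm.NoConsistentGapError):
                    rm.narrow_interval(matrix, design, chrom_length=10_000_000)

    def test_true_position_always_contained_under_single_crossover_model(self):
        """When every gamete respects the at-most-one-crossover-per-side
        assumption, containment of the true position is a logical certainty."""
        rng = np.random.default_rng(42)
        marker_pos = [500_000 * (i + 1) for i in range(6)]
        for rep in range(300):
            mode = rm.Mode.HOM_F2 if rep % 2 else rm.Mode.HET_BC
            design = rm.MappingDesign(mode=mode)
            true_gap = int(rng.integers(0, 7))
            rows = []
            for _ in range(8):
                doses = _model_compliant_doses(rng, 6, true_gap, design.n_gametes)
                if mode is rm.Mode.HOM_F2:
                    rows.append([{0: "A", 1: "H", 2: "B"}[d] for d in doses])
                else:
                    rows.append([{0: "H", 1: "B"}[d] for d in doses])
            m = matrix_from(marker_pos, rows)
            res = rm.narrow_interval(m, design, chrom_length=3_500_000)
            assert true_gap in res.consistent_gaps
            true_pos = 250_000 + 500_000 * true_gap  # a point inside the true gap
            assert res.interval.start <= true_pos <= res.interval.end

    def test_recombinant_count_grows_with_distance_from_locus(self):
        """Expected number of recombinants is non-decreasing in genetic
        distance from the causal locus (rank correlation over seeds)."""
        genome = [("Chr1", 20_000_000)]
        parents = cross_sim.simulate_parents(
            40, genome=genome, seed=9, n_private_mutations=0)
        causal_pos = parents.causal.pos
        site_idx = [i for i in range(len(parents.sites)) if not parents.sites[i].is_causal]
        spec = cross_sim.PedigreeSpec(mode=rm.Mode.HOM_F2, n_selected=30)
        counts = np.zeros(len(site_idx))
        for seed in range(40):
            pop = cross_sim.simulate_population(parents, spec, seed=seed)
            counts += [(pop.a_dose[:, i] != 2).sum() for i in site_idx]
        dist = [abs(parents.sites[i].pos - causal_pos) for i in site_idx]
        rho = sps.spearmanr(dist, counts).statistic
        assert rho > 0.95


class TestIntervalSize:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10_068_751, 11_595_846, 1.53),
            (5, 5, 0.00),
            (3_804_685, 5_189_063, 1.38),  # printed as "1.32M"; coordinates say 1.38
        ],
    )
    def test_mbp_half_up_two_decimals(self, a, b, expected):
        assert rm.interval_size_mbp(a, b) == expected


def _model_compliant_doses(rng, k, true_gap, n_gametes):
    """Doses at k markers for one plant with a single breakpoint region: all
    crossovers on one side of the causal locus (in ``true_gap``), at most one
    per gamete, so recombinant markers form an outward run on that side."""
    doses = [0] * k
    side_left = bool(rng.integers(2))
    for _ in range(n_gametes):
        if side_left:
            run = int(rng.integers(0, true_gap + 1))     # outermost `run` left markers
            for j in range(run):
                doses[j] += 1
        else:
            run = int(rng.integers(0, k - true_gap + 1))  # outermost `run` right markers
            for j in range(k - run, k):
                doses[j] += 1
    return doses
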