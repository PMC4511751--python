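import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bittersel as b
from bittersel.io import HaplotypeAlignment, PopulationMap, SequenceRecord as R
from bittersel.popgen import harmonic_number


class TestNucleotideDiversity:
    def test_identical_sequences_have_zero_diversity(self):
        aln = HaplotypeAlignment([R("a", "ACGT"), R("b", "ACGT"), R("c", "ACGT")])
        assert b.nucleotide_diversity(aln) == 0.0

    def test_single_pair_single_mismatch(self):
        s1 = "A" * 100
        s2 = "A" * 99 + "T"
        aln = HaplotypeAlignment([R("a", s1), R("b", s2)])
        assert b.nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_matches_brute_force_pair_enumeration(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
        aln = HaplotypeAlignment([R(f"s{i}", s) for i, s in enumerate(seqs)])
        diffs = [
            sum(x != y for x, y in zip(seqs[i], seqs[j]))
            for i, j in combinations(range(4), 2)
        ]
        assert b.nucleotide_diversity(aln) == pytest.approx(np.mean(diffs) / 30)

    def test_requires_two_chromosomes(self):
        aln = HaplotypeAlignment([R("a", "ACGT")])
        with pytest.raises(ValueError):
            b.nucleotide_diversity(aln)

    def test_indel_and_missing_columns_excluded(self):
        aln = HaplotypeAlignment([R("a", "A-NT"), R("b", "AANA")])
        # usable columns: 1 and 4; one mismatch over two sites
        assert b.effective_length(aln) == 2
        assert b.nucleotide_diversity(aln) == pytest.approx(0.5)


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert b.watterson_theta(0, 10, 1000) == 0.0

    def test_pooled_sample_value(self):
        # S=15 over 1194 chromosomes and 1002 bp -> 0.195% per site
        assert b.watterson_theta(15, 1194, 1002) * 100 == pytest.approx(0.195, abs=5e-4)

    def test_small_population_value(self):
        # S=3 over 166 chromosomes and 1002 bp -> 0.053% per site
        assert b.watterson_theta(3, 166, 1002) * 100 == pytest.approx(0.053, abs=5e-4)

    def test_rejects_single_chromosome(self):
        with pytest.raises(ValueError):
            b.watterson_theta(3, 1, 1002)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, S, L = 10, 5, 1000
        pi = S / harmonic_number(n - 1) / L
        assert b.tajimas_d(pi, S, n, L) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        assert math.isnan(b.tajimas_d(0.0, 0, 10, 1000))

    def test_hand_computed_four_sequence_case(self):
        # n=4, L=10, S=2, pairwise-diff total 7 over 6 pairs; Tajima (1989)
        # constants evaluated by hand give D = 0.5915801398995606
        aln = HaplotypeAlignment(
            [
                R("s1", "AAAAAAAAAA"),
                R("s2", "AAAAAAAAAT"),
                R("s3", "AAAATAAAAT"),
                R("s4", "AAAATAAAAT"),
            ]
        )
        pi = b.nucleotide_diversity(aln)
        S = b.segregating_sites(aln)
        assert S == 2
        assert pi == pytest.approx(7 / 6 / 10)
        assert b.tajimas_d(pi, S, 4, 10) == pytest.approx(0.5915801398995606, rel=1e-12)

    def test_neutral_coalescent_samples_center_near_zero(self):
        ds = []
        for seed in range(150):
            aln = b.simulate_coalescent_alignment(b.CoalescentSpec(12, 4.0, 1000, seed=seed))
            S = b.segregating_sites(aln)
            if S == 0:
                continue
            ds.append(b.tajimas_d(b.nucleotide_diversity(aln), S, 12, b.effective_length(aln)))
        ds = np.array(ds)
        assert abs(ds.mean()) < 3 * ds.std() / math.sqrt(ds.size)
        # sign balance: neither tail collapses
        assert 0.2 < np.mean(ds > 0) < 0.8


class TestTajimaDPvalue:
    def test_central_observation_has_p_near_one(self):
        p = b.tajima_d_pvalue(0.0, 20, 0.005, 1000, replicates=1000, seed=5)
        assert p > 0.9

    def test_extreme_observation_rejected(self):
        p = b.tajima_d_pvalue(5.0, 20, 0.005, 1000, replicates=1000, seed=5)
        assert p < 0.01

    def test_moderate_positive_d_not_significant(self):
        # a D of 0.94 in a sample of 166 chromosomes stays above 0.05
        theta = b.watterson_theta(3, 166, 1002)
        p = b.tajima_d_pvalue(0.94, 166, theta, 1002, replicates=2000, seed=9)
        assert p >= 0.05

    def test_zero_theta_undefined(self):
        assert math.isnan(b.tajima_d_pvalue(1.0, 20, 0.0, 1000, replicates=1000, seed=0))

    def test_deterministic_given_seed(self):
        args = (1.2, 16, 0.004, 800)
        assert b.tajima_d_pvalue(*args, replicates=500, seed=3) == b.tajima_d_pvalue(
            *args, replicates=500, seed=3
        )


class TestFst:
    def test_two_by_two_brute_force(self, tiny_alignment, tiny_map):
        # within means: p1 -> 1, p2 -> 1; between mean: 1.5 -> F_ST = 1/3
        res = b.pairwise_fst(tiny_alignment, tiny_map, "p1", "p2")
        assert res.fst == pytest.approx(1 / 3)
        assert res.nm == pytest.approx(0.5)

    def test_fixed_divergent_populations(self):
        aln = HaplotypeAlignment([R("a1", "AAAA"), R("a2", "AAAA"), R("b1", "TTTT"), R("b2", "TTTT")])
        pmap = PopulationMap([("a1", "x"), ("a2", "x"), ("b1", "y"), ("b2", "y")])
        assert b.pairwise_fst(aln, pmap, "x", "y").fst == pytest.approx(1.0)

    def test_identical_composition_near_zero(self):
        # same 50/50 haplotype mix in both populations; the Hudson estimator
        # is slightly negative at finite n (exactly -1/(2n-1) here)
        records, rows = [], []
        for pop in ("x", "y"):
            for i in range(20):
                for allele, seq in (("A", "AAAA"), ("T", "TTTT")):
                    rid = f"{pop}{allele}{i}"
                    records.append(R(rid, seq))
                    rows.append((rid, pop))
        res = b.pairwise_fst(HaplotypeAlignment(records), PopulationMap(rows), "x", "y")
        assert res.fst == pytest.approx(0.0, abs=0.05)

    def test_monomorphic_identical_populations_undefined(self):
        aln = HaplotypeAlignment([R("a1", "AAAA"), R("a2", "AAAA"), R("b1", "AAAA"), R("b2", "AAAA")])
        pmap = PopulationMap([("a1", "x"), ("a2", "x"), ("b1", "y"), ("b2", "y")])
        assert math.isnan(b.pairwise_fst(aln, pmap, "x", "y").fst)


class TestNmConversion:
    def test_algebra(self):
        assert b.nm_from_fst(0.5) == pytest.approx(0.25)
        assert b.fst_from_nm(0.25) == pytest.approx(0.5)

    def test_seven_pairwise_values_average(self):
        nm = [3.27, 2.19, 1.75, 12.02, 15.49, 2.20, 2.09]
        assert round(float(np.mean(nm)), 1) == 5.6

    def test_high_migration_pair_rounds_to_low_fst(self):
        assert round(b.fst_from_nm(12.02), 2) == 0.02

    def test_nonpositive_fst_maps_to_infinite_migration(self):
        assert math.isinf(b.nm_from_fst(0.0))
        assert math.isinf(b.nm_from_fst(-0.05))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=1e-9, max_value=1.0))
    def test_round_trip_identity_on_unit_interval(self, fst):
        assert b.fst_from_nm(b.nm_from_fst(fst)) == pytest.approx(fst, abs=1e-12)


class TestHaplotypeSpectrum:
    def test_focal_population_private_fraction(self, kii_like_alignment):
        aln, pmap = kii_like_alignment
        spec = b.haplotype_spectrum(aln, pmap)
        # 23 of 80 chromosomes carry the population-private haplotype
        assert spec.private_fraction["focal"] == pytest.approx(0.2875)
        assert spec.shared_fraction["focal"] == pytest.approx(0.7125)
        focal = spec.table[spec.table.population == "focal"]
        assert sorted(focal["count"]) == [1, 1, 6, 17, 23, 32]
        assert focal["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_population_all_private(self, tiny_alignment):
        pmap = PopulationMap([(i, "only") for i in tiny_alignment.ids])
        spec = b.haplotype_spectrum(tiny_alignment, pmap)
        assert spec.private_fraction["only"] == 1.0

    def test_fully_shared_haplotype(self):
        aln = HaplotypeAlignment([R(f"c{i}", "ACGT") for i in range(4)])
        pmap = PopulationMap([("c0", "x"), ("c1", "x"), ("c2", "y"), ("c3", "y")])
        spec = b.haplotype_spectrum(aln, pmap)
        assert spec.private_fraction == {"x": 0.0, "y": 0.0}

    def test_counts_conserve_population_sizes(self, kii_like_alignment):
        aln, pmap = kii_like_alignment
        spec = b.haplotype_spectrum(aln, pmap)
        for pop in pmap.populations:
            total = spec.table[spec.table.population == pop]["count"].sum()
            assert total == len(pmap.chromosomes(pop))


class TestSiteCounting:
    @pytest.mark.parametrize(
        "cds, syn, nonsyn",
        [
            ("GGG", 1.0, 2.0),          # glycine: 3rd position fully synonymous
            ("", 0.0, 0.0),
            ("ATGAAA", 1 / 3, 17 / 3),  # ATG has no synonymous change; AAA one
        ],
    )
    def test_enumerated_codon_examples(self, cds, syn, nonsyn):
        counts = b.count_syn_nonsyn_sites(cds)
        assert counts.syn_sites == pytest.approx(syn)
        assert counts.nonsyn_sites == pytest.approx(nonsyn)

    def test_totals_are_three_per_counted_codon(self, rng):
        # random CDS without internal stops: syn + nonsyn = 3 x codons
        codons = [c for c in _all_codons() if _aa(c) != "*"]
        cds = "".join(rng.choice(codons, 20))
        counts = b.count_syn_nonsyn_sites(cds)
        assert counts.syn_sites + counts.nonsyn_sites == pytest.approx(60)

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            b.count_syn_nonsyn_sites("ACGT")


class TestClassifySnv:
    @pytest.mark.parametrize(
        "cds, pos, alt, expected",
        [
            ("ATGGGGTGG", 2, "C", "start-loss"),   # ATG -> ACG
            ("ATGGGGTGG", 6, "A", "synonymous"),   # GGG -> GGA
            ("ATGGGGTGG", 8, "A", "nonsense"),     # TGG -> TAG
            ("ATGGGGTGG", 4, "A", "nonsynonymous"),  # GGG -> AGG
        ],
    )
    def test_classification(self, cds, pos, alt, expected):
        assert b.classify_snv(cds, pos, alt) == expected

    def test_reference_base_rejected(self):
        with pytest.raises(ValueError):
            b.classify_snv("ATG", 1, "A")


class TestDiversitySummary:
    def test_pooled_and_per_population_rows(self, tiny_alignment, tiny_map):
        rows = b.diversity_summary(tiny_alignment, tiny_map)
        assert [r.population for r in rows] == ["p1", "p2", "all"]
        pooled = rows[-1]
        assert pooled.n_chromosomes == 4
        assert pooled.S == 2
        assert pooled.n_haplotypes == 4
        assert pooled.pi == pytest.approx(b.nucleotide_diversity(tiny_alignment))


def _all_codons():
    from itertools import product

    return ["".join(c) for c in product("ACGT", repeat=3)]


def _aa(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())
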