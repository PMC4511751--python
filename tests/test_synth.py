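import math
from itertools import combinations

import numpy as np
import pytest

import bittersel as b
from bittersel.popgen import _mean_pairwise_diff, _seq_matrix, harmonic_number


class TestCoalescentGenerator:
    def test_zero_theta_monomorphic(self):
        aln = b.simulate_coalescent_alignment(b.CoalescentSpec(6, 0.0, 200, seed=1))
        assert b.segregating_sites(aln) == 0
        assert len({r.sequence for r in aln.records}) == 1

    def test_deterministic_under_seed_and_sensitive_to_it(self):
        a1 = b.simulate_coalescent_alignment(b.CoalescentSpec(6, 4.0, 500, seed=7))
        a2 = b.simulate_coalescent_alignment(b.CoalescentSpec(6, 4.0, 500, seed=7))
        a3 = b.simulate_coalescent_alignment(b.CoalescentSpec(6, 4.0, 500, seed=8))
        assert [r.sequence for r in a1.records] == [r.sequence for r in a2.records]
        assert [r.sequence for r in a1.records] != [r.sequence for r in a3.records]

    def test_watterson_and_pairwise_expectations(self):
        # E[S] = theta * a_{n-1} and E[pi * L] = theta under neutrality
        theta, n, reps = 3.0, 10, 1000
        S, piL = [], []
        for seed in range(reps):
            aln = b.simulate_coalescent_alignment(b.CoalescentSpec(n, theta, 1000, seed=seed))
            S.append(b.segregating_sites(aln))
            piL.append(b.nucleotide_diversity(aln) * b.effective_length(aln))
        expect_S = theta * harmonic_number(n - 1)
        assert np.mean(S) == pytest.approx(expect_S, rel=0.06)
        assert np.mean(piL) == pytest.approx(theta, rel=0.08)

    def test_matches_msprime_oracle_mean_segregating_sites(self):
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 4.0, 8, 400
        ours = []
        for seed in range(reps):
            aln = b.simulate_coalescent_alignment(b.CoalescentSpec(n, theta, 2000, seed=seed))
            ours.append(b.segregating_sites(aln))
        # msprime with haploid samples and population_size=1: pairs coalesce
        # at rate 1, matching branch lengths in 2N-generation units, so the
        # locus mutation rate is theta/2
        reference = []
        for ts in msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1, num_replicates=reps, random_seed=11
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=12, discrete_genome=False
            )
            reference.append(mts.num_sites)
        se = math.hypot(np.std(ours) / math.sqrt(reps), np.std(reference) / math.sqrt(reps))
        assert abs(np.mean(ours) - np.mean(reference)) < 3 * se

    def test_exchangeable_epoch_durations(self):
        # expected time while k lineages are active is proportional to 1/(k(k-1))
        from bittersel.synth import _kingman_tree

        rng = np.random.default_rng(5)
        n = 6
        sums = np.zeros(n - 1)
        reps = 2000
        for _ in range(reps):
            parent, time = _kingman_tree(n, rng)
            heights = sorted(time[n:])
            prev = 0.0
            for k, h in zip(range(n, 1, -1), heights):
                sums[n - k] += h - prev
                prev = h
        means = sums / reps
        ks = np.arange(n, 1, -1)
        expected = 2.0 / (ks * (ks - 1))
        assert np.allclose(means, expected, rtol=0.15)


class TestIslandGenerator:
    def test_panmixia_limit_near_zero_fst(self):
        hw, hb = [], []
        for seed in range(25):
            aln, pmap = b.simulate_island_samples(b.IslandSpec(4, 6, 100.0, 2.0, 1000, seed=seed))
            mat = _seq_matrix(aln)
            idx = {p: [aln.ids.index(c) for c in pmap.chromosomes(p)] for p in pmap.populations}
            for pa, pb in combinations(pmap.populations, 2):
                hw.append(0.5 * (_mean_pairwise_diff(mat, idx[pa]) + _mean_pairwise_diff(mat, idx[pb])))
                hb.append(_mean_pairwise_diff(mat, idx[pa], idx[pb]))
        fst = 1 - np.mean(hw) / np.mean(hb)
        assert abs(fst) < 0.05

    def test_equilibrium_fst_matches_finite_island_formula(self):
        d, nm = 10, 1.0
        hw, hb = [], []
        for seed in range(60):
            aln, pmap = b.simulate_island_samples(b.IslandSpec(d, 8, nm, 2.0, 2000, seed=seed))
            mat = _seq_matrix(aln)
            idx = {p: [aln.ids.index(c) for c in pmap.chromosomes(p)] for p in pmap.populations}
            for pa, pb in combinations(pmap.populations, 2):
                hw.append(0.5 * (_mean_pairwise_diff(mat, idx[pa]) + _mean_pairwise_diff(mat, idx[pb])))
                hb.append(_mean_pairwise_diff(mat, idx[pa], idx[pb]))
        fst = 1 - np.mean(hw) / np.mean(hb)
        expected = 1.0 / (1.0 + 4 * nm * (d / (d - 1)) ** 2)
        assert fst == pytest.approx(expected, rel=0.20)

    def test_isolated_demes_diverge_completely(self):
        aln, pmap = b.simulate_island_samples(b.IslandSpec(2, 4, 0.0, 1.0, 5000, seed=3))
        res = b.pairwise_fst(aln, pmap, "deme1", "deme2")
        assert res.fst > 0.9

    def test_labels_cover_all_demes_equally(self):
        aln, pmap = b.simulate_island_samples(b.IslandSpec(3, 5, 1.0, 1.0, 500, seed=0))
        assert len(pmap.populations) == 3
        assert all(len(pmap.chromosomes(p)) == 5 for p in pmap.populations)


class TestStarGenerator:
    def test_zero_time_all_identical(self):
        aln = b.generate_star_haplotypes(b.StarSpec(10, 1000, 1e-9, 0.0, seed=1))
        assert len({r.sequence for r in aln.records}) == 1

    def test_mean_total_mutations_matches_poisson_rate(self):
        n, L, mu, t = 23, 10_000, 1e-9, 13_024
        counts = []
        for seed in range(300):
            aln = b.generate_star_haplotypes(b.StarSpec(n, L, mu, t, seed=seed))
            counts.append(b.segregating_sites(aln))
        lam = n * L * mu * t
        assert np.mean(counts) == pytest.approx(lam, rel=0.15)


class TestBehavioralFixtures:
    def test_preference_noise_free_points_on_curve(self):
        trials = b.generate_preference_trials(100.0, 2.0, noise_sd=0.0, seed=0)
        for c, arr in zip(trials.concentrations, trials.ratios):
            assert arr == pytest.approx(b.preference_model(c, 100.0, 2.0))

    def test_preference_mean_near_quarter_at_ec50(self):
        trials = b.generate_preference_trials(
            100.0, 2.0, concentrations=(100.0,), trials=500, noise_sd=0.05, seed=1
        )
        assert float(np.mean(trials.ratios[0])) == pytest.approx(0.25, abs=0.02)

    def test_default_design_matches_two_bottle_protocol(self):
        trials = b.generate_preference_trials(100.0, 2.0, seed=0)
        assert list(trials.concentrations) == [1.0, 10.0, 100.0, 250.0, 1000.0]
        assert all(arr.size == 6 for arr in trials.ratios)

    def test_titration_limits_and_midpoint(self):
        curve = b.generate_titration_curves(0.2, 1.8, 50.0, 2.0, (50.0, 1e7), replicates=1, noise_sd=0.0, seed=0)
        mid, high = (float(arr[0]) for arr in curve.responses)
        assert mid == pytest.approx((0.2 + 1.8) / 2)
        assert high == pytest.approx(1.8, rel=1e-6)

    def test_titration_default_replicates_are_triplicate(self):
        curve = b.generate_titration_curves(0, 1, 10.0, 1.0, (1.0, 10.0, 100.0), seed=0)
        assert all(arr.size == 3 for arr in curve.responses)
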