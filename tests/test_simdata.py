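import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_map, make_matrix, random_matrix
from neld import (
    EmptySelectionError,
    InvalidConfigError,
    MISSING,
    NeldError,
    PairPolicy,
    SimConfig,
    downsample_loci,
    fragment_map,
    inject_missing,
    pairwise_r2,
    sample_individuals,
    simulate_population,
    stratify_by_q,
)
from neld.ldcore import LINKED_BINNED
from neld.simdata import inject_missing_genotype_dependent


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = SimConfig()
        assert cfg.burnin_generations == min(4 * cfg.final_n, 500)

    def test_rejects_tiny_population(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(ne_trajectory=[(0, 1)])

    def test_rejects_migration_with_one_deme(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_demes=1, migration_rate=0.1)

    def test_rejects_bad_init_bounds(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(init_freq_low=0.9, init_freq_high=0.1)

    def test_trajectory_step_lookup(self):
        cfg = SimConfig(ne_trajectory=[(0, 100), (10, 30)])
        assert cfg.n_at(0) == 100
        assert cfg.n_at(9) == 100
        assert cfg.n_at(10) == 30
        assert cfg.final_n == 30


class TestSimulatePopulation:
    def test_seeded_determinism(self):
        cfg = dict(
            ne_trajectory=[(0, 20)],
            n_chromosomes=2,
            loci_per_chromosome=30,
            burnin_generations=15,
            seed=5,
        )
        a = simulate_population(SimConfig(**cfg))
        b = simulate_population(SimConfig(**cfg))
        assert np.array_equal(a.matrix.dosages, b.matrix.dosages)
        assert np.array_equal(a.matrix.map.bp, b.matrix.map.bp)
        assert np.array_equal(a.q_values, b.q_values)

    def test_two_demes_no_migration_pure_q(self, two_deme_population):
        q = two_deme_population.q_values
        assert set(np.unique(q)) <= {0.0, 1.0}
        labels = two_deme_population.matrix.deme_labels
        assert np.all((q == 1.0) == (labels == "A"))

    def test_population_size_matches_trajectory(self):
        pop = simulate_population(
            SimConfig(
                ne_trajectory=[(0, 30), (5, 12)],
                n_chromosomes=1,
                loci_per_chromosome=10,
                burnin_generations=5,
                seed=2,
            )
        )
        assert pop.matrix.n_individuals == 12
        assert pop.true_ne_trajectory[-1] == (5, 12)

    def test_heterozygosity_drift_decay(self):
        """Mean heterozygosity decays by (1 - 1/(2N)) per generation.

        Closed-form oracle: founders in linkage equilibrium at
        p ~ U(0.05, 0.95) have E[het] = 2(E[p] - E[p^2]) = 0.365; after t
        generations the expectation is multiplied by (1 - 1/(2N))^t.
        """
        N, t, reps = 50, 60, 60
        h0 = 2 * (0.5 - (0.25 + 0.9**2 / 12))
        expected = h0 * (1 - 1 / (2 * N)) ** t
        hets = []
        for rep in range(reps):
            pop = simulate_population(
                SimConfig(
                    ne_trajectory=[(0, N), (t, N)],
                    n_chromosomes=1,
                    loci_per_chromosome=150,
                    burnin_generations=0,
                    seed=31000 + rep,
                )
            )
            hets.append(float((pop.matrix.dosages == 1).mean()))
        got = float(np.mean(hets))
        se = float(np.std(hets) / math.sqrt(reps))
        assert abs(got - expected) < 4 * se + 0.004, (got, expected, se)

    def test_allele_frequency_conserved_and_drift_calibrated(self):
        """Single-generation transitions: E[dp] = 0, Var[dp] = p(1-p)/(2N)."""
        N, reps = 40, 200
        z_sq, dps = [], []
        for rep in range(reps):
            pop = simulate_population(
                SimConfig(
                    ne_trajectory=[(0, N), (1, N)],
                    n_chromosomes=1,
                    loci_per_chromosome=60,
                    burnin_generations=0,
                    seed=52000 + rep,
                )
            )
            p0 = pop.founder_freqs
            p1 = pop.matrix.allele_frequencies()
            seg = (p0 > 0) & (p0 < 1)  # loci already fixed in founders carry no drift
            dp = p1[seg] - p0[seg]
            dps.extend(dp.tolist())
            z_sq.extend((dp**2 / (p0[seg] * (1 - p0[seg]))).tolist())
        dps = np.asarray(dps)
        mean_dp = dps.mean()
        se = dps.std() / math.sqrt(dps.size)
        assert abs(mean_dp) < 4 * se + 1e-4
        mean_z = float(np.mean(z_sq))
        assert mean_z == pytest.approx(1 / (2 * N), rel=0.10)

    def test_ld_decays_with_distance(self):
        """Mean r^2 non-increasing over within-chromosome distance bins."""
        wins = 0
        edges = np.geomspace(0.02, 0.5, 6)
        for rep in range(10):
            pop = simulate_population(
                SimConfig(
                    ne_trajectory=[(0, 50)],
                    n_chromosomes=1,
                    loci_per_chromosome=150,
                    burnin_generations=200,
                    seed=64000 + rep,
                )
            )
            summary = pairwise_r2(
                pop.matrix,
                PairPolicy(
                    mode=LINKED_BINNED, bin_edges=edges, min_pairs_per_bin=5, seed=rep
                ),
            )
            cs, r2s = [], []
            for cls in summary.classes:
                if cls.n_pairs >= 20:
                    cs.append(cls.c_mean)
                    r2s.append(cls.mean_r2)
            if len(cs) >= 3:
                rho = stats.spearmanr(cs, r2s).statistic
                wins += rho <= 0
        assert wins >= 6, f"LD-distance monotonicity held in only {wins}/10 runs"


class TestSampleIndividuals:
    def test_full_sample_is_identity_set(self, small_population):
        G = small_population.matrix
        sub = sample_individuals(G, G.n_individuals, seed=1)
        assert sorted(sub.individual_ids) == sorted(G.individual_ids)

    def test_sweep_sizes_supported(self, small_population):
        for n in (15, 40):
            assert sample_individuals(small_population, n, seed=0).n_individuals == n

    def test_oversample_rejected(self, small_population):
        G = small_population.matrix
        with pytest.raises(NeldError, match=str(G.n_individuals)):
            sample_individuals(G, G.n_individuals + 1)

    def test_two_seeds_differ(self, small_population):
        a = sample_individuals(small_population, 10, seed=1)
        b = sample_individuals(small_population, 10, seed=2)
        assert set(a.individual_ids) != set(b.individual_ids)

    def test_metadata_carried(self, two_deme_population):
        sub = sample_individuals(two_deme_population, 20, seed=3)
        assert sub.q_values is not None and sub.deme_labels is not None


class TestInjectMissing:
    def test_zero_rate_unchanged(self, rng):
        G = random_matrix(rng)
        out = inject_missing(G, 0.0, seed=1)
        assert np.array_equal(out.dosages, G.dosages)

    def test_realized_rate_within_binomial_bounds(self, rng):
        G = random_matrix(rng, n_ind=100, n_loci=1000)
        out = inject_missing(G, 0.4, seed=2)
        per_ind = out.missing_mask().mean(axis=1)
        half_width = 2.58 * math.sqrt(0.4 * 0.6 / 1000)
        assert np.all(per_ind > 0.4 - 2 * half_width)
        assert np.all(per_ind < 0.4 + 2 * half_width)

    def test_per_individual_rate_vector(self, rng):
        G = random_matrix(rng, n_ind=10, n_loci=800)
        rates = np.zeros(10)
        rates[3] = 0.95
        out = inject_missing(G, rates, seed=3)
        per_ind = out.missing_mask().mean(axis=1)
        assert per_ind[3] == pytest.approx(0.95, abs=0.05)
        others = np.delete(per_ind, 3)
        assert np.all(others == 0)

    def test_rate_out_of_range(self, rng):
        G = random_matrix(rng)
        with pytest.raises(NeldError):
            inject_missing(G, 1.0)

    def test_non_mutating(self, rng):
        G = random_matrix(rng)
        before = G.dosages.copy()
        inject_missing(G, 0.5, seed=4)
        assert np.array_equal(G.dosages, before)

    def test_genotype_dependent_mode_hits_hets_harder(self, rng):
        G = random_matrix(rng, n_ind=60, n_loci=600)
        out = inject_missing_genotype_dependent(G, 0.2, het_factor=3.0, seed=5)
        was_het = G.dosages == 1
        miss = out.missing_mask()
        het_rate = miss[was_het].mean()
        hom_rate = miss[~was_het].mean()
        assert het_rate > 1.5 * hom_rate


class TestDownsampleLoci:
    def test_identity(self, rng):
        G = random_matrix(rng, n_loci=30)
        out = downsample_loci(G, 30, seed=1)
        assert np.array_equal(out.dosages, G.dosages)

    def test_order_preserved(self, rng):
        G = random_matrix(rng, n_ind=10, n_loci=60, n_chrom=4)
        out = downsample_loci(G, 25, seed=2)
        m = out.map
        order = np.lexsort((m.bp, m.chrom_id))
        assert np.array_equal(order, np.arange(m.n_loci))

    def test_oversample_rejected(self, rng):
        G = random_matrix(rng, n_loci=20)
        with pytest.raises(NeldError):
            downsample_loci(G, 21)

    def test_desk_scale_ladder(self, rng):
        G = random_matrix(rng, n_ind=8, n_loci=500, n_chrom=5)
        for n in (50, 120, 400):
            assert downsample_loci(G, n, seed=3).n_loci == n


class TestFragmentMap:
    def test_factor_one_noop_on_unit_map(self):
        m = make_map(np.repeat([1, 2], 10), length=1.0)
        out = fragment_map(m, 2)
        assert np.array_equal(out.chrom_id, m.chrom_id)
        np.testing.assert_allclose(out.genetic_pos, m.genetic_pos, atol=1e-12)

    def test_block_sizes_ten_into_three(self):
        # 10 loci on one chromosome -> 3 blocks of sizes {4, 3, 3}
        m = make_map(np.ones(10, dtype=int))
        out = fragment_map(m, 3)
        _, counts = np.unique(out.chrom_id, return_counts=True)
        assert sorted(counts.tolist(), reverse=True) == [4, 3, 3]

    def test_fragmentation_series_constructible(self, rng):
        m = make_map(np.repeat(np.arange(1, 9), 16))
        for n in (8, 16, 32, 64, 128):
            out = fragment_map(m, n)
            assert out.n_chromosomes == n
            assert np.array_equal(out.chromosomes, np.arange(1, n + 1))

    def test_non_multiple_rejected(self):
        m = make_map(np.repeat([1, 2, 3], 6))
        with pytest.raises(NeldError):
            fragment_map(m, 7)
        with pytest.raises(NeldError):
            fragment_map(m, 2)

    def test_rescaled_positions_within_morgan(self):
        m = make_map(np.repeat([1, 2], 40), length=1.0)
        out = fragment_map(m, 8)
        assert out.genetic_pos.min() >= 0
        assert out.genetic_pos.max() <= 1.0
        for c in out.chromosomes:
            g = out.genetic_pos[out.chrom_id == c]
            assert np.all(np.diff(g) >= 0)

    def test_non_mutating(self):
        m = make_map(np.repeat([1, 2], 10))
        gpos_before = m.genetic_pos.copy()
        fragment_map(m, 4)
        assert np.array_equal(m.genetic_pos, gpos_before)


class TestStratifyByQ:
    def test_zero_threshold_keeps_all(self, two_deme_population):
        G = two_deme_population.matrix
        assert stratify_by_q(G, 0.0).n_individuals == G.n_individuals

    def test_threshold_ladder_accepted(self, two_deme_population):
        G = two_deme_population.matrix
        for q in (0.70, 0.80, 0.90, 0.95, 0.99):
            sub = stratify_by_q(G, q, "A")
            assert sub.n_individuals >= 1

    def test_pure_threshold_recovers_founder_deme(self, two_deme_population):
        G = two_deme_population.matrix
        a = stratify_by_q(G, 0.99, "A")
        assert set(a.deme_labels) == {"A"}
        assert a.n_individuals == int((G.deme_labels == "A").sum())
        b = stratify_by_q(G, 0.99, "B")
        assert set(b.deme_labels) == {"B"}

    def test_empty_selection_raises(self, rng):
        G = random_matrix(rng)
        G = G.replace(q_values=np.full(G.n_individuals, 0.5))
        with pytest.raises(EmptySelectionError):
            stratify_by_q(G, 0.99, "A")

    def test_missing_q_rejected(self, rng):
        with pytest.raises(NeldError):
            stratify_by_q(random_matrix(rng), 0.5)
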