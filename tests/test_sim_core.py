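"""Simulation engine: life cycle, fitness scheme, recombination, mutation."""

import math

import numpy as np
import pytest

from congeal import sim_core
from congeal.sim_core import (
    ConfigurationError,
    EmptyDemeError,
    SimulationParams,
    effective_migration_rate,
    fitness_vector,
    init_population,
    introduce_mutations,
    make_gamete,
    migrate,
    prune_sites,
    reproduce,
    run_simulation,
    step_generation,
)
from conftest import build_state


def small_params(**kw):
    defaults = dict(s_mean=0.02, m=0.01, N_total=100, seed=0)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestInit:
    def test_standard_population(self):
        st = init_population(SimulationParams(s_mean=0.005, m=0.01,
                                              N_total=5000))
        assert (st.deme == 0).sum() == 2500
        assert (st.deme == 1).sum() == 2500
        assert st.n_sites == 0
        assert st.generation == 0

    def test_smallest_even_case(self):
        st = init_population(small_params(N_total=4))
        assert (st.deme == 0).sum() == 2

    @pytest.mark.parametrize("bad", [5001, 3, 0, -10])
    def test_odd_or_tiny_sizes_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            small_params(N_total=bad)

    def test_param_range_validation(self):
        with pytest.raises(ConfigurationError):
            small_params(m=1.5)
        with pytest.raises(ConfigurationError):
            small_params(s_mean=0.0)
        with pytest.raises(ConfigurationError):
            small_params(p_neutral=1.2)


class TestMigration:
    def test_m_zero_is_identity(self, rng):
        st = init_population(small_params())
        before = st.deme.copy()
        migrate(st, 0.0, rng)
        assert np.array_equal(st.deme, before)
        assert not st.immigrant.any()

    def test_m_one_swaps_demes(self, rng):
        st = init_population(small_params())
        before = st.deme.copy()
        migrate(st, 1.0, rng)
        assert np.array_equal(st.deme, 1 - before)
        assert st.immigrant.all()

    def test_migrant_count_matches_binomial_expectation(self, rng):
        # Nm expectation: mean migrants/generation ~ N*m within binomial error
        n, m, reps = 1000, 0.1, 300
        counts = []
        for _ in range(reps):
            st = init_population(small_params(N_total=n))
            migrate(st, m, rng)
            counts.append(st.immigrant.sum())
        expected = n * m
        se = math.sqrt(n * m * (1 - m) / reps)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_total_count_conserved(self, rng):
        st = init_population(small_params())
        migrate(st, 0.3, rng)
        assert len(st.deme) == 100


class TestFitness:
    def _one_locus_state(self, genotypes_by_deme, s_i):
        """genotypes_by_deme: dict deme -> list of dosages (one locus);
        demes are padded with ancestral homozygotes to the minimum size."""
        n_per = max(2, max(len(v) for v in genotypes_by_deme.values()))
        H = np.zeros((4 * n_per, 1), dtype=np.uint8)
        for k, dosages in genotypes_by_deme.items():
            for i, g in enumerate(dosages):
                row = 2 * (k * n_per + i)
                H[row, 0] = 1 if g >= 1 else 0
                H[row + 1, 0] = 1 if g == 2 else 0
        return build_state(H, [0.2], [s_i], [False])

    def test_ancestral_homozygote_favored_in_deme1(self):
        # deme index 0 is "deme 1": ancestral AiAi gets 1+si there
        st = self._one_locus_state({0: [0, 1, 2], 1: [0, 1, 2]}, 0.02)
        w0 = fitness_vector(st, 0)
        assert w0 == pytest.approx([1.02, 1.01, 1.0])
        w1 = fitness_vector(st, 1)
        assert w1 == pytest.approx([1.0, 1.01, 1.02])

    def test_heterozygote_intermediate_in_both_demes(self):
        st = self._one_locus_state({0: [1], 1: [1]}, 0.02)
        assert fitness_vector(st, 0)[0] == pytest.approx(1.01)
        assert fitness_vector(st, 1)[0] == pytest.approx(1.01)

    def test_multiplicative_across_loci(self):
        # AiAi at locus 1 (s=0.1) and BiBi at locus 2 (s=0.2) in deme 1
        H = np.zeros((8, 2), dtype=np.uint8)
        H[0:2, 1] = 1  # individual 0 (deme 0): homozygous derived at locus 2
        st = build_state(H, [0.1, 0.3], [0.1, 0.2], [False, False])
        w = fitness_vector(st, 0)
        assert w[0] == pytest.approx(1.1 * 1.0)

    def test_fitness_at_least_one_and_neutral_ignored(self, rng):
        p = small_params(s_mean=0.1, N_total=60)
        st = init_population(p)
        r = np.random.default_rng(0)
        for _ in range(60):
            step_generation(st, p, r)
        for k in (0, 1):
            assert (fitness_vector(st, k) >= 1.0).all()

    def test_fast_path_matches_reference(self):
        p = small_params(s_mean=0.05, N_total=80)
        st = init_population(p)
        r = np.random.default_rng(1)
        for i in range(120):
            step_generation(st, p, r, compact=(i % 7 == 0))
        fast = sim_core._relative_fitness_by_deme(st)
        for k in (0, 1):
            ref = fitness_vector(st, k)
            ratio = ref / fast[k]
            assert ratio.max() / ratio.min() == pytest.approx(1.0, abs=1e-5)


class TestEffectiveMigration:
    def test_no_immigrants(self):
        w = {0: np.ones(5), 1: np.ones(5)}
        imm = {0: np.zeros(5, bool), 1: np.zeros(5, bool)}
        assert effective_migration_rate(w, imm) == 0.0

    def test_equal_fitness_gives_immigrant_fraction(self):
        w = {0: np.ones(10), 1: np.ones(10)}
        imm = {0: np.arange(10) < 3, 1: np.arange(10) < 3}
        assert effective_migration_rate(w, imm) == pytest.approx(0.3)

    def test_weighted_ratio(self):
        # 2 immigrants with W=1 among 8 residents with W=2 -> 2/18
        w = {0: np.array([1.0] * 2 + [2.0] * 8)}
        imm = {0: np.arange(10) < 2}
        assert effective_migration_rate(w, imm) == pytest.approx(2 / 18)

    def test_empty_deme_signalled(self):
        with pytest.raises(EmptyDemeError):
            effective_migration_rate({0: np.empty(0)},
                                     {0: np.empty(0, bool)})


class TestRecombination:
    def test_no_crossover_copies_parent_verbatim(self):
        params = small_params(n_chromosomes=1, chrom_length_morgans=1e-9)
        hap_a = np.array([0, 1, 0, 1, 1], dtype=np.uint8)
        hap_b = np.array([1, 0, 1, 0, 0], dtype=np.uint8)
        pos = np.linspace(0, 1e-10, 5)
        r = np.random.default_rng(0)
        for _ in range(20):
            g = make_gamete((hap_a, hap_b), pos, params, r)
            assert np.array_equal(g, hap_a) or np.array_equal(g, hap_b)

    def test_mean_crossover_count_equals_map_length(self):
        """Four 0.5 M chromosomes: mean total crossovers per gamete ~ 2."""
        params = SimulationParams(s_mean=0.01, m=0.01, N_total=100)
        r = np.random.default_rng(2)
        n = 50_000
        total = 0
        for _ in range(n):
            _, events = sim_core.draw_recombination_events(params, r)
            # events include Bernoulli(1/2) boundary switches at the three
            # chromosome junctions; exclude those to count true crossovers
            total += np.sum(~np.isin(events, [0.5, 1.0, 1.5]))
        assert total / n == pytest.approx(2.0, abs=0.05)

    def test_haldane_recombinant_fraction(self):
        """Two loci 0.1 M apart: recombinant fraction matches Haldane's
        0.5(1 - exp(-0.2)) ~ 0.0906 under Poisson crossovers."""
        params = SimulationParams(s_mean=0.01, m=0.01, N_total=100,
                                  n_chromosomes=1, chrom_length_morgans=0.5)
        hap_a = np.array([1, 1], dtype=np.uint8)  # repulsion double het
        hap_b = np.array([0, 0], dtype=np.uint8)
        pos = np.array([0.2, 0.3])
        r = np.random.default_rng(3)
        n = 40_000
        rec = 0
        for _ in range(n):
            g = make_gamete((hap_a, hap_b), pos, params, r)
            rec += g[0] != g[1]
        expected = 0.5 * (1 - math.exp(-0.2))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 4 * se

    def test_independent_assortment_between_chromosomes(self):
        params = SimulationParams(s_mean=0.01, m=0.01, N_total=100,
                                  n_chromosomes=4, chrom_length_morgans=0.5)
        hap_a = np.array([1, 1], dtype=np.uint8)
        hap_b = np.array([0, 0], dtype=np.uint8)
        pos = np.array([0.25, 1.75])  # chromosomes 0 and 3
        r = np.random.default_rng(4)
        n = 20_000
        rec = sum(int(g[0] != g[1]) for g in
                  (make_gamete((hap_a, hap_b), pos, params, r)
                   for _ in range(n)))
        assert abs(rec / n - 0.5) < 4 * math.sqrt(0.25 / n)

    def test_batch_kernel_matches_reference(self):
        """The compiled gamete assembly agrees with the numpy reference."""
        if not sim_core._HAVE_NUMBA:
            pytest.skip("numba unavailable")
        rng = np.random.default_rng(9)
        for trial in range(5):
            n, S = 17, 43
            H = rng.integers(0, 2, size=(2 * n, S)).astype(np.uint8)
            positions = rng.random(S) * 2.0
            parents = rng.integers(0, n, size=2 * n).astype(np.int64)
            starts = rng.integers(0, 2, size=2 * n).astype(np.int64)
            n_x = rng.poisson(2.0, size=2 * n)
            xoff = np.zeros(2 * n + 1, dtype=np.int64)
            np.cumsum(n_x, out=xoff[1:])
            xpos = rng.random(int(xoff[-1])) * 2.0
            flips = (rng.random((2 * n, 3)) < 0.5).astype(np.uint8)
            bound_pos = np.arange(1, 4) * 0.5
            rows, cols = np.nonzero(H[0::2] != H[1::2])
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(np.bincount(rows, minlength=n), out=indptr[1:])
            o1 = np.empty((2 * n, S), dtype=np.uint8)
            o2 = np.empty_like(o1)
            sim_core._assemble_gametes_nb(
                H, indptr, cols.astype(np.int64), parents, starts, xpos,
                xoff, flips, bound_pos, positions, o1)
            sim_core._assemble_gametes_py(
                H, indptr, cols.astype(np.int64), parents, starts, xpos,
                xoff, flips, bound_pos, positions, o2)
            assert np.array_equal(o1, o2)


class TestReproduction:
    def test_deme_size_preserved_exactly(self, rng):
        p = small_params()
        st = init_population(p)
        for _ in range(5):
            step_generation(st, p, rng)
        assert (st.deme == 0).sum() == p.deme_size
        assert (st.deme == 1).sum() == p.deme_size

    def test_dominant_parent_monopolizes_but_never_selfs(self, rng):
        p = small_params(N_total=20)
        st = init_population(p)
        idx = st.deme_indices(0)
        w = np.ones(len(idx))
        w[0] = 1e6
        p1, p2 = sim_core._sample_parent_pairs(idx, w, 500, rng)
        both = np.concatenate([p1, p2])
        assert (both == idx[0]).mean() > 0.45
        assert not np.any(p1 == p2)

    def test_too_small_deme_raises(self, rng):
        p = small_params(N_total=4)
        st = init_population(p)
        st.deme[:] = 0  # everyone in deme 0
        with pytest.raises(EmptyDemeError):
            reproduce(st, p, rng)

    def test_neutral_drift_matches_wright_fisher_variance(self):
        """With equal fitness, one generation of reproduction changes the
        allele frequency with variance ~ p(1-p)/(2 deme_size)."""
        p = small_params(N_total=200, m=0.0)
        deme = p.deme_size
        freqs = []
        rng = np.random.default_rng(11)
        for _ in range(400):
            st = init_population(p)
            H = np.zeros((2 * p.N_total, 1), dtype=np.uint8)
            # exactly p = 0.5 within each deme, so the offspring variance
            # is purely the resampling (drift) variance
            half = p.N_total  # haplotype rows per deme
            H[rng.permutation(half)[:half // 2], 0] = 1
            H[half + rng.permutation(half)[:half // 2], 0] = 1
            st.haplotypes = H
            st.positions = np.array([0.3])
            st.s_coef = np.array([0.0])
            st.neutral = np.array([True])
            st.favored = np.ones(1, dtype=np.int8)
            reproduce(st, p, rng)
            freqs.append(st.haplotypes[: 2 * deme, 0].mean())
        var = np.var(freqs)
        # parents drawn with replacement: WF variance p q / (2 N_deme)
        expected = 0.5 * 0.5 / (2 * deme)
        assert var == pytest.approx(expected, rel=0.35)


class TestMutation:
    def test_exact_count_per_generation(self, rng):
        p = small_params()
        st = init_population(p)
        introduce_mutations(st, p, rng)
        assert st.mutations_introduced_total == 10
        assert st.n_sites == 10
        assert st.haplotypes.sum() == 10  # one copy each

    def test_neutral_fraction_statistics(self):
        p = small_params(N_total=20, s_mean=0.02)
        rng = np.random.default_rng(6)
        st = init_population(p)
        neutral = 0
        s_draws = []
        n_gen = 3000
        for _ in range(n_gen):
            recs = introduce_mutations(st, p, rng)
            for r in recs:
                if r.kind == "neutral":
                    neutral += 1
                else:
                    s_draws.append(r.s_i)
        n = 10 * n_gen
        frac = neutral / n
        p_exp = 10 / 11
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(frac - p_exp) < 4 * se
        mean_s = np.mean(s_draws)
        se_s = np.std(s_draws) / math.sqrt(len(s_draws))
        assert abs(mean_s - 0.02) < 4 * se_s

    def test_positions_unique_and_in_range(self, rng):
        p = small_params()
        st = init_population(p)
        for _ in range(50):
            introduce_mutations(st, p, rng)
        assert len(np.unique(st.positions)) == st.n_sites
        assert (st.positions >= 0).all()
        assert (st.positions < p.genome_length).all()

    def test_record_invariants(self, rng):
        p = small_params()
        st = init_population(p)
        introduce_mutations(st, p, rng)
        for r in st.records:
            assert (r.s_i == 0) == (r.kind == "neutral")
            assert 0 <= r.position_morgans < p.chrom_length_morgans


class TestPrune:
    def test_lost_and_fixed_removed(self):
        H = np.zeros((8, 3), dtype=np.uint8)
        H[:, 1] = 1          # fixed
        H[0, 2] = 1          # segregating
        st = build_state(H, [0.1, 0.2, 0.3], [0.0] * 3, [True] * 3)
        st.records = [
            sim_core.MutationRecord(i, 0, p, "neutral", 0.0, 0, 0)
            for i, p in enumerate([0.1, 0.2, 0.3])]
        resolved = prune_sites(st)
        assert st.n_sites == 1
        assert {r.status for r in resolved} == {"lost", "fixed"}
        assert st.records[0].site_id == 2

    def test_column_count_equals_segregating(self, rng):
        p = small_params()
        st = init_population(p)
        for _ in range(30):
            step_generation(st, p, rng)
        assert st.n_sites == sum(
            1 for r in st.records if r.status == "segregating")
        assert st.n_sites == len(st.records)

    def test_restores_map_order_after_deferred_compaction(self, rng):
        p = small_params()
        st = init_population(p)
        for i in range(20):
            step_generation(st, p, rng, compact=False)
        prune_sites(st)
        assert (np.diff(st.positions) > 0).all()


class TestFullRun:
    def test_mutation_cap_stops_after_exact_generations(self):
        p = small_params(max_mutations_introduced=100)
        res = run_simulation(p, record_ld=False)
        assert res.stop_reason == "mutation_cap"
        assert res.final_state.generation == 10

    def test_population_size_conserved(self, rng):
        p = small_params()
        st = init_population(p)
        for _ in range(50):
            step_generation(st, p, rng)
            assert len(st.deme) == p.N_total
            assert st.haplotypes.shape[0] == 2 * p.N_total

    def test_fixed_seed_replay_is_bit_identical(self):
        def go():
            p = small_params(N_total=60, seed=123,
                             max_mutations_introduced=1500)
            return run_simulation(p, record_ld=False)

        a, b = go(), go()
        assert np.array_equal(a.final_state.haplotypes,
                              b.final_state.haplotypes)
        assert np.array_equal(a.final_state.positions,
                              b.final_state.positions)
        assert [r.afd_neutral for r in a.records] == \
               [r.afd_neutral for r in b.records]

    def test_deferred_compaction_does_not_change_dynamics_stats(self):
        """Summary statistics at record points are identical whether
        pruning runs every generation or is amortized (resolved columns
        are inert under soft selection)."""
        # note: RNG streams differ once pruning timing changes, so compare
        # a run against itself with the same cadence; the bitwise-replay
        # test plus the inertness argument cover the rest.  Here we check
        # the invariant directly: appending an already-fixed column leaves
        # relative fitness unchanged.
        p = small_params(N_total=40, s_mean=0.05)
        st = init_population(p)
        rng = np.random.default_rng(3)
        for _ in range(30):
            step_generation(st, p, rng)
        base = sim_core._relative_fitness_by_deme(st)
        H2 = np.concatenate(
            [st.haplotypes, np.ones((2 * p.N_total, 1), np.uint8)], axis=1)
        st.haplotypes = H2
        st.positions = np.concatenate([st.positions, [0.123]])
        st.s_coef = np.concatenate([st.s_coef, [0.5]])
        st.neutral = np.concatenate([st.neutral, [False]])
        st.favored = np.concatenate([st.favored, np.ones(1, np.int8)])
        st._buffer = None
        mod = sim_core._relative_fitness_by_deme(st)
        for k in (0, 1):
            assert np.allclose(base[k], mod[k], rtol=1e-5)

    def test_stop_reason_nme_threshold(self):
        # diverged demes with strong selection collapse m_e quickly
        p = small_params(N_total=100, s_mean=0.5, m=0.001,
                         nme_threshold=0.5, nme_window=5)
        res = run_simulation(p, max_generations=4000, record_ld=False)
        assert res.stop_reason in ("nme_threshold", "max_generations")
        assert res.records[-1].generation <= 4000
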