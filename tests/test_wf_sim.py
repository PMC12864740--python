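"""Unit and property tests for the Wright-Fisher plasmid engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidwf import (
    CellState,
    ConfigurationError,
    Population,
    SimConfig,
    SimulationError,
    generations_from_culture_time,
    mutation_step,
    partition_step,
    replication_step,
    run_generation,
    run_simulation,
    selection_step,
    summarize_population,
)
from plasmidwf.wf_sim import NO_MUTATION, replicate_rng


def test_generation_count_from_culture_time():
    """22 h of growth at a 90 min doubling time spans 15 generations."""
    assert generations_from_culture_time(22, 90) == 15
    assert generations_from_culture_time(10, 60) == 10
    with pytest.raises(ConfigurationError):
        generations_from_culture_time(-1, 90)


class TestSimConfig:
    def test_defaults_are_experimental_regime(self):
        cfg = SimConfig()
        assert cfg.mu == pytest.approx(2.5e-6)
        assert cfg.pop_size == 100_000
        assert cfg.generations == 15

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": -0.1},
            {"mu": 1.5},
            {"pop_size": 7},  # odd
            {"pop_size": 0},
            {"generations": 0},
            {"pcn": 0},
            {"n_replicates": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestMutationStep:
    def test_zero_rate_is_identity(self, rng):
        pop = Population.wild_type(50, 10)
        before = pop.x_wt.copy()
        mutation_step(pop, 0.0, rng)
        assert (pop.x_wt == before).all() and (pop.x_m == 0).all()

    def test_certain_mutation_converts_everything(self, rng):
        pop = Population.wild_type(20, 10)
        mutation_step(pop, 1.0, rng, gen=3)
        assert (pop.x_m == 10).all() and (pop.x_wt == 0).all()
        assert (pop.first_mutation_gen == 3).all()

    def test_first_mutation_gen_not_overwritten(self, rng):
        pop = Population(x_m=[1], x_wt=[5], first_mutation_gen=[2])
        mutation_step(pop, 1.0, rng, gen=9)
        assert pop.first_mutation_gen[0] == 2

    def test_binomial_mean(self, rng):
        """Mean conversions per cell match the binomial expectation x_wt * mu."""
        n, x_wt, mu = 100_000, 10, 0.01
        pop = Population.wild_type(n, x_wt)
        mutation_step(pop, mu, rng)
        se = np.sqrt(x_wt * mu * (1 - mu) / n)
        assert pop.x_m.mean() == pytest.approx(x_wt * mu, abs=3 * se)

    def test_invalid_mu_raises(self, rng):
        with pytest.raises(ConfigurationError):
            mutation_step(Population.wild_type(2, 3), 1.2, rng)


class TestReplicationStep:
    def test_all_wild_type_yields_no_mutant_copies(self, rng):
        for _ in range(50):
            p_new, new_m, new_wt = replication_step(CellState(0, 8), 8, rng)
            assert new_m == 0 and new_m + new_wt == p_new

    def test_empty_cell_flagged(self, rng):
        with pytest.raises(SimulationError):
            replication_step(CellState(0, 0), 5, rng)

    def test_assignment_follows_mutated_proportion(self, rng):
        """Pooled over draws, new mutant copies arrive at rate x_m / total = 1/2."""
        tot_m = tot_new = 0
        for _ in range(3000):
            p_new, new_m, _ = replication_step(CellState(4, 4), 8, rng)
            tot_m += new_m
            tot_new += p_new
        se = np.sqrt(0.25 / tot_new)
        assert tot_m / tot_new == pytest.approx(0.5, abs=3 * se)


class TestPartitionStep:
    def test_homogeneous_even_pool_splits_exactly(self, rng):
        a, b = partition_step(0, 12, rng)
        assert (a.x_m, a.x_wt, b.x_m, b.x_wt) == (0, 6, 0, 6)
        a, b = partition_step(10, 0, rng)
        assert a.x_m + b.x_m == 10 and a.x_wt == b.x_wt == 0

    @given(total_m=st.integers(0, 60), total_wt=st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_conservation_no_segregational_loss(self, total_m, total_wt):
        """Daughter counts always sum exactly to the parental pool."""
        if total_m + total_wt == 0:
            return
        rng = np.random.default_rng(total_m * 100 + total_wt)
        a, b = partition_step(total_m, total_wt, rng)
        assert a.x_m + b.x_m == total_m
        assert a.x_wt + b.x_wt == total_wt
        assert abs(a.total - b.total) <= (total_m + total_wt) % 2

    def test_hypergeometric_mean(self, rng):
        """Daughter A's mutant count averages size_A * (m / T) = 6 * (3/12)."""
        n = 20_000
        draws = np.array([partition_step(3, 9, rng)[0].x_m for _ in range(n)])
        var = 6 * 0.25 * 0.75 * (12 - 6) / (12 - 1)
        se = np.sqrt(var / n)
        assert draws.mean() == pytest.approx(1.5, abs=3 * se)

    def test_negative_counts_rejected(self, rng):
        with pytest.raises(SimulationError):
            partition_step(-1, 5, rng)


class TestSelectionStep:
    def test_size_contract_and_identity_composition(self, rng):
        pop = Population(x_m=[2] * 4, x_wt=[3] * 4, first_mutation_gen=[1] * 4)
        out = selection_step(pop, rng)
        assert len(out) == 2
        assert (out.x_m == 2).all() and (out.x_wt == 3).all()

    def test_odd_input_rejected(self, rng):
        pop = Population.wild_type(3, 2)
        with pytest.raises(SimulationError):
            selection_step(pop, rng)

    def test_unbiased_sampling(self):
        """Selected mutant fraction is unbiased for the input fraction."""
        f, reps, size = 0.25, 400, 40
        x_m = np.array([1] * 10 + [0] * 30)
        fractions = []
        for i in range(reps):
            pop = Population(x_m=x_m, x_wt=1 - x_m, first_mutation_gen=[NO_MUTATION] * size)
            out = selection_step(pop, np.random.default_rng(i))
            fractions.append(out.is_mutant.mean())
        # variance of the mean of a without-replacement sample of half the pool
        var_single = f * (1 - f) * (size - size // 2) / (size - 1) / (size // 2)
        se = np.sqrt(var_single / reps)
        assert np.mean(fractions) == pytest.approx(f, abs=3 * se)


class TestRunGeneration:
    def test_population_size_preserved(self, rng):
        cfg = SimConfig(mu=0.01, pop_size=500, generations=1, pcn=5, n_replicates=1)
        pop, _ = run_generation(Population.wild_type(500, 5), cfg, rng)
        assert len(pop) == 500

    def test_no_mutation_no_mutants(self, rng):
        cfg = SimConfig(mu=0.0, pop_size=200, generations=1, pcn=5, n_replicates=1)
        _, summary = run_generation(Population.wild_type(200, 5), cfg, rng)
        assert summary.n_mutant_cells == 0

    def test_certain_mutation_single_generation(self, rng):
        """With mu=1 every pre-replication copy mutates, so all cells are mutant
        and new copies are assigned from an all-mutant proportion: frac = 1."""
        cfg = SimConfig(mu=1.0, pop_size=400, generations=1, pcn=7, n_replicates=1)
        pop, summary = run_generation(Population.wild_type(400, 7), cfg, rng)
        assert summary.n_mutant_cells == 400
        assert summary.total_mutant_plasmid_frac == pytest.approx(1.0)
        assert (pop.x_wt == 0).all()

    def test_plasmid_conservation_through_division(self, rng):
        """Total plasmids after partition equal parental plus replicated pool;
        selection halves the cells, not the per-cell content."""
        cfg = SimConfig(mu=0.5, pop_size=300, generations=1, pcn=4, n_replicates=1)
        pop, _ = run_generation(Population.wild_type(300, 4), cfg, rng)
        assert (pop.total >= 0).all()
        # daughters inherit roughly half the pool: mean near pcn
        assert pop.total.mean() == pytest.approx(4.0, rel=0.2)


class TestRunSimulation:
    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(mu=1e-3, pop_size=200, generations=5, pcn=5, n_replicates=3, seed=7)
        a = run_simulation(cfg).to_frame()
        b = run_simulation(cfg).to_frame()
        assert a.equals(b)

    def test_different_seeds_differ(self):
        base = dict(mu=1e-2, pop_size=200, generations=5, pcn=5, n_replicates=2)
        a = run_simulation(SimConfig(seed=1, **base)).to_frame()
        b = run_simulation(SimConfig(seed=2, **base)).to_frame()
        assert not a.equals(b)

    def test_replicate_streams_independent(self):
        r0 = replicate_rng(3, 0).integers(0, 2**31, 4)
        r1 = replicate_rng(3, 1).integers(0, 2**31, 4)
        assert not np.array_equal(r0, r1)

    def test_zero_rate_all_summaries_empty(self):
        cfg = SimConfig(mu=0.0, pop_size=100, generations=4, pcn=3, n_replicates=2, seed=0)
        df = run_simulation(cfg).to_frame()
        assert (df.n_mutant_cells == 0).all()
        assert (df.total_mutant_plasmid_frac == 0).all()

    def test_neutral_frequency_matches_mutation_process(self):
        """E[mutant-plasmid frequency at gen g] = 1-(1-mu)^g: replication and
        partitioning are unbiased, so the frequency follows mutation alone."""
        mu, gens = 1e-3, 10
        cfg = SimConfig(mu=mu, pop_size=2000, generations=gens, pcn=5, n_replicates=30, seed=11)
        df = run_simulation(cfg).to_frame()
        final = df[df.gen == gens].total_mutant_plasmid_frac
        expected = 1 - (1 - mu) ** gens
        sem = final.std(ddof=1) / np.sqrt(len(final))
        assert final.mean() == pytest.approx(expected, abs=3 * sem)

    def test_emergence_histogram_counts_mutant_cells(self, rng):
        cfg = SimConfig(mu=0.02, pop_size=400, generations=6, pcn=5, n_replicates=1, seed=5)
        res = run_simulation(cfg, keep_final_population=True)
        final = res.summaries[0][-1]
        assert sum(final.emergence_histogram.values()) == final.n_mutant_cells
        assert all(1 <= g <= 6 for g in final.emergence_histogram)
        # summary invariants
        assert final.mean_xm_per_mutant >= 1
        assert 0 <= final.mean_frac_per_mutant <= 1

    def test_final_population_matches_summary(self):
        cfg = SimConfig(mu=0.05, pop_size=200, generations=3, pcn=5, n_replicates=1, seed=2)
        res = run_simulation(cfg, keep_final_population=True)
        pop = res.final_populations[0]
        recomputed = summarize_population(pop, 3)
        assert recomputed.n_mutant_cells == res.summaries[0][-1].n_mutant_cells
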