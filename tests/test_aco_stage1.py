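"""Stage-1 colony mechanics: selection rule, pheromone dynamics, turning
point, candidate archive, and reproducibility of the full search."""

import numpy as np
import pytest

from epicolony.aco_stage1 import (
    ACOConfig,
    AntSolution,
    CandidateArchive,
    PheromoneState,
    _pick_one,
    init_state,
    run_stage1,
    select_combination,
    turning_point,
    update_pheromone,
)
from epicolony.simulator import SimulationSpec, model_registry, simulate_dataset


def _config(**kw):
    defaults = dict(n_ants=10, n_iterations=5, seed=0)
    defaults.update(kw)
    return ACOConfig(**defaults)


class TestConfig:
    def test_q0_defaults_to_reciprocal_of_iterations(self):
        assert _config(n_iterations=40).resolved_q0 == pytest.approx(1 / 40)
        assert _config(q0=0.3).resolved_q0 == 0.3

    @pytest.mark.parametrize(
        "kw",
        [dict(n_ants=2), dict(rho=1.5), dict(q0=-0.1), dict(alpha=-1),
         dict(tau0=0.0), dict(eta_mode="bogus"), dict(selection_semantics="no")],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            _config(**kw)


class TestInitState:
    def test_constant_mode_defaults(self):
        state = init_state(5, _config())
        assert np.array_equal(state.tau, np.ones(5))
        assert np.array_equal(state.eta, np.ones(5))

    def test_marginal_mi_mode_floors_null_snps(self):
        rng = np.random.default_rng(0)
        from conftest import random_dataset

        ds = random_dataset(rng, n_samples=500, n_snps=6)
        state = init_state(6, _config(eta_mode="marginal_mi"), ds)
        assert (state.eta > 0).all()
        assert state.eta.shape == (6,)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            init_state(1, _config())

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            PheromoneState(tau=np.array([1.0, 0.0]), eta=np.ones(2))


class TestSelection:
    def test_pheromone_rule_probabilities(self):
        """tau=(3,1), alpha=beta=1, forced pheromone branch -> (0.75, 0.25)."""
        state = PheromoneState(tau=np.array([3.0, 1.0]), eta=np.ones(2))
        cfg = _config(q0=1.0)  # literal semantics: q <= 1 always -> pheromone rule
        rng = np.random.default_rng(123)
        n_draws = 100_000
        hits = sum(
            _pick_one(state, cfg, np.arange(2), rng) == 0 for _ in range(n_draws)
        )
        sigma = np.sqrt(0.75 * 0.25 / n_draws)
        assert abs(hits / n_draws - 0.75) < 3 * sigma

    def test_q0_zero_means_every_pick_uniform(self):
        """With q0=0 a huge pheromone imbalance must not bias selection."""
        state = PheromoneState(tau=np.array([1000.0, 1.0, 1.0]), eta=np.ones(3))
        cfg = _config(q0=0.0)
        rng = np.random.default_rng(7)
        n_draws = 30_000
        hits = sum(
            _pick_one(state, cfg, np.arange(3), rng) == 0 for _ in range(n_draws)
        )
        sigma = np.sqrt((1 / 3) * (2 / 3) / n_draws)
        assert abs(hits / n_draws - 1 / 3) < 4 * sigma

    def test_swapped_semantics_inverts_branch(self):
        state = PheromoneState(tau=np.array([1000.0, 1.0]), eta=np.ones(2))
        cfg = _config(q0=0.0, selection_semantics="swapped")  # q > 0 -> pheromone rule
        rng = np.random.default_rng(11)
        hits = sum(_pick_one(state, cfg, np.arange(2), rng) == 0 for _ in range(2000))
        assert hits / 2000 > 0.95

    def test_pair_members_distinct(self):
        state = PheromoneState(tau=np.ones(4), eta=np.ones(4))
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = select_combination(state, _config(), set(), rng)
            assert a < b

    def test_visited_snps_excluded(self):
        state = PheromoneState(tau=np.ones(4), eta=np.ones(4))
        rng = np.random.default_rng(2)
        for _ in range(100):
            pair = select_combination(state, _config(), {0, 1}, rng)
            assert set(pair) == {2, 3}

    def test_too_few_unvisited_rejected(self):
        state = PheromoneState(tau=np.ones(3), eta=np.ones(3))
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            select_combination(state, _config(), {0, 1}, rng)


class TestPheromoneUpdate:
    def test_full_evaporation_with_no_solutions_hits_floor(self):
        state = PheromoneState(tau=np.full(3, 2.0), eta=np.ones(3))
        new = update_pheromone(state, [], _config(rho=1.0))
        assert np.array_equal(new.tau, np.full(3, 1e-12))

    def test_pure_decay_for_unselected_snp(self):
        state = PheromoneState(tau=np.array([4.0, 1.0, 1.0]), eta=np.ones(3))
        new = update_pheromone(
            state, [AntSolution(pair=(1, 2), fitness=0.5)], _config(rho=0.1)
        )
        assert new.tau[0] == pytest.approx(4.0 * 0.9, abs=0)

    def test_deposits_sum_over_ants(self):
        state = PheromoneState(tau=np.ones(3), eta=np.ones(3))
        sols = [
            AntSolution(pair=(0, 1), fitness=0.2),
            AntSolution(pair=(0, 2), fitness=0.3),
        ]
        new = update_pheromone(state, sols, _config(rho=0.0))
        assert new.tau[0] == pytest.approx(1.5)
        assert new.tau[1] == pytest.approx(1.2)
        assert new.tau[2] == pytest.approx(1.3)

    def test_positivity_preserved_over_many_iterations(self):
        state = PheromoneState(tau=np.ones(4), eta=np.ones(4))
        cfg = _config(rho=0.99)
        for _ in range(100):
            state = update_pheromone(state, [], cfg)
            assert (state.tau > 0).all()


class TestTurningPoint:
    def test_all_equal_ties_break_to_three(self):
        assert turning_point([0.5] * 6) == 3

    def test_elbow_found_by_second_difference(self):
        # second differences at g=3,4,5: 0.35, 0.04, 0.00 -> maximum at g=3
        assert turning_point([0.9, 0.5, 0.45, 0.44, 0.43]) == 3

    def test_three_solutions_always_three(self):
        assert turning_point([0.7, 0.3, 0.29]) == 3

    def test_late_elbow(self):
        # flat then cliff: largest curvature at the cliff bottom
        assert turning_point([1.0, 0.99, 0.98, 0.97, 0.1, 0.09]) == 6

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            turning_point([0.1, 0.9, 0.5])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            turning_point([0.9, 0.1])


class TestArchive:
    def _solutions(self, fits):
        return [AntSolution(pair=(i, i + 1), fitness=f) for i, f in enumerate(fits)]

    def test_first_update_stores_ranks_before_turning_point(self):
        archive = CandidateArchive()
        archive.update(self._solutions([0.9, 0.5, 0.45, 0.44, 0.43]))
        assert len(archive.entries) == 2  # ranks 1-2 (f = 3)
        assert archive.filter_threshold == 0.5

    def test_filter_blocks_weaker_later_solutions(self):
        archive = CandidateArchive()
        archive.update(self._solutions([0.9, 0.5, 0.45, 0.44, 0.43]))
        before = dict(archive.entries)
        archive.update(self._solutions([0.4, 0.35, 0.3]))
        assert archive.entries == before

    def test_duplicate_pair_keeps_best_fitness(self):
        archive = CandidateArchive()
        sols = [
            AntSolution(pair=(0, 1), fitness=0.9),
            AntSolution(pair=(2, 3), fitness=0.5),
            AntSolution(pair=(4, 5), fitness=0.1),
        ]
        archive.update(sols)
        sols2 = [
            AntSolution(pair=(0, 1), fitness=0.95),
            AntSolution(pair=(2, 3), fitness=0.55),
            AntSolution(pair=(4, 5), fitness=0.1),
        ]
        archive.update(sols2)
        assert archive.entries[(0, 1)] == 0.95

    def test_threshold_non_decreasing_over_random_updates(self):
        rng = np.random.default_rng(4)
        archive = CandidateArchive()
        prev = archive.filter_threshold
        for _ in range(50):
            fits = np.sort(rng.random(8))[::-1]
            sols = [
                AntSolution(pair=tuple(sorted(rng.choice(10, 2, replace=False))), fitness=f)
                for f in fits
            ]
            archive.update(sols)
            assert archive.filter_threshold >= prev
            prev = archive.filter_threshold


@pytest.fixture(scope="module")
def small_dataset():
    ds, manifest = simulate_dataset(
        SimulationSpec(
            model=model_registry()["Model3"], n_cases=400, n_controls=400,
            n_snps=20, seed=2024,
        )
    )
    return ds, manifest


class TestRunStage1:

    def test_identical_seeds_give_identical_archives(self, small_dataset):
        ds, _ = small_dataset
        cfg = _config(n_ants=20, n_iterations=5, seed=99)
        _, a1 = run_stage1(ds, cfg)
        _, a2 = run_stage1(ds, cfg)
        assert a1.entries == a2.entries
        assert a1.filter_threshold == a2.filter_threshold

    def test_causal_snps_usually_in_candidate_set(self, small_dataset):
        """On a strong 20-SNP model the causal pair's SNPs should be found
        in nearly all seeded runs."""
        ds, manifest = small_dataset
        causal_idx = {ds.snp_index(s) for s in manifest.causal_pair}
        cfg_base = dict(n_ants=50, n_iterations=30)
        hits = 0
        for seed in range(10):
            candidates, _ = run_stage1(ds, ACOConfig(seed=seed, **cfg_base))
            hits += causal_idx <= candidates
        assert hits >= 9

    def test_minimal_colony_archive_bound(self, small_dataset):
        ds, _ = small_dataset
        _, archive = run_stage1(ds, _config(n_ants=3, n_iterations=1, seed=5))
        assert len(archive.entries) <= 2

    def test_candidate_set_is_union_of_archived_pairs(self, small_dataset):
        ds, _ = small_dataset
        candidates, archive = run_stage1(ds, _config(n_ants=10, n_iterations=3, seed=1))
        assert candidates == {i for pair in archive.entries for i in pair}
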