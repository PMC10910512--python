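"""Genetic-algorithm operators, invariants, and synthetic-landscape recovery."""

import numpy as np
import pytest

from netham.evolution import (
    GAConfig,
    GenerationState,
    Individual,
    StallError,
    advance_generation,
    breed_pair,
    evaluate_fitness,
    run_evolution,
    seed_sphere,
    select_survivors,
    simulation_fitness,
)
from netham.netstats import StatSpec

SPEC4 = StatSpec(["edges", "twostar", "nsp1", "nsp2"])
SPEC3 = StatSpec(["edges", "twostar", "nsp1"])


def make_cfg(**kw):
    base = dict(spec=SPEC4, template="2-ribbon", n_nodes=48, reps=2, master_seed=0)
    base.update(kw)
    return GAConfig(**base)


def gauss_fitness(target):
    def fn(phi, ind_id, cfg):
        free = list(cfg.free_dims)
        return [float(np.exp(-np.sum((phi[free] - np.asarray(target)[free]) ** 2)))]

    return fn


class TestSeedSphere:
    def test_points_inside_ball_and_edge_fixed(self):
        cfg = make_cfg()
        rng = np.random.default_rng(0)
        center = np.array([100.0, 20.0, -1.0, -5.0])
        pts = seed_sphere(center, 3.0, 500, cfg, rng)
        free = list(cfg.free_dims)
        for p in pts:
            assert np.linalg.norm(p.phi[free] - center[free]) <= 3.0 + 1e-12
            assert p.phi[cfg.spec.index("edges")] == cfg.fixEdgeValue

    def test_degenerate_radius_collapses_to_center(self):
        cfg = make_cfg()
        pts = seed_sphere(
            np.array([100.0, 1.0, 2.0, 3.0]), 1e-12, 20, cfg, np.random.default_rng(1)
        )
        for p in pts:
            assert p.phi == pytest.approx([100.0, 1.0, 2.0, 3.0], abs=1e-9)

    def test_no_free_dimensions_rejected(self):
        cfg = GAConfig(spec=StatSpec(["edges"]), template="1-ribbon", fixEdge=True)
        with pytest.raises(ValueError):
            seed_sphere(np.array([100.0]), 1.0, 5, cfg, np.random.default_rng(0))


class TestBreeding:
    def test_linear_children_evenly_spaced(self):
        # parents 3 apart with density 1.2 -> floor(3.6) = 3 linear children
        cfg = GAConfig(spec=SPEC3, template="2-ribbon")
        state = GenerationState(0, [], [], 1.0, 1, 0.0)
        p1 = Individual(0, np.array([100.0, 0.0, 0.0]), "seed")
        p2 = Individual(1, np.array([100.0, 0.0, 3.0]), "seed")
        kids = breed_pair(p1, p2, state, cfg, np.random.default_rng(0))
        linear = [k for k in kids if k.origin == "linear"]
        mutant = [k for k in kids if k.origin == "mutant"]
        assert [k.phi[2] for k in linear] == pytest.approx([0.75, 1.5, 2.25])
        assert len(mutant) == 3  # one mutant per linear child initially
        assert all(k.parents == (0, 1) for k in kids)

    def test_close_parents_do_not_breed(self):
        cfg = GAConfig(spec=SPEC3, template="2-ribbon")
        state = GenerationState(0, [], [], 1.0, 1, 0.0)
        p1 = Individual(0, np.array([100.0, 0.0, 0.0]), "seed")
        p2 = Individual(1, np.array([100.0, 0.0, 0.5]), "seed")
        assert breed_pair(p1, p2, state, cfg, np.random.default_rng(0)) == []

    def test_child_max_cap(self):
        cfg = make_cfg(childMax=2)
        state = GenerationState(0, [], [], 1.0, 1, 0.0)
        p1 = Individual(0, np.array([100.0, 0.0, 0.0, 0.0]), "seed")
        p2 = Individual(1, np.array([100.0, 0.0, 0.0, 3.0]), "seed")
        kids = breed_pair(p1, p2, state, cfg, np.random.default_rng(0))
        assert len(kids) == 2

    def test_linear_children_collinear(self):
        cfg = make_cfg()
        state = GenerationState(0, [], [], 1.0, 2, 0.0)
        rng = np.random.default_rng(3)
        p1 = Individual(0, np.array([100.0, 1.0, -2.0, 0.5]), "seed")
        p2 = Individual(1, np.array([100.0, -3.0, 4.0, 2.5]), "seed")
        free = list(cfg.free_dims)
        d = p2.phi[free] - p1.phi[free]
        d = d / np.linalg.norm(d)
        for k in breed_pair(p1, p2, state, cfg, rng):
            if k.origin != "linear":
                continue
            r = k.phi[free] - p1.phi[free]
            residual = r - (r @ d) * d
            assert np.all(np.abs(residual) < 1e-9)

    def test_mutants_perturb_only_free_dimensions(self):
        cfg = make_cfg(noiseVarInit=4.0)
        state = GenerationState(0, [], [], 4.0, 3, 0.0)
        p1 = Individual(0, np.array([100.0, 0.0, 0.0, 0.0]), "seed")
        p2 = Individual(1, np.array([100.0, 0.0, 0.0, 5.0]), "seed")
        kids = breed_pair(p1, p2, state, cfg, np.random.default_rng(1))
        for k in kids:
            assert k.phi[0] == 100.0


class TestFitness:
    def test_mean_of_draws(self):
        cfg = make_cfg()
        ind = Individual(0, np.array([100.0, 0, 0, 0.0]), "seed")
        mean = evaluate_fitness(ind, cfg, fitness=lambda phi, i, c: [0.25, 0.75])
        assert mean == pytest.approx(0.5)
        assert ind.fitness_draws == (0.25, 0.75)

    def test_bond_averse_model_yields_zero(self):
        # strongly positive phi_e -> empty graphs -> fibril fraction 0
        cfg = GAConfig(
            spec=SPEC4, template="2-ribbon", n_nodes=16, reps=2, fixEdge=False
        )
        draws = simulation_fitness(np.array([50.0, 0.0, 0.0, 0.0]), 0, cfg)
        assert draws == [0.0, 0.0]

    def test_degenerate_region_scores_zero_without_crashing(self):
        # phi_e very negative with no 2-star brake -> runaway densification
        cfg = GAConfig(
            spec=SPEC4, template="2-ribbon", n_nodes=24, reps=2, fixEdge=False
        )
        draws = simulation_fitness(np.array([-10.0, 0.0, 0.0, 0.0]), 0, cfg)
        assert draws == [0.0, 0.0]

    def test_reproducible_and_schedule_independent(self):
        cfg = make_cfg(n_nodes=20, reps=3)
        phi = np.array([100.0, 25.0, 0.0, -5.0])
        a = simulation_fitness(phi, 7, cfg)
        b = simulation_fitness(phi, 7, cfg)
        assert a == b
        assert simulation_fitness(phi, 8, cfg) != a  # seeds keyed by individual


class TestSelection:
    def _pop(self, means):
        out = []
        for i, m in enumerate(means):
            ind = Individual(i, np.zeros(4), "seed")
            ind.fitness_draws = (m,)
            out.append(ind)
        return out

    def test_top_quarter(self):
        cfg = make_cfg(topFraction=0.25)
        pop = self._pop([i / 20 for i in range(20)])
        survivors = select_survivors(pop, cfg, np.random.default_rng(0))
        assert sorted(s.id for s in survivors) == [15, 16, 17, 18, 19]

    def test_max_survivors_cap_random_subset_of_top(self):
        cfg = make_cfg(topFraction=1.0, maxSurvivors=20)
        pop = self._pop([0.5] * 100)
        survivors = select_survivors(pop, cfg, np.random.default_rng(0))
        assert len(survivors) == 20

    def test_ties_broken_by_lower_id(self):
        cfg = make_cfg(topFraction=0.5)
        pop = self._pop([0.3, 0.3, 0.3, 0.3])
        survivors = select_survivors(pop, cfg, np.random.default_rng(0))
        assert sorted(s.id for s in survivors) == [0, 1]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            select_survivors([], make_cfg(), np.random.default_rng(0))


class TestGenerationLoop:
    def test_accepted_generation_improves_best(self):
        cfg = make_cfg(reps=1, max_generations=3)
        target = np.array([100.0, 1.0, 1.0, 1.0])
        hist = run_evolution(
            cfg,
            initial=[[100.0, 3.0, 3.0, 3.0], [100.0, -1.0, -1.0, -1.0]],
            fitness=gauss_fitness(target),
        )
        assert len(hist.generations) >= 2
        traj = hist.best_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:]))
        assert traj[-1] > traj[0]

    def test_parent_copies_join_each_generation(self):
        cfg = make_cfg(reps=1, max_generations=2)
        hist = run_evolution(
            cfg,
            initial=[[100.0, 3.0, 3.0, 3.0], [100.0, -1.0, -1.0, -1.0]],
            fitness=gauss_fitness(np.array([100.0, 1.0, 1.0, 1.0])),
        )
        for prev, gen in zip(hist.generations, hist.generations[1:]):
            copies = [i for i in gen.population if i.origin == "parent-copy"]
            assert len(copies) == len(prev.survivors)
            prev_phis = {tuple(s.phi) for s in prev.survivors}
            assert {tuple(c.phi) for c in copies} == prev_phis

    def test_failed_brood_applies_smart_variance_and_points(self):
        calls = {"n": 0}

        def flaky(phi, ind_id, cfg):
            # children are worthless in the first brood, excellent afterwards
            calls["n"] += 1
            return [0.0] if calls["n"] <= 40 else [1.0]

        cfg = make_cfg(reps=1, max_generations=1, max_retries_per_generation=5)
        hist = run_evolution(
            cfg,
            initial=[[100.0, 0.0, 0.0, 0.0], [100.0, 0.0, 0.0, 4.0]],
            fitness=flaky,
        )
        final = hist.generations[-1]
        assert final.current_noise_var > cfg.noiseVarInit  # smartVar doubled it
        assert final.current_mutants_per_child > 1  # smartPts incremented

    def test_gen0_already_optimal_stalls(self):
        # nothing can strictly beat a parent sitting on the optimum
        target = np.array([100.0, 1.0, 1.0, 1.0])
        cfg = make_cfg(reps=1, max_generations=3, max_retries_per_generation=1)
        hist = run_evolution(
            cfg,
            initial=[target.tolist(), [100.0, 4.0, 4.0, 4.0]],
            fitness=gauss_fitness(target),
        )
        assert hist.stalled
        assert hist.best.phi == pytest.approx(target)

    def test_single_individual_gen0_stalls_immediately(self):
        cfg = make_cfg(reps=1)
        hist = run_evolution(
            cfg, initial=[[100.0, 1.0, 1.0, 1.0]], fitness=gauss_fitness(np.zeros(4))
        )
        assert hist.stalled and len(hist.generations) == 1

    def test_bitwise_reproducible(self):
        cfg = make_cfg(reps=1, max_generations=4, master_seed=5)
        runs = [
            run_evolution(
                cfg,
                seed_center=np.array([100.0, 2.0, 2.0, 2.0]),
                seed_radius=2.0,
                seed_count=30,
                fitness=gauss_fitness(np.array([100.0, 1.0, 0.0, 1.0])),
            )
            for _ in range(2)
        ]
        a, b = runs
        assert len(a.individuals) == len(b.individuals)
        for x, y in zip(a.individuals, b.individuals):
            assert np.array_equal(x.phi, y.phi) and x.fitness_draws == y.fitness_draws

    def test_fix_edge_exact_in_every_individual(self):
        cfg = make_cfg(reps=1, max_generations=3)
        hist = run_evolution(
            cfg,
            seed_center=np.array([100.0, 2.0, 2.0, 2.0]),
            seed_radius=2.0,
            seed_count=30,
            fitness=gauss_fitness(np.array([100.0, 1.0, 0.0, 1.0])),
        )
        e = cfg.spec.index("edges")
        assert all(ind.phi[e] == cfg.fixEdgeValue for ind in hist.individuals)
        assert all(len(g.survivors) <= cfg.maxSurvivors for g in hist.generations)

    def test_recovers_synthetic_gaussian_optimum(self):
        # smooth unimodal landscape: the GA localizes the optimum closely
        target = np.array([0.0, 2.0, -1.0, 3.0])
        cfg = make_cfg(
            reps=1,
            master_seed=2,
            max_generations=15,
            noiseVarInit=0.25,
            minLineDensity=2.0,
        )
        hist = run_evolution(
            cfg,
            seed_center=np.array([100.0, 3.0, 0.5, 2.0]),
            seed_radius=3.0,
            seed_count=100,
            fitness=gauss_fitness(target),
        )
        free = list(cfg.free_dims)
        assert np.linalg.norm(hist.best.phi[free] - target[free]) < 0.1
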