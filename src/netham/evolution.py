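"""Genetic algorithm for parameterizing network Hamiltonian models.

The GA searches phi space (one dimension per sufficient statistic) for
models that maximize mean fibril yield.  Its ingredients:

* generation 0 sampled uniformly in a ball around a center (or supplied);
* *line breeding*: every pair of survivors is joined by a straight line in
  parameter space and linear children are placed at evenly spaced interior
  points — the number of children grows with the parents' separation
  (``minLineDensity`` children per unit distance), and pairs too close to
  yield even one child are deemed too closely related to breed;
* *mutant children*: noisy Gaussian copies of each linear child;
* fitness = mean fibril fraction over ``reps`` independent equilibrium
  draws (degenerate draws score 0);
* selection keeps the top ``topFraction`` (capped at ``maxSurvivors``);
* a generation whose best child does not beat the best parent is discarded
  and rebred, with the mutation variance doubled (``smartVar``) and one
  more mutant per linear child (``smartPts``);
* every new generation carries copies of all breeding parents, so a
  consistently top-performing parameter can become immortal.

With ``fixEdge`` enabled the edge coordinate is excluded from breeding and
mutation, held at ``fixEdgeValue``, and used directly as theta_e during
simulation (the value is in theta form); all other coordinates are phi and
simulate with theta_X = -phi_X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .fibril_assay import TEMPLATES, FibrilTemplate, fibril_fraction
from .hamiltonian import ThetaVector
from .netstats import StatSpec
from .sampler import DegeneracyError, SamplerConfig, simulate_draw_theta

__all__ = [
    "GAConfig",
    "Individual",
    "GenerationState",
    "RunHistory",
    "StallError",
    "seed_sphere",
    "breed_pair",
    "evaluate_fitness",
    "select_survivors",
    "advance_generation",
    "run_evolution",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the genetic algorithm (names follow the method's
    vocabulary) plus the simulation context the fitness function needs."""

    spec: StatSpec
    template: FibrilTemplate | str
    n_nodes: int = 48
    reps: int = 16
    noiseVarInit: float = 1.0
    topFraction: float = 0.25
    maxSurvivors: int = 20
    fixEdge: bool = True
    fixEdgeValue: float = 100.0
    smartVar: bool = True
    smartPts: bool = True
    useLineDensity: bool = True
    minLineDensity: float = 1.2
    linearChildren: int = 3  # fixed per-pair count when useLineDensity is off
    childMax: int = 100
    max_generations: int = 10
    max_retries_per_generation: int = 5
    master_seed: int = 0
    target_fitness: float | None = None  # stop once the best mean reaches this
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def __post_init__(self) -> None:
        if not (0 < self.topFraction <= 1):
            raise ValueError("topFraction must be in (0, 1]")
        for name in ("reps", "maxSurvivors", "childMax", "max_generations", "linearChildren"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noiseVarInit <= 0 or self.minLineDensity <= 0:
            raise ValueError("noiseVarInit and minLineDensity must be positive")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.max_retries_per_generation < 0:
            raise ValueError("max_retries_per_generation must be >= 0")
        if isinstance(self.template, str):
            object.__setattr__(self, "template", TEMPLATES[self.template])
        if self.fixEdge and "edges" not in self.spec.names:
            raise ValueError("fixEdge requires an 'edges' statistic")

    @property
    def free_dims(self) -> tuple[int, ...]:
        """Parameter coordinates subject to breeding and mutation."""
        if self.fixEdge:
            e = self.spec.index("edges")
            return tuple(i for i in range(len(self.spec)) if i != e)
        return tuple(range(len(self.spec)))


@dataclass
class Individual:
    """One point in parameter space with its evaluated fitness draws."""

    id: int
    phi: np.ndarray  # aligned with GAConfig.spec; edge coord is theta-form under fixEdge
    origin: str  # seed | linear | mutant | parent-copy
    parents: tuple[int, ...] = ()
    fitness_draws: tuple[float, ...] | None = None

    @property
    def fitness_mean(self) -> float | None:
        if self.fitness_draws is None:
            return None
        return float(np.mean(self.fitness_draws))


@dataclass
class GenerationState:
    """GA state after an accepted generation."""

    index: int
    population: list[Individual]
    survivors: list[Individual]
    current_noise_var: float
    current_mutants_per_child: int
    best_mean: float


@dataclass
class RunHistory:
    """Complete record of a run: every accepted generation, every evaluated
    individual (including discarded ones), and the best-so-far trajectory."""

    generations: list[GenerationState]
    individuals: list[Individual]
    best_trajectory: list[float]
    stalled: bool = False

    @property
    def best(self) -> Individual:
        evaluated = [i for i in self.individuals if i.fitness_draws is not None]
        return max(evaluated, key=lambda i: (i.fitness_mean, -i.id))


class StallError(RuntimeError):
    """Run ended because a generation could not outperform its parents
    within the retry budget."""


FitnessFn = Callable[[np.ndarray, int, "GAConfig"], Sequence[float]]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def seed_sphere(
    center: np.ndarray | Sequence[float],
    radius: float,
    count: int,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """``count`` points uniform in the ball of ``radius`` around ``center``
    over the free dimensions; fixed dimensions set to ``fixEdgeValue``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if count < 1:
        raise ValueError("count must be >= 1")
    free = cfg.free_dims
    if not free:
        raise ValueError("no free dimensions to sample")
    center = np.asarray(center, dtype=np.float64)
    if center.shape != (len(cfg.spec),):
        raise ValueError("center must align with the statistic set")
    d = len(free)
    out = []
    for i in range(count):
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        r = radius * rng.random() ** (1.0 / d)
        phi = center.copy()
        phi[list(free)] = center[list(free)] + r * direction
        if cfg.fixEdge:
            phi[cfg.spec.index("edges")] = cfg.fixEdgeValue
        out.append(Individual(id=i, phi=phi, origin="seed"))
    return out


def breed_pair(
    p1: Individual,
    p2: Individual,
    state: GenerationState,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """Linear children evenly spaced along the segment between the parents
    (endpoints excluded) plus Gaussian mutant copies of each; an empty list
    if the parents are too close to breed.  Child ids are assigned later."""
    if p1.id == p2.id:
        raise ValueError("cannot breed an individual with itself")
    free = list(cfg.free_dims)
    dist = float(np.linalg.norm(p1.phi[free] - p2.phi[free]))
    if cfg.useLineDensity:
        n_linear = math.floor(cfg.minLineDensity * dist)
    else:
        n_linear = cfg.linearChildren
    if n_linear < 1:
        return []  # deemed too closely related to breed

    children: list[Individual] = []
    sd = math.sqrt(state.current_noise_var)
    for k in range(1, n_linear + 1):
        lam = k / (n_linear + 1)
        phi = (1.0 - lam) * p1.phi + lam * p2.phi
        if cfg.fixEdge:
            phi[cfg.spec.index("edges")] = cfg.fixEdgeValue
        children.append(
            Individual(id=-1, phi=phi, origin="linear", parents=(p1.id, p2.id))
        )
        for _ in range(state.current_mutants_per_child):
            mphi = phi.copy()
            mphi[free] = phi[free] + rng.normal(scale=sd, size=len(free))
            children.append(
                Individual(id=-1, phi=mphi, origin="mutant", parents=(p1.id, p2.id))
            )
    if len(children) > cfg.childMax:
        keep = rng.choice(len(children), size=cfg.childMax, replace=False)
        children = [children[i] for i in sorted(keep)]
    return children


def _theta_for(phi: np.ndarray, cfg: GAConfig) -> ThetaVector:
    theta = -phi
    if cfg.fixEdge:
        e = cfg.spec.index("edges")
        theta[e] = cfg.fixEdgeValue
    return ThetaVector(cfg.spec, theta)


def simulation_fitness(phi: np.ndarray, ind_id: int, cfg: GAConfig) -> list[float]:
    """Default fitness: fibril fraction of ``reps`` equilibrium draws.

    Rep seeds are keyed by (master seed, individual id, rep), so fitness is
    reproducible regardless of evaluation order; degenerate draws score 0.
    """
    theta = _theta_for(phi.copy(), cfg)
    template = cfg.template
    draws: list[float] = []
    for rep in range(cfg.reps):
        seed = int(
            np.random.SeedSequence(
                cfg.master_seed, spawn_key=(ind_id, rep)
            ).generate_state(1)[0]
        )
        config = replace(cfg.sampler, seed=seed)
        try:
            result = simulate_draw_theta(theta, cfg.n_nodes, config)
        except DegeneracyError:
            draws.append(0.0)
            continue
        draws.append(fibril_fraction(result.graph, template))
    return draws


def evaluate_fitness(
    ind: Individual, cfg: GAConfig, fitness: FitnessFn | None = None
) -> float:
    """Evaluate (in place) and return the individual's mean fibril yield."""
    fn = fitness if fitness is not None else simulation_fitness
    draws = tuple(float(x) for x in fn(ind.phi, ind.id, cfg))
    if len(draws) < 1:
        raise ValueError("fitness function returned no draws")
    ind.fitness_draws = draws
    return ind.fitness_mean


def select_survivors(
    population: Sequence[Individual], cfg: GAConfig, rng: np.random.Generator
) -> list[Individual]:
    """Top ``topFraction`` by mean fitness (ties broken by lower id), then a
    uniform random subset of ``maxSurvivors`` if the fraction is larger."""
    if not population:
        raise ValueError("cannot select from an empty population")
    if any(ind.fitness_draws is None for ind in population):
        raise ValueError("population must be fully evaluated before selection")
    ranked = sorted(population, key=lambda i: (-i.fitness_mean, i.id))
    k = math.ceil(cfg.topFraction * len(ranked))
    top = ranked[:k]
    if len(top) > cfg.maxSurvivors:
        keep = rng.choice(len(top), size=cfg.maxSurvivors, replace=False)
        top = [top[i] for i in sorted(keep)]
    return top


# ---------------------------------------------------------------------------
# generation loop
# ---------------------------------------------------------------------------

class _Run:
    """Mutable bookkeeping shared by advance_generation/run_evolution."""

    def __init__(self, cfg: GAConfig, fitness: FitnessFn | None) -> None:
        self.cfg = cfg
        self.fitness = fitness
        self.individuals: list[Individual] = []
        self.next_id = 0

    def register(self, ind: Individual) -> Individual:
        ind.id = self.next_id
        self.next_id += 1
        self.individuals.append(ind)
        return ind


def advance_generation(
    state: GenerationState,
    cfg: GAConfig,
    rng: np.random.Generator,
    *,
    fitness: FitnessFn | None = None,
    _run: _Run | None = None,
) -> GenerationState:
    """One accepted generation: breed all survivor pairs, evaluate, and
    select.  A brood whose best child does not strictly beat the best
    parent is discarded and rebred with smartVar/smartPts applied, up to
    the retry budget; exhaustion raises :class:`StallError`."""
    if not state.survivors:
        raise StallError("no survivors to breed")
    if len(state.survivors) < 2:
        raise StallError("need at least two survivors to form a breeding pair")
    run = _run if _run is not None else _Run(cfg, fitness)
    if _run is None:
        run.next_id = max((i.id for i in state.population), default=-1) + 1

    parent_best = max(s.fitness_mean for s in state.survivors)
    noise_var = state.current_noise_var
    mutants = state.current_mutants_per_child

    for _attempt in range(cfg.max_retries_per_generation + 1):
        trial = replace(
            state, current_noise_var=noise_var, current_mutants_per_child=mutants
        )
        children: list[Individual] = []
        for i in range(len(state.survivors)):
            for j in range(i + 1, len(state.survivors)):
                children.extend(
                    breed_pair(state.survivors[i], state.survivors[j], trial, cfg, rng)
                )
        for child in children:
            run.register(child)
            evaluate_fitness(child, cfg, run.fitness)

        if children and max(c.fitness_mean for c in children) > parent_best:
            copies = [
                run.register(
                    Individual(
                        id=-1,
                        phi=parent.phi.copy(),
                        origin="parent-copy",
                        parents=(parent.id,),
                        fitness_draws=parent.fitness_draws,
                    )
                )
                for parent in state.survivors
            ]
            population = children + copies
            survivors = select_survivors(population, cfg, rng)
            return GenerationState(
                index=state.index + 1,
                population=population,
                survivors=survivors,
                current_noise_var=noise_var,
                current_mutants_per_child=mutants,
                best_mean=max(parent_best, max(c.fitness_mean for c in children)),
            )
        # rejected: children leave the gene pool, the search broadens
        if cfg.smartVar:
            noise_var *= 2.0
        if cfg.smartPts:
            mutants += 1
    raise StallError(
        f"generation {state.index + 1}: children failed to outperform the best "
        f"parent ({parent_best:.4f}) in {cfg.max_retries_per_generation + 1} broods"
    )


def run_evolution(
    cfg: GAConfig,
    initial: Sequence[Individual] | Sequence[Sequence[float]] | None = None,
    *,
    seed_center: np.ndarray | Sequence[float] | None = None,
    seed_radius: float = 5.0,
    seed_count: int = 100,
    fitness: FitnessFn | None = None,
) -> RunHistory:
    """Run the GA for up to ``max_generations`` accepted generations.

    Generation 0 comes from ``initial`` (Individuals or raw phi vectors) or
    from ``seed_sphere`` around ``seed_center``.  A custom ``fitness``
    callable (phi, individual id, cfg) -> draws replaces the simulation,
    e.g. for synthetic landscapes.  The run is reproducible bit for bit
    under a fixed ``cfg.master_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed, spawn_key=(1,)))
    run = _Run(cfg, fitness)

    if initial is None:
        if seed_center is None:
            raise ValueError("provide initial individuals or a seed_center")
        gen0 = seed_sphere(seed_center, seed_radius, seed_count, cfg, rng)
        for ind in gen0:
            ind.id = -1
    else:
        gen0 = []
        for item in initial:
            if isinstance(item, Individual):
                gen0.append(item)
            else:
                phi = np.asarray(item, dtype=np.float64)
                if phi.shape != (len(cfg.spec),):
                    raise ValueError("initial phi vectors must align with the statistic set")
                if cfg.fixEdge:
                    phi = phi.copy()
                    phi[cfg.spec.index("edges")] = cfg.fixEdgeValue
                gen0.append(Individual(id=-1, phi=phi, origin="seed"))
    for ind in gen0:
        run.register(ind)
        if ind.fitness_draws is None:
            evaluate_fitness(ind, cfg, fitness)

    # generation 0 is the user's chosen breeding stock: everyone breeds
    # (capped at maxSurvivors by rank); top-fraction selection starts with
    # the first bred generation.
    gen0_ranked = sorted(gen0, key=lambda i: (-i.fitness_mean, i.id))
    state = GenerationState(
        index=0,
        population=list(gen0),
        survivors=gen0_ranked[: cfg.maxSurvivors],
        current_noise_var=cfg.noiseVarInit,
        current_mutants_per_child=1,
        best_mean=max(i.fitness_mean for i in gen0),
    )
    history = RunHistory(
        generations=[state], individuals=run.individuals, best_trajectory=[state.best_mean]
    )
    for _ in range(cfg.max_generations):
        if cfg.target_fitness is not None and state.best_mean >= cfg.target_fitness:
            break
        try:
            state = advance_generation(state, cfg, rng, fitness=fitness, _run=run)
        except StallError:
            history.stalled = True
            break
        history.generations.append(state)
        history.best_trajectory.append(state.best_mean)
    return history
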