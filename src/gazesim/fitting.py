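"""Parameter search: evolutionary optimisation, grid search, recovery harness.

The free parameters of a scanpath model are fitted by maximising the
Kolmogorov-Smirnov fitness against a reference event table with a simple
elitist evolution strategy: uniform initial population inside the bounds,
rank selection of the best individuals as parents, offspring by
per-parameter Gaussian mutation whose step size adapts multiplicatively
(up on improvement of the generation best, down otherwise).  Any
rank-selection Gaussian-mutation strategy with the published population
and generation counts fits the protocol; the default budget is an initial
population of 64, an ongoing population of 32, and 50 generations.

Fitness evaluations reuse a fixed seed schedule for every individual
(common random numbers), so the objective is a deterministic function of
the parameters and selection noise is reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from gazesim.evaluation import filter_events, fitness
from gazesim.scene_data import SceneBundle
from gazesim.simulator import ModelSpec, run_batch, scanpaths_to_events
from gazesim.synth_reference import model_as_reference

__all__ = [
    "SearchSpace",
    "EvolutionConfig",
    "evolve",
    "grid_search",
    "make_fitness_objective",
    "recover_parameters",
    "SWEEP_FACTORS",
]

# one-parameter sweep factors used by the sensitivity grid search
SWEEP_FACTORS = (0.5, 0.75, 0.9, 1.1, 1.25, 2.0)

Params = Dict[str, float]
Objective = Callable[[Params], float]


@dataclass
class SearchSpace:
    """Box bounds per fitted parameter plus fixed parameters.

    ``bounds`` maps a parameter name (a :class:`ModelSpec` field such as
    ``theta`` or ``sigma_s``) to finite ``(lower, upper)`` on a linear
    scale.  ``fixed`` holds parameters held constant during the search
    (e.g. the fixational-jitter scale ``sigma_d``).
    """

    bounds: Dict[str, Tuple[float, float]]
    fixed: Params = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lower < upper")

    @property
    def names(self) -> List[str]:
        return list(self.bounds)

    def clip(self, params: Params) -> Params:
        return {
            k: float(np.clip(v, *self.bounds[k])) if k in self.bounds else v
            for k, v in params.items()
        }

    def sample(self, rng: np.random.Generator) -> Params:
        return {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in self.bounds.items()}


@dataclass
class EvolutionConfig:
    initial_population: int = 64
    population: int = 32
    generations: int = 50
    init_step: float = 0.2  # mutation sd as a fraction of each bound range
    step_up: float = 1.3  # multiplicative step adaptation on improvement
    step_down: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_population < 2 or self.population < 2:
            raise ValueError("populations must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def evolve(objective: Objective, space: SearchSpace,
           config: EvolutionConfig) -> Dict[str, object]:
    """Run the evolution strategy; deterministic per config seed.

    Each generation after the first evaluates ``config.population`` new
    offspring, so the total number of objective calls is
    ``initial_population + population * (generations - 1)``.  An objective
    failure assigns fitness ``-inf`` to that individual.  Returns all
    evaluated individuals, the best one, and the step-size history.
    """
    rng = np.random.default_rng(config.seed)
    names = space.names
    ranges = np.array([hi - lo for lo, hi in space.bounds.values()])
    step = np.full(len(names), config.init_step)

    def evaluate(p: Params) -> float:
        try:
            return float(objective({**space.fixed, **p}))
        except Exception:
            return float("-inf")

    records: List[Dict[str, float]] = []

    def record(p: Params, fit: float, gen: int) -> None:
        records.append({**p, "fitness": fit, "generation": gen})

    pop = [space.sample(rng) for _ in range(config.initial_population)]
    fits = [evaluate(p) for p in pop]
    for p, f in zip(pop, fits):
        record(p, f, 0)
    best_fit = max(fits)
    step_history = [step.copy()]

    for gen in range(1, config.generations):
        order = np.argsort(fits)[::-1]
        keep = order[: config.population]
        parents = [pop[i] for i in keep]
        parent_fits = [fits[i] for i in keep]
        offspring, off_fits = [], []
        for k in range(config.population):
            parent = parents[k % len(parents)]
            vec = np.array([parent[n] for n in names])
            child_vec = vec + rng.normal(0.0, step * ranges)
            child = space.clip(dict(zip(names, child_vec)))
            f = evaluate(child)
            record(child, f, gen)
            offspring.append(child)
            off_fits.append(f)
        gen_best = max(off_fits)
        step = step * (config.step_up if gen_best > best_fit else config.step_down)
        best_fit = max(best_fit, gen_best)
        pop = parents + offspring
        fits = parent_fits + off_fits
        step_history.append(step.copy())

    table = pd.DataFrame(records)
    best_row = table.loc[table.fitness.idxmax()]
    best = {n: float(best_row[n]) for n in names}
    return {
        "population": table,
        "best_params": best,
        "best_fitness": float(best_row.fitness),
        "n_evaluations": len(table),
        "step_history": np.array(step_history),
    }


def grid_search(objective: Objective, grid: Sequence[Params]) -> pd.DataFrame:
    """Exhaustively evaluate a finite list of parameter points."""
    rows = []
    for params in grid:
        rows.append({**params, "fitness": float(objective(params))})
    return pd.DataFrame(rows)


def sweep_grid(defaults: Params, name: str,
               factors: Sequence[float] = SWEEP_FACTORS) -> List[Params]:
    """One-parameter sweep: scale ``name`` by each factor around defaults."""
    return [{**defaults, name: defaults[name] * f} for f in factors]


def make_fitness_objective(bundles: Sequence[SceneBundle], base_spec: ModelSpec,
                           reference: pd.DataFrame, n_runs: int = 6,
                           seed: int = 0) -> Objective:
    """Objective: simulate with candidate parameters, score KS fitness.

    The same base seed is used for every candidate, so the objective is a
    deterministic function of the parameters.
    """
    ref_f = filter_events(reference)

    def objective(params: Params) -> float:
        spec = replace(base_spec, **params)
        spec.validate()
        paths = run_batch(bundles, spec, n_runs=n_runs, base_seed=seed)
        sim = filter_events(scanpaths_to_events(paths))
        if sim[sim.event_type == "sac"].empty:
            return float("-inf")  # degenerate parameters: no saccade survived
        return fitness(sim, ref_f)

    return objective


def recover_parameters(bundles: Sequence[SceneBundle], true_spec: ModelSpec,
                       space: SearchSpace, config: EvolutionConfig,
                       n_runs: int = 6, ref_runs: int = 12,
                       reference: Optional[pd.DataFrame] = None
                       ) -> Dict[str, object]:
    """Fit against a self-generated reference with known ground truth.

    The reference uses the standard batch of 12 runs per scene (independent
    of the objective's seed schedule); candidate evaluations use ``n_runs``
    runs per scene.  Returns the evolution result plus per-parameter
    relative errors of the best individual with respect to the generating
    values.
    """
    if reference is None:
        reference, _ = model_as_reference(list(bundles), true_spec,
                                          n_runs=ref_runs, seed=config.seed + 1)
    objective = make_fitness_objective(bundles, true_spec, reference,
                                       n_runs=n_runs, seed=config.seed)
    result = evolve(objective, space, config)
    truth = {n: getattr(true_spec, n) for n in space.names}
    result["true_params"] = truth
    result["relative_error"] = {
        n: abs(result["best_params"][n] - truth[n]) / abs(truth[n])
        for n in space.names
    }
    return result
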