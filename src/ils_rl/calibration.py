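"""Genetic-algorithm calibration of decision models to cohort mean curves.

The loss for a candidate parameter vector is ``SSD1 + (1 - R**2)`` between
the model cohort's mean investment-ratio curve and the target (human or
synthetic) mean curve.  Because the model curve is itself a stochastic
simulation, the objective uses common random numbers: every candidate is
evaluated on the same fixed set of replicate seeds, making the objective a
deterministic function of the parameters and the calibration well-posed.

The optimizer is a small real-coded genetic algorithm — tournament
selection (size 2), uniform arithmetic crossover, Gaussian mutation with
standard deviation 10% of each parameter's range and reflection at the
bounds, plus one-elite preservation (so the best-so-far objective is
non-increasing).  Population size 20, crossover rate 0.80, mutation rate
0.01; the search stops after 50 stall generations, when the relative
improvement falls below 1e-8, or at the generation cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluation, rl_agents
from .ils_env import ILSConfig
from .rl_agents import ModelParams, params_from_dict
from .synthetic_cohort import simulate_model_cohort_fast

__all__ = ["GAConfig", "FitResult", "objective", "model_mean_curve", "genetic_calibrate"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm and objective-evaluation settings."""

    population_size: int = 20
    crossover_rate: float = 0.80
    mutation_rate: float = 0.01
    stall_generations: int = 50
    function_tolerance: float = 1e-8
    max_generations: int = 500
    n_sim_participants: int = 23
    n_rounds: int = 30
    n_objective_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.function_tolerance <= 0:
            raise ValueError("function_tolerance must be positive")
        if min(self.population_size, self.max_generations,
               self.n_sim_participants, self.n_objective_replicates) < 1:
            raise ValueError("population/generations/participants/replicates must be >= 1")

    @classmethod
    def smoke(cls, seed: int = 0, n_sim_participants: int = 23, **kw) -> "GAConfig":
        """Reduced-budget profile for desk-scale runs and CI."""
        kw.setdefault("max_generations", 30)
        kw.setdefault("n_objective_replicates", 5)
        return cls(seed=seed, n_sim_participants=n_sim_participants, **kw)

    @classmethod
    def full(cls, seed: int = 0, n_sim_participants: int = 23, **kw) -> "GAConfig":
        """Publication-scale profile: generation cap 500."""
        return cls(seed=seed, n_sim_participants=n_sim_participants, **kw)


@dataclass
class FitResult:
    """Calibrated parameters and diagnostics for one model x condition.

    ``ssd1`` and ``r_squared`` are replicate means, so the identity
    ``objective == ssd1 + (1 - r_squared)`` holds exactly.
    """

    model_id: str
    condition_id: str
    params: dict
    objective: float
    ssd1: float
    r_squared: float
    aic1: float
    ssd2: float
    aic2: float
    generations_run: int
    seed: int
    mean_curve: list = field(default_factory=list)
    best_history: list = field(default_factory=list)

    def params_object(self) -> ModelParams:
        return params_from_dict(self.model_id, self.params)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def _replicate_rng(ga_config: GAConfig, rep: int) -> np.random.Generator:
    # common random numbers: the seed depends only on (ga seed, replicate)
    return np.random.default_rng(np.random.SeedSequence([ga_config.seed, rep]))


def _replicate_curves(model_id: str, params: ModelParams, ils_config: ILSConfig,
                      ga_config: GAConfig) -> np.ndarray:
    curves = np.empty((ga_config.n_objective_replicates, ga_config.n_rounds))
    for rep in range(ga_config.n_objective_replicates):
        ratios = simulate_model_cohort_fast(
            model_id, params, ils_config, ga_config.n_sim_participants,
            ga_config.n_rounds, _replicate_rng(ga_config, rep))
        curves[rep] = ratios.mean(axis=0)
    return curves


def _objective_terms(model_id: str, params: ModelParams, ils_config: ILSConfig,
                     target: np.ndarray, ga_config: GAConfig) -> tuple[float, float, np.ndarray]:
    """Replicate-mean (ssd1, r_squared) plus the replicate-averaged curve."""
    curves = _replicate_curves(model_id, params, ils_config, ga_config)
    s1 = np.mean([evaluation.ssd1(c, target) for c in curves])
    r2 = np.mean([evaluation.r_squared(c, target) for c in curves])
    return float(s1), float(r2), curves.mean(axis=0)


def objective(model_id: str, params: ModelParams, ils_config: ILSConfig,
              target_mean_curve, ga_config: GAConfig) -> float:
    """Deterministic simulation loss ``mean_r[SSD1_r + (1 - R2_r)]``."""
    target = np.asarray(target_mean_curve, dtype=float)
    if len(target) != ga_config.n_rounds:
        raise ValueError("target curve length must equal ga_config.n_rounds")
    s1, r2, _ = _objective_terms(model_id, params, ils_config, target, ga_config)
    return s1 + (1.0 - r2)


def model_mean_curve(model_id: str, params: ModelParams, ils_config: ILSConfig,
                     ga_config: GAConfig) -> np.ndarray:
    """Replicate-averaged mean investment-ratio curve of a model cohort."""
    return _replicate_curves(model_id, params, ils_config, ga_config).mean(axis=0)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bound coordinates back into [lo, hi]."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.minimum(y, 2 * span - y)


def genetic_calibrate(model_id: str, ils_config: ILSConfig, target_mean_curve,
                      bounds: dict[str, tuple[float, float]] | None = None,
                      ga_config: GAConfig = GAConfig()) -> FitResult:
    """Calibrate one model to a target mean curve.

    For the parameter-free random model the objective is simply evaluated
    (a zero-dimensional search).  Returns the best individual found along
    with fit diagnostics and the per-generation best-objective trace.
    """
    target = np.asarray(target_mean_curve, dtype=float)
    if len(target) != ga_config.n_rounds:
        raise ValueError("target curve length must equal ga_config.n_rounds")
    if bounds is None:
        bounds = rl_agents.param_bounds(model_id)
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy lo < hi")

    def fit_from(params_dict: dict, gens: int, history: list[float]) -> FitResult:
        params = params_from_dict(model_id, params_dict)
        s1, r2, curve = _objective_terms(model_id, params, ils_config, target, ga_config)
        p = rl_agents.n_free_params(model_id)
        s2, a2 = evaluation.ssd2_aic2(float(curve.mean()), float(target.mean()), p)
        return FitResult(
            model_id=model_id, condition_id=ils_config.condition_id,
            params=params_dict, objective=s1 + (1.0 - r2), ssd1=s1, r_squared=r2,
            aic1=evaluation.aic1(s1, p, n_rounds=ga_config.n_rounds),
            ssd2=s2, aic2=a2, generations_run=gens, seed=ga_config.seed,
            mean_curve=curve.tolist(), best_history=history)

    if model_id == "random":
        res = fit_from({}, 0, [])
        res.best_history = [res.objective]
        return res

    d = len(names)
    rng = np.random.default_rng(np.random.SeedSequence([ga_config.seed, 0x6A]))
    pop = lo + rng.uniform(size=(ga_config.population_size, d)) * (hi - lo)

    def evaluate(x: np.ndarray) -> float:
        params = params_from_dict(model_id, dict(zip(names, map(float, x))))
        s1, r2, _ = _objective_terms(model_id, params, ils_config, target, ga_config)
        return s1 + (1.0 - r2)

    fitness = np.array([evaluate(x) for x in pop])
    best_history = [float(fitness.min())]
    stall = 0
    gen = 0
    mut_sd = 0.1 * (hi - lo)

    for gen in range(1, ga_config.max_generations + 1):
        elite_idx = int(np.argmin(fitness))
        children = [pop[elite_idx].copy()]
        while len(children) < ga_config.population_size:
            # tournament selection, size 2
            i, j = rng.integers(ga_config.population_size, size=2)
            p1 = pop[i] if fitness[i] <= fitness[j] else pop[j]
            i, j = rng.integers(ga_config.population_size, size=2)
            p2 = pop[i] if fitness[i] <= fitness[j] else pop[j]
            if rng.uniform() < ga_config.crossover_rate:
                u = rng.uniform(size=d)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mutate = rng.uniform(size=d) < ga_config.mutation_rate
            if mutate.any():
                child = child + mutate * rng.normal(0.0, mut_sd)
                child = _reflect(child, lo, hi)
            children.append(child)
        pop = np.array(children)
        fitness = np.array([evaluate(x) for x in pop])
        best = float(fitness.min())
        prev = best_history[-1]
        best_history.append(min(best, prev))
        rel_change = (prev - best) / max(abs(prev), 1e-30)
        if rel_change > ga_config.function_tolerance:
            stall = 0
        else:
            stall += 1
        if stall >= ga_config.stall_generations:
            break

    best_idx = int(np.argmin(fitness))
    best_x = pop[best_idx]
    # the elite is carried over, so the final population contains the best-ever
    best_params = dict(zip(names, map(float, best_x)))
    return fit_from(best_params, gen, best_history)
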