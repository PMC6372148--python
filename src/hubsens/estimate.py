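"""Candidate generation: log-uniform random sampling and genetic local search.

The estimator is a generational genetic algorithm in natural-log parameter
space (tournament selection, uniform crossover, Gaussian mutation, elitism)
whose elites are refined by Nelder-Mead local search, followed by an
intensification phase that perturbs and re-polishes the best basins.  A
minimum pairwise log-distance filter keeps the returned candidate list
diverse.  This is a generic stand-in honouring the contract "diverse
candidate sets with low cosine fitness" of the asynchronous genetic local
search (AGLSDC) family; no fidelity to a specific optimizer is attempted.

All parameters live in the box [-15, 5] in natural-log coordinates
(values in [e^-15, e^5]); a log10 reading of the same bounds is available via
``SearchConfig.log_base``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fit import cosine_fitness
from .models import ModelSpec
from .paramsets import LOG_BOUNDS, ParameterSet
from .simulate import ControlData, IntegrationError, simulate_patterns
from .signals import load_patterns

__all__ = ["SearchConfig", "random_sample_params", "estimate_parameters", "FitnessEvaluator"]

log = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Budgets and operators of the genetic local search (all config-exposed)."""

    seed: int
    population: int | None = None    # default: 16 * n_parameters
    generations: int = 60
    polish_every: int = 10           # memetic: NM-polish the best individual
    polish_iters: int = 80           # and re-inject it every this many generations
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma: float = 0.8
    tournament_k: int = 3
    n_elites: int = 6
    n_polish: int = 10
    n_restarts: int = 4              # fresh random multi-start local searches
    max_restarts: int = 20           # extra restarts while above fitness_goal
    ga_retries: int = 3              # extra full GA rounds while above fitness_goal
    fitness_goal: float = 6e-3       # stop restarting once the best is this good
    local_budget: int = 150          # Nelder-Mead iteration budget per polish
    intensify_rounds: int = 1
    intensify_sigma: float = 0.3
    diversity_radius: float = 0.05   # min pairwise distance in log space
    n_candidates: int = 100
    n_random: int = 1000
    bounds: tuple[float, float] = LOG_BOUNDS
    log_base: str = "nat"            # "nat" | "log10"
    rounds: int = 1                  # control data re-drawn per round if a factory is given

    def __post_init__(self):
        if self.population is not None and self.population < 1:
            raise ValueError("population must be positive")
        if self.generations < 0 or self.n_candidates < 1:
            raise ValueError("search budgets must be positive")

    def pop_size(self, n_params: int) -> int:
        return self.population if self.population is not None else 16 * n_params

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        return x * np.log(10.0) if self.log_base == "log10" else x


def random_sample_params(model: ModelSpec, n: int, seed: int, *,
                         bounds: tuple[float, float] = LOG_BOUNDS) -> list[ParameterSet]:
    """Draw ``n`` parameter sets, each coordinate uniform on ``bounds`` in log space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    d = len(model.param_names)
    draws = rng.uniform(lo, hi, size=(n, d))
    return [ParameterSet(id=f"{model.id}-rand-{i:05d}", model_id=model.id,
                         param_names=model.param_names, log_values=draws[i],
                         provenance="random")
            for i in range(n)]


class FitnessEvaluator:
    """Cosine fitness of a log-parameter vector against control means.

    Integration failures score the worst case (N = number of patterns) and
    are counted, matching the downstream exclusion rule.  Evaluations are
    archived for the diversity filter.
    """

    def __init__(self, model: ModelSpec, control: ControlData, *,
                 bounds=LOG_BOUNDS, rtol=1e-5, atol=1e-4, max_steps=4_000,
                 method="rk45", archive: bool = True):
        self.model = model
        self.compiled = model.compile()
        self.control = control
        self.patterns = load_patterns()
        self.bounds = bounds
        self.rtol, self.atol, self.max_steps = rtol, atol, max_steps
        # during the search a stiff corner that exhausts the fast integrator
        # simply scores worst-case; final candidates are re-evaluated with the
        # stiff fallback at classification time
        self.method = method
        self.n_failed = 0
        self.n_eval = 0
        self.worst = float(control.mean.shape[0])
        self.archive: list[tuple[np.ndarray, float]] | None = [] if archive else None

    def __call__(self, logv: np.ndarray) -> float:
        lo, hi = self.bounds
        x = np.clip(logv, lo, hi)
        penalty = float(np.sum((logv - x) ** 2))
        self.n_eval += 1
        try:
            sim = simulate_patterns(self.model, np.exp(x), self.patterns,
                                    self.control.sample_times, compiled=self.compiled,
                                    rtol=self.rtol, atol=self.atol,
                                    max_steps=self.max_steps, method=self.method)
            fit = cosine_fitness(sim, self.control.mean)
        except IntegrationError:
            self.n_failed += 1
            fit = self.worst
        if self.archive is not None and penalty == 0.0:
            self.archive.append((x.copy(), fit))
        return fit + penalty


def _diverse_filter(points: list[tuple[np.ndarray, float]], radius: float,
                    n_max: int) -> list[tuple[np.ndarray, float]]:
    """Greedy best-first selection with a minimum pairwise distance."""
    chosen: list[tuple[np.ndarray, float]] = []
    for x, f in sorted(points, key=lambda p: p[1]):
        if all(np.linalg.norm(x - cx) >= radius for cx, _ in chosen):
            chosen.append((x, f))
            if len(chosen) >= n_max:
                break
    return chosen


def estimate_parameters(model: ModelSpec, control: ControlData, config: SearchConfig, *,
                        control_factory=None, return_info: bool = False):
    """Genetic local search for up to ``config.n_candidates`` diverse candidates.

    ``control_factory(round_index) -> ControlData`` re-draws the control data
    per estimation round when given (one GA run per round, shared archive).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    d = len(model.param_names)
    best_history: list[list[float]] = []  # one monotone series per GA run
    archive: list[tuple[np.ndarray, float]] = []

    rounds = max(1, config.rounds if control_factory is not None else 1)
    retries = [0] + list(range(1, config.ga_retries + 1))
    for rnd in range(rounds):
        ctrl = control if (control_factory is None or rnd == 0) else control_factory(rnd)
        for retry in retries:
            if retry and min((f for _, f in archive), default=np.inf) <= config.fitness_goal:
                break
            if retry:
                log.info("fitness goal unmet; GA retry %d with a derived seed", retry)
                rng = np.random.default_rng([config.seed, rnd, retry])
            ev = FitnessEvaluator(model, ctrl, bounds=config.bounds)

            n_pop = config.pop_size(d)
            pop = rng.uniform(lo, hi, size=(n_pop, d))
            fit = np.array([ev(x) for x in pop])
            order = np.argsort(fit)
            pop, fit = pop[order], fit[order]
            run_history = [float(fit[0])]
            best_history.append(run_history)

            nm_opts_mid = {"maxiter": config.polish_iters, "adaptive": True,
                           "xatol": 1e-8, "fatol": 1e-12}
            for gen in range(config.generations):
                children = np.empty_like(pop)
                n_el = min(config.n_elites, n_pop)
                children[:n_el] = pop[:n_el]  # elitism: best never lost
                for c in range(n_el, n_pop):
                    i = _tournament(rng, fit, config.tournament_k)
                    j = _tournament(rng, fit, config.tournament_k)
                    child = pop[i].copy()
                    if rng.random() < config.crossover_rate:
                        swap = rng.random(d) < 0.5
                        child[swap] = pop[j][swap]
                    mut = rng.random(d) < config.mutation_rate
                    child[mut] += rng.normal(0.0, config.mutation_sigma, size=int(mut.sum()))
                    children[c] = np.clip(child, lo, hi)
                child_fit = fit.copy()
                for c in range(n_el, n_pop):
                    child_fit[c] = ev(children[c])
                order = np.argsort(child_fit)
                pop, fit = children[order], child_fit[order]
                # memetic step: Lamarckian refinement of the current best,
                # re-injected in place of the worst individual
                if (config.polish_every > 0 and config.polish_iters > 0
                        and (gen + 1) % config.polish_every == 0):
                    res = minimize(ev, pop[0], method="Nelder-Mead", options=nm_opts_mid)
                    if res.fun < fit[-1]:
                        pop[-1], fit[-1] = np.clip(res.x, lo, hi), res.fun
                        order = np.argsort(fit)
                        pop, fit = pop[order], fit[order]
                run_history.append(float(fit[0]))

            # local refinement: distinct elites plus fresh multi-start seeds (the
            # restarts guard against the whole population collapsing into one
            # basin of the multimodal fitness landscape)
            if config.local_budget > 0 and config.n_polish > 0:
                seeds_lp = [x for x, _ in _diverse_filter(ev.archive or [], radius=1.0,
                                                          n_max=config.n_polish)]
                seeds_lp += [rng.uniform(lo, hi, d) for _ in range(config.n_restarts)]
                nm_opts = {"maxiter": config.local_budget, "adaptive": True,
                           "xatol": 1e-8, "fatol": 1e-12}
                best_f = np.inf
                for x0 in seeds_lp:
                    res = minimize(ev, x0, method="Nelder-Mead", options=nm_opts)
                    best_f = min(best_f, res.fun)
                # restart until the goal is met or the budget runs out: the
                # landscape is multimodal and a single converged population can
                # sit in a degenerate basin
                for _ in range(config.max_restarts):
                    if best_f <= config.fitness_goal:
                        break
                    res = minimize(ev, rng.uniform(lo, hi, d), method="Nelder-Mead",
                                   options=nm_opts)
                    best_f = min(best_f, res.fun)
                # intensification: perturb the current best basins and re-polish
                for _ in range(config.intensify_rounds):
                    tops = sorted(ev.archive or [], key=lambda p: p[1])[:config.n_polish]
                    for x0, _f in tops:
                        xp = np.clip(x0 + rng.normal(0.0, config.intensify_sigma, d), lo, hi)
                        minimize(ev, xp, method="Nelder-Mead",
                                 options={**nm_opts, "maxiter": config.local_budget // 2})
            archive.extend(ev.archive or [])
        log.info("round %d: %d evaluations, %d integration failures, best fitness %.3g",
                 rnd, ev.n_eval, ev.n_failed, min(f for _, f in archive))

    chosen = _diverse_filter(archive, config.diversity_radius, config.n_candidates)
    if len(chosen) < config.n_candidates:
        log.warning("diversity radius %.3g admits only %d of %d requested candidates",
                    config.diversity_radius, len(chosen), config.n_candidates)
    sets = [ParameterSet(id=f"{model.id}-est-{i:04d}", model_id=model.id,
                         param_names=model.param_names, log_values=x,
                         provenance="estimated", fitness=f)
            for i, (x, f) in enumerate(chosen)]
    if return_info:
        return sets, {"best_history": best_history}
    return sets


def _tournament(rng, fit: np.ndarray, k: int) -> int:
    idx = rng.integers(0, fit.size, size=max(1, k))
    return int(idx[np.argmin(fit[idx])])
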