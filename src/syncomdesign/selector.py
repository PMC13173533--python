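"""Community selection: genetic-algorithm subset search and pathway activation.

The selector searches for a fixed-size community (k = 9 by default) that
maximizes mean predicted degradation across the three pollutant classes
minus a gamma-weighted (gamma = 0.15) functional-redundancy penalty. The
search is a steady-state genetic algorithm over k-subsets with uniform
crossover, swap mutation, duplicate repair and elitism, so the best-so-far
fitness trace is monotone nondecreasing.

The activation simulator evaluates how much of each pollutant's degradation
chain a community can actually engage under substrate-limited, fluctuating
conditions: each pathway is a linear chain of unit-stoichiometry conversion
steps; a step is available when some member carries one of its enzymes;
per-time-step engagement is the maximum terminal-product flux of the linear
program subject to steady-state mass balance at internal metabolites and
an uptake bound scaled by the environmental multiplier schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = ["GAConfig", "ActivationScenario", "fitness", "ga_select", "activation_simulate"]


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for k-subset community search."""

    k: int = 9
    gamma: float = 0.15
    population: int = 200
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.population < 2 or self.generations < 1:
            raise ValueError("k, population and generations must be positive")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")


@dataclass
class ActivationScenario:
    """Substrate uptake bounds per pollutant and a multiplier schedule.

    ``uptake_bounds[pollutant]`` caps the pollutant influx (>= 0);
    ``multipliers`` is a sequence of per-time-step environmental factors
    applied multiplicatively to every uptake bound.
    """

    uptake_bounds: dict[str, float]
    multipliers: list[float] = field(default_factory=lambda: [1.0])

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.uptake_bounds.values()):
            raise ValueError("uptake bounds must be nonnegative")
        if any(m < 0 for m in self.multipliers):
            raise ValueError("multipliers must be nonnegative")


# ---------------------------------------------------------------------------
# fitness and GA


def fitness(community, predict_fn, redundancy_fn, gamma: float = 0.15) -> float:
    """mean(predicted 3-vector of efficiencies) - gamma * redundancy."""
    members = list(community)
    if len(set(members)) != len(members):
        raise ValueError("community members must be distinct")
    pred = np.asarray(predict_fn(members), dtype=float)
    red = float(redundancy_fn(members))
    return float(pred.mean() - gamma * red)


def _repair(chrom: list, candidates: list, k: int, rng: np.random.Generator) -> list:
    """Deduplicate and pad/trim a chromosome back to a k-subset."""
    seen = list(dict.fromkeys(chrom))
    if len(seen) > k:
        seen = seen[:k]
    if len(seen) < k:
        pool = [c for c in candidates if c not in seen]
        extra = rng.choice(len(pool), size=k - len(seen), replace=False)
        seen += [pool[i] for i in extra]
    return sorted(seen)


def ga_select(
    candidates,
    config: GAConfig,
    predict_fn,
    redundancy_fn,
) -> dict:
    """Search for the fittest k-member community among ``candidates``.

    ``predict_fn(members) -> 3-vector`` and ``redundancy_fn(members) ->
    scalar`` supply the two fitness components. Fitness values are memoized
    per subset, so repeated evaluation of the same community is free.
    Returns ``{"community": tuple, "fitness": float, "trace": [...]}`` where
    ``trace`` is the best-so-far fitness per generation (nondecreasing).
    """
    candidates = sorted(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate strains must be distinct")
    if len(candidates) < config.k:
        raise ValueError(f"need at least k={config.k} candidates, got {len(candidates)}")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, float] = {}

    def fit(members: list) -> float:
        key = tuple(members)
        if key not in cache:
            cache[key] = fitness(members, predict_fn, redundancy_fn, gamma=config.gamma)
        return cache[key]

    if len(candidates) == config.k:
        best = sorted(candidates)
        f = fit(best)
        return {"community": tuple(best), "fitness": f, "trace": [f]}

    pop = [
        sorted(rng.choice(candidates, size=config.k, replace=False).tolist())
        for _ in range(config.population)
    ]
    scores = [fit(c) for c in pop]
    order = np.argsort(scores)[::-1]
    best, best_f = list(pop[order[0]]), scores[order[0]]
    trace = [best_f]

    for _ in range(config.generations):
        order = np.argsort(scores)[::-1]
        new_pop = [list(pop[i]) for i in order[: config.elitism]]
        while len(new_pop) < config.population:
            # binary tournament selection
            def pick() -> list:
                i, j = rng.integers(len(pop), size=2)
                return pop[i] if scores[i] >= scores[j] else pop[j]

            a, b = pick(), pick()
            if rng.random() < config.crossover_rate:
                mask = rng.random(config.k) < 0.5
                child = [a[i] if mask[i] else b[i] for i in range(config.k)]
            else:
                child = list(a)
            if rng.random() < config.mutation_rate:
                pos = int(rng.integers(config.k))
                outside = [c for c in candidates if c not in child]
                if outside:
                    child[pos] = outside[int(rng.integers(len(outside)))]
            new_pop.append(_repair(child, candidates, config.k, rng))
        pop = new_pop
        scores = [fit(c) for c in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_f:
            best_f, best = scores[gen_best], list(pop[gen_best])
        trace.append(best_f)

    return {"community": tuple(sorted(best)), "fitness": best_f, "trace": trace}


# ---------------------------------------------------------------------------
# pathway activation (toy flux balance)


def _chain_lp(steps_available: list[bool], uptake_bound: float, step_cap: float = 1e6):
    """Max terminal flux through a linear conversion chain.

    Reactions: uptake (<= bound) -> m0; step_i: m_i -> m_{i+1} (cap 0 if the
    community lacks every enzyme of the step); sink on the terminal
    metabolite. Steady state at every internal metabolite. Returns
    (objective, fluxes, residual mass-balance error, status).
    """
    n_steps = len(steps_available)
    # variables: v_uptake, v_step_0..n-1  (sink flux equals the last step's)
    n_var = 1 + n_steps
    n_int = n_steps  # metabolites m0..m_{n-1} are internal; the product is drained
    S = np.zeros((n_int, n_var))
    for m in range(n_int):
        if m == 0:
            S[m, 0] = 1.0
        else:
            S[m, m] = 1.0  # produced by step m-1 (variable index m)
        S[m, m + 1] = -1.0  # consumed by step m (variable index m+1)
    bounds = [(0.0, uptake_bound)] + [
        (0.0, step_cap if avail else 0.0) for avail in steps_available
    ]
    c = np.zeros(n_var)
    c[-1] = -1.0  # maximize the last conversion step's flux
    res = linprog(c, A_eq=S, b_eq=np.zeros(n_int), bounds=bounds, method="highs")
    if not res.success:
        return 0.0, np.zeros(n_var), np.inf, "infeasible"
    resid = float(np.abs(S @ res.x).max())
    return float(-res.fun) + 0.0, res.x, resid, "optimal"


def activation_simulate(
    community,
    pathway_map: dict,
    scenario: ActivationScenario,
    profiles: pd.DataFrame | None = None,
) -> dict:
    """Per-pathway degradation engagement (flux) at each scenario time step.

    A conversion step is available to the community if any member carries at
    least one of the step's enzymes (``profiles`` gives the copy numbers;
    without profiles, membership in the pathway map alone decides nothing
    and a KeyError is raised). Infeasible or fully blocked chains report an
    engagement of 0 with a diagnostic rather than raising.

    Returns ``{"engagement": DataFrame (time step x pollutant),
    "diagnostics": {pollutant: str}}``.
    """
    if profiles is None:
        raise ValueError("activation_simulate needs the strain profile table")
    members = list(community)
    missing = [m for m in members if m not in profiles.index]
    if missing:
        raise KeyError(f"strains not in profile table: {missing}")
    sub = profiles.loc[members]

    def community_has(enzymes: list[str]) -> bool:
        return any(e in sub.columns and (sub[e] > 0).any() for e in enzymes)

    pollutants = list(pathway_map["pollutants"])
    engagement = np.zeros((len(scenario.multipliers), len(pollutants)))
    diagnostics: dict[str, str] = {}
    for pj, pol in enumerate(pollutants):
        steps = pathway_map["chains"].get(pol, [])
        if not steps:
            diagnostics[pol] = "no conversion chain defined"
            continue
        avail = [community_has(step["enzymes"]) for step in steps]
        if not all(avail):
            broken = [i for i, a in enumerate(avail) if not a]
            diagnostics[pol] = f"chain broken at step(s) {broken}: no member enzyme"
        base = scenario.uptake_bounds.get(pol, 0.0)
        for ti, mult in enumerate(scenario.multipliers):
            obj, _flux, resid, status = _chain_lp(avail, base * mult)
            if status != "optimal":
                diagnostics[pol] = "infeasible linear program"
                obj = 0.0
            elif resid > 1e-8:
                diagnostics[pol] = f"mass-balance residual {resid:.2e}"
            engagement[ti, pj] = obj
    table = pd.DataFrame(
        engagement, columns=pollutants, index=range(len(scenario.multipliers))
    )
    return {"engagement": table, "diagnostics": diagnostics}
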