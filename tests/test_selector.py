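"""GA subset search vs exhaustive oracle; toy flux-balance activation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import syncomdesign as scd
from syncomdesign.selector import ActivationScenario, GAConfig, activation_simulate, fitness, ga_select


def planted_fitness_functions(seed=0, n=10):
    """Deterministic per-strain scores: community mean minus fixed redundancy."""
    rng = np.random.default_rng(seed)
    strains = [f"s{i:02d}" for i in range(n)]
    scores = {s: rng.uniform(0.1, 0.9, size=3) for s in strains}
    pair_bonus = {frozenset(p): rng.uniform(-0.05, 0.05) for p in itertools.combinations(strains, 2)}

    def predict_fn(members):
        base = np.mean([scores[m] for m in members], axis=0)
        bonus = np.mean(
            [pair_bonus[frozenset(p)] for p in itertools.combinations(sorted(members), 2)]
        )
        return np.clip(base + bonus, 0, 1)

    def redundancy_fn(members):
        return 0.3

    return strains, predict_fn, redundancy_fn


class TestFitness:
    def test_gamma_zero_equals_mean_prediction(self):
        f = fitness(["a", "b"], lambda m: np.array([0.2, 0.4, 0.9]), lambda m: 0.7, gamma=0.0)
        assert f == pytest.approx(0.5)

    def test_closed_form_with_redundancy_penalty(self):
        f = fitness(["a"], lambda m: np.ones(3), lambda m: 1.0, gamma=0.15)
        assert f == pytest.approx(0.85)

    def test_zero_prediction_zero_redundancy(self):
        assert fitness(["a"], lambda m: np.zeros(3), lambda m: 0.0) == 0.0

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            fitness(["a", "a"], lambda m: np.ones(3), lambda m: 0.0)


class TestGASelect:
    def test_matches_exhaustive_search_on_small_instances(self):
        # C(10, 3) = 120 <= 500: the GA must find the global optimum on
        # nearly every seed
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=seed)
            best_exh = max(
                itertools.combinations(strains, 3),
                key=lambda c: fitness(list(c), predict_fn, redundancy_fn, gamma=0.15),
            )
            f_exh = fitness(list(best_exh), predict_fn, redundancy_fn, gamma=0.15)
            cfg = GAConfig(k=3, population=40, generations=30, seed=seed)
            res = ga_select(strains, cfg, predict_fn, redundancy_fn)
            if res["fitness"] == pytest.approx(f_exh, abs=1e-12):
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_returns_k_distinct_members(self):
        strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=1, n=45)
        cfg = GAConfig(k=9, population=40, generations=10, seed=0)
        res = ga_select(strains, cfg, predict_fn, redundancy_fn)
        assert len(res["community"]) == 9
        assert len(set(res["community"])) == 9

    def test_trace_is_monotone_nondecreasing(self):
        strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=2)
        res = ga_select(strains, GAConfig(k=4, population=30, generations=25, seed=3), predict_fn, redundancy_fn)
        trace = res["trace"]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_k_equals_candidates_returns_full_set(self):
        strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=3, n=5)
        res = ga_select(strains, GAConfig(k=5, population=10, generations=5, seed=0), predict_fn, redundancy_fn)
        assert set(res["community"]) == set(strains)

    def test_too_few_candidates_rejected(self):
        strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=4, n=5)
        with pytest.raises(ValueError):
            ga_select(strains, GAConfig(k=9), predict_fn, redundancy_fn)

    def test_seeded_reproducibility(self):
        strains, predict_fn, redundancy_fn = planted_fitness_functions(seed=5)
        cfg = GAConfig(k=3, population=20, generations=10, seed=11)
        r1 = ga_select(strains, cfg, predict_fn, redundancy_fn)
        r2 = ga_select(strains, cfg, predict_fn, redundancy_fn)
        assert r1["community"] == r2["community"]
        assert r1["trace"] == r2["trace"]


def linear_chain_map(enzymes_per_step):
    """Pathway map with one pollutant and a linear chain m1 -> m2 -> m3."""
    mets = [f"m{i}" for i in range(1, len(enzymes_per_step) + 2)]
    steps = [
        {"substrate": mets[i], "product": mets[i + 1], "enzymes": list(es)}
        for i, es in enumerate(enzymes_per_step)
    ]
    return {
        "pollutants": ["lignin"],
        "pathways": {"lignin": sorted({e for es in enzymes_per_step for e in es})},
        "chains": {"lignin": steps},
        "enzyme_substrate": [],
        "metabolites": mets,
    }


class TestActivationSimulate:
    def _profiles(self, rows, enzymes):
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))], columns=enzymes)

    def test_zero_uptake_bounds_give_zero_engagement(self):
        pmap = linear_chain_map([["eA"], ["eB"]])
        prof = self._profiles([[1, 1]], ["eA", "eB"])
        scen = ActivationScenario(uptake_bounds={"lignin": 0.0})
        res = activation_simulate(["s0"], pmap, scen, profiles=prof)
        assert (res["engagement"].to_numpy() == 0).all()

    def test_linear_chain_product_flux_equals_uptake_bound(self):
        # hand LP solution: with both steps available, all flux runs through
        pmap = linear_chain_map([["eA"], ["eB"]])
        prof = self._profiles([[2, 0], [0, 1]], ["eA", "eB"])
        scen = ActivationScenario(uptake_bounds={"lignin": 3.5})
        res = activation_simulate(["s0", "s1"], pmap, scen, profiles=prof)
        assert res["engagement"].loc[0, "lignin"] == pytest.approx(3.5)

    def test_missing_middle_enzyme_breaks_the_chain(self):
        pmap = linear_chain_map([["eA"], ["eB"], ["eC"]])
        prof = self._profiles([[1, 0, 1]], ["eA", "eB", "eC"])
        scen = ActivationScenario(uptake_bounds={"lignin": 2.0})
        res = activation_simulate(["s0"], pmap, scen, profiles=prof)
        assert res["engagement"].loc[0, "lignin"] == 0.0
        assert "lignin" in res["diagnostics"]

    def test_mass_balance_conserved_to_1e_8(self):
        from syncomdesign.selector import _chain_lp

        for avail in [[True] * 4, [True, True, False, True]]:
            obj, flux, resid, status = _chain_lp(avail, uptake_bound=2.0)
            assert resid <= 1e-8

    def test_engagement_monotone_in_uptake_bound(self):
        pmap = linear_chain_map([["eA"], ["eB"]])
        prof = self._profiles([[1, 1]], ["eA", "eB"])
        prev = -1.0
        for u in [0.0, 0.5, 1.0, 4.0]:
            scen = ActivationScenario(uptake_bounds={"lignin": u})
            res = activation_simulate(["s0"], pmap, scen, profiles=prof)
            val = res["engagement"].loc[0, "lignin"]
            assert val >= prev
            prev = val

    def test_multiplier_schedule_scales_engagement(self):
        pmap = linear_chain_map([["eA"], ["eB"]])
        prof = self._profiles([[1, 1]], ["eA", "eB"])
        scen = ActivationScenario(uptake_bounds={"lignin": 2.0}, multipliers=[1.0, 0.25])
        res = activation_simulate(["s0"], pmap, scen, profiles=prof)
        assert res["engagement"].loc[1, "lignin"] == pytest.approx(0.5)

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            ActivationScenario(uptake_bounds={"lignin": -1.0})
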