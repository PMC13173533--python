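"""Mass-balance arithmetic, kinetic fits and community-stability indices."""

import numpy as np
import pytest

import syncomdesign as scd
from syncomdesign.assay import (
    AbundanceTable,
    AssaySeries,
    CSI_SENTINEL,
    StoichiometrySpec,
    bray_curtis,
    convert_concentration,
    mass_to_molar,
    molar_to_mass,
)


class TestRatios:
    @pytest.mark.parametrize(
        "c0,ct,expected",
        [
            (31.825, 2.736, 91.4),  # atrazine, liquid culture day 3
            (18.58, 1.28, 93.1),  # PFOS, day 7
            (5.0, 5.0, 0.0),
        ],
    )
    def test_percent_removal(self, c0, ct, expected):
        assert scd.percent_removal(c0, ct)["percent"] == expected

    def test_percent_removal_roundtrip(self):
        for p in [0.0, 12.5, 55.6, 100.0]:
            c0 = 20.0
            assert scd.percent_removal(c0, c0 * (1 - p / 100))["raw"] == pytest.approx(p)

    def test_percent_removal_rejects_nonpositive_initial(self):
        with pytest.raises(ValueError):
            scd.percent_removal(0.0, 0.0)

    @pytest.mark.parametrize(
        "cons,best,expected",
        [(93.1, 41.8, 2.23), (91.4, 62.2, 1.47), (50.0, 50.0, 1.0)],
    )
    def test_fold_improvement(self, cons, best, expected):
        assert scd.fold_improvement(cons, best)["fold"] == pytest.approx(expected)

    def test_soil_enhancement_ratios(self):
        # soil microcosm: removal 73.2 vs 18.4 -> 4.0x; rates 0.058 vs 0.009 -> 6.4x
        assert round(scd.fold_improvement(73.2, 18.4)["raw"], 1) == 4.0
        assert round(scd.fold_improvement(0.058, 0.009)["raw"], 1) == 6.4

    @pytest.mark.parametrize(
        "measured,theoretical,expected",
        [(6.12, 6.54, 93.6), (22.22, 64.08, 34.7), (3.3, 3.3, 100.0)],
    )
    def test_percent_of_theoretical(self, measured, theoretical, expected):
        assert scd.percent_of_theoretical(measured, theoretical)["percent"] == expected

    @pytest.mark.parametrize(
        "a0,at,expected", [(11.1, 15.6, 40.5), (11.2, 14.1, 25.9), (9.0, 9.0, 0.0)]
    )
    def test_relative_change(self, a0, at, expected):
        assert scd.relative_change(a0, at)["percent"] == expected


class TestStoichiometry:
    def test_atrazine_nitrogen_theoretical_yield(self):
        # 200 ug/L atrazine, 5 N of 14.007 g/mol, M = 215.68 g/mol
        spec = StoichiometrySpec(215.68, 5, 14.007)
        assert scd.theoretical_element_yield(200.0, spec) == pytest.approx(64.9, abs=0.05)

    def test_yield_linear_in_concentration_and_atoms(self):
        spec1 = StoichiometrySpec(100.0, 2, 14.007)
        spec2 = StoichiometrySpec(100.0, 4, 14.007)
        y1 = scd.theoretical_element_yield(100.0, spec1)
        assert y1 == pytest.approx(28.014)
        assert scd.theoretical_element_yield(200.0, spec1) == pytest.approx(2 * y1)
        assert scd.theoretical_element_yield(100.0, spec2) == pytest.approx(2 * y1)
        assert scd.theoretical_element_yield(0.0, spec1) == 0.0

    def test_pfos_fluoride_molar_product(self):
        # 37.1 uM PFOS x 17 F x 19 g/mol = 12.0 mg/L
        assert scd.molar_element_yield(37.1, 17, 19.0) == pytest.approx(12.0, abs=0.02)
        assert scd.molar_element_yield(10.0, 1, 19.0) == pytest.approx(0.19)
        assert scd.molar_element_yield(0.0, 17, 19.0) == 0.0

    def test_unit_conversions(self):
        assert convert_concentration(200.0, "ng/mL", "ug/L") == pytest.approx(200.0)
        assert convert_concentration(200.0, "ng/mL", "mg/L") == pytest.approx(0.2)
        assert mass_to_molar(18.58, 500.13) == pytest.approx(37.1, abs=0.06)  # PFOS
        assert molar_to_mass(37.1, 500.13) == pytest.approx(18.58, abs=0.03)
        with pytest.raises(ValueError):
            convert_concentration(1.0, "stone/acre", "mg/L")


class TestKineticFits:
    def _series(self, k, c0=10.0, days=14):
        t = np.arange(0.0, days + 1)
        return AssaySeries(times=t, mean=c0 * np.exp(-k * t), sd=np.zeros(days + 1))

    @pytest.mark.parametrize("k", [0.065, 0.058])
    def test_noiseless_rate_recovery(self, k):
        fit = scd.first_order_fit(self._series(k))
        assert fit["k"] == pytest.approx(k, rel=1e-10)
        assert fit["r2"] == pytest.approx(1.0)

    def test_constant_series_flagged(self):
        t = np.arange(5.0)
        s = AssaySeries(times=t, mean=np.full(5, 3.0), sd=np.zeros(5))
        fit = scd.first_order_fit(s)
        assert fit["k"] == pytest.approx(0.0)
        assert fit["degenerate"]

    def test_unbiased_under_replicate_noise(self):
        ks = []
        for seed in range(200):
            s = scd.generate_assay_series(
                {"kind": "first_order", "k": 0.2}, c0=50.0, days=10,
                noise_sd=0.5, seed=seed,
            )
            ks.append(scd.first_order_fit(s)["k"])
        assert np.mean(ks) == pytest.approx(0.2, abs=0.01)

    def test_nonpositive_concentration_rejected(self):
        t = np.arange(3.0)
        s = AssaySeries(times=t, mean=np.array([1.0, 0.0, 0.5]), sd=np.zeros(3))
        with pytest.raises(ValueError):
            scd.first_order_fit(s)

    def test_linear_window_ols_on_printed_points(self):
        # OLS on (1, 12.31), (2, 7.67), (3, 2.74): slope from the closed form
        t = np.array([0.0, 1.0, 2.0, 3.0])
        c = np.array([31.825, 12.31, 7.67, 2.74])
        s = AssaySeries(times=t, mean=c, sd=np.zeros(4))
        fit = scd.linear_window_fit(s, 1.0, 3.0)
        x, y = t[1:], c[1:]
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit["slope"] == pytest.approx(slope)
        assert fit["slope"] == pytest.approx(-4.785, abs=0.001)

    def test_two_points_fit_exactly(self):
        s = AssaySeries(times=np.array([0.0, 2.0]), mean=np.array([4.0, 1.0]), sd=np.zeros(2))
        fit = scd.linear_window_fit(s, 0.0, 2.0)
        assert fit["slope"] == pytest.approx(-1.5)
        assert fit["r2"] == 1.0

    def test_collinear_triple_r2_one(self):
        s = AssaySeries(times=np.arange(3.0), mean=np.array([6.0, 4.0, 2.0]), sd=np.zeros(3))
        assert scd.linear_window_fit(s, 0, 2)["r2"] == pytest.approx(1.0)


class TestDiversityAndStability:
    def test_uniform_nine_taxa_shannon(self):
        d = scd.diversity_indices(np.ones(9) / 9)
        assert d["shannon"] == pytest.approx(np.log(9))
        assert d["richness"] == 9

    def test_single_taxon(self):
        d = scd.diversity_indices([0.0, 1.0, 0.0])
        assert d["shannon"] == 0.0
        assert d["simpson"] == 0.0
        assert d["richness"] == 1

    def test_even_pair_simpson_half(self):
        assert scd.diversity_indices([0.5, 0.5])["simpson"] == pytest.approx(0.5)

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        h_max = scd.diversity_indices(np.ones(6) / 6)["shannon"]
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            assert scd.diversity_indices(p)["shannon"] <= h_max + 1e-12

    def test_bray_curtis_bounds_and_extremes(self):
        assert bray_curtis([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0
        assert 0.0 <= bray_curtis([0.7, 0.3], [0.3, 0.7]) <= 1.0

    def test_csi_hand_computed(self):
        tab = AbundanceTable(
            times=[0, 3, 7],
            abundances=[[0.5, 0.3, 0.2], [0.4, 0.4, 0.2], [0.35, 0.3, 0.35]],
        )
        # consecutive Bray-Curtis: 0.10 and 0.15 -> CV = std/mean
        d = np.array([0.10, 0.15])
        expected = d.mean() / d.std(ddof=1)
        out = scd.community_stability_index(tab)
        np.testing.assert_allclose(out["dissimilarities"], d, atol=1e-12)
        assert out["csi"] == pytest.approx(expected)

    def test_identical_compositions_hit_sentinel(self):
        tab = AbundanceTable(
            times=[0, 1, 2], abundances=[[0.6, 0.4]] * 3
        )
        out = scd.community_stability_index(tab)
        assert out["degenerate"] and out["csi"] == CSI_SENTINEL

    def test_alternating_states_zero_spread_hits_sentinel(self):
        a, b = [0.7, 0.3], [0.3, 0.7]
        tab = AbundanceTable(times=[0, 1, 2, 3], abundances=[a, b, a, b])
        out = scd.community_stability_index(tab)
        assert out["degenerate"] and out["csi"] == CSI_SENTINEL

    def test_too_few_time_points_rejected(self):
        tab = AbundanceTable(times=[0, 1], abundances=[[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError):
            scd.community_stability_index(tab)

    def test_abundance_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AbundanceTable(times=[0], abundances=[[0.5, 0.2]])
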