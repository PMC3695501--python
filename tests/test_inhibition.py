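"""Product-inhibition inference: MM fits, Dixon/Cornish-Bowden, IC50s."""

import numpy as np
import pytest

import mnmekin as mk
from mnmekin.inhibition import ParallelLinesError
from mnmekin.panels import dissociation_mm_panel


def _mm_fits(grid, e0=30.0):
    return [mk.fit_michaelis_menten(grid.substrate, grid.rates[:, j], e0,
                                    grid.inhibitor_name, grid.inhibitor[j])
            for j in range(grid.inhibitor.size)]


@pytest.fixture(scope="module")
def gdp_grid_exact():
    return mk.generate_inhibition_grid(0.23, 30.0, 19.5, "GDP", ki_e=41.2,
                                       noise_frac=0.0)


@pytest.fixture(scope="module")
def pi_grid_exact():
    return mk.generate_inhibition_grid(
        0.41, 30.0, 8.7, "Pi", ki_e=670.0, ki_es=5800.0,
        s_list=np.array([2.5, 5.0, 7.5]),
        i_list=np.linspace(0.0, 10000.0, 5), noise_frac=0.0)


class TestMichaelisMenten:
    def test_exact_uninhibited_dissociation_parameters(self):
        s = np.array([5.0, 10.0, 20.0, 50.0, 100.0])
        v = 0.23 * 30.0 * s / (19.5 + s)
        fit = mk.fit_michaelis_menten(s, v, 30.0)
        assert fit.kcat == pytest.approx(0.23, rel=1e-8)
        assert fit.Km == pytest.approx(19.5, rel=1e-8)

    def test_rate_at_km_is_half_maximal(self):
        s = np.array([5.0, 19.5, 50.0, 100.0])
        v = 0.23 * 30.0 * s / (19.5 + s)
        fit = mk.fit_michaelis_menten(s, v, 30.0)
        assert v[1] == pytest.approx(fit.Vmax / 2.0, rel=1e-8)

    def test_two_substrate_levels_rejected(self):
        with pytest.raises(ValueError):
            mk.fit_michaelis_menten([5.0, 50.0], [1.0, 2.0], 30.0)

    def test_nonsaturating_design_warns(self):
        s = np.array([0.5, 1.0, 2.0])
        v = 0.23 * 30.0 * s / (19.5 + s)
        with pytest.warns(UserWarning, match="non-saturating"):
            mk.fit_michaelis_menten(s, v, 30.0)


class TestDixon:
    def test_noiseless_competitive_grid_intersects_at_minus_kie(
            self, gdp_grid_exact):
        res = mk.dixon_fit(gdp_grid_exact)
        assert res["K_IE"] == pytest.approx(41.2, abs=1e-5)
        assert res["intersection_residual"] < 1e-8
        assert res["K_IE_global"] == pytest.approx(41.2, rel=1e-6)

    def test_noiseless_mixed_grid_gives_pi_free_enzyme_constant(
            self, pi_grid_exact):
        res = mk.dixon_fit(pi_grid_exact)
        assert res["K_IE"] == pytest.approx(670.0, rel=1e-5)

    def test_uncompetitive_pattern_has_parallel_lines(self):
        grid = mk.generate_inhibition_grid(
            0.3, 30.0, 20.0, "X", ki_e=1e9, ki_es=50.0, model="mixed",
            noise_frac=0.0)
        with pytest.raises(ParallelLinesError, match="uncompetitive"):
            mk.dixon_fit(grid)

    def test_noisy_median_recovery(self):
        vals = [mk.dixon_fit(mk.generate_inhibition_grid(
            0.23, 30.0, 19.5, "GDP", ki_e=41.2, noise_frac=0.03,
            seed=s))["K_IE"] for s in range(15)]
        assert np.median(vals) == pytest.approx(41.2, rel=0.10)


class TestCornishBowden:
    def test_noiseless_mixed_grid_intersects_at_minus_kies(
            self, pi_grid_exact):
        res = mk.cornish_bowden_fit(pi_grid_exact)
        assert res["K_IES"] == pytest.approx(5800.0, abs=1e-2)
        assert res["intersection_residual"] < 1e-8
        assert res["K_IES_global"] == pytest.approx(5800.0, rel=1e-6)

    def test_competitive_grid_has_unbounded_kies(self, gdp_grid_exact):
        with pytest.raises(ParallelLinesError, match="unbounded"):
            mk.cornish_bowden_fit(gdp_grid_exact)

    def test_noisy_median_recovery_within_15_percent(self):
        # parallel-pattern seeds are censored as unbounded (+inf) so the
        # median is not biased toward small estimates
        vals = []
        for s in range(101):
            g = mk.generate_inhibition_grid(
                0.41, 30.0, 8.7, "Pi", ki_e=670.0, ki_es=5800.0,
                s_list=np.array([2.5, 5.0, 7.5]),
                i_list=np.linspace(0.0, 10000.0, 5),
                noise_frac=0.03, seed=100 + s)
            try:
                vals.append(mk.cornish_bowden_fit(g)["K_IES"])
            except ParallelLinesError:
                vals.append(np.inf)
        assert np.median(vals) == pytest.approx(5800.0, rel=0.15)


class TestClassification:
    def test_printed_gdp_series_is_competitive(self):
        fits = [mk.MMFit(kcat=r["kcat"], Km=r["Km"], Vmax=r["kcat"] * 30.0,
                         inhibitor_name="GDP", inhibitor_conc=r["inhibitor"])
                for r in dissociation_mm_panel()["GDP"]]
        assert mk.classify_inhibition(fits) == "competitive"

    def test_printed_pi_series_is_mixed(self):
        fits = [mk.MMFit(kcat=r["kcat"], Km=r["Km"], Vmax=r["kcat"] * 30.0,
                         inhibitor_name="Pi", inhibitor_conc=r["inhibitor"])
                for r in dissociation_mm_panel()["Pi"]]
        assert mk.classify_inhibition(fits) == "mixed"

    def test_identical_fits_classify_as_none(self):
        fits = [mk.MMFit(kcat=0.2, Km=20.0, Vmax=6.0, inhibitor_conc=c)
                for c in (0.0, 10.0, 100.0)]
        assert mk.classify_inhibition(fits) == "none"

    def test_unordered_levels_rejected(self):
        fits = [mk.MMFit(kcat=0.2, Km=20.0, Vmax=6.0, inhibitor_conc=c)
                for c in (0.0, 100.0, 10.0)]
        with pytest.raises(ValueError):
            mk.classify_inhibition(fits)

    @pytest.mark.parametrize("pattern", ["competitive", "mixed"])
    def test_generated_grids_classified_correctly_in_95_of_100_seeds(
            self, pattern):
        hits = 0
        for seed in range(100):
            if pattern == "competitive":
                g = mk.generate_inhibition_grid(
                    0.23, 30.0, 19.5, "GDP", ki_e=41.2,
                    s_list=np.geomspace(5.0, 100.0, 5),
                    i_list=np.array([0.0, 10.0, 50.0, 80.0, 100.0]),
                    noise_frac=0.03, seed=seed)
            else:
                g = mk.generate_inhibition_grid(
                    0.41, 30.0, 8.7, "Pi", ki_e=670.0, ki_es=5800.0,
                    s_list=np.geomspace(2.5, 50.0, 5),
                    i_list=np.array([0.0, 500.0, 2000.0, 5000.0, 10000.0]),
                    noise_frac=0.03, seed=seed)
            if mk.classify_inhibition(_mm_fits(g)) == pattern:
                hits += 1
        assert hits >= 95


class TestIC50AndFractions:
    def test_competitive_ic50_from_printed_constants(self):
        # K_IE (1 + [GTP]_cell / Km) with K_IE=41.2, Km=710, GTP=5 mM
        assert mk.ic50_competitive(41.2, 710.0, 5000.0) \
            == pytest.approx(331.3, abs=0.1)

    def test_competitive_ic50_limits(self):
        assert mk.ic50_competitive(41.2, 710.0, 1e-12) \
            == pytest.approx(41.2)
        assert mk.ic50_competitive(41.2, 710.0, 710.0) \
            == pytest.approx(2 * 41.2)

    def test_competitive_ic50_linear_in_kie_increasing_in_substrate(self):
        base = mk.ic50_competitive(41.2, 710.0, 5000.0)
        assert mk.ic50_competitive(82.4, 710.0, 5000.0) \
            == pytest.approx(2 * base)
        assert mk.ic50_competitive(41.2, 710.0, 6000.0) > base

    def test_mixed_ic50_both_readings(self):
        res = mk.ic50_mixed(670.0, 5800.0, 710.0, 5000.0)
        assert res["IC50"] == pytest.approx(2602.0, abs=1.0)
        assert res["IC50_textbook"] == pytest.approx(2971.0, abs=1.0)

    def test_mixed_ic50_reduces_to_competitive_limit(self):
        res = mk.ic50_mixed(670.0, 1e15, 710.0, 5000.0)
        assert res["IC50"] == pytest.approx(670.0 * 5000.0 / 710.0, rel=1e-6)

    def test_fraction_inhibited_zero_without_inhibitor(self):
        assert mk.fraction_inhibited("competitive", 0.0, 5000.0, 710.0,
                                     41.2) == 0.0

    def test_fraction_inhibited_at_cellular_gdp(self):
        f = mk.fraction_inhibited("competitive", 700.0, 5000.0, 710.0, 41.2)
        assert f == pytest.approx(0.679, abs=0.001)

    def test_mixed_fraction_saturates_at_one(self):
        f = mk.fraction_inhibited("mixed", 1e12, 5000.0, 710.0, 670.0,
                                  5800.0)
        assert f == pytest.approx(1.0, abs=1e-4)


class TestRatePercentages:
    @pytest.mark.parametrize("k_test,k_ref,of_ref,inhib", [
        (201.0, 301.0, 67, 33),   # full protein vs isolated G-domain
        (48.0, 201.0, 24, 76),    # hydrolysis at 10 mM Pi
        (5.0, 5.0, 100, 0),
    ])
    def test_printed_table_convention(self, k_test, k_ref, of_ref, inhib):
        res = mk.rate_percentages(k_test, k_ref)
        assert res["percent_of_reference"] == of_ref
        assert res["percent_inhibition"] == inhib

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mk.rate_percentages(-1.0, 10.0)
        with pytest.raises(ValueError):
            mk.rate_percentages(1.0, 0.0)
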