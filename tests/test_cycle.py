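"""Mechanistic five-step cycle: integrator, closed form, projections."""

import numpy as np
import pytest

import mnmekin as mk
from mnmekin.cycle import bateman_chain


class TestBatemanChain:
    def test_initial_condition_is_all_first_state(self):
        occ = bateman_chain([2.0, 1.0], [0.0])
        assert occ[0] == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_two_step_intermediate_peaks_at_log_rate_ratio(self):
        # chain ka=2, kb=1 min^-1: intermediate maximum at t* = ln 2 min
        t = np.linspace(0.0, 180.0, 36001)  # seconds
        occ = bateman_chain([2.0, 1.0], t)
        t_star = t[np.argmax(occ[:, 1])]
        assert t_star == pytest.approx(np.log(2.0) * 60.0, abs=0.01)

    def test_occupancies_sum_to_one_and_stay_nonnegative(self):
        t = np.linspace(0.0, 60.0, 500)
        occ = bateman_chain([201.0, 12.4, 3.0], t)
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert occ.min() > -1e-12

    def test_matches_direct_ode_integration(self):
        from scipy.integrate import solve_ivp

        rates = np.array([201.0, 12.4]) / 60.0
        t = np.array([0.0, 0.3, 0.6, 2.0, 10.0])

        def rhs(_, y):
            return [-rates[0] * y[0],
                    rates[0] * y[0] - rates[1] * y[1],
                    rates[1] * y[1]]

        sol = solve_ivp(rhs, (0, 10.0), [1.0, 0.0, 0.0], t_eval=t,
                        rtol=1e-11, atol=1e-13)
        occ = bateman_chain([201.0, 12.4], t)
        assert np.max(np.abs(occ - sol.y.T)) < 1e-6

    def test_degenerate_rates_raise_unless_perturbed(self):
        with pytest.raises(ValueError, match="degenerate"):
            bateman_chain([5.0, 5.0], [1.0])
        with pytest.warns(UserWarning, match="perturbed"):
            occ = bateman_chain([5.0, 5.0], [1.0], perturb=True)
        assert np.isfinite(occ).all()

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            bateman_chain([1.0, 0.0], [1.0])


class TestSimulateCycle:
    def test_pseudo_first_order_matches_bateman_closed_form(self, wt):
        e0, t0 = 50.0, 1e-3
        grid = np.linspace(0.0, 17.0, 150)
        ts = mk.simulate_cycle(wt, e0, t0, t_grid=grid)
        rates = [mk.effective_binding_rate(wt, e0), wt.k_dim, wt.k_hyd,
                 wt.k_diss]
        occ = bateman_chain(rates, grid)
        frac = ts.conc[["T_free", "E_T", "D_T", "D_P", "E_D"]].to_numpy() / t0
        assert np.max(np.abs(occ - frac)) < 1e-6

    def test_mass_conservation_with_products_and_inhibitors(self):
        p = mk.wt_parameters(k_pi_rel=2.0)  # finite release branch
        ctx = mk.InhibitorContext(gdp_conc=50.0, pi_conc=1000.0)
        ts = mk.simulate_cycle(p, 2.5, 2.0, ctx,
                               np.linspace(0.0, 60.0, 200))
        assert np.max(np.abs(ts.enzyme_total() - 2.5)) < 1e-6 * 2.5
        assert np.max(np.abs(ts.gamma_phosphate_total() - 2.0)) < 1e-6 * 2.0
        assert np.max(np.abs(ts.nucleotide_total() - 2.0)) < 1e-6 * 2.0
        assert (ts.conc.to_numpy() > -1e-12).all()

    def test_wt_mant_rises_then_decays_to_gdp_level(self, wt_mant):
        i_peak = np.argmax(wt_mant.signal)
        assert wt_mant.time[i_peak] < 0.5
        assert wt_mant.signal[i_peak] == pytest.approx(0.15, abs=0.01)
        assert wt_mant.signal[-1] == pytest.approx(0.10, abs=0.01)

    def test_no_hydrolysis_gives_dimer_plateau(self):
        # enzyme excess so the binding step terminates exponentially
        p = mk.wt_parameters(k_hyd=0.0)
        ts = mk.simulate_cycle(p, 50.0, 0.5,
                               t_grid=np.linspace(0.0, 17.0, 300))
        d_t = ts.conc["D_T"].to_numpy()
        late = ts.time > 2.0
        assert np.ptp(d_t[late]) < 1e-6  # plateau
        quench = mk.project_observable(ts, "quench").signal
        assert np.ptp(quench[late]) < 1e-4  # %GTP constant
        assert ts.conc["E_D"].to_numpy().max() < 1e-9

    def test_gdp_dead_end_pool_reported_and_slows_binding(self, wt):
        ctx = mk.InhibitorContext(gdp_conc=41.2)  # equal to K_IE_gdp
        grid = np.linspace(0.0, 0.2, 80)
        inhibited = mk.simulate_cycle(wt, 2.5, 2.5, ctx, grid)
        free = mk.simulate_cycle(wt, 2.5, 2.5, None, grid)
        assert inhibited.conc["E_I"].iloc[0] == pytest.approx(1.25, rel=1e-6)
        assert (inhibited.conc["T_free"].iloc[-1]
                > free.conc["T_free"].iloc[-1])

    def test_invalid_inputs_raise(self, wt):
        with pytest.raises(ValueError):
            mk.simulate_cycle(wt, 0.0, 2.5)
        with pytest.raises(ValueError):
            mk.simulate_cycle(wt, 2.5, 2.5,
                              t_grid=np.array([1.0, 2.0]))  # no t=0
        with pytest.raises(ValueError):
            mk.CycleParameters(k_hyd=-1.0)

    def test_high_pi_warns_about_atypical_fluorescence(self, wt):
        with pytest.warns(UserWarning, match="atypical"):
            mk.simulate_cycle(wt, 2.5, 2.5,
                              mk.InhibitorContext(pi_conc=5000.0),
                              np.linspace(0.0, 1.0, 30))


class TestProjections:
    def test_apo_state_has_zero_mant_signal(self, wt_mant):
        assert wt_mant.signal[0] == pytest.approx(0.0, abs=1e-9)

    def test_quench_nonincreasing_pbp_nondecreasing(self, wt_states):
        quench = mk.project_observable(wt_states, "quench").signal
        pbp = mk.project_observable(wt_states, "pbp").signal
        assert np.all(np.diff(quench) <= 1e-9)
        assert np.all(np.diff(pbp) >= -1e-9)
        assert quench[0] == pytest.approx(100.0)

    def test_quench_rate_equals_hydrolysis_when_upstream_fast(self):
        # make binding and dimerization >> hydrolysis so the quench decay
        # isolates the hydrolysis step
        p = mk.wt_parameters(k_max_bind=50000.0, k_dim=20000.0)
        ts = mk.simulate_cycle(p, 50.0, 50.0,
                               t_grid=np.linspace(0.0, 3.0, 600))
        tr = mk.project_observable(ts, "quench")
        fit = mk.fit_one_phase_decay(tr)
        assert fit.params["k"] == pytest.approx(201.0, rel=0.01)

    def test_pbp_apparent_rate_tracks_dissociation_not_hydrolysis(
            self, wt_states, wt):
        tr = mk.project_observable(wt_states, "pbp")
        fit = mk.fit_single_exponential(tr, "rise")
        k_app = fit.params["k"]
        assert k_app <= wt.k_diss * 1.05  # cannot outrun dissociation
        assert k_app > wt.k_diss * 0.7
        assert k_app < wt.k_hyd / 5.0

    def test_mant_signal_constant_while_only_hydrolysis_proceeds(self):
        # with dissociation blocked, hydrolysis D_T -> D_P continues but
        # the mant projection must not change (the lag-phase property)
        # slow hydrolysis so D_T -> D_P is still running late in the trace
        p = mk.wt_parameters(k_diss=0.0, k_hyd=5.0)
        ts = mk.simulate_cycle(p, 50.0, 0.5,
                               t_grid=np.linspace(0.0, 17.0, 500))
        sig = mk.project_observable(ts, "mant").signal
        late = ts.time > 2.0  # binding/dimerization complete
        assert np.ptp(sig[late]) < 1e-7
        # but hydrolysis is genuinely proceeding in that interval
        assert ts.conc.loc[late, "D_P"].iloc[-1] \
            > ts.conc.loc[late, "D_P"].iloc[0] + 0.1

    def test_unknown_channel_rejected(self, wt_states):
        with pytest.raises(ValueError, match="unknown channel"):
            mk.project_observable(wt_states, "absorbance")


class TestRateLaws:
    def test_effective_binding_half_saturation(self, wt):
        assert mk.effective_binding_rate(wt, wt.K_D_bind) \
            == pytest.approx(wt.k_max_bind / 2.0)

    def test_effective_binding_at_standard_concentration(self, wt):
        # k_max [E]/(K_D + [E]) at 2.5 uM with the titration parameters
        assert mk.effective_binding_rate(wt, 2.5) \
            == pytest.approx(3141.9, abs=0.5)

    def test_gdp_at_its_inhibition_constant_halves_binding(self, wt):
        ctx = mk.InhibitorContext()
        k0 = mk.effective_binding_rate(wt, 2.5, 0.0, ctx)
        k1 = mk.effective_binding_rate(wt, 2.5, ctx.K_IE_gdp, ctx)
        assert k1 == pytest.approx(k0 / 2.0)

    @pytest.mark.parametrize("model", ["competitive", "mixed"])
    def test_uninhibited_rate_reduces_to_michaelis_menten(self, model):
        v = mk.steady_state_rate(0.23, 30.0, 19.5, 19.5, 0.0, model,
                                 ki_e=41.2, ki_es=5800.0)
        assert v == pytest.approx(0.23 * 30.0 / 2.0)

    def test_mixed_rate_vanishes_at_saturating_inhibitor(self):
        i_levels = np.geomspace(1.0, 1e6 * 5800.0, 30)
        v = [mk.steady_state_rate(0.41, 30.0, 8.7, 10.0, i, "mixed",
                                  670.0, 5800.0) for i in i_levels]
        assert np.all(np.diff(v) < 0)
        assert v[-1] < 1e-6 * v[0]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            mk.steady_state_rate(1.0, 1.0, 1.0, 1.0, 0.0, "allosteric")


class TestChase:
    def test_rate_constant_and_saturating_amplitude(self, wt):
        t = np.arange(0.0, 70.0, 0.001)
        amps, rates = [], []
        for comp in (0.8, 80.0, 800.0):
            tr = mk.simulate_chase(wt, comp, 60.0, t)
            post = tr.window(60.0, 70.0)
            post = mk.Trace("fret", post.time - 60.0, post.signal)
            fit = mk.fit_single_exponential(post, "decay")
            rates.append(fit.params["k"])
            amps.append(tr.meta["amplitude"])
        assert rates[-1] == pytest.approx(300.0, rel=0.01)
        assert np.all(np.diff(amps) > 0)  # amplitude grows with competitor
        assert max(rates) / min(rates) < 1.05  # rate does not

    def test_no_competitor_means_no_signal_change(self, wt):
        t = np.linspace(0.0, 70.0, 500)
        tr = mk.simulate_chase(wt, 0.0, 60.0, t)
        assert np.ptp(tr.signal) == 0.0

    def test_negative_competitor_rejected(self, wt):
        with pytest.raises(ValueError):
            mk.simulate_chase(wt, -1.0, 60.0, np.linspace(0, 70, 100))
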