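"""Filament-surfing theory: oscillator, gamma, inner search, encounter
integral, fluxes, near-field estimate."""

import numpy as np
import pytest

import chemosurf as cs
from chemosurf.agents import ChemotaxisParams
from chemosurf.ensemble import DomainConfig
from chemosurf.field import FilamentParams
from chemosurf.theory import (
    SurfState,
    TheoryInputs,
    encounter_probability_theory,
    gamma_from_filament,
    inner_search,
    integrate_surf,
    j_out_ballistic,
    log_decrement,
    near_field_estimate,
    surf_rhs,
    theory_curve,
)

PARAMS = ChemotaxisParams(v_h=160e-6, v_phi=400e-6, c_b=1e-8)


def make_fp(c0=1e-6, k=350.0, sigma=3.3e-4, a_y=1.0):
    return FilamentParams(
        c0=c0, k=k, a_y=a_y,
        x_nodes=np.array([0.0, 1.0]),
        sigma_nodes=np.array([sigma, sigma]),
        y0_nodes=np.array([0.0, 0.0]),
    )


class TestSurfOscillator:
    def test_centerline_fixed_point(self):
        assert surf_rhs(SurfState(0.0, 0.0), gamma=0.2) == 0.0

    def test_unit_speed_manifold(self):
        assert surf_rhs(SurfState(0.5, 1.0), gamma=0.2) == 0.0
        assert surf_rhs(SurfState(0.5, -1.0), gamma=0.2) == 0.0

    @pytest.mark.parametrize("gamma", [0.05, 0.1, 0.2])
    def test_log_decrement_pi_gamma(self, gamma):
        # small amplitude, toward-egg: damped oscillator with decrement pi*gamma
        t, Y, _ = integrate_surf(0.3, 0.0, gamma, 60.0)
        d = log_decrement(t, Y)
        assert abs(d - np.pi * gamma) < 0.05 * np.pi * gamma

    def test_away_from_egg_amplifies(self):
        t, Y, _ = integrate_surf(0.1, 0.0, 0.1, 40.0, direction="away-from-egg")
        assert np.abs(Y[-500:]).max() > np.abs(Y[:500]).max()

    def test_dimmer_slows_oscillation(self):
        _, Y_full, _ = integrate_surf(0.3, 0.0, 0.0, 20.0, dimmer=1.0)
        _, Y_dim, _ = integrate_surf(0.3, 0.0, 0.0, 20.0, dimmer=0.25)
        # half the frequency: first zero crossing twice as late
        z_full = np.argmax(Y_full < 0)
        z_dim = np.argmax(Y_dim < 0)
        assert z_dim > 1.7 * z_full


class TestGamma:
    def test_vanishes_without_chemotaxis(self):
        p = ChemotaxisParams(v_h=160e-6, v_phi=0.0, c_b=1e-8)
        assert gamma_from_filament(make_fp(), p) == 0.0

    def test_monotonicity(self):
        g0 = gamma_from_filament(make_fp(), PARAMS)
        assert gamma_from_filament(make_fp(k=700.0), PARAMS) > g0  # shorter
        assert gamma_from_filament(make_fp(sigma=1e-4), PARAMS) < g0  # thinner
        p2 = ChemotaxisParams(v_h=160e-6, v_phi=800e-6, c_b=1e-8)
        assert gamma_from_filament(make_fp(), p2) > g0

    def test_decreases_along_alpha_sweep(self, fig2_src, fig2_params):
        gammas = []
        for a in (0.05, 0.1, 0.2, 0.4):
            fp = cs.fit_filament(fig2_src, cs.ShearFlow(alpha=a), fig2_src.t_release)
            gammas.append(gamma_from_filament(fp, fig2_params))
        assert np.all(np.diff(gammas) < 0)

    def test_calibrated_gamma_predicts_other_alpha(self, fig2_src, fig2_params,
                                                   fig2_field_01):
        # calibrate K at alpha = 0.1, check the damping at alpha = 0.2 without
        # re-fitting (30% contract)
        fl1 = cs.ShearFlow(alpha=0.1)
        fp1 = cs.fit_filament(fig2_field_01, fl1, fig2_src.t_release)
        _, K = cs.calibrate_gamma(fig2_field_01, fp1, fig2_params, fl1, x_start=5e-3)
        fl2 = cs.ShearFlow(alpha=0.2)
        fp2 = cs.fit_filament(fig2_src, fl2, fig2_src.t_release)
        g_pred = gamma_from_filament(fp2, fig2_params, K=K)
        field2 = cs.tabulate_field(fig2_src, fl2, fig2_src.t_release)
        g_meas, _ = cs.calibrate_gamma(field2, fp2, fig2_params, fl2, x_start=8e-3)
        assert abs(g_pred - g_meas) < 0.3 * g_meas

    def test_degenerate_filament_raises(self):
        fp = make_fp()
        fp.k = 0.0
        with pytest.raises(ValueError):
            gamma_from_filament(fp, PARAMS)


class TestInnerSearch:
    def test_beyond_tip_zero(self):
        fp = make_fp()
        p, _ = inner_search(1.0, fp, PARAMS, t_max=360.0, mode="criterion")
        assert p == 0.0

    def test_too_far_to_surf_in_time(self):
        fp = make_fp(k=10.0)  # long filament
        p_near, t_near = inner_search(1e-3, fp, PARAMS, t_max=360.0)
        p_far, _ = inner_search(0.3, fp, PARAMS, t_max=360.0)
        assert p_near == 1.0 and t_near < 360.0
        assert p_far == 0.0

    def test_too_thin_for_first_turn(self):
        p_weak = ChemotaxisParams(v_h=160e-6, v_phi=1e-6, c_b=1e-8)
        fp = make_fp()
        p, _ = inner_search(1e-3, fp, p_weak, t_max=1e9, mode="criterion")
        assert p == 0.0

    def test_montecarlo_entry_at_source(self, fig2_src, fig2_params, fig2_field_01):
        fl = cs.ShearFlow(alpha=0.1)
        fp = cs.fit_filament(fig2_field_01, fl, fig2_src.t_release)
        p, t_in = inner_search(
            1.5e-3, fp, fig2_params, t_max=360.0, mode="montecarlo",
            field=fig2_field_01, flow=fl, r_egg=fig2_src.r_egg, n=100,
            rng=np.random.default_rng(0),
        )
        assert p > 0.6
        assert t_in < 120.0

    def test_montecarlo_nonincreasing_in_x(self, fig2_src, fig2_params, fig2_field_01):
        fl = cs.ShearFlow(alpha=0.1)
        fp = cs.fit_filament(fig2_field_01, fl, fig2_src.t_release)
        ps = []
        for x in (2e-3, 30e-3):
            p, _ = inner_search(
                x, fp, fig2_params, t_max=360.0, mode="montecarlo",
                field=fig2_field_01, flow=fl, r_egg=fig2_src.r_egg, n=100,
                rng=np.random.default_rng(1),
            )
            ps.append(p)
        assert ps[1] <= ps[0] + 0.15


class TestEncounterIntegral:
    CFG = DomainConfig(rho_egg=1000.0, r_egg=50e-6, t_max=360.0, n_sperm=10)

    def test_zero_p_in_gives_zero(self):
        ti = TheoryInputs(fp=make_fp(), cfg=self.CFG, params=PARAMS, j_out=0.04)
        P = encounter_probability_theory(ti, p_in_fn=lambda x: (0.0, np.nan))
        assert P == 0.0

    def test_constant_integrand_closed_form(self):
        # p_in = 1, t_in = 0, A and S ~ constant over the domain:
        # P = 2 r_max (A rho_egg + S j_out t_max)
        fp = make_fp(c0=1.0, k=1e-6)  # L ~ constant over |x| <= r_max
        j = 0.04
        ti = TheoryInputs(fp=fp, cfg=self.CFG, params=PARAMS, j_out=j)
        P = encounter_probability_theory(ti, p_in_fn=lambda x: (1.0, 0.0))
        g = cs.level_set_geometry(0.5 * self.CFG.r_max, fp, PARAMS.c_b)
        P_exact = 2 * self.CFG.r_max * (
            g.A * self.CFG.rho_egg + g.S * j * self.CFG.t_max
        )
        np.testing.assert_allclose(P, P_exact, rtol=0.01)

    def test_resident_term_only_when_no_flux(self):
        fp = make_fp(c0=1.0, k=1e-6)
        ti0 = TheoryInputs(fp=fp, cfg=self.CFG, params=PARAMS, j_out=0.0)
        P0 = encounter_probability_theory(ti0, p_in_fn=lambda x: (1.0, 0.0))
        g = cs.level_set_geometry(0.5 * self.CFG.r_max, fp, PARAMS.c_b)
        np.testing.assert_allclose(P0, 2 * self.CFG.r_max * g.A * self.CFG.rho_egg,
                                   rtol=0.01)

    def test_clipped_to_unit_interval(self):
        fp = make_fp(c0=1.0, k=1e-6)
        ti = TheoryInputs(fp=fp, cfg=self.CFG, params=PARAMS, j_out=1e9)
        P = encounter_probability_theory(ti, p_in_fn=lambda x: (1.0, 0.0))
        assert P == 1.0

    def test_theory_curve_has_interior_maximum(self, fig2, fig2_src, fig2_params):
        cfg = fig2.domain(seed=0)
        tab = theory_curve(
            [0.03, 0.06, 0.1, 0.15, 0.2, 0.3, 0.45, 0.9],
            fig2_src, cfg, fig2_params,
        )
        P = tab["P_theory"].to_numpy()
        i = int(np.argmax(P))
        assert 0 < i < len(P) - 1
        assert 0.05 <= tab["alpha"][i] <= 0.45

    def test_chemotactic_volume_monotone_in_alpha(self, fig2_src, fig2_params):
        cfg = DomainConfig(rho_egg=1000.0, r_egg=50e-6, t_max=360.0, n_sperm=10)
        tab = theory_curve([0.05, 0.1, 0.2, 0.4], fig2_src, cfg, fig2_params)
        assert np.all(np.diff(tab["V_tot"]) > 0)


class TestFluxes:
    def test_ballistic_flux_arithmetic(self):
        np.testing.assert_allclose(j_out_ballistic(1000.0, 160e-6), 0.04, rtol=1e-12)
        assert j_out_ballistic(0.0, 1e-4) == 0.0

    def test_fit_j_out_recovers_scale(self):
        import pandas as pd

        theory_tab = pd.DataFrame(dict(alpha=[0.1, 0.2], P_theory=[1e-3, 2e-3]))
        sim_tab = pd.DataFrame(
            dict(alpha=[0.1, 0.2], P=[1.5e-3, 3e-3], sd=[1e-4, 1e-4])
        )
        j = cs.fit_j_out(theory_tab, sim_tab, j_ref=0.04)
        np.testing.assert_allclose(j, 0.06, rtol=1e-6)


class TestNearField:
    def test_high_background_decreasing_curve(self):
        sc = cs.load_scenario("fig3_rufescens")
        tab = near_field_estimate(
            sc.source(), sc.chemotaxis(), sc.domain(), [0.1, 0.3, 1.0, 3.0, 10.0]
        )
        assert np.all(np.diff(tab["R_c"]) <= 1e-12)
        assert np.all(np.diff(tab["P_enc"]) <= 1e-12)

    def test_infinite_background_gives_ballistic_baseline(self):
        sc = cs.load_scenario("fig3_rufescens")
        src = sc.source()
        src.c_bg = 1.0  # absurdly high background: chemotaxis useless
        cfg = sc.domain()
        tab = near_field_estimate(src, sc.chemotaxis(), cfg, [0.5])
        params = sc.chemotaxis()
        q = np.pi * cfg.r_egg**2 * params.v_h * cfg.rho_egg
        np.testing.assert_allclose(
            tab["P_enc"][0], 1 - np.exp(-q * cfg.t_max), rtol=1e-9
        )
        np.testing.assert_allclose(tab["R_c"][0], cfg.r_egg, rtol=1e-6)
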