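"""Chemoattractant field: propagator moments, quadrature oracles,
tabulation, filament fit, level-set geometry."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

from chemosurf.field import (
    FilamentParams,
    SourceParams,
    concentration,
    concentration_gradient,
    fit_filament,
    level_set_geometry,
    point_release_moments,
    tabulate_field,
    total_chemotactic_volume,
)
from chemosurf.flow import ShearFlow

SRC = SourceParams(Qdot=0.46e-15 / 60, D=239e-12, t_release=360.0, r_egg=50e-6)


class TestMoments:
    def test_still_water_isotropic(self):
        _, C = point_release_moments(100.0, ShearFlow(alpha=0.0), SRC.D)
        np.testing.assert_allclose(C, 2 * SRC.D * 100.0 * np.eye(3), rtol=1e-14)

    def test_closed_form_matches_moment_ode(self):
        fl = ShearFlow(alpha=0.13)
        A = fl.gradient_tensor()

        def rhs(t, y):
            C = y.reshape(3, 3)
            return (A @ C + C @ A.T + 2 * SRC.D * np.eye(3)).ravel()

        for tau in (1.0, 40.0, 300.0):
            sol = solve_ivp(rhs, (0, tau), np.zeros(9), rtol=1e-12, atol=1e-24)
            _, C = point_release_moments(tau, fl, SRC.D)
            np.testing.assert_allclose(
                sol.y[:, -1].reshape(3, 3), C, rtol=1e-9, atol=1e-25
            )

    def test_determinant_closed_form(self):
        alpha, tau = 0.3, 120.0
        _, C = point_release_moments(tau, ShearFlow(alpha=alpha), SRC.D)
        det_exp = (2 * SRC.D * tau) ** 3 * (1 + alpha**2 * tau**2 / 12)
        np.testing.assert_allclose(np.linalg.det(C), det_exp, rtol=1e-12)

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            point_release_moments(-1.0, ShearFlow(alpha=0.1), SRC.D)

    def test_unsteady_zero_drot_matches_steady(self):
        fl_u = ShearFlow(alpha=0.2, unsteady=True, D_rot=0.0, seed=0)
        fl_s = ShearFlow(alpha=0.2)
        _, Cu = point_release_moments(50.0, fl_u, SRC.D)
        _, Cs = point_release_moments(50.0, fl_s, SRC.D)
        np.testing.assert_allclose(Cu, Cs, rtol=1e-12)


class TestConcentration:
    def test_zero_release_is_background(self):
        src = SourceParams(Qdot=0.0, D=SRC.D, t_release=100.0, c_bg=3.5e-6)
        fl = ShearFlow(alpha=0.2)
        pts = np.array([[1e-3, 0, 0], [0, 2e-3, 1e-3]])
        np.testing.assert_allclose(concentration(pts, 100.0, src, fl), 3.5e-6)

    @pytest.mark.parametrize("method", ["adaptive", "fixed"])
    def test_still_water_erfc_oracle(self, method):
        # continuous point release: c = Q/(4 pi D r) erfc(r / sqrt(4 D t))
        fl = ShearFlow(alpha=0.0)
        t = SRC.t_release
        rs = np.array([2 * SRC.r_egg, 5e-4, 1e-3, 1.5e-3])
        for r in rs:
            c = concentration(np.array([r, 0.0, 0.0]), t, SRC, fl, method=method)
            c_exact = SRC.Qdot / (4 * np.pi * SRC.D * r) * erfc(
                r / np.sqrt(4 * SRC.D * t)
            )
            assert abs(c - c_exact) < 1e-5 * c_exact

    def test_gradient_matches_finite_differences(self):
        fl = ShearFlow(alpha=0.1)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1, 1, size=(40, 3)) * [4e-3, 1e-3, 1e-3]
        pts = pts[np.linalg.norm(pts, axis=1) > 2 * SRC.r_egg][:25]
        g = concentration_gradient(pts, 360.0, SRC, fl, method="fixed")
        h = 2e-7
        for j in range(3):
            d = np.zeros(3)
            d[j] = h
            fd = (
                concentration(pts + d, 360.0, SRC, fl, method="fixed")
                - concentration(pts - d, 360.0, SRC, fl, method="fixed")
            ) / (2 * h)
            scale = np.abs(g).max()
            np.testing.assert_allclose(g[:, j], fd, atol=1e-4 * scale)

    def test_point_symmetry(self):
        # c(x, y, z) = c(-x, -y, z) and c even in z
        fl = ShearFlow(alpha=0.2)
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, size=(20, 3)) * [5e-3, 1.5e-3, 1.5e-3]
        c1 = concentration(pts, 360.0, SRC, fl, method="fixed")
        c2 = concentration(pts * [-1, -1, 1], 360.0, SRC, fl, method="fixed")
        c3 = concentration(pts * [1, 1, -1], 360.0, SRC, fl, method="fixed")
        np.testing.assert_allclose(c1, c2, rtol=1e-10)
        np.testing.assert_allclose(c1, c3, rtol=1e-10)

    def test_inside_egg_clamped_with_warning(self):
        fl = ShearFlow(alpha=0.0)
        with pytest.warns(UserWarning):
            c_in = concentration(np.array([1e-5, 0, 0]), 360.0, SRC, fl)
        c_surf = concentration(np.array([SRC.r_egg, 0, 0]), 360.0, SRC, fl)
        assert np.isclose(c_in, c_surf, rtol=1e-10)

    def test_mass_conservation(self):
        # integral of (c - c_bg) over the tabulation grid = Qdot * t
        fl = ShearFlow(alpha=0.1)
        tf = tabulate_field(SRC, fl, 360.0)
        mass = np.trapezoid(
            np.trapezoid(np.trapezoid(tf.c_values, tf.zs, axis=2), tf.ys, axis=1),
            tf.xs,
        )
        np.testing.assert_allclose(mass, SRC.Qdot * 360.0, rtol=5e-3)

    def test_unsteady_concentration_reduces_to_steady(self):
        fl_u = ShearFlow(alpha=0.2, unsteady=True, D_rot=0.0, seed=0)
        fl_s = ShearFlow(alpha=0.2)
        p = np.array([2e-3, 3e-4, 1e-4])
        c_u = concentration(p, 120.0, SRC, fl_u)
        c_s = concentration(p, 120.0, SRC, fl_s)
        assert abs(c_u - c_s) < 1e-3 * c_s


@pytest.fixture(scope="module")
def tf():
    return tabulate_field(SRC, ShearFlow(alpha=0.1), 360.0)


@pytest.fixture(scope="module")
def filament_fits():
    return {
        a: fit_filament(SRC, ShearFlow(alpha=a), 360.0)
        for a in (0.05, 0.1, 0.2, 0.5)
    }


class TestTabulatedField:
    def test_validation_within_one_percent(self, tf):
        assert tf.validate(n_points=1000) < 0.01

    def test_gradient_interpolation_accuracy(self, tf):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1, 1, size=(300, 3)) * [1e-2, 2e-3, 2e-3]
        keep = np.linalg.norm(pts, axis=1) > tf.r_near
        pts = pts[keep]
        c_i, g_i = tf.evaluate(pts)
        c_d, g_d = tf._direct(pts)
        scale = np.abs(g_d).max()
        mask = c_d > 1e-3 * c_d.max()
        assert np.abs(g_i[mask] - g_d[mask]).max() < 0.05 * scale

    def test_outside_grid_is_background(self, tf):
        c, g = tf.evaluate(np.array([0.0, tf.ys[-1] * 1.5, 0.0]))
        assert c == SRC.c_bg and np.all(g == 0.0)

    def test_still_water_rotation_invariance(self):
        tf0 = tabulate_field(SRC, ShearFlow(alpha=0.0), 360.0, nx=121, nyz=101)
        rng = np.random.default_rng(7)
        d = rng.normal(size=(100, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = 8e-4
        c, _ = tf0.evaluate(r * d)
        assert (c.max() - c.min()) < 0.01 * c.mean()


class TestFilament:
    def test_axial_decay_length_proportional_to_alpha(self, filament_fits):
        fits = filament_fits
        a = np.array(sorted(fits))
        invk = np.array([1 / fits[x].k for x in a])
        slope = np.polyfit(np.log(a), np.log(invk), 1)[0]
        assert abs(slope - 1.0) < 0.15

    def test_base_concentration_inverse_in_alpha(self, filament_fits):
        fits = filament_fits
        a = np.array(sorted(fits))
        c0 = np.array([fits[x].c0 for x in a])
        slope = np.polyfit(np.log(a), np.log(c0), 1)[0]
        assert abs(slope + 1.0) < 0.15

    def test_sigma_independent_of_flow(self, filament_fits):
        sig = np.array([filament_fits[a].sigma for a in sorted(filament_fits)])
        assert sig.max() / sig.min() < 1.2

    def test_no_filament_in_still_water(self):
        with pytest.raises(ValueError):
            fit_filament(SRC, ShearFlow(alpha=0.0), 360.0)

    def test_parameter_recovery_from_synthetic_filament(self):
        # a field generated *from* the filament form is recovered to 1%
        truth = FilamentParams(
            c0=2e-6, k=350.0, a_y=1.3,
            x_nodes=np.array([1e-4, 5e-2]),
            sigma_nodes=np.array([3e-4, 3e-4]),
            y0_nodes=np.array([0.0, 0.0]),
        )

        class _Synthetic:
            src = SourceParams(Qdot=1e-18, D=239e-12, t_release=360.0, c_bg=0.0)

            def evaluate(self, pts):
                return truth.profile(np.atleast_2d(pts)), None

        fp = fit_filament(_Synthetic(), ShearFlow(alpha=0.1), 360.0,
                          x_range=(1e-3, 2e-2))
        assert abs(fp.c0 - truth.c0) < 0.01 * truth.c0
        assert abs(fp.k - truth.k) < 0.01 * truth.k
        assert abs(fp.sigma - truth.sigma) < 0.01 * truth.sigma
        assert abs(fp.a_y - truth.a_y) < 0.013 * truth.a_y


class TestLevelSet:
    FP = FilamentParams(
        c0=1e-6, k=300.0, a_y=1.0,
        x_nodes=np.array([0.0, 1.0]),
        sigma_nodes=np.array([1e-3, 1e-3]),
        y0_nodes=np.array([0.0, 0.0]),
    )

    def test_empty_above_peak(self):
        g = level_set_geometry(0.0, self.FP, c_thresh=2e-6)
        assert g.A == 0.0 and g.S == 0.0

    def test_circular_case(self):
        # a_y = 1, L = 1, sigma = 1 mm: A = 2 pi 1e-6, S = 2 pi sqrt(2) 1e-3
        fp = self.FP
        c_th = fp.c0 * np.exp(-1.0)  # L = 1 at x = 0
        g = level_set_geometry(0.0, fp, c_th)
        np.testing.assert_allclose(g.A, 2 * np.pi * 1e-6, rtol=1e-12)
        np.testing.assert_allclose(g.S, 2 * np.pi * np.sqrt(2) * 1e-3, rtol=1e-4)

    def test_matches_contour_of_sampled_field(self):
        from skimage import measure

        fp = FilamentParams(
            c0=1e-6, k=300.0, a_y=1.4,
            x_nodes=np.array([0.0, 1.0]),
            sigma_nodes=np.array([4e-4, 4e-4]),
            y0_nodes=np.array([2e-4, 2e-4]),
        )
        x, c_th = 3e-3, 1e-8
        span = 6e-3
        ys = np.linspace(-span, span, 1201) + fp.y0_at(x)
        zs = np.linspace(-span, span, 1201)
        Y, Z = np.meshgrid(ys, zs, indexing="ij")
        pts = np.stack([np.full(Y.shape, x), Y, Z], axis=-1)
        cgrid = fp.profile(pts)
        contours = measure.find_contours(cgrid, c_th)
        assert len(contours) == 1
        dy, dz = ys[1] - ys[0], zs[1] - zs[0]
        A_pix = (cgrid >= c_th).sum() * dy * dz
        cont = contours[0]
        seg = np.diff(cont, axis=0) * [dy, dz]
        S_cont = np.sum(np.linalg.norm(seg, axis=1))
        g = level_set_geometry(x, fp, c_th)
        np.testing.assert_allclose(g.A, A_pix, rtol=0.01)
        np.testing.assert_allclose(g.S, S_cont, rtol=0.01)

    def test_total_volume_closed_form(self):
        # x-independent sigma: V = 2 pi a_y sigma^2 L0^2 / k
        fp = self.FP
        c_th = 1e-9
        L0 = np.log(fp.c0 / c_th)
        V_exact = 2 * np.pi * fp.a_y * fp.sigma**2 * L0**2 / fp.k
        V_num = total_chemotactic_volume(fp, c_th)
        np.testing.assert_allclose(V_num, V_exact, rtol=1e-5)

    def test_empty_filament_zero_volume(self):
        assert total_chemotactic_volume(self.FP, c_thresh=1.0) == 0.0
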